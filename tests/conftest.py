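import numpy as np
import pandas as pd
import pytest

from heatstress import synthetic


@pytest.fixture(scope="session")
def small_config():
    return synthetic.StudyDesignConfig(seed=11)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return synthetic.default_expression_truth(
        small_config, n_features=300, n_consensus=20, n_node=40, noise_sd=0.1
    )


@pytest.fixture(scope="session")
def small_study(small_config, small_truth):
    return synthetic.generate_expression_study(small_config, small_truth)


@pytest.fixture(scope="session")
def proteome_truth():
    return synthetic.default_proteome_truth(
        n_proteins=120, n_changed=24, delta=1.0, seed=7
    )


@pytest.fixture(scope="session")
def peptide_table(proteome_truth):
    return synthetic.generate_peptide_table(proteome_truth, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_peptides():
    """Hand-built two-channel-relevant peptide table for exact median checks."""
    rows = []
    for i, (p1, p2) in enumerate(
        [(10, 20), (8, 16), (12, 24), (10, 20), (9, 18), (11, 22)]
    ):
        row = {
            "protein": "P1" if i < 3 else "P2",
            "peptide": f"pep{i}",
            "charge": 2,
            "fraction": 1 + i % 3,
            "precursor_intensity": 100.0 + i,
            "run": "run1",
        }
        for j, channel in enumerate(
            [f"reporter_{k}" for k in range(1, 9)]
        ):
            row[channel] = float(p1 if j == 0 else p2)
        rows.append(row)
    return pd.DataFrame(rows)
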