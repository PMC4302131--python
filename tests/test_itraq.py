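"""iTRAQ quantitation: correction round trip, median normalization,
rollup rules, Top3 brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from heatstress import itraq
from heatstress.util import ConfigurationError

CH = list(itraq.REPORTER_COLUMNS)


def make_table(reporters, proteins=None, peptides=None, **overrides):
    reporters = np.atleast_2d(np.asarray(reporters, dtype=float))
    n = reporters.shape[0]
    base = {
        "protein": proteins or ["P1"] * n,
        "peptide": peptides or [f"pep{i}" for i in range(n)],
        "charge": [2] * n,
        "fraction": [1] * n,
        "precursor_intensity": [100.0] * n,
        "run": ["run1"] * n,
    }
    base.update(overrides)
    df = pd.DataFrame(base)
    for j, c in enumerate(CH):
        df[c] = reporters[:, j] if reporters.shape[1] == 8 else reporters[:, 0]
    return df


# --- isotope correction ----------------------------------------------------


def test_identity_correction_is_noop(rng):
    obs = rng.uniform(10, 100, size=(5, 8))
    corrected, clamped = itraq.apply_isotope_correction(obs, np.eye(8))
    assert np.allclose(corrected, obs)
    assert not clamped.any()


def test_forward_simulated_spillover_is_inverted(rng):
    true = rng.uniform(10, 100, size=(20, 2))
    mixing = np.array([[0.9, 0.1], [0.1, 0.9]])
    observed = true @ mixing  # observed_j = sum_i true_i * M[i, j]
    corrected, clamped = itraq.apply_isotope_correction(observed, mixing)
    assert np.allclose(corrected, true)
    assert not clamped.any()


def test_singular_matrix_rejected():
    with pytest.raises(ConfigurationError, match="singular"):
        itraq.apply_isotope_correction(
            np.ones((2, 2)), np.array([[0.5, 0.5], [0.5, 0.5]])
        )
    with pytest.raises(ConfigurationError, match="sum"):
        itraq.apply_isotope_correction(np.ones((2, 2)), np.eye(2) * 1.2)


# --- normalization ----------------------------------------------------------


def test_normalize_toy_table_medians(toy_peptides):
    """Channel 1 (median 10) and the rest (median 20) equalize to 1."""
    normalized = itraq.normalize_reporters(toy_peptides)
    for c in CH:
        assert normalized[c].median() == pytest.approx(1.0)
    # relative structure within a channel is preserved
    ratio = toy_peptides[CH[0]] / toy_peptides[CH[0]].median()
    assert np.allclose(normalized[CH[0]], ratio)


def test_normalize_idempotent_and_scale_invariant(peptide_table):
    once = itraq.normalize_reporters(peptide_table)
    twice = itraq.normalize_reporters(once)
    pd.testing.assert_frame_equal(once, twice)
    scaled = peptide_table.copy()
    scaled[CH] = scaled[CH] * 37.5
    pd.testing.assert_frame_equal(
        itraq.normalize_reporters(scaled)[CH], once[CH]
    )


def test_normalize_rejects_zero_channel(toy_peptides):
    bad = toy_peptides.copy()
    bad[CH[2]] = 0.0
    with pytest.raises(ConfigurationError, match="reporter_3"):
        itraq.normalize_reporters(bad)


def test_normalize_aligns_runs(toy_peptides):
    """A run measured at 10x intensity normalizes onto the same scale."""
    other = toy_peptides.copy()
    other["run"] = "run2"
    other[CH] = other[CH] * 10
    both = itraq.normalize_reporters(pd.concat([toy_peptides, other]))
    for run in ("run1", "run2"):
        block = both[both["run"] == run]
        for c in CH:
            assert block[c].median() == pytest.approx(1.0)


# --- rollup -----------------------------------------------------------------


def test_rollup_reference_ratio_exactly_one(peptide_table):
    quant = itraq.rollup_protein_ratios(peptide_table)
    assert (quant.table["ratio_reporter_1"] == 1.0).all()


def test_rollup_threshold_examples():
    r = [100.0, 130.0] + [100.0] * 6
    quant = itraq.rollup_protein_ratios(make_table([r]))
    fold = itraq.protein_fold_changes(quant, "reporter_2")
    assert fold.loc["P1", "fold_change"] == pytest.approx(1.3)
    assert bool(fold.loc["P1", "significant"])  # boundary inclusive

    quant = itraq.rollup_protein_ratios(make_table([[100.0, 120.0] + [100.0] * 6]))
    fold = itraq.protein_fold_changes(quant, "reporter_2")
    assert not bool(fold.loc["P1", "significant"])


def test_rollup_median_of_peptide_ratios():
    rows = [[100.0, 100.0 * r] + [100.0] * 6 for r in (1.1, 1.4, 1.6)]
    quant = itraq.rollup_protein_ratios(
        make_table(rows, proteins=["P1"] * 3)
    )
    assert quant.table.loc["P1", "ratio_reporter_2"] == pytest.approx(1.4)
    assert quant.table.loc["P1", "n_peptides"] == 3


def test_rollup_skips_zero_reference_protein():
    rows = [[0.0] + [50.0] * 7]
    quant = itraq.rollup_protein_ratios(make_table(rows, proteins=["Pz"]))
    assert quant.skipped == ["Pz"]
    assert quant.table.empty


def test_downregulation_signed_convention():
    quant = itraq.rollup_protein_ratios(make_table([[100.0, 50.0] + [100.0] * 6]))
    fold = itraq.protein_fold_changes(quant, "reporter_2")
    assert fold.loc["P1", "fold_change"] == pytest.approx(-2.0)


# --- Top3 -------------------------------------------------------------------


def top3_bruteforce(table, min_peptides=3):
    best = {}
    for (protein, peptide), grp in table.groupby(["protein", "peptide"]):
        total = 0.0
        for _, frac_grp in grp.groupby("fraction"):
            total += frac_grp["precursor_intensity"].max()
        best.setdefault(protein, []).append(total)
    out = {}
    for protein, totals in best.items():
        if len(totals) >= min_peptides:
            out[protein] = sum(sorted(totals, reverse=True)[:3])
    return out


def test_top3_examples():
    # peptide totals [10, 8, 6, 4] -> 24
    rows = []
    for i, total in enumerate([10.0, 8.0, 6.0, 4.0]):
        rows.append({"protein": "P1", "peptide": f"pep{i}", "charge": 2,
                     "fraction": 1, "precursor_intensity": total,
                     "run": "run1"})
    # one peptide seen twice in fraction 3 (50, 70) and once in fraction 4 (20)
    for fraction, intensity in [(3, 50.0), (3, 70.0), (4, 20.0)]:
        rows.append({"protein": "P2", "peptide": "pepA", "charge": 2,
                     "fraction": fraction, "precursor_intensity": intensity,
                     "run": "run1"})
    for i in range(2):
        rows.append({"protein": "P2", "peptide": f"pepB{i}", "charge": 2,
                     "fraction": 1, "precursor_intensity": 5.0, "run": "run1"})
    # a two-peptide protein must be omitted
    for i in range(2):
        rows.append({"protein": "P3", "peptide": f"pep{i}", "charge": 2,
                     "fraction": 1, "precursor_intensity": 100.0,
                     "run": "run1"})
    table = pd.DataFrame(rows)
    for c in CH:
        table[c] = 1.0
    top3 = itraq.top3_abundance(table)
    assert top3["P1"] == pytest.approx(24.0)
    assert top3["P2"] == pytest.approx(90.0 + 10.0)
    assert "P3" not in top3.index


def test_top3_matches_bruteforce_on_random_tables(rng):
    for _ in range(10):
        n = int(rng.integers(20, 80))
        table = pd.DataFrame(
            {
                "protein": rng.choice([f"P{i}" for i in range(10)], size=n),
                "peptide": rng.choice([f"pep{i}" for i in range(8)], size=n),
                "charge": rng.choice([2, 3], size=n),
                "fraction": rng.integers(1, 6, size=n),
                "precursor_intensity": rng.uniform(1, 1000, size=n),
                "run": "run1",
            }
        )
        for c in CH:
            table[c] = 1.0
        ours = itraq.top3_abundance(table)
        brute = top3_bruteforce(table)
        assert set(ours.index) == set(brute)
        for protein, value in brute.items():
            assert ours[protein] == pytest.approx(value)


def test_probability_filters():
    table = make_table(
        [[100.0] * 8] * 4,
        proteins=["P1", "P1", "P1", "P2"],
        peptides=["a", "b", "c", "d"],
    )
    table["peptide_prob"] = [0.99, 0.99, 0.90, 0.99]
    table["protein_prob"] = [1.0, 1.0, 1.0, 0.95]
    kept = itraq.filter_by_probability(table)
    assert set(kept["protein"]) == {"P1"}
    assert set(kept["peptide"]) == {"a", "b"}
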