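"""Differential expression: BH oracle, t-test oracle, filters, consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from heatstress import de
from heatstress.util import ConfigurationError


def bh_stepup_bruteforce(p):
    """O(n^2) literal step-up definition, independent of the implementation."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    for pos, i in enumerate(order):
        candidates = [
            p[order[j]] * n / (j + 1) for j in range(pos, n)
        ]
        q[i] = min(1.0, min(candidates))
    return q


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
             min_size=1, max_size=50)
)
def test_bh_matches_bruteforce_and_statsmodels(pvals):
    ours = de.benjamini_hochberg(pvals)
    brute = bh_stepup_bruteforce(pvals)
    assert np.allclose(ours, brute, atol=1e-12)
    sm = multipletests(pvals, method="fdr_bh")[1]
    assert np.allclose(ours, sm, atol=1e-12)


def test_bh_examples():
    assert np.allclose(
        de.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
    )
    assert de.benjamini_hochberg([0.5]) == pytest.approx([0.5])
    assert np.allclose(de.benjamini_hochberg([0.2, 0.2, 0.2]), [0.2] * 3)
    with pytest.raises(ValueError):
        de.benjamini_hochberg([0.5, 1.2])


def test_bh_monotone_over_sorted_p(rng):
    p = rng.uniform(size=200)
    q = de.benjamini_hochberg(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()


def test_plier_offset_transform():
    assert de.plier_offset_transform(np.array([0.0]), 16)[0] == 16
    assert de.plier_offset_transform(np.array([16.0]), 16)[0] == 32
    x = np.array([1.0, 2.0])
    assert np.array_equal(de.plier_offset_transform(x, 0), x)
    with pytest.raises(ValueError):
        de.plier_offset_transform(np.array([-1.0]))


def _study_from_matrix(values, organ="heart", time="TcMax"):
    n = values.shape[1] // 2
    design = pd.DataFrame(
        {
            "organ": organ,
            "time": time,
            "arm": [de.HEAT_ARM] * n + [de.CONTROL_ARM] * n,
            "animal": [f"a{i}" for i in range(2 * n)],
            "injured": False,
        },
        index=values.columns,
    )
    return de.ExpressionStudy(values=values, design=design)


def test_variance_filter_rules(rng):
    # forced examples: variances [1,2,3,4] -> keep top 2; ties keep all
    base = rng.normal(size=8)
    rows = {f"f{v}": base * np.sqrt(v) for v in (1, 2, 3, 4)}
    values = pd.DataFrame(rows).T
    values.columns = [f"s{i}" for i in range(8)]
    kept = de.variance_filter(values + 100, log2=False)
    assert set(kept) == {"f3", "f4"}

    tied = pd.DataFrame(np.tile(base, (4, 1)), index=list("abcd"))
    assert len(de.variance_filter(tied + 100, log2=False)) == 4

    big = pd.DataFrame(rng.normal(size=(1000, 6)))
    kept = de.variance_filter(big, log2=False)
    variances = big.var(axis=1)
    expected = set(variances.sort_values(ascending=False).index[:500])
    assert set(kept) == expected and len(kept) == 500


def test_variance_filter_constant_matrix_warns():
    values = pd.DataFrame(np.ones((3, 4)), index=list("abc"))
    with pytest.warns(UserWarning):
        kept = de.variance_filter(values)
    assert len(kept) == 3


def test_fold_change_sign_convention(rng):
    noise = rng.normal(0, 0.01, size=(2, 12))
    log2 = np.array([[2.0] * 6 + [1.0] * 6, [0.0] * 6 + [1.0] * 6]) + noise
    values = pd.DataFrame(
        np.exp2(log2), index=["up", "down"],
        columns=[f"s{i}" for i in range(12)],
    )
    records = de.differential_expression(_study_from_matrix(values), "heart", "TcMax")
    assert records.loc["up", "fold_change"] == pytest.approx(2.0, rel=0.05)
    assert records.loc["down", "fold_change"] == pytest.approx(-2.0, rel=0.05)


def test_single_time_p_equals_pooled_t_test(rng):
    values = pd.DataFrame(
        np.exp2(rng.normal(8, 1, size=(30, 12))),
        index=[f"f{i}" for i in range(30)],
        columns=[f"s{i}" for i in range(12)],
    )
    records = de.differential_expression(_study_from_matrix(values), "heart", "TcMax")
    log2 = np.log2(values.to_numpy())
    expected = stats.ttest_ind(log2[:, :6], log2[:, 6:], axis=1, equal_var=True)
    assert np.allclose(records["p"], expected.pvalue, atol=1e-12)


def test_degenerate_zero_variance_features():
    values = pd.DataFrame(
        [[4.0] * 6 + [2.0] * 6, [3.0] * 12],
        index=["diff", "same"],
        columns=[f"s{i}" for i in range(12)],
    )
    records = de.differential_expression(_study_from_matrix(values), "heart", "TcMax")
    assert records.loc["diff", "degenerate"] and records.loc["diff", "p"] == 0.0
    assert records.loc["same", "degenerate"] and records.loc["same", "p"] == 1.0
    assert records.loc["diff", "fold_change"] == pytest.approx(2.0)


def test_two_factor_contrast_uses_requested_time(small_study, small_truth):
    """Planted TcMax effects are called at TcMax but not at 24 h."""
    organ = "heart"
    planted = list(small_truth.consensus_fold_changes)
    at_tcmax = de.differential_expression(small_study.organ_subset(organ), organ, "TcMax")
    at_24h = de.differential_expression(small_study.organ_subset(organ), organ, "24h")
    assert at_tcmax.loc[planted, "significant"].all()
    assert not at_24h.loc[planted, "significant"].any()


def test_consensus_intersection_rules():
    def rec(sig):
        return pd.DataFrame(
            {
                "fold_change": [2.5] * len(sig),
                "significant": list(sig.values()),
            },
            index=list(sig),
        )

    organs = {
        "heart": rec({"a": True, "b": True, "c": True}),
        "liver": rec({"a": True, "b": True, "c": False}),
        "lung": rec({"a": True, "b": True, "c": True}),
        "kidney": rec({"a": True, "b": True, "c": False}),
    }
    result = de.consensus_intersection(organs, "TcMax")
    assert result.features == ["a", "b"]
    # order invariance
    reordered = dict(reversed(list(organs.items())))
    assert de.consensus_intersection(reordered, "TcMax").features == ["a", "b"]
    # empty organ list -> empty consensus
    organs["lung"] = rec({"a": False, "b": False, "c": False})
    assert de.consensus_intersection(organs, "TcMax").features == []
    with pytest.raises(ConfigurationError):
        de.consensus_intersection(organs, "TcMax", organs=["heart", "spleen"])


def test_null_study_controls_false_discoveries():
    """Under the global null, q < 0.05 calls stay near the nominal rate."""
    from heatstress import synthetic

    rates = []
    for seed in range(20):
        config = synthetic.StudyDesignConfig(
            organs=("heart",), time_points=("TcMax",), seed=100 + seed
        )
        truth = synthetic.ExpressionTruth(
            n_features=200, consensus_fold_changes={}, noise_sd=0.2
        )
        study = synthetic.generate_expression_study(config, truth)
        records = de.differential_expression(study, "heart", "TcMax")
        rates.append(np.mean(records["q"] < 0.05))
        assert not records["significant"].any()
    se = np.sqrt(0.05 * 0.95 / (20 * 200))
    assert np.mean(rates) <= 0.05 + 3 * se
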