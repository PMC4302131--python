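"""Protein supersaturation scoring and changed-vs-unchanged contrasts.

A protein's supersaturation score is its aggregation propensity (Z_agg,
supplied externally) plus the log10 of its cellular concentration; scores
are median-corrected across all detected proteins, so sigma_f > 0 marks
proteins supersaturated relative to the detected proteome. Concentrations
come from a log-log calibrant regression of Top3 intensity onto known
concentrations. Proteins are grouped by the +/-1.3-fold changed and
<+/-1.1-fold unchanged rules (the gap in between is an explicit "excluded"
group) and the groups are contrasted by one-way ANOVA with Bonferroni
post-hoc pairwise tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from heatstress.util import ConfigurationError

logger = logging.getLogger(__name__)

CHANGED = "changed"
UNCHANGED = "unchanged"
EXCLUDED = "excluded"


@dataclass
class CalibrationModel:
    """log10(intensity) -> log10(concentration) regression."""

    slope: float
    intercept: float
    residual_sd: float
    calibrant_ids: list[str]

    @property
    def n_calibrants(self) -> int:
        return len(self.calibrant_ids)


def fit_calibration(
    top3: Mapping[str, float] | pd.Series,
    calibrants: Mapping[str, float] | pd.Series,
    method: str = "ols",
) -> CalibrationModel:
    """Fit the calibrant regression on (log10 intensity, log10 concentration).

    ``method`` is "ols" (default) or "theil-sen" for a robust slope. At
    least 3 calibrants must be present in the Top3 mapping.
    """
    top3 = pd.Series(dict(top3)) if not isinstance(top3, pd.Series) else top3
    cal = pd.Series(dict(calibrants)) if not isinstance(calibrants, pd.Series) \
        else calibrants
    present = [p for p in cal.index if p in top3.index and top3[p] > 0]
    missing = [p for p in cal.index if p not in present]
    if len(present) < 3:
        raise ConfigurationError(
            f"need >= 3 calibrants with Top3 intensities; missing {missing}"
        )
    x = np.log10(top3[present].to_numpy(dtype=float))
    y = np.log10(cal[present].to_numpy(dtype=float))
    if method == "ols":
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
    elif method == "theil-sen":
        slope, intercept, *_ = stats.theilslopes(y, x)
        slope, intercept = float(slope), float(intercept)
    else:
        raise ConfigurationError(f"unknown calibration method {method!r}")
    if not math.isfinite(slope):
        raise ConfigurationError("calibration slope is not finite")
    resid = y - (slope * x + intercept)
    residual_sd = float(np.std(resid, ddof=2)) if len(present) > 2 else 0.0
    return CalibrationModel(
        slope=slope, intercept=intercept, residual_sd=residual_sd,
        calibrant_ids=list(present),
    )


def infer_concentrations(
    model: CalibrationModel, top3: Mapping[str, float] | pd.Series
) -> pd.Series:
    """Concentration c = 10^(slope * log10(I) + intercept) per protein.

    Proteins with zero or negative intensity are skipped with a logged count.
    """
    top3 = pd.Series(dict(top3)) if not isinstance(top3, pd.Series) else top3
    positive = top3[top3 > 0]
    if len(positive) < len(top3):
        logger.warning("skipped %d proteins with non-positive Top3 intensity",
                       len(top3) - len(positive))
    conc = 10.0 ** (model.slope * np.log10(positive.to_numpy(dtype=float))
                    + model.intercept)
    return pd.Series(conc, index=positive.index, name="concentration")


def assign_groups(
    fold_changes: Mapping[str, float] | pd.Series,
    changed_threshold: float = 1.3,
    unchanged_threshold: float = 1.1,
) -> pd.Series:
    """Label proteins changed (|FC| >= 1.3), unchanged (|FC| <= 1.1) or excluded."""
    fc = pd.Series(dict(fold_changes)) if not isinstance(fold_changes, pd.Series) \
        else fold_changes
    mag = fc.abs()
    group = pd.Series(EXCLUDED, index=fc.index, name="group")
    group[mag >= changed_threshold] = CHANGED
    group[mag <= unchanged_threshold] = UNCHANGED
    return group


def supersaturation_scores(
    z_agg: Mapping[str, float] | pd.Series,
    concentrations: Mapping[str, float] | pd.Series,
    fold_changes: Mapping[str, float] | pd.Series | None = None,
    changed_threshold: float = 1.3,
    unchanged_threshold: float = 1.1,
    log_base: float = 10.0,
    variant: str = "Z_agg",
) -> pd.DataFrame:
    """Median-corrected supersaturation scores for all detected proteins.

    sigma_raw = z_agg + log_base-log(concentration); sigma_f subtracts the
    median sigma_raw over all scored proteins, so median(sigma_f) is exactly
    zero. Proteins lacking either input are excluded with a logged count;
    group labels are attached when fold changes are supplied.
    """
    z = pd.Series(dict(z_agg)) if not isinstance(z_agg, pd.Series) else z_agg
    c = pd.Series(dict(concentrations)) if not isinstance(concentrations, pd.Series) \
        else concentrations
    shared = z.index.intersection(c.index)
    if len(shared) == 0:
        raise ConfigurationError("no proteins have both z_agg and concentration")
    dropped = len(z.index.union(c.index)) - len(shared)
    if dropped:
        logger.info("excluded %d proteins missing z_agg or concentration", dropped)
    log_c = np.log(c[shared].to_numpy(dtype=float)) / np.log(log_base)
    sigma_raw = z[shared].to_numpy(dtype=float) + log_c
    sigma_f = sigma_raw - np.median(sigma_raw)
    out = pd.DataFrame(
        {
            "z_agg": z[shared],
            "variant": variant,
            "concentration": c[shared],
            "sigma_raw": sigma_raw,
            "sigma_f": sigma_f,
        },
        index=shared,
    )
    if fold_changes is not None:
        groups = assign_groups(fold_changes, changed_threshold, unchanged_threshold)
        out["group"] = groups.reindex(shared).fillna(EXCLUDED)
    out.index.name = "protein"
    return out


@dataclass
class GroupComparison:
    """Per-group mean +/- SEM of sigma_f with ANOVA and Bonferroni contrasts."""

    means: dict[str, float]
    sems: dict[str, float]
    sizes: dict[str, int]
    f_statistic: float
    p_value: float
    pairwise_p: dict[tuple[str, str], float]  # Bonferroni-adjusted
    skipped_groups: list[str]


def compare_groups(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """One-way ANOVA across score groups with Bonferroni pairwise t-tests.

    Groups with fewer than 2 observations are skipped with a warning; at
    least two usable groups are required. With exactly two groups the ANOVA
    F equals the squared pooled-variance t statistic.
    """
    usable = {}
    skipped = []
    for label, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            skipped.append(label)
            logger.warning("group %r has n=%d < 2; skipped", label, arr.size)
            continue
        usable[label] = arr
    if len(usable) < 2:
        raise ConfigurationError("need >= 2 groups with n >= 2 to compare")
    labels = list(usable)
    f_stat, p = stats.f_oneway(*(usable[g] for g in labels))
    # guard against tiny negative F (and the resulting nan p) from roundoff
    f_stat = max(float(f_stat), 0.0)
    if np.isnan(p):
        dfn = len(labels) - 1
        dfd = sum(v.size for v in usable.values()) - len(labels)
        p = float(stats.f.sf(f_stat, dfn, dfd))
    n_pairs = len(labels) * (len(labels) - 1) // 2
    pairwise = {}
    for a, b in combinations(labels, 2):
        t_p = stats.ttest_ind(usable[a], usable[b], equal_var=True).pvalue
        pairwise[(a, b)] = min(1.0, float(t_p) * n_pairs)
    return GroupComparison(
        means={g: float(v.mean()) for g, v in usable.items()},
        sems={g: float(v.std(ddof=1) / np.sqrt(v.size)) for g, v in usable.items()},
        sizes={g: int(v.size) for g, v in usable.items()},
        f_statistic=float(f_stat),
        p_value=float(p),
        pairwise_p=pairwise,
        skipped_groups=skipped,
    )
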