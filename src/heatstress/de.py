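"""Per-organ differential expression and the multi-organ consensus set.

The modeling path mirrors a classical microarray workflow: a
variance-stabilizing offset on linear intensities, log2 transform, a
non-specific variance pre-filter that discards the low-variance half of the
features, a per-feature two-factor (arm x time, with interaction) linear
model, a heat-vs-control contrast at each time point, Benjamini-Hochberg
multiplicity correction, and a joint fold-change + FDR significance rule.
Features significant in every organ at a time point form the consensus set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from heatstress.util import ConfigurationError, signed_ratio

HEAT_ARM = "heat"
CONTROL_ARM = "control"

DESIGN_COLUMNS = ("organ", "time", "arm", "animal", "injured")


@dataclass
class ExpressionStudy:
    """A positive feature x sample matrix plus its sample design table.

    ``values`` holds linear-scale expression (rows = features, columns =
    sample ids); ``design`` is indexed by sample id with columns
    ``organ, time, arm, animal, injured``.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing:
            raise ConfigurationError(f"design table missing columns: {missing}")
        if list(self.values.columns) != list(self.design.index):
            raise ConfigurationError("value columns and design rows must match")
        vals = self.values.to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ConfigurationError("expression values must be finite and > 0")

    @property
    def organs(self) -> list[str]:
        return list(dict.fromkeys(self.design["organ"]))

    @property
    def time_points(self) -> list[str]:
        return list(dict.fromkeys(self.design["time"]))

    def organ_subset(self, organ: str) -> "ExpressionStudy":
        mask = self.design["organ"] == organ
        if not mask.any():
            raise ConfigurationError(f"no samples for organ {organ!r}")
        return ExpressionStudy(
            self.values.loc[:, mask.to_numpy()], self.design.loc[mask]
        )


@dataclass
class ConsensusSet:
    """Features significant in every organ at one time point."""

    time: str
    features: list[str]
    fold_changes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.features)


def plier_offset_transform(values, offset: float = 16.0):
    """Add a variance-stabilizing offset to non-negative linear intensities."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("intensities must be non-negative")
    out = arr + offset
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def variance_filter(values: pd.DataFrame, log2: bool = True) -> pd.Index:
    """Retain features whose variance is >= the median feature variance.

    Implements the non-specific pre-filter of dropping the low-variance half
    of the features; ties at the median are retained, so slightly more than
    half may survive. With ``log2`` (default) the variance is computed on
    log2-transformed values -- the variance-stabilized scale -- so the
    ranking reflects relative expression changes rather than baseline
    magnitude. A constant matrix (all variances zero) retains everything
    with a warning.
    """
    if values.shape[1] < 2:
        raise ConfigurationError("variance filter needs >= 2 samples")
    work = np.log2(values) if log2 else values
    variances = work.var(axis=1, ddof=1)
    if (variances == 0).all():
        warnings.warn("all features have zero variance; retaining all")
        return values.index
    median = variances.median()
    return values.index[variances >= median]


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * n / j over sorted p, mapped back to the
    input order and clipped to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_expression(
    study: ExpressionStudy,
    organ: str,
    time: str,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
    offset: float = 0.0,
) -> pd.DataFrame:
    """Heat-vs-control differential expression for one organ at one time.

    Fits, per feature, a two-factor cell-means model (arm x time with
    interaction) on log2 values over all of the organ's samples; the residual
    variance is pooled across all cells. The reported p-value tests the
    heat-vs-control contrast at the requested time point; the fold change is
    the linear-scale ratio of the (geometric) group means in the signed-ratio
    convention. Significance requires |FC| >= ``fc_threshold`` (inclusive)
    and BH-adjusted q < ``q_threshold``.

    Features with zero pooled residual variance are flagged ``degenerate``:
    their p is 0 when the contrasted means differ and 1 when they agree, so
    noiseless synthetic constructions remain exact.
    """
    sub = study.organ_subset(organ)
    design = sub.design
    if time not in set(design["time"]):
        raise ConfigurationError(f"time point {time!r} absent for organ {organ!r}")
    log2 = np.log2(sub.values.to_numpy() + offset) if offset else np.log2(
        sub.values.to_numpy()
    )

    cells = design.groupby(["time", "arm"], sort=False).indices
    for arm in (HEAT_ARM, CONTROL_ARM):
        idx = cells.get((time, arm))
        if idx is None or len(idx) < 2:
            raise ConfigurationError(
                f"need >= 2 {arm!r} samples at {time!r} for organ {organ!r}"
            )

    n_total = log2.shape[1]
    n_cells = len(cells)
    rss = np.zeros(log2.shape[0])
    means: dict[tuple[str, str], np.ndarray] = {}
    counts: dict[tuple[str, str], int] = {}
    for cell, idx in cells.items():
        block = log2[:, idx]
        m = block.mean(axis=1)
        means[cell] = m
        counts[cell] = len(idx)
        rss += ((block - m[:, None]) ** 2).sum(axis=1)

    df_resid = n_total - n_cells
    if df_resid <= 0:
        raise ConfigurationError("no residual degrees of freedom (singleton cells)")
    s2 = rss / df_resid

    m_heat = means[(time, HEAT_ARM)]
    m_ctrl = means[(time, CONTROL_ARM)]
    n_heat = counts[(time, HEAT_ARM)]
    n_ctrl = counts[(time, CONTROL_ARM)]
    diff = m_heat - m_ctrl

    degenerate = s2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2 * (1.0 / n_heat + 1.0 / n_ctrl))
        tstat = diff / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
    p[degenerate] = np.where(diff[degenerate] != 0.0, 0.0, 1.0)

    q = benjamini_hochberg(p)
    fc = signed_ratio(np.exp2(diff))
    significant = (np.abs(fc) >= fc_threshold) & (q < q_threshold)

    return pd.DataFrame(
        {
            "feature": sub.values.index,
            "organ": organ,
            "time": time,
            "fold_change": fc,
            "p": p,
            "q": q,
            "significant": significant,
            "degenerate": degenerate,
        }
    ).set_index("feature")


def consensus_intersection(
    records_by_organ: Mapping[str, pd.DataFrame],
    time: str,
    organs: Iterable[str] | None = None,
) -> ConsensusSet:
    """Intersect the significant feature ids of every organ at one time point."""
    organs = list(organs) if organs is not None else list(records_by_organ)
    missing = [o for o in organs if o not in records_by_organ]
    if missing or not organs:
        raise ConfigurationError(f"missing DE records for organs: {missing or organs}")
    sig_sets = []
    for organ in organs:
        rec = records_by_organ[organ]
        sig_sets.append(set(rec.index[rec["significant"]]))
    members = set.intersection(*sig_sets) if sig_sets else set()
    features = sorted(members)
    fc = pd.DataFrame(
        {o: records_by_organ[o].loc[features, "fold_change"] for o in organs}
    )
    return ConsensusSet(time=time, features=features, fold_changes=fc)
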