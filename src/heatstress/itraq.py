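"""iTRAQ reporter-ion quantitation: isotope correction, median
normalization, peptide-to-protein rollup, +/-1.3-fold differential calling,
and Top3 precursor-intensity abundance estimation.

The entry point is an identified-peptide table (one row per precursor
observation) with columns ``protein, peptide, charge, fraction,
precursor_intensity, reporter_1..reporter_8, run`` and optional Scaffold-style
``peptide_prob`` / ``protein_prob`` columns. Spectrum search, peptide FDR and
reporter-ion extraction happen upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from heatstress.util import ConfigurationError, signed_ratio

logger = logging.getLogger(__name__)

N_CHANNELS = 8
REPORTER_COLUMNS = tuple(f"reporter_{i}" for i in range(1, N_CHANNELS + 1))

REQUIRED_COLUMNS = (
    "protein",
    "peptide",
    "charge",
    "fraction",
    "precursor_intensity",
    "run",
)


def validate_peptide_table(
    table: pd.DataFrame, channels: Sequence[str] = REPORTER_COLUMNS
) -> None:
    missing = [c for c in (*REQUIRED_COLUMNS, *channels) if c not in table.columns]
    if missing:
        raise ConfigurationError(f"peptide table missing columns: {missing}")
    block = table[list(channels) + ["precursor_intensity"]].to_numpy()
    if np.any(block < 0) or not np.all(np.isfinite(block)):
        raise ConfigurationError("intensities must be finite and >= 0")


def filter_by_probability(
    table: pd.DataFrame,
    min_peptide_prob: float = 0.95,
    min_protein_prob: float = 0.99,
    min_peptides: int = 2,
) -> pd.DataFrame:
    """Apply Scaffold-style identification-probability filters when present.

    Rows below ``min_peptide_prob`` (column ``peptide_prob``) are dropped;
    proteins below ``min_protein_prob`` (column ``protein_prob``) or with
    fewer than ``min_peptides`` distinct surviving peptides are dropped.
    Absent columns skip the corresponding filter.
    """
    out = table
    if "peptide_prob" in out.columns:
        out = out[out["peptide_prob"] >= min_peptide_prob]
    if "protein_prob" in out.columns:
        out = out[out["protein_prob"] >= min_protein_prob]
    counts = out.groupby("protein")["peptide"].nunique()
    keep = counts.index[counts >= min_peptides]
    return out[out["protein"].isin(keep)].copy()


def apply_isotope_correction(
    reporters: pd.DataFrame | np.ndarray,
    correction: np.ndarray,
) -> tuple[pd.DataFrame | np.ndarray, np.ndarray]:
    """Invert isotope-impurity mixing of reporter channels.

    ``correction[i, j]`` is the fraction of channel i's true signal observed
    in channel j (i-Tracker convention), so observed = C.T @ true per row.
    Returns the corrected intensities and a boolean row mask flagging rows
    where negative solutions were clamped to zero.
    """
    mat = np.asarray(correction, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ConfigurationError("correction matrix must be square")
    if np.any(mat.sum(axis=1) > 1.05):
        raise ConfigurationError("correction matrix rows must sum to <= 1.05")
    obs = np.asarray(reporters, dtype=float)
    if obs.shape[-1] != mat.shape[0]:
        raise ConfigurationError(
            f"reporter width {obs.shape[-1]} != matrix size {mat.shape[0]}"
        )
    try:
        corrected = np.linalg.solve(mat.T, obs.T).T
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("correction matrix is singular") from exc
    clamped = (corrected < 0).any(axis=-1)
    corrected = np.clip(corrected, 0.0, None)
    if clamped.any():
        logger.warning("clamped negative corrected intensities in %d rows",
                       int(clamped.sum()))
    if isinstance(reporters, pd.DataFrame):
        corrected = pd.DataFrame(
            corrected, index=reporters.index, columns=reporters.columns
        )
    return corrected, clamped


def normalize_reporters(
    table: pd.DataFrame,
    channels: Sequence[str] = REPORTER_COLUMNS,
    run_col: str = "run",
) -> pd.DataFrame:
    """Median-based multiplicative normalization within and across runs.

    Within each acquisition run, every channel is scaled so its median equals
    the run's grand median (the median of its channel medians); runs are then
    scaled to a common global median, and the output is expressed relative to
    that global median -- every channel median in the output is exactly 1.
    The transform is idempotent and invariant to rescaling the entire input
    by a constant.
    """
    validate_peptide_table(table, channels)
    out = table.copy()
    arr = out[list(channels)].to_numpy(dtype=float).copy()
    positions = out.groupby(run_col).indices  # positional, robust to dup labels
    run_medians: dict[object, float] = {}
    for run, pos in positions.items():
        block = arr[pos]
        channel_medians = np.median(block, axis=0)
        zero = np.flatnonzero(channel_medians == 0)
        if zero.size:
            raise ConfigurationError(
                f"channel {channels[zero[0]]!r} has zero median in run {run!r}"
            )
        grand = float(np.median(channel_medians))
        arr[pos] = block * (grand / channel_medians)
        run_medians[run] = grand
    global_median = float(np.median(list(run_medians.values())))
    for run, pos in positions.items():
        arr[pos] *= global_median / run_medians[run]
    arr /= global_median
    out[list(channels)] = arr
    return out


@dataclass
class ProteinQuant:
    """Per-protein channel ratios relative to the reference channel."""

    table: pd.DataFrame  # index: protein; columns: ratio_<channel>, n_peptides
    reference_channel: str
    skipped: list[str]

    def ratios(self) -> pd.DataFrame:
        return self.table[[c for c in self.table.columns if c.startswith("ratio_")]]


def rollup_protein_ratios(
    table: pd.DataFrame,
    reference_channel: str = "reporter_1",
    channels: Sequence[str] = REPORTER_COLUMNS,
) -> ProteinQuant:
    """Roll peptide reporter intensities up to per-protein channel ratios.

    Each peptide observation is converted to channel ratios against the
    reference channel (normalizing the reference to a 1:1 fold change); the
    protein ratio per channel is the median over its peptide observations.
    Proteins whose reference channel is zero in every observation are
    skipped and reported in ``skipped``.
    """
    validate_peptide_table(table, channels)
    if reference_channel not in channels:
        raise ConfigurationError(f"unknown reference channel {reference_channel!r}")
    rows = {}
    skipped: list[str] = []
    for protein, grp in table.groupby("protein", sort=True):
        ref = grp[reference_channel].to_numpy(dtype=float)
        ok = ref > 0
        if not ok.any():
            skipped.append(str(protein))
            continue
        ratios = grp.loc[ok, list(channels)].to_numpy(dtype=float) / ref[ok, None]
        med = np.median(ratios, axis=0)
        row = {f"ratio_{c}": med[i] for i, c in enumerate(channels)}
        row[f"ratio_{reference_channel}"] = 1.0  # exact by construction
        row["n_peptides"] = grp["peptide"].nunique()
        rows[protein] = row
    if skipped:
        logger.warning("skipped %d proteins with all-zero reference channel",
                       len(skipped))
    quant = pd.DataFrame.from_dict(rows, orient="index")
    quant.index.name = "protein"
    return ProteinQuant(table=quant, reference_channel=reference_channel,
                        skipped=skipped)


def protein_fold_changes(
    quant: ProteinQuant,
    sample_channel: str,
    control_channel: str | None = None,
    fc_threshold: float = 1.3,
) -> pd.DataFrame:
    """Signed fold change of a sample channel vs a control, +/-1.3 rule.

    With ``control_channel`` None the comparison is against the (pooled)
    reference channel itself; otherwise the ratio of channel ratios is used
    (time-matched control convention). |FC| >= ``fc_threshold`` (inclusive)
    marks a protein as differentially expressed.
    """
    ratios = quant.table
    s = ratios[f"ratio_{sample_channel}"]
    c = (
        ratios[f"ratio_{control_channel}"]
        if control_channel is not None
        else pd.Series(1.0, index=ratios.index)
    )
    ratio = s / c
    if np.any(ratio <= 0):
        bad = ratio.index[ratio <= 0].tolist()
        raise ConfigurationError(f"non-positive channel ratios for {bad}")
    fc = signed_ratio(ratio.to_numpy())
    return pd.DataFrame(
        {
            "fold_change": fc,
            "significant": np.abs(fc) >= fc_threshold,
            "n_peptides": ratios["n_peptides"],
        },
        index=ratios.index,
    )


def peptide_totals(table: pd.DataFrame) -> pd.DataFrame:
    """Total precursor intensity per (protein, peptide).

    Within each fraction only the highest reported precursor intensity is
    kept (repeated reports, e.g. additional charge states, are redundant);
    the kept values are summed across fractions.
    """
    validate_peptide_table(table, channels=())
    per_fraction = table.groupby(["protein", "peptide", "fraction"], sort=False)[
        "precursor_intensity"
    ].max()
    return (
        per_fraction.groupby(["protein", "peptide"]).sum().rename("total").reset_index()
    )


def top3_abundance(table: pd.DataFrame, min_peptides: int = 3) -> pd.Series:
    """Top3 label-free abundance: sum of the 3 largest peptide totals.

    Proteins with fewer than ``min_peptides`` distinct peptides are omitted
    (and logged), since the Top3 estimator is undefined for them.
    """
    totals = peptide_totals(table)
    omitted = []
    values = {}
    for protein, grp in totals.groupby("protein", sort=True):
        if grp.shape[0] < min_peptides:
            omitted.append(str(protein))
            continue
        values[protein] = float(
            grp["total"].nlargest(3).sum()
        )
    if omitted:
        logger.info("top3_abundance omitted %d proteins with < %d peptides",
                    len(omitted), min_peptides)
    out = pd.Series(values, name="top3_intensity")
    out.index.name = "protein"
    return out
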