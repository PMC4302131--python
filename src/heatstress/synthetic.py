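"""Synthetic expression studies and iTRAQ peptide tables with known truth.

The generator emulates the design of a multi-organ heat-stress study in the
rat: four organs sampled at maximal core temperature (Tc,Max = 41.8 C) and
at 24 h and 48 h of recovery, six heated and six time-matched control
animals per time point, a consensus set of transcripts induced at least
two-fold in every organ at Tc,Max, and a subgroup of heated animals at 48 h
carrying coherent up- and down-regulated expression blocks that mark
histopathological cardiac injury. On the proteomics side it emits
peptide-level tables whose 8-plex reporter channels encode per-condition
protein ratios and whose precursor intensities track true concentration, so
that Top3 abundance, calibration, and supersaturation scoring can be
validated against planted ground truth.

Expression is generated on the log2 scale with Gaussian noise and
exponentiated to the linear scale, so fold-change arithmetic downstream is
exact in the noiseless limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from heatstress.de import CONTROL_ARM, HEAT_ARM, ExpressionStudy
from heatstress.itraq import REPORTER_COLUMNS
from heatstress.util import ConfigurationError

TC_MAX_CELSIUS = 41.8

DEFAULT_ORGANS = ("heart", "liver", "lung", "kidney")
DEFAULT_TIME_POINTS = ("TcMax", "24h", "48h")

#: calibrant protein ids mirroring the human homologs used for absolute scaling
CALIBRANT_IDS = ("MB", "HBB", "CKM", "MYL2", "GAPDH", "FABP3", "LDHB")


@dataclass
class StudyDesignConfig:
    """Experimental layout of a synthetic heat-stress study."""

    organs: Sequence[str] = DEFAULT_ORGANS
    time_points: Sequence[str] = DEFAULT_TIME_POINTS
    n_per_group: int = 6
    tc_max_celsius: float = TC_MAX_CELSIUS
    injured_fraction_48h: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if not (0.0 <= self.injured_fraction_48h <= 1.0):
            raise ConfigurationError("injured_fraction_48h must lie in [0, 1]")
        if not self.organs or len(set(self.organs)) != len(self.organs):
            raise ConfigurationError("organs must be non-empty and unique")
        if not self.time_points:
            raise ConfigurationError("time_points must be non-empty")


@dataclass
class ExpressionTruth:
    """Planted ground truth for a synthetic expression study.

    ``consensus_fold_changes`` maps feature id -> organ -> linear fold change
    (applied to heated samples at the first time point); ``node_up`` /
    ``node_down`` are perturbed by ``node_shift_log2`` only in injured heated
    animals at the last time point.
    """

    n_features: int
    consensus_fold_changes: Mapping[str, Mapping[str, float]]
    node_up: Sequence[str] = ()
    node_down: Sequence[str] = ()
    node_shift_log2: float = 2.0
    noise_sd: float = 0.1
    baseline_log_mean: float = 8.0
    baseline_log_sd: float = 1.5

    def validate(self, config: StudyDesignConfig) -> None:
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if set(self.node_up) & set(self.node_down):
            raise ConfigurationError("node_up and node_down must be disjoint")
        for feat, per_organ in self.consensus_fold_changes.items():
            for organ, fc in per_organ.items():
                if organ not in config.organs:
                    raise ConfigurationError(f"unknown organ {organ!r} for {feat!r}")
                if abs(fc) < 2.0 or fc <= 0:
                    raise ConfigurationError(
                        f"consensus fold changes must be positive with magnitude"
                        f" >= 2 (feature {feat!r}, organ {organ!r}: {fc})"
                    )


def feature_ids(n: int) -> list[str]:
    return [f"TX{i:06d}" for i in range(n)]


def default_expression_truth(
    config: StudyDesignConfig,
    n_features: int = 1000,
    n_consensus: int = 78,
    n_node: int = 100,
    noise_sd: float = 0.1,
    fc_log2_range: tuple[float, float] = (1.2, 4.5),
    seed: int | None = None,
) -> ExpressionTruth:
    """Draw a truth with planted consensus and injury-node feature sets.

    Consensus per-organ fold changes are log-uniform between 2^1.2 and
    2^4.5 (about 2.3- to 23-fold), spanning the bulk of the effect sizes
    seen for heat-shock and apoptosis-regulation transcripts while staying
    clear of the two-fold calling boundary, so planted membership stays
    well-defined under measurement noise; injury nodes shift by +/-
    ``ExpressionTruth.node_shift_log2`` log2 units in injured animals.
    """
    config.validate()
    if n_consensus + 2 * n_node > n_features:
        raise ConfigurationError("planted sets exceed n_features")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ids = feature_ids(n_features)
    consensus = ids[:n_consensus]
    node_up = ids[n_consensus : n_consensus + n_node]
    node_down = ids[n_consensus + n_node : n_consensus + 2 * n_node]
    lo, hi = fc_log2_range
    fcs = {
        feat: {
            organ: float(np.exp2(rng.uniform(lo, hi))) for organ in config.organs
        }
        for feat in consensus
    }
    return ExpressionTruth(
        n_features=n_features,
        consensus_fold_changes=fcs,
        node_up=node_up,
        node_down=node_down,
        noise_sd=noise_sd,
    )


def generate_expression_study(
    config: StudyDesignConfig, truth: ExpressionTruth
) -> ExpressionStudy:
    """Simulate a linear-scale expression matrix plus design table.

    Every (organ, time, arm) cell holds ``config.n_per_group`` animals; a
    feature's log2 value is organ baseline + planted effect + N(0, noise_sd).
    Injury labels are drawn without replacement among heated animals at the
    last time point; controls are never injured. Identical (config, truth)
    gives bit-identical output.
    """
    config.validate()
    truth.validate(config)
    rng = np.random.default_rng(config.seed)
    ids = feature_ids(truth.n_features)
    id_pos = {f: i for i, f in enumerate(ids)}
    first_time = config.time_points[0]
    last_time = config.time_points[-1]
    n_injured = int(round(config.injured_fraction_48h * config.n_per_group))

    columns: list[str] = []
    design_rows: list[dict] = []
    blocks: list[np.ndarray] = []

    for organ in config.organs:
        baseline = rng.normal(
            truth.baseline_log_mean, truth.baseline_log_sd, truth.n_features
        )
        for time in config.time_points:
            injured_idx: set[int] = set()
            if time == last_time and n_injured:
                injured_idx = set(
                    rng.choice(config.n_per_group, size=n_injured, replace=False)
                )
            for arm in (HEAT_ARM, CONTROL_ARM):
                for k in range(config.n_per_group):
                    animal = f"{arm[0].upper()}{time}-{k + 1}"
                    injured = arm == HEAT_ARM and k in injured_idx
                    log2 = baseline + rng.normal(0.0, truth.noise_sd, truth.n_features)
                    if arm == HEAT_ARM and time == first_time:
                        for feat, per_organ in truth.consensus_fold_changes.items():
                            fc = per_organ.get(organ)
                            if fc is not None:
                                log2[id_pos[feat]] += np.log2(fc)
                    if injured and time == last_time:
                        for feat in truth.node_up:
                            log2[id_pos[feat]] += truth.node_shift_log2
                        for feat in truth.node_down:
                            log2[id_pos[feat]] -= truth.node_shift_log2
                    columns.append(f"{organ}_{time}_{arm}_{k + 1}")
                    design_rows.append(
                        {
                            "sample": columns[-1],
                            "organ": organ,
                            "time": time,
                            "arm": arm,
                            "animal": animal,
                            "injured": injured,
                        }
                    )
                    blocks.append(np.exp2(log2))

    values = pd.DataFrame(np.column_stack(blocks), index=ids, columns=columns)
    values.index.name = "feature"
    design = pd.DataFrame(design_rows).set_index("sample")
    return ExpressionStudy(values=values, design=design)


def percent_dehydration(pre_bw: float, post_bw: float) -> float:
    """Percent body-weight change, (post - pre) / pre * 100; negative = loss."""
    if pre_bw <= 0:
        raise ValueError("pre-heat-stress body weight must be positive")
    return (post_bw - pre_bw) / pre_bw * 100.0


# ---------------------------------------------------------------------------
# proteomics truth and peptide-table generation
# ---------------------------------------------------------------------------


@dataclass
class ProteomeTruth:
    """Planted ground truth for a synthetic iTRAQ experiment.

    ``fold_changes`` maps condition label -> per-protein linear ratio vs the
    reference channel; ``channel_conditions`` assigns each non-reference
    reporter channel a condition (the reference channel carries ratio 1).
    ``z_agg`` holds externally supplied aggregation-propensity scores; the
    changed group is shifted by ``delta`` so a supersaturation gap of known
    size is planted.
    """

    protein_ids: Sequence[str]
    concentrations: Mapping[str, float]
    fold_changes: Mapping[str, Mapping[str, float]]
    z_agg: Mapping[str, float]
    calibrants: Mapping[str, float]
    n_peptides: Mapping[str, int]
    channel_conditions: Mapping[str, str]
    reference_channel: str = "reporter_1"
    response_factor_sd: float = 0.5
    reporter_noise_sd: float = 0.0
    precursor_noise_sd: float = 0.0
    n_fractions: int = 15
    delta: float = 0.0

    def validate(self) -> None:
        if len(self.calibrants) < 5:
            raise ConfigurationError("need >= 5 calibrant proteins")
        if self.delta < 0:
            raise ConfigurationError("planted effect size delta must be >= 0")
        for pid in self.protein_ids:
            if self.n_peptides.get(pid, 0) < 1:
                raise ConfigurationError(f"protein {pid!r} needs >= 1 peptide")
        unknown = set(self.calibrants) - set(self.protein_ids)
        if unknown:
            raise ConfigurationError(f"calibrants absent from proteome: {unknown}")


def default_proteome_truth(
    n_proteins: int = 300,
    n_changed: int = 60,
    delta: float = 1.0,
    condition: str = "48h_injured",
    changed_fc: float = 2.0,
    reporter_noise_sd: float = 0.0,
    precursor_noise_sd: float = 0.0,
    seed: int = 0,
) -> ProteomeTruth:
    """Build a proteome truth with a planted supersaturation gap.

    The first ``n_changed`` proteins change ``changed_fc``-fold (alternating
    up/down) in ``condition`` and carry Z_agg ~ N(delta, 1); the remainder
    are unchanged with Z_agg ~ N(0, 1). True concentrations are log-uniform
    over 1e-9..1e-4 M; the seven calibrants take their true concentrations
    as "known". Peptide counts are 3..8 so most proteins are Top3-eligible.
    """
    rng = np.random.default_rng(seed)
    ids = list(CALIBRANT_IDS) + [f"P{i:05d}" for i in range(n_proteins - len(CALIBRANT_IDS))]
    if n_changed > n_proteins:
        raise ConfigurationError("n_changed exceeds n_proteins")
    conc = {pid: float(10 ** rng.uniform(-9, -4)) for pid in ids}
    # calibrants are kept out of the changed group so calibration is stable
    non_cal = [p for p in ids if p not in CALIBRANT_IDS]
    changed = non_cal[:n_changed]
    changed_set = set(changed)
    fcs = {}
    for i, pid in enumerate(ids):
        if pid in changed_set:
            fcs[pid] = changed_fc if i % 2 == 0 else 1.0 / changed_fc
        else:
            fcs[pid] = 1.0
    z = {
        pid: float(rng.normal(delta if pid in changed_set else 0.0, 1.0))
        for pid in ids
    }
    n_pep = {pid: int(rng.integers(3, 9)) for pid in ids}
    return ProteomeTruth(
        protein_ids=ids,
        concentrations=conc,
        fold_changes={condition: fcs},
        z_agg=z,
        calibrants={pid: conc[pid] for pid in CALIBRANT_IDS},
        n_peptides=n_pep,
        channel_conditions={"reporter_2": condition},
        reporter_noise_sd=reporter_noise_sd,
        precursor_noise_sd=precursor_noise_sd,
        delta=delta,
    )


def generate_peptide_table(truth: ProteomeTruth, seed: int = 0) -> pd.DataFrame:
    """Simulate a peptide-level iTRAQ table from planted truth.

    Each peptide gets a fixed log-normal response factor shared across
    channels; its total (base) intensity is concentration x response factor.
    Chromatographic fractionation splits that total over 1-3 fractions with
    Dirichlet weights summing to one, and an optional second charge state
    within a fraction is a redundant report at reduced intensity -- so the
    downstream rule (max within fraction, summed over fractions) recovers
    exactly the base intensity when noise is zero. Reporter channel
    intensities encode the per-condition ratios of ``truth.fold_changes``
    around the same per-record amount.
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    scale = 1e12  # arbitrary instrument response putting intensities in a familiar range
    rows: list[dict] = []
    for pid in truth.protein_ids:
        conc = truth.concentrations[pid]
        for j in range(truth.n_peptides[pid]):
            response = float(np.exp(rng.normal(0.0, truth.response_factor_sd)))
            base = conc * response * scale
            peptide = f"{pid}_pep{j + 1}"
            n_frac = int(rng.integers(1, 4))
            fractions = rng.choice(truth.n_fractions, size=n_frac, replace=False) + 1
            weights = rng.dirichlet(np.full(n_frac, 5.0))
            n_charge = int(rng.integers(1, 3))
            charges = (2, 3)[:n_charge]
            order = np.argsort(fractions)
            for fraction, weight in zip(fractions[order], weights[order]):
                for charge in charges:
                    # charge 3 is a redundant, weaker report of the same ion;
                    # the max-within-fraction rule discards it
                    charge_factor = 1.0 if charge == 2 else 0.6
                    amount = base * float(weight) * charge_factor
                    precursor = amount * float(
                        np.exp(rng.normal(0.0, truth.precursor_noise_sd))
                    )
                    row = {
                        "protein": pid,
                        "peptide": peptide,
                        "charge": charge,
                        "fraction": int(fraction),
                        "precursor_intensity": precursor,
                        "run": "run1",
                    }
                    for channel in REPORTER_COLUMNS:
                        condition = truth.channel_conditions.get(channel)
                        ratio = (
                            1.0
                            if condition is None
                            else truth.fold_changes[condition][pid]
                        )
                        noise = float(
                            np.exp(rng.normal(0.0, truth.reporter_noise_sd))
                        )
                        row[channel] = amount * ratio * noise
                    rows.append(row)
    return pd.DataFrame(rows)
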