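"""Tabular readers/writers, pipeline configuration, and packaged fixtures.

All interchange is plain text: TSV for matrices, designs and result tables,
CSV for peptide tables, GMT for gene sets, YAML for configuration. The
packaged fixtures are machine-readable transcriptions of the two printed
summary tables of the source study: the gene-set/KEGG enrichment scores
common to all four organs, and the functionally clustered consensus
transcripts with their per-organ fold changes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from heatstress.de import ExpressionStudy
from heatstress.util import ConfigurationError

PROCESS_LABELS = ("PF", "PF/RA", "RA")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All tunable thresholds and parameters of the analysis chain."""

    gene_fc_threshold: float = 2.0
    protein_fc_threshold: float = 1.3
    unchanged_threshold: float = 1.1
    fdr_threshold: float = 0.05
    ora_max_term_size: int = 500
    ora_min_overlap: int = 4
    ora_min_es: float = 2.0
    ora_max_p: float = 0.05
    som_grid: tuple[int, int] = (4, 4)
    som_epochs: int = 200
    som_learning_rate: float = 0.5
    anchor_threshold: float = 1.0
    reference_channel: str = "reporter_1"
    log_base: float = 10.0
    plier_offset: float = 16.0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "gene_fc_threshold",
            "protein_fc_threshold",
            "unchanged_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ConfigurationError("fdr_threshold must lie in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["som_grid"] = list(self.som_grid)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "som_grid" in data:
            data["som_grid"] = tuple(data["som_grid"])
        config = cls(**data)
        config.validate()
        return config

    def config_hash(self) -> str:
        """Stable hash over all semantically meaningful fields."""
        data = asdict(self)
        data["som_grid"] = list(self.som_grid)
        canonical = json.dumps(data, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# expression matrices and designs
# ---------------------------------------------------------------------------


def write_expression_study(study: ExpressionStudy, values_path, design_path) -> None:
    study.values.rename_axis("feature").to_csv(values_path, sep="\t")
    study.design.rename_axis("sample").to_csv(design_path, sep="\t")


def read_expression_study(values_path, design_path) -> ExpressionStudy:
    values = pd.read_csv(values_path, sep="\t", index_col="feature")
    design = pd.read_csv(design_path, sep="\t", index_col="sample")
    design["injured"] = design["injured"].astype(bool)
    return ExpressionStudy(values=values, design=design)


def write_table(table: pd.DataFrame, path, index: bool = True) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    table.to_csv(path, sep=sep, index=index)


def read_peptide_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_peptide_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_zagg_table(path) -> pd.Series:
    """Read a protein aggregation-propensity TSV (protein, z_agg[, variant])."""
    df = pd.read_csv(path, sep="\t")
    if not {"protein", "z_agg"} <= set(df.columns):
        raise ConfigurationError("z_agg table needs protein and z_agg columns")
    return df.set_index("protein")["z_agg"]


def read_calibrant_table(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"protein", "concentration_molar"} <= set(df.columns):
        raise ConfigurationError(
            "calibrant table needs protein and concentration_molar columns"
        )
    return df.set_index("protein")["concentration_molar"]


# ---------------------------------------------------------------------------
# printed-table fixtures
# ---------------------------------------------------------------------------


def _fixture(name: str) -> pd.DataFrame:
    with resources.files("heatstress.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_enrichment_fixture() -> pd.DataFrame:
    """The GO/KEGG terms enriched in all four organs, with per-organ ES."""
    return _fixture("table1_enrichment.tsv")


def load_consensus_fixture() -> pd.DataFrame:
    """The functionally clustered consensus transcripts with per-organ FCs."""
    df = _fixture("table2_consensus.tsv")
    df["transcript_id"] = df["transcript_id"].astype(str)
    return df


@dataclass
class FixtureCounts:
    by_process: dict[str, int] = field(default_factory=dict)
    n_rows: int = 0
    n_distinct_transcripts: int = 0


def summarize_fixture_counts(fixture: pd.DataFrame) -> FixtureCounts:
    """Row counts per functional-process label and distinct transcript ids.

    Every row must carry exactly one of the PF / PF/RA / RA labels and all
    fold changes must exceed 1; duplicated transcript ids are a validation
    error.
    """
    if fixture.empty:
        return FixtureCounts(by_process={label: 0 for label in PROCESS_LABELS})
    bad = set(fixture["process"]) - set(PROCESS_LABELS)
    if bad:
        raise ConfigurationError(f"unknown process labels: {sorted(bad)}")
    dupes = fixture["transcript_id"][fixture["transcript_id"].duplicated()]
    if not dupes.empty:
        raise ConfigurationError(f"duplicate transcript ids: {sorted(set(dupes))}")
    fc_cols = [c for c in fixture.columns if c.endswith("_fc")]
    if (fixture[fc_cols] <= 1.0).any().any():
        raise ConfigurationError("all consensus fold changes must exceed 1")
    by_process = {
        label: int((fixture["process"] == label).sum()) for label in PROCESS_LABELS
    }
    return FixtureCounts(
        by_process=by_process,
        n_rows=int(len(fixture)),
        n_distinct_transcripts=int(fixture["transcript_id"].nunique()),
    )
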