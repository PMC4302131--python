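"""Self-organizing maps over transcript profiles, anchored to injury labels.

Transcripts are the mapped observations and samples (animals) are the
dimensions, so a node collects genes sharing an across-animal expression
pattern. After training, nodes whose member genes are coherently shifted in
a labeled sample subgroup (e.g. the heated animals with histopathological
cardiac injury at 48 h) are reported as anchored, with an up/down direction
and a separation score in z-score units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from heatstress.util import ConfigurationError


@dataclass
class SOMParams:
    """Kohonen online-training hyperparameters.

    ``radius0`` defaults to half the larger grid dimension; learning rate
    and neighborhood radius decay exponentially over epochs.
    """

    epochs: int = 200
    learning_rate: float = 0.5
    radius0: float | None = None
    decay: float = 3.0  # e-foldings of decay over the full schedule


@dataclass
class SOMModel:
    grid: tuple[int, int]
    codebook: np.ndarray  # (rows * cols, n_dimensions)
    params: SOMParams
    seed: int
    coords: np.ndarray = field(init=False)  # (n_nodes, 2) grid coordinates

    def __post_init__(self) -> None:
        rows, cols = self.grid
        if rows < 1 or cols < 1:
            raise ConfigurationError("grid dimensions must be >= 1")
        if not np.all(np.isfinite(self.codebook)):
            raise ConfigurationError("codebook must be finite")
        self.coords = np.array(
            [(r, c) for r in range(rows) for c in range(cols)], dtype=float
        )

    @property
    def n_nodes(self) -> int:
        return self.grid[0] * self.grid[1]


@dataclass
class AnchoredNode:
    """A node whose members separate the labeled subgroup from the rest."""

    node: int
    members: list[str]
    direction: str  # "up" or "down" in the labeled subgroup
    separation: float


def zscore_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Standardize each feature (row) to mean 0, SD 1; constant rows -> 0."""
    arr = profiles.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((arr - mean) / sd, index=profiles.index,
                        columns=profiles.columns)


def _as_matrix(profiles) -> np.ndarray:
    arr = profiles.to_numpy(dtype=float) if isinstance(profiles, pd.DataFrame) \
        else np.asarray(profiles, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ConfigurationError("profiles must be a non-empty 2-D matrix")
    return arr


def train_som(
    profiles,
    grid: tuple[int, int] = (4, 4),
    params: SOMParams | None = None,
    seed: int = 0,
) -> SOMModel:
    """Train a Kohonen map by online best-matching-unit updates.

    The codebook is initialized from randomly chosen input rows; each epoch
    presents every row in a shuffled order, moving the BMU and its Gaussian
    grid neighborhood toward the row with an exponentially decaying learning
    rate and radius. Deterministic for a fixed seed.
    """
    params = params or SOMParams()
    data = _as_matrix(profiles)
    n, dim = data.shape
    rows, cols = grid
    n_nodes = rows * cols
    if n_nodes < 1:
        raise ConfigurationError("grid must contain at least one node")
    rng = np.random.default_rng(seed)
    init_idx = rng.integers(0, n, size=n_nodes)
    model = SOMModel(
        grid=grid,
        codebook=data[init_idx].astype(float).copy(),
        params=params,
        seed=seed,
    )
    codebook = model.codebook
    coords = model.coords
    radius0 = params.radius0 if params.radius0 is not None else max(rows, cols) / 2.0
    radius0 = max(radius0, 1e-9)
    for epoch in range(params.epochs):
        frac = epoch / max(params.epochs - 1, 1)
        lr = params.learning_rate * np.exp(-params.decay * frac)
        radius = radius0 * np.exp(-params.decay * frac)
        two_r2 = 2.0 * max(radius, 1e-9) ** 2
        for i in rng.permutation(n):
            x = data[i]
            bmu = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
            grid_d2 = ((coords - coords[bmu]) ** 2).sum(axis=1)
            h = np.exp(-grid_d2 / two_r2)
            codebook += (lr * h)[:, None] * (x - codebook)
    return model


def assign_nodes(model: SOMModel, profiles) -> pd.Series:
    """Map each feature to its nearest codebook vector (Euclidean).

    Ties are broken toward the lowest node index (row-major grid order).
    """
    data = _as_matrix(profiles)
    if data.shape[1] != model.codebook.shape[1]:
        raise ConfigurationError(
            f"profile length {data.shape[1]} != codebook length "
            f"{model.codebook.shape[1]}"
        )
    d2 = ((data[:, None, :] - model.codebook[None, :, :]) ** 2).sum(axis=2)
    nodes = d2.argmin(axis=1)  # argmin returns the first (lowest) index on ties
    index = profiles.index if isinstance(profiles, pd.DataFrame) else pd.RangeIndex(
        data.shape[0]
    )
    return pd.Series(nodes, index=index, name="node")


def quantization_error(model: SOMModel, profiles) -> float:
    """Mean Euclidean distance of each feature to its best-matching unit."""
    data = _as_matrix(profiles)
    d2 = ((data[:, None, :] - model.codebook[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min(axis=1)).mean())


def anchor_nodes(
    model: SOMModel,
    assignment: pd.Series,
    profiles: pd.DataFrame,
    subgroup: Sequence[bool],
    threshold: float = 1.0,
) -> list[AnchoredNode]:
    """Find nodes whose members separate the labeled subgroup.

    Profiles are z-scored per feature; a node's separation score s is the
    mean (over member features) of mean z in the labeled samples minus mean
    z in the remaining samples. Nodes with |s| >= ``threshold`` are returned
    with direction "up" (s > 0) or "down".
    """
    mask = np.asarray(subgroup, dtype=bool)
    if mask.size != profiles.shape[1]:
        raise ConfigurationError("subgroup labels must match sample count")
    if mask.all() or not mask.any():
        raise ConfigurationError("need labeled and unlabeled samples")
    z = zscore_profiles(profiles).to_numpy()
    per_feature = z[:, mask].mean(axis=1) - z[:, ~mask].mean(axis=1)
    sep = pd.Series(per_feature, index=profiles.index)
    anchored: list[AnchoredNode] = []
    for node in range(model.n_nodes):
        members = assignment.index[assignment == node]
        if len(members) == 0:
            continue
        s = float(sep.loc[members].mean())
        if abs(s) >= threshold:
            anchored.append(
                AnchoredNode(
                    node=node,
                    members=list(members),
                    direction="up" if s > 0 else "down",
                    separation=s,
                )
            )
    return anchored
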