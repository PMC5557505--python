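"""Distances between neurons.

* ``wasserstein1`` (d_P): degree-1 Wasserstein distance between persistence
  diagrams, solved exactly as an optimal assignment on the two point sets
  augmented with their diagonal projections.  Ground cost between points is
  the L-infinity norm; an unmatched point pays its L-infinity distance to the
  diagonal, |death - birth| / 2.
* ``bottleneck``: same cost model, minimizing the maximum matched cost; used
  for stability checks.
* ``lp_vector_distance`` (d_V): L_p norm between persistence vectors
  (default p = 1).
* ``sholl_distance`` (d_S): L1 norm between discretized Sholl profiles.
* ``lmeasure_distance`` (d_L): L2 after per-feature z-scoring over the
  collection ("normalized L2"); ``combined_distance`` (d_C) mixes d_V and
  d_L entrywise after rescaling each matrix to unit maximum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .errors import (
    ConfigMismatchError,
    DimensionMismatchError,
    GridMismatchError,
    MissingFeatureError,
    OrderMismatchError,
)
from .persistence import PersistenceDiagram
from .sholl import ShollProfile
from .signatures import PersistenceVector

__all__ = [
    "DistanceMatrix",
    "LMeasureVector",
    "wasserstein1",
    "bottleneck",
    "lp_vector_distance",
    "sholl_distance",
    "lmeasure_distance",
    "lmeasure_collection_stats",
    "combined_distance",
    "pairwise_matrix",
]


@dataclass
class DistanceMatrix:
    names: list[str]
    values: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise DimensionMismatchError(
                f"matrix shape {self.values.shape} does not match {n} names"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix entries must be finite")

    def get(self, a: str, b: str) -> float:
        i, j = self.names.index(a), self.names.index(b)
        return float(self.values[i, j])

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame(self.values, index=self.names, columns=self.names).to_csv(path)
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump({"metric": self.metric_name}, fh)

    @staticmethod
    def from_csv(path: str | Path, metric_name: str = "") -> "DistanceMatrix":
        df = pd.read_csv(Path(path), index_col=0)
        return DistanceMatrix(
            names=[str(n) for n in df.index], values=df.to_numpy(), metric_name=metric_name
        )


@dataclass(frozen=True)
class LMeasureVector:
    """One neuron's morphometric summary vector (named features)."""

    name: str
    features: Mapping[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# diagram distances


def _augmented_cost_matrix(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Square cost matrix over D1 + diagonal slots vs D2 + diagonal slots.

    Entry (i, j), i < n1, j < n2: L-inf distance between points.  Point vs a
    diagonal slot: the point's |d - b| / 2.  Diagonal vs diagonal: 0.
    """
    n1, n2 = len(p1), len(p2)
    size = n1 + n2
    cost = np.zeros((size, size))
    if n1 and n2:
        cost[:n1, :n2] = np.max(
            np.abs(p1[:, None, :] - p2[None, :, :]), axis=2
        )
    diag1 = np.abs(p1[:, 1] - p1[:, 0]) / 2.0 if n1 else np.empty(0)
    diag2 = np.abs(p2[:, 1] - p2[:, 0]) / 2.0 if n2 else np.empty(0)
    cost[:n1, n2:] = diag1[:, None]
    cost[n1:, :n2] = diag2[None, :]
    return cost


def wasserstein1(d1: PersistenceDiagram, d2: PersistenceDiagram) -> float:
    """Exact degree-1 Wasserstein distance (sum of matched costs) between two
    diagrams; empty diagrams allowed."""
    p1, p2 = d1.as_array(), d2.as_array()
    if len(p1) == 0 and len(p2) == 0:
        return 0.0
    cost = _augmented_cost_matrix(p1, p2)
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum())


def bottleneck(d1: PersistenceDiagram, d2: PersistenceDiagram) -> float:
    """Exact bottleneck distance: minimize the maximum matched cost.

    Binary search over the candidate costs, testing feasibility with a
    maximum bipartite matching on the edges not exceeding the threshold.
    """
    p1, p2 = d1.as_array(), d2.as_array()
    if len(p1) == 0 and len(p2) == 0:
        return 0.0
    cost = _augmented_cost_matrix(p1, p2)
    candidates = np.unique(cost)
    lo, hi = 0, len(candidates) - 1
    size = cost.shape[0]

    def feasible(threshold: float) -> bool:
        adj = csr_matrix((cost <= threshold).astype(np.int8))
        match = maximum_bipartite_matching(adj, perm_type="column")
        return bool(np.all(match >= 0)) and len(match) == size

    while lo < hi:
        mid = (lo + hi) // 2
        if feasible(candidates[mid]):
            hi = mid
        else:
            lo = mid + 1
    return float(candidates[lo])


# ---------------------------------------------------------------------------
# vector distances


def lp_vector_distance(
    v1: PersistenceVector, v2: PersistenceVector, p: float = 1
) -> float:
    """Standard L_p distance between persistence vectors built under the
    same config (default p = 1)."""
    if v1.config.dimension != v2.config.dimension:
        raise DimensionMismatchError("persistence vectors differ in dimension")
    if v1.config != v2.config:
        raise ConfigMismatchError(
            f"configs differ: {v1.config} vs {v2.config}"
        )
    return float(np.linalg.norm(v1.values - v2.values, ord=p))


def sholl_distance(s1: ShollProfile, s2: ShollProfile) -> float:
    """L1 distance between Sholl count vectors on an identical radius grid."""
    if s1.radii.shape != s2.radii.shape or not np.allclose(
        s1.radii, s2.radii, rtol=0.0, atol=0.0
    ):
        raise GridMismatchError("Sholl profiles are on different radius grids")
    return float(np.abs(s1.vector - s2.vector).sum())


# ---------------------------------------------------------------------------
# L-Measure distances


def lmeasure_collection_stats(
    vectors: Sequence[LMeasureVector],
) -> dict[str, tuple[float, float]]:
    """Per-feature (mean, SD) over the collection; zero-variance features are
    dropped with a warning so they cannot produce 0/0."""
    import warnings

    names = sorted({k for v in vectors for k in v.features})
    stats: dict[str, tuple[float, float]] = {}
    for feat in names:
        vals = []
        for v in vectors:
            if feat not in v.features:
                raise MissingFeatureError(f"{v.name} lacks feature {feat!r}")
            vals.append(v.features[feat])
        arr = np.asarray(vals, dtype=float)
        mean, sd = float(arr.mean()), float(arr.std(ddof=0))
        if sd == 0.0:
            warnings.warn(f"dropping zero-variance L-Measure feature {feat!r}")
            continue
        stats[feat] = (mean, sd)
    return stats


def lmeasure_distance(
    l1: LMeasureVector,
    l2: LMeasureVector,
    collection_stats: Mapping[str, tuple[float, float]],
) -> float:
    """Normalized-L2: z-score each feature with the collection mean/SD, then
    take the Euclidean distance over the retained features."""
    diffs = []
    for feat, (mean, sd) in collection_stats.items():
        for vec in (l1, l2):
            if feat not in vec.features:
                raise MissingFeatureError(f"{vec.name} lacks feature {feat!r}")
        z1 = (l1.features[feat] - mean) / sd
        z2 = (l2.features[feat] - mean) / sd
        diffs.append(z1 - z2)
    return float(np.linalg.norm(diffs, ord=2))


def read_lmeasure_csv(path: str | Path) -> list[LMeasureVector]:
    """Read an L-Measure table (one row per neuron, first column = name)."""
    df = pd.read_csv(Path(path))
    name_col = df.columns[0]
    return [
        LMeasureVector(
            name=str(row[name_col]),
            features={c: float(row[c]) for c in df.columns[1:] if pd.notna(row[c])},
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# matrix assembly


def combined_distance(
    dv: DistanceMatrix,
    dl: DistanceMatrix,
    weights: tuple[float, float] = (0.5, 0.5),
) -> DistanceMatrix:
    """Entrywise weighted mix of two distance matrices, each first rescaled
    to unit maximum entry (the two inputs live on incomparable scales)."""
    if dv.names != dl.names:
        raise OrderMismatchError("matrices have different neuron orderings")
    wv, wl = weights

    def unit_max(m: np.ndarray) -> np.ndarray:
        peak = m.max()
        return m / peak if peak > 0 else m

    mixed = wv * unit_max(dv.values) + wl * unit_max(dl.values)
    return DistanceMatrix(
        names=list(dv.names), values=mixed,
        metric_name=f"{wv}*{dv.metric_name}+{wl}*{dl.metric_name}",
    )


def pairwise_matrix(
    items: Sequence,
    metric: Callable[[object, object], float],
    names: Sequence[str] | None = None,
    metric_name: str = "",
) -> DistanceMatrix:
    """Symmetric matrix computed once per unordered pair."""
    n = len(items)
    if names is None:
        names = [getattr(it, "tree_name", None) or getattr(it, "name", str(i))
                 for i, it in enumerate(items)]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(metric(items[i], items[j]))
            values[i, j] = values[j, i] = d
    return DistanceMatrix(names=list(names), values=values, metric_name=metric_name)
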