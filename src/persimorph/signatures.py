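"""Persistence vectors: kernel-density vectorization of persistence diagrams.

Each diagram point (x, y) becomes a weighted point on the line at location x
(its first stored coordinate, whichever sweep it came from) with mass
|y - x|, its persistence.  The weighted points define the density

    rho_D(s) = sum_i m_i * exp(-(s - x_i)^2 / (2 t^2)),

an untruncated Gaussian mixture whose kernel width t is the standard
deviation; features with larger persistence weigh more.  Sampling rho_D at m
positions evenly spaced over a range [a, b] shared by the whole collection —
the grid a + I/m, a + 2I/m, ..., a + mI/m = b with I = b - a — yields the
m-dimensional persistence vector.  Defaults t = 50 (descriptor units, µm for
the distance descriptors) and m = 100.

Multiple descriptors per neuron are handled by concatenating their vectors in
a fixed descriptor order (length r*m), optionally followed by a
collection-level PCA projection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError, DimensionMismatchError, EmptyCollectionError
from .persistence import PersistenceDiagram

__all__ = [
    "WeightedPoint1D",
    "SignatureConfig",
    "PersistenceVector",
    "diagram_to_weighted_points",
    "density_value",
    "vectorize",
    "collection_range",
    "combine_descriptor_vectors",
    "pca_project",
]


@dataclass(frozen=True)
class WeightedPoint1D:
    location: float
    mass: float

    def __post_init__(self) -> None:
        if not (self.mass >= 0.0) or not np.isfinite(self.mass):
            raise ValueError(f"mass must be finite and >= 0, got {self.mass}")
        if not np.isfinite(self.location):
            raise ValueError(f"location must be finite, got {self.location}")


@dataclass(frozen=True)
class SignatureConfig:
    """Kernel width t (> 0, descriptor units), dimension m and range [a, b]."""

    kernel_width: float = 50.0
    dimension: int = 100
    a: float = 0.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.kernel_width <= 0:
            raise ConfigError("kernel_width must be > 0")
        if self.dimension < 1:
            raise ConfigError("dimension must be >= 1")
        if self.b <= self.a:
            raise ConfigError(f"range [{self.a}, {self.b}] needs b > a")

    @property
    def grid(self) -> np.ndarray:
        """The m sample positions a + I/m, ..., a + m*I/m = b."""
        m, I = self.dimension, self.b - self.a
        return self.a + (np.arange(1, m + 1) / m) * I


@dataclass
class PersistenceVector:
    values: np.ndarray
    config: SignatureConfig
    tree_name: str = ""
    descriptor_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.config.dimension,):
            raise DimensionMismatchError(
                f"vector length {self.values.shape} != m = {self.config.dimension}"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("persistence vector entries must be finite and >= 0")

    def __len__(self) -> int:
        return self.config.dimension


def diagram_to_weighted_points(
    diagram: PersistenceDiagram, include_essential: bool = True
) -> list[WeightedPoint1D]:
    """Map each diagram point (x, y) to the weighted point (x; |y - x|).

    Essential points are included by default — they carry the largest masses
    (the total descriptor depth) and excluding them would discard that
    signal.
    """
    return [
        WeightedPoint1D(location=p.birth, mass=p.persistence)
        for p in diagram.points
        if include_essential or not p.essential
    ]


def density_value(
    points: Sequence[WeightedPoint1D], x: float, kernel_width: float
) -> float:
    """Evaluate the persistence-weighted Gaussian density at one position."""
    if kernel_width <= 0:
        raise ConfigError("kernel_width must be > 0")
    if not points:
        return 0.0
    locs = np.array([p.location for p in points])
    masses = np.array([p.mass for p in points])
    return float(np.sum(masses * np.exp(-((x - locs) ** 2) / (2.0 * kernel_width**2))))


def vectorize(
    diagram: PersistenceDiagram,
    config: SignatureConfig,
    include_essential: bool = True,
) -> PersistenceVector:
    """Sample the diagram's density on the config grid (deterministic)."""
    pts = diagram_to_weighted_points(diagram, include_essential=include_essential)
    # canonical summation order makes the result independent of diagram
    # point order down to the last bit
    pts = sorted(pts, key=lambda p: (p.location, p.mass))
    grid = config.grid
    if pts:
        locs = np.array([p.location for p in pts])
        masses = np.array([p.mass for p in pts])
        diffs = grid[:, None] - locs[None, :]
        values = np.exp(-(diffs**2) / (2.0 * config.kernel_width**2)) @ masses
    else:
        values = np.zeros_like(grid)
    return PersistenceVector(
        values=values,
        config=config,
        tree_name=diagram.tree_name,
        descriptor_name=diagram.descriptor_name,
    )


def collection_range(
    diagrams: Sequence[PersistenceDiagram], padding: float = 0.0
) -> tuple[float, float]:
    """Shared [a, b]: min/max over all birth and death coordinates of all
    diagrams, expanded by ``padding * (b - a)`` on each side."""
    coords = [
        c for dg in diagrams for p in dg.points for c in (p.birth, p.death)
    ]
    if not coords:
        raise EmptyCollectionError("no diagram points to fit a range to")
    a, b = min(coords), max(coords)
    span = b - a
    return a - padding * span, b + padding * span


def combine_descriptor_vectors(
    per_descriptor: Sequence[PersistenceVector],
) -> np.ndarray:
    """Concatenate one neuron's per-descriptor vectors (fixed order, length r*m)."""
    if not per_descriptor:
        raise EmptyCollectionError("no vectors to combine")
    return np.concatenate([v.values for v in per_descriptor])


def pca_project(matrix: np.ndarray, target_dim: int) -> np.ndarray:
    """Collection-level PCA: project rows onto the top principal components.

    Deterministic sign convention: each component is oriented so its
    largest-magnitude loading is positive.  An exact low-rank collection is
    embedded isometrically (pairwise distances preserved).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise DimensionMismatchError("expected a 2D (neurons x features) matrix")
    if not (1 <= target_dim <= min(X.shape)):
        raise ConfigError(f"target_dim {target_dim} out of range for shape {X.shape}")
    centered = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    components = vt[:target_dim]
    for i, comp in enumerate(components):
        if comp[np.argmax(np.abs(comp))] < 0:
            components[i] = -comp
    return centered @ components.T


def write_feature_matrix(
    path: str | Path,
    names: Sequence[str],
    matrix: np.ndarray,
    config: SignatureConfig,
    descriptor_names: Sequence[str],
) -> None:
    """Feature CSV (rows = neurons) with a JSON sidecar recording the config."""
    path = Path(path)
    X = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        fh.write("name," + ",".join(f"v{i}" for i in range(X.shape[1])) + "\n")
        for name, row in zip(names, X):
            fh.write(name + "," + ",".join(f"{v:.17g}" for v in row) + "\n")
    sidecar = {
        "kernel_width": config.kernel_width,
        "dimension": config.dimension,
        "range": [config.a, config.b],
        "descriptors": list(descriptor_names),
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
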