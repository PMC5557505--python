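"""Sholl analysis and its recovery from the extended persistence diagram.

The Sholl function N(r) counts the intersections of a neuron with the sphere
of radius r centered at the root.  With the radial (Euclidean) distance to
the root taken as a PL descriptor f on the tree, N(r) is the number of
connected components of the level set f^{-1}(r): for non-critical r each
straddling arc contributes exactly one crossing.  The same count is
recoverable from the extended persistence diagram of f —

    N(r) = #{(b, d) in sublevel part : b <= r, d >= r}
         + #{(b, d) in superlevel part : b >= r, d <= r} - 1,

where both essential points are counted and the -1 corrects for the root's
class appearing once per sweep direction.  The PL convention is what makes
the identity exact: a straight chord geometrically crossing a sphere twice
between consecutive sample points is still counted once.

Vertices lying exactly on the sphere are resolved by the half-open straddle
rule f(u) < r <= f(v); such radii are critical and excluded from the
identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .descriptors import euclidean_descriptor
from .errors import ConfigError, NonPositiveRadiusError
from .persistence import PersistenceDiagram
from .swc_io import NeuronTree

__all__ = ["ShollProfile", "sholl_count", "sholl_from_diagram", "sholl_vector"]


@dataclass
class ShollProfile:
    """Intersection counts on a strictly increasing radius grid, plus the
    float discretization used as a feature vector."""

    radii: np.ndarray
    counts: np.ndarray
    tree_name: str = ""

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.radii.shape != self.counts.shape:
            raise ConfigError("radii and counts must align")
        if len(self.radii) and (np.any(np.diff(self.radii) <= 0) or self.radii[0] <= 0):
            raise ConfigError("radii must be strictly increasing and positive")
        if np.any(self.counts < 0):
            raise ConfigError("counts must be non-negative")

    @property
    def vector(self) -> np.ndarray:
        return self.counts.astype(float)

    def to_csv(self, path: str | Path) -> None:
        with open(Path(path), "w") as fh:
            fh.write("radius,count\n")
            for r, c in zip(self.radii, self.counts):
                fh.write(f"{r:.17g},{c}\n")


def _radial_values(tree: NeuronTree) -> dict[int, float]:
    return euclidean_descriptor(tree).values


def sholl_count(tree: NeuronTree, r: float) -> int:
    """Number of intersections of the tree with the radius-r sphere at the
    root: arcs (u, v) whose radial values straddle r under the half-open
    rule f(u) < r <= f(v) or f(v) < r <= f(u)."""
    if r <= 0:
        raise NonPositiveRadiusError(f"radius must be > 0, got {r}")
    f = _radial_values(tree)
    count = 0
    for parent, child, _ in tree.arcs():
        fu, fv = f[parent], f[child]
        if (fu < r <= fv) or (fv < r <= fu):
            count += 1
    return count


def sholl_from_diagram(diagram: PersistenceDiagram, r: float, negated: bool = False) -> int:
    """Recover N(r) from the extended diagram of the radial descriptor.

    ``negated=True`` states that the diagram was built from the negated
    descriptor; the query level is then -r.  Requires a diagram with both
    sweep parts (essential points included).  Raises ValueError if the
    formula goes negative, which signals a diagram not of the required form.
    """
    if r <= 0:
        raise NonPositiveRadiusError(f"radius must be > 0, got {r}")
    level = -r if negated else r
    n = 0
    for p in diagram.points:
        if p.origin == "sublevel" and p.birth <= level <= p.death:
            n += 1
        elif p.origin == "superlevel" and p.death <= level <= p.birth:
            n += 1
    n -= 1
    if n < 0:
        raise ValueError(
            "level-set count came out negative; the diagram is not an "
            "extended diagram of a radial descriptor"
        )
    return n


def sholl_vector(tree: NeuronTree, grid_size: int = 100, r_max: float | None = None) -> ShollProfile:
    """Sholl counts at ``grid_size`` radii r_k = k * r_max / grid_size
    (k = 1..grid_size), the same sampling convention as the persistence
    vector grid.  ``r_max`` should be shared across a collection; it
    defaults to this tree's maximum radial node distance."""
    if grid_size < 1:
        raise ConfigError("grid_size must be >= 1")
    if r_max is None:
        r_max = max(_radial_values(tree).values())
    if r_max <= 0:
        raise ConfigError("r_max must be > 0")
    radii = (np.arange(1, grid_size + 1) / grid_size) * r_max
    counts = np.array([sholl_count(tree, float(r)) for r in radii], dtype=int)
    return ShollProfile(radii=radii, counts=counts, tree_name=tree.name)


def collection_r_max(trees) -> float:
    """Shared r_max: the maximum radial node distance over the collection."""
    return max(max(_radial_values(t).values()) for t in trees)
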