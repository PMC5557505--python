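"""Classification, clustering and embedding on top of a distance matrix.

* Leave-one-out k-NN: a query neuron is a *hit* if any of its k nearest
  others (by the chosen distance) belongs to the same class; the success
  rate SR_k is hits / neurons evaluated.  Classes smaller than
  ``min_class_size`` (default 2) are removed from the collection before
  evaluation — with a single member there is nothing of the same class to
  find.
* Bootstrap: SR_k mean and SD over random subsamples drawn without
  replacement.
* Average-linkage (UPGMA) hierarchical clustering, exportable as Newick.
* Laplacian-eigenmap 2D embedding of the distance matrix for visualization.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import ConfigError, DisconnectedGraphError
from .metrics import DistanceMatrix

log = logging.getLogger(__name__)

__all__ = [
    "LabeledCollection",
    "KnnResult",
    "HctNode",
    "knn_loocv",
    "knn_bootstrap",
    "average_linkage_hct",
    "laplacian_eigenmap_2d",
]


@dataclass
class LabeledCollection:
    distance: DistanceMatrix
    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = set(self.distance.names) - set(self.labels)
        if missing:
            raise ConfigError(f"no class label for {sorted(missing)[:5]}")

    @property
    def names(self) -> list[str]:
        return list(self.distance.names)

    def filtered(self, min_class_size: int) -> "LabeledCollection":
        """Drop all members of classes with fewer than ``min_class_size``
        neurons (they are removed entirely, not just skipped as queries)."""
        counts: dict[str, int] = {}
        for name in self.names:
            counts[self.labels[name]] = counts.get(self.labels[name], 0) + 1
        keep = [n for n in self.names if counts[self.labels[n]] >= min_class_size]
        idx = [self.distance.names.index(n) for n in keep]
        sub = self.distance.values[np.ix_(idx, idx)]
        return LabeledCollection(
            distance=DistanceMatrix(
                names=keep, values=sub, metric_name=self.distance.metric_name
            ),
            labels={n: self.labels[n] for n in keep},
        )


@dataclass
class KnnResult:
    k: int
    hits: int
    n_evaluated: int
    hit_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def success_rate(self) -> float:
        return self.hits / self.n_evaluated

    def to_json(self, path: str | Path) -> None:
        with open(Path(path), "w") as fh:
            json.dump(
                {
                    "k": self.k,
                    "hits": self.hits,
                    "n_evaluated": self.n_evaluated,
                    "success_rate": self.success_rate,
                    "hit_flags": self.hit_flags,
                },
                fh,
                indent=2,
            )


def _k_nearest(
    names: Sequence[str], values: np.ndarray, i: int, k: int
) -> list[int]:
    """Indices of the k nearest others of item i; distance ties resolved in
    favor of the lexicographically smaller name."""
    order = sorted(
        (j for j in range(len(names)) if j != i),
        key=lambda j: (values[i, j], names[j]),
    )
    if k < len(order) and values[i, order[k - 1]] == values[i, order[k]]:
        log.debug("distance tie at the k-th neighbor of %s", names[i])
    return order[:k]


def knn_loocv(
    collection: LabeledCollection, k: int, min_class_size: int = 2
) -> KnnResult:
    """Leave-one-out k-NN evaluation of a labelled distance matrix."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    c = collection.filtered(min_class_size)
    names, values = c.names, c.distance.values
    if k >= len(names):
        raise ConfigError(
            f"k = {k} is not below the filtered collection size {len(names)}"
        )
    hit_flags: dict[str, bool] = {}
    for i, name in enumerate(names):
        neighbors = _k_nearest(names, values, i, k)
        hit_flags[name] = any(
            c.labels[names[j]] == c.labels[name] for j in neighbors
        )
    hits = sum(hit_flags.values())
    return KnnResult(k=k, hits=hits, n_evaluated=len(names), hit_flags=hit_flags)


def knn_bootstrap(
    collection: LabeledCollection,
    k: int,
    n_rep: int,
    subsample: int,
    seed: int,
    min_class_size: int = 2,
) -> tuple[float, float]:
    """Mean and SD of SR_k over ``n_rep`` subsamples of size ``subsample``
    drawn without replacement; deterministic given the seed."""
    names = collection.names
    if subsample > len(names):
        raise ConfigError("subsample exceeds the collection size")
    rng = np.random.default_rng(seed)
    rates = []
    for _ in range(n_rep):
        chosen = sorted(rng.choice(len(names), size=subsample, replace=False))
        sub_names = [names[i] for i in chosen]
        sub = DistanceMatrix(
            names=sub_names,
            values=collection.distance.values[np.ix_(chosen, chosen)],
            metric_name=collection.distance.metric_name,
        )
        sub_c = LabeledCollection(
            distance=sub, labels={n: collection.labels[n] for n in sub_names}
        )
        rates.append(knn_loocv(sub_c, k, min_class_size).success_rate)
    arr = np.asarray(rates)
    return float(arr.mean()), float(arr.std(ddof=0))


# ---------------------------------------------------------------------------
# clustering


@dataclass
class HctNode:
    """A node of the average-linkage hierarchical clustering tree."""

    merge_height: float
    members: list[str]
    children: list["HctNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""

        def render(node: HctNode, parent_height: float) -> str:
            length = parent_height - node.merge_height
            if node.is_leaf:
                return f"{node.members[0]}:{length:g}"
            inner = ",".join(render(c, node.merge_height) for c in node.children)
            return f"({inner}):{length:g}"

        if self.is_leaf:
            return f"{self.members[0]}:0;"
        inner = ",".join(render(c, self.merge_height) for c in self.children)
        return f"({inner});"


def average_linkage_hct(d: DistanceMatrix) -> HctNode:
    """UPGMA dendrogram of a distance matrix: repeatedly merge the two
    clusters at minimum average inter-cluster distance; the merge height is
    that average."""
    n = len(d.names)
    if n < 2:
        raise ConfigError("clustering needs at least 2 items")
    Z = linkage(squareform(d.values, checks=False), method="average")
    nodes: dict[int, HctNode] = {
        i: HctNode(merge_height=0.0, members=[name]) for i, name in enumerate(d.names)
    }
    for row_idx, (a, b, height, _) in enumerate(Z):
        left, right = nodes.pop(int(a)), nodes.pop(int(b))
        nodes[n + row_idx] = HctNode(
            merge_height=float(height),
            members=sorted(left.members + right.members),
            children=sorted([left, right], key=lambda nd: nd.members),
        )
    (root,) = nodes.values()
    return root


# ---------------------------------------------------------------------------
# embedding


def laplacian_eigenmap_2d(
    d: DistanceMatrix, n_neighbors: int = 10, seed: int = 0
) -> dict[str, tuple[float, float]]:
    """2D Laplacian-eigenmap embedding of a distance matrix.

    A symmetric k-NN graph is built from the distances with heat-kernel
    weights exp(-d^2 / sigma^2), sigma = the median of the included
    distances; coordinates are the eigenvectors of the symmetric normalized
    Laplacian with the two smallest non-zero eigenvalues, each sign-fixed so
    its largest-magnitude entry is positive.  ``seed`` is accepted for
    interface stability; the dense eigensolver is already deterministic.
    """
    n = len(d.names)
    if not (1 <= n_neighbors < n):
        raise ConfigError("need collection size > n_neighbors >= 1")
    del seed  # deterministic dense solve
    values = d.values
    # directed kNN edges, then symmetrize
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        order = np.argsort(values[i])
        picked = [j for j in order if j != i][:n_neighbors]
        mask[i, picked] = True
    mask |= mask.T
    included = values[mask]
    sigma = float(np.median(included))
    if sigma == 0.0:
        sigma = 1.0  # all-coincident points: uniform weights
    # floor keeps structural kNN edges alive when the heat kernel underflows
    # (pairs many bandwidths apart); the coupling stays negligible
    W = np.where(mask, np.maximum(np.exp(-(values**2) / sigma**2), 1e-12), 0.0)
    # connectivity check
    from scipy.sparse.csgraph import connected_components

    n_comp, _ = connected_components(csgraph=(W > 0).astype(int), directed=False)
    if n_comp > 1:
        raise DisconnectedGraphError(
            f"kNN graph has {n_comp} components; raise n_neighbors"
        )
    deg = W.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(n) - (d_inv_sqrt[:, None] * W) * d_inv_sqrt[None, :]
    eigvals, eigvecs = np.linalg.eigh(L)
    # skip the trivial eigenvector (eigenvalue ~ 0)
    coords = eigvecs[:, 1:3]
    # map back from the D^{1/2}-scaled eigenbasis to the embedding
    coords = coords * d_inv_sqrt[:, None]
    for c in range(2):
        col = coords[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    return {name: (float(x), float(y)) for name, (x, y) in zip(d.names, coords)}


def write_embedding(path: str | Path, embedding: Mapping[str, tuple[float, float]]) -> None:
    with open(Path(path), "w") as fh:
        fh.write("name,x,y\n")
        for name, (x, y) in embedding.items():
            fh.write(f"{name},{x:.17g},{y:.17g}\n")
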