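"""Extended persistence diagrams of descriptor functions on trees.

The sweep tracks connected components of the sublevel set {x : f(x) <= t} as
t grows (and, symmetrically, of the superlevel set {x : f(x) >= t} as t
shrinks).  A component is born at a local extremum and dies when it merges
into an older component at a branching node; the elder rule keeps the
component with the more extreme generating value alive.  Each death yields a
finite point (f(extremum), f(merge node)).  The component that survives the
whole sweep contributes the essential pair coupling the global minimum and
the global maximum of f; it is recorded once per sweep direction, so the
merged (extended) diagram carries the essential pair twice — the level-set
count recovery in :mod:`persimorph.sholl` relies on exactly this double
entry.

Implementation: nodes are totally ordered by (value, id) — ties are broken by
id, and the elder rule compares the same key — and processed with a
union-find, giving an O(n log n), sort-dominated algorithm.  Finite points
whose birth equals their death after tie-breaking are discarded: they carry
zero mass in the kernel-density vectorization and zero cost in any matching
distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .descriptors import DescriptorField
from .errors import DisconnectedTreeError

__all__ = [
    "PersistencePoint",
    "PersistenceDiagram",
    "sublevel_diagram",
    "superlevel_diagram",
    "extended_diagram",
]

Origin = Literal["sublevel", "superlevel"]


@dataclass(frozen=True)
class PersistencePoint:
    """One (birth, death) pair with provenance.

    For sublevel points birth < death; for superlevel points birth > death
    (the birth is the value of the dying local maximum).  Essential points
    couple the global extrema of f: (min, max) tagged sublevel and
    (max, min) tagged superlevel.
    """

    birth: float
    death: float
    origin: Origin
    essential: bool
    birth_node: int
    death_node: int

    @property
    def persistence(self) -> float:
        return abs(self.death - self.birth)


@dataclass
class PersistenceDiagram:
    points: list[PersistencePoint]
    f_min: float
    f_max: float
    tree_name: str = ""
    descriptor_name: str = ""

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def finite_points(self, origin: Origin | None = None) -> list[PersistencePoint]:
        return [
            p for p in self.points
            if not p.essential and (origin is None or p.origin == origin)
        ]

    def essential_points(self) -> list[PersistencePoint]:
        return [p for p in self.points if p.essential]

    def as_array(self, include_essential: bool = True) -> np.ndarray:
        """(k, 2) array of (birth, death) rows."""
        pts = [p for p in self.points if include_essential or not p.essential]
        if not pts:
            return np.empty((0, 2))
        return np.array([[p.birth, p.death] for p in pts], dtype=float)

    def multiset(self) -> list[tuple[float, float, str]]:
        """Sorted (birth, death, origin) triples, for multiset comparison."""
        return sorted((p.birth, p.death, p.origin) for p in self.points)

    def to_tsv(self, path: str | Path) -> None:
        with open(Path(path), "w") as fh:
            fh.write("birth\tdeath\torigin\tessential\tbirth_node\tdeath_node\n")
            for p in self.points:
                fh.write(
                    f"{p.birth:.17g}\t{p.death:.17g}\t{p.origin}\t"
                    f"{int(p.essential)}\t{p.birth_node}\t{p.death_node}\n"
                )

    @staticmethod
    def from_tsv(path: str | Path, tree_name: str = "", descriptor_name: str = "") -> "PersistenceDiagram":
        points = []
        with open(Path(path)) as fh:
            header = fh.readline()
            assert header.startswith("birth"), "not a diagram TSV"
            for line in fh:
                b, d, origin, ess, bn, dn = line.split("\t")
                points.append(
                    PersistencePoint(
                        birth=float(b), death=float(d), origin=origin,  # type: ignore[arg-type]
                        essential=bool(int(ess)), birth_node=int(bn), death_node=int(dn),
                    )
                )
        values = [v for p in points for v in (p.birth, p.death)]
        return PersistenceDiagram(
            points=points,
            f_min=min(values) if values else 0.0,
            f_max=max(values) if values else 0.0,
            tree_name=tree_name,
            descriptor_name=descriptor_name,
        )


class _UnionFind:
    """Union-find whose components remember their generating (eldest) node."""

    def __init__(self) -> None:
        self.parent: dict[int, int] = {}
        self.eldest: dict[int, int] = {}  # root of set -> generating node id

    def make(self, nid: int) -> None:
        self.parent[nid] = nid
        self.eldest[nid] = nid

    def find(self, nid: int) -> int:
        root = nid
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[nid] != root:
            self.parent[nid], nid = root, self.parent[nid]
        return root

    def union(self, a: int, b: int, keep_eldest_of: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        self.parent[rb] = ra
        self.eldest[ra] = keep_eldest_of


def _sweep(
    d: DescriptorField, descending: bool
) -> tuple[list[tuple[int, int]], int]:
    """Run the union-find sweep; return finite (extremum node, merge node)
    pairs and the generating node of the surviving component."""
    tree = d.tree
    sign = -1.0 if descending else 1.0
    key = {nid: (sign * d.values[nid], nid) for nid in tree.positions}
    order = sorted(tree.positions, key=key.__getitem__)
    adj = tree.neighbors()
    uf = _UnionFind()
    processed: set[int] = set()
    pairs: list[tuple[int, int]] = []

    for v in order:
        uf.make(v)
        processed.add(v)
        lower_roots: dict[int, int] = {}
        for u in adj[v]:
            if u in processed and u != v:
                r = uf.find(u)
                lower_roots[r] = uf.eldest[r]
        if not lower_roots:
            continue  # v is a local extremum: a new component is born at v
        # elder rule: the component generated at the most extreme key survives
        survivor_root = min(lower_roots, key=lambda r: key[lower_roots[r]])
        survivor_gen = lower_roots[survivor_root]
        for r, gen in lower_roots.items():
            if r != survivor_root:
                pairs.append((gen, v))
        for r in lower_roots:
            uf.union(survivor_root, r, survivor_gen)
        uf.union(survivor_root, v, survivor_gen)

    if len(processed) != tree.n_nodes:
        raise DisconnectedTreeError("descriptor field tree is not connected")
    return pairs, uf.eldest[uf.find(order[0])]


def _half_diagram(d: DescriptorField, origin: Origin) -> PersistenceDiagram:
    descending = origin == "superlevel"
    pairs, survivor = _sweep(d, descending)
    vals = d.values
    points = [
        PersistencePoint(
            birth=vals[m], death=vals[s], origin=origin, essential=False,
            birth_node=m, death_node=s,
        )
        for m, s in pairs
        if vals[m] != vals[s]  # zero-persistence pairs are dropped
    ]
    # essential class: global extremum pair, oriented by sweep direction
    min_node = min(vals, key=lambda n: (vals[n], n))
    max_node = min(vals, key=lambda n: (-vals[n], n))
    if descending:
        ess = PersistencePoint(
            birth=vals[max_node], death=vals[min_node], origin=origin,
            essential=True, birth_node=max_node, death_node=min_node,
        )
    else:
        ess = PersistencePoint(
            birth=vals[min_node], death=vals[max_node], origin=origin,
            essential=True, birth_node=min_node, death_node=max_node,
        )
    points.append(ess)
    return PersistenceDiagram(
        points=points,
        f_min=vals[min_node],
        f_max=vals[max_node],
        tree_name=d.tree.name,
        descriptor_name=d.name,
    )


def sublevel_diagram(d: DescriptorField) -> PersistenceDiagram:
    """Diagram of the ascending sweep (births at local minima, elder rule at
    merges) plus the essential (global min, global max) point."""
    return _half_diagram(d, "sublevel")


def superlevel_diagram(d: DescriptorField) -> PersistenceDiagram:
    """Diagram of the descending sweep: finite points (f(local max), f(merge))
    with birth > death, plus the essential (global max, global min) point."""
    return _half_diagram(d, "superlevel")


def extended_diagram(d: DescriptorField) -> PersistenceDiagram:
    """Merged diagram: union of the sublevel and superlevel sweeps.

    Both essential points are retained, one per sweep direction; a constant
    field yields exactly the two coincident zero-persistence essential
    points.
    """
    lo = sublevel_diagram(d)
    hi = superlevel_diagram(d)
    return PersistenceDiagram(
        points=lo.points + hi.points,
        f_min=lo.f_min,
        f_max=lo.f_max,
        tree_name=d.tree.name,
        descriptor_name=d.name,
    )


def local_minima(d: DescriptorField) -> list[int]:
    """Nodes that are strict local minima under the (value, id) total order."""
    adj = d.tree.neighbors()
    key = {nid: (d.values[nid], nid) for nid in d.tree.positions}
    return sorted(
        v for v in d.tree.positions if all(key[u] > key[v] for u in adj[v])
    )


def local_maxima(d: DescriptorField) -> list[int]:
    """Nodes that are strict local maxima under the (-value, id) total order."""
    adj = d.tree.neighbors()
    key = {nid: (-d.values[nid], nid) for nid in d.tree.positions}
    return sorted(
        v for v in d.tree.positions if all(key[u] > key[v] for u in adj[v])
    )
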