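"""Reading, writing and simplifying SWC neuron reconstructions.

An SWC file is plain text with '#' comment lines and seven whitespace-separated
columns per record: ``id type x y z radius parent`` (root parent = -1).  A file
is turned into a :class:`NeuronTree`: a rooted geometric tree embedded in 3D
whose arcs carry positive length weights in µm.  Process thickness (the radius
column) is carried along but plays no role in any downstream computation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .errors import (
    CycleError,
    MissingParentError,
    MultipleRootsError,
    ParseError,
)

log = logging.getLogger(__name__)

__all__ = ["SwcRecord", "NeuronTree", "read_swc", "write_swc", "simplify_tree"]


@dataclass(frozen=True)
class SwcRecord:
    """One line of an SWC file."""

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent: int

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class NeuronTree:
    """Rooted geometric tree in 3D with weighted arcs.

    Arcs are stored child-side: ``parents[child] = parent`` and
    ``arc_weights[child]`` is the length (µm) of the arc from the parent to
    that child.  Weights default to the chord (Euclidean) distance between the
    endpoint positions but may be set explicitly, e.g. to polyline lengths by
    :func:`simplify_tree`.
    """

    name: str
    root: int
    positions: dict[int, np.ndarray]
    parents: dict[int, int]
    radii: dict[int, float] = field(default_factory=dict)
    type_codes: dict[int, int] = field(default_factory=dict)
    arc_weights: dict[int, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for nid in self.positions:
            self.radii.setdefault(nid, 1.0)
            self.type_codes.setdefault(nid, 0)
        for child, parent in self.parents.items():
            if child not in self.arc_weights:
                w = float(
                    np.linalg.norm(self.positions[child] - self.positions[parent])
                )
                self.arc_weights[child] = w
        self.validate()

    # -- structure -----------------------------------------------------

    @property
    def node_ids(self) -> list[int]:
        return sorted(self.positions)

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    def arcs(self) -> Iterator[tuple[int, int, float]]:
        """Yield (parent, child, weight) for every arc."""
        for child, parent in self.parents.items():
            yield parent, child, self.arc_weights[child]

    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {nid: [] for nid in self.positions}
        for child, parent in self.parents.items():
            ch[parent].append(child)
        for lst in ch.values():
            lst.sort()
        return ch

    def neighbors(self) -> dict[int, list[int]]:
        """Undirected adjacency (parent and children of each node)."""
        adj: dict[int, list[int]] = {nid: [] for nid in self.positions}
        for child, parent in self.parents.items():
            adj[parent].append(child)
            adj[child].append(parent)
        return adj

    def degree(self, nid: int) -> int:
        return len(self.neighbors()[nid])

    def leaves(self) -> list[int]:
        adj = self.neighbors()
        return sorted(n for n in self.positions if len(adj[n]) == 1 and n != self.root)

    def branch_nodes(self) -> list[int]:
        adj = self.neighbors()
        return sorted(n for n in self.positions if len(adj[n]) > 2)

    def total_cable_length(self) -> float:
        return float(sum(self.arc_weights.values()))

    def topological_order(self) -> list[int]:
        """Root-first order in which every parent precedes its children."""
        ch = self.children()
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(ch[v]))
        return order

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        if not self.positions:
            raise ParseError("tree has no nodes")
        if self.root not in self.positions:
            raise ParseError(f"root id {self.root} has no position")
        if self.root in self.parents:
            raise ParseError("root must not have a parent")
        if set(self.parents) != set(self.positions) - {self.root}:
            raise ParseError("every non-root node needs exactly one parent")
        for child, parent in self.parents.items():
            if parent not in self.positions:
                raise MissingParentError(f"node {child} references missing {parent}")
        for nid, pos in self.positions.items():
            if pos.shape != (3,) or not np.all(np.isfinite(pos)):
                raise ParseError(f"node {nid} has a non-finite position")
        for child, w in self.arc_weights.items():
            if not (w > 0.0) or not math.isfinite(w):
                raise ParseError(f"arc to node {child} has non-positive weight {w}")
        # parent pointers on a finite id set with a single root are acyclic
        # iff every node reaches the root
        seen_order = set(self.topological_order())
        if seen_order != set(self.positions):
            raise CycleError("parent pointers do not span the tree from the root")

    # -- transforms ----------------------------------------------------

    def relabel(self, mapping: dict[int, int]) -> "NeuronTree":
        """Return a copy with node ids renamed through ``mapping``."""
        return NeuronTree(
            name=self.name,
            root=mapping[self.root],
            positions={mapping[n]: p.copy() for n, p in self.positions.items()},
            parents={mapping[c]: mapping[p] for c, p in self.parents.items()},
            radii={mapping[n]: r for n, r in self.radii.items()},
            type_codes={mapping[n]: t for n, t in self.type_codes.items()},
            arc_weights={mapping[c]: w for c, w in self.arc_weights.items()},
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "NeuronTree":
        """Return a copy with positions mapped through ``R @ p + t``."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return NeuronTree(
            name=self.name,
            root=self.root,
            positions={n: R @ p + t for n, p in self.positions.items()},
            parents=dict(self.parents),
            radii=dict(self.radii),
            type_codes=dict(self.type_codes),
            arc_weights=dict(self.arc_weights),
        )


# ---------------------------------------------------------------------------
# parsing


def _parse_line(line: str, lineno: int, path: str) -> SwcRecord | None:
    stripped = line.strip()
    if not stripped or stripped.startswith("#"):
        return None
    fields = stripped.split()
    if len(fields) != 7:
        raise ParseError(f"{path}:{lineno}: expected 7 fields, got {len(fields)}")
    try:
        rec = SwcRecord(
            id=int(fields[0]),
            type_code=int(fields[1]),
            x=float(fields[2]),
            y=float(fields[3]),
            z=float(fields[4]),
            radius=float(fields[5]),
            parent=int(fields[6]),
        )
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not all(math.isfinite(v) for v in (rec.x, rec.y, rec.z, rec.radius)):
        raise ParseError(f"{path}:{lineno}: non-finite coordinate")
    if rec.id <= 0:
        raise ParseError(f"{path}:{lineno}: node id must be positive")
    return rec


def tree_from_records(
    records: Iterable[SwcRecord], name: str = "", forest: bool = False
) -> NeuronTree:
    """Assemble a :class:`NeuronTree` from SWC records (two-pass; file order free).

    Zero-length arcs (child at the same coordinates as its parent) are
    collapsed into the parent with a logged warning, because every downstream
    descriptor requires strictly positive arc weights.
    """
    recs = list(records)
    by_id: dict[int, SwcRecord] = {}
    for r in recs:
        if r.id in by_id:
            raise ParseError(f"duplicate node id {r.id}")
        by_id[r.id] = r
    roots = [r.id for r in recs if r.parent == -1]
    if not roots:
        raise ParseError("no root record (parent = -1)")
    for r in recs:
        if r.parent != -1 and r.parent not in by_id:
            raise MissingParentError(f"node {r.id} references missing parent {r.parent}")
    if len(roots) > 1:
        if not forest:
            raise MultipleRootsError(
                f"{len(roots)} roots found; pass forest=True to keep the "
                "largest component"
            )
        comp = _largest_component(by_id, roots)
        log.warning(
            "%s: forest with %d roots; keeping largest component (%d of %d nodes)",
            name, len(roots), len(comp), len(recs),
        )
        recs = [by_id[i] for i in comp]
        by_id = {r.id: r for r in recs}
        roots = [r.id for r in recs if r.parent == -1]
    root = roots[0]

    _check_acyclic(by_id, root)

    # collapse zero-length arcs: remap the child onto its parent
    alias: dict[int, int] = {}

    def resolve(nid: int) -> int:
        while nid in alias:
            nid = alias[nid]
        return nid

    for r in sorted(by_id.values(), key=lambda r: r.id):
        if r.parent == -1:
            continue
        parent = resolve(r.parent)
        if np.allclose(r.position, by_id[parent].position, rtol=0.0, atol=0.0):
            alias[r.id] = parent
            log.warning("%s: collapsing zero-length arc %d -> %d", name, r.id, parent)

    positions, radii, types, parents = {}, {}, {}, {}
    for r in by_id.values():
        if r.id in alias:
            continue
        positions[r.id] = r.position
        radii[r.id] = r.radius
        types[r.id] = r.type_code
        if r.parent != -1:
            parents[r.id] = resolve(r.parent)
    return NeuronTree(
        name=name, root=root, positions=positions, parents=parents,
        radii=radii, type_codes=types,
    )


def _largest_component(by_id: dict[int, SwcRecord], roots: list[int]) -> set[int]:
    comp_of: dict[int, int] = {}
    children: dict[int, list[int]] = {i: [] for i in by_id}
    for r in by_id.values():
        if r.parent != -1:
            children[r.parent].append(r.id)
    comps: list[set[int]] = []
    for root in roots:
        comp, stack = set(), [root]
        while stack:
            v = stack.pop()
            if v in comp:
                raise CycleError("cycle among parent pointers")
            comp.add(v)
            stack.extend(children[v])
        comps.append(comp)
    claimed = set().union(*comps)
    if claimed != set(by_id):
        raise CycleError("records unreachable from any root (cycle)")
    return max(comps, key=lambda c: (len(c), -min(c)))


def _check_acyclic(by_id: dict[int, SwcRecord], root: int) -> None:
    state: dict[int, int] = {}
    for start in by_id:
        chain = []
        nid = start
        while nid != -1 and state.get(nid) is None:
            state[nid] = 1
            chain.append(nid)
            nid = by_id[nid].parent
        if nid != -1 and state.get(nid) == 1 and nid in chain:
            raise CycleError(f"cycle through node {nid}")
        for c in chain:
            state[c] = 2


def read_swc(path: str | Path, name: str | None = None, forest: bool = False) -> NeuronTree:
    """Read an SWC file into a :class:`NeuronTree`.

    Parameters
    ----------
    path:
        File to read. '#' lines are comments; records may appear in any order.
    name:
        Label for the tree; defaults to the file stem.
    forest:
        If the file contains several parent=-1 records, keep the largest
        connected component instead of raising :class:`MultipleRootsError`.
    """
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = _parse_line(line, lineno, str(path))
            if rec is not None:
                records.append(rec)
    return tree_from_records(records, name=name or path.stem, forest=forest)


def write_swc(tree: NeuronTree, path: str | Path) -> None:
    """Write a tree as standard 7-column SWC (round-trips exactly)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {tree.name}\n# id type x y z radius parent\n")
        for nid in tree.node_ids:
            p = tree.positions[nid]
            parent = tree.parents.get(nid, -1)
            fh.write(
                f"{nid} {tree.type_codes[nid]} {p[0]:.17g} {p[1]:.17g} "
                f"{p[2]:.17g} {tree.radii[nid]:.17g} {parent}\n"
            )


# ---------------------------------------------------------------------------
# simplification


def simplify_tree(tree: NeuronTree, mode: str = "chord") -> NeuronTree:
    """Drop degree-2 nodes, keeping the root, leaves and branching nodes.

    Consecutive kept nodes along the original tree are joined by a single arc.
    Under the default ``mode="chord"`` the arc weight is the straight-line
    Euclidean distance between the endpoint positions; ``mode="polyline"``
    instead sums the lengths of the replaced original segments, preserving
    root-to-node geodesic distances exactly.
    """
    if mode not in ("chord", "polyline"):
        raise ValueError(f"unknown mode {mode!r}")
    adj = tree.neighbors()
    keep = {
        nid
        for nid in tree.positions
        if nid == tree.root or len(adj[nid]) != 2
    }
    ch = tree.children()
    parents: dict[int, int] = {}
    weights: dict[int, float] = {}
    # walk down from each kept node to the next kept node on each branch
    for anchor in keep:
        for first in ch[anchor]:
            path_len = tree.arc_weights[first]
            node = first
            while node not in keep:
                (node,) = ch[node]  # degree-2: exactly one child
                path_len += tree.arc_weights[node]
            parents[node] = anchor
            if mode == "polyline":
                weights[node] = path_len
            else:
                weights[node] = float(
                    np.linalg.norm(tree.positions[node] - tree.positions[anchor])
                )
    return NeuronTree(
        name=tree.name,
        root=tree.root,
        positions={n: tree.positions[n].copy() for n in keep},
        parents=parents,
        radii={n: tree.radii[n] for n in keep},
        type_codes={n: tree.type_codes[n] for n in keep},
        arc_weights=weights,
    )
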