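"""Real-valued descriptor functions on neuron trees.

A descriptor assigns one real value to every tree node and is understood as a
piecewise-linear (PL) function on the whole tree: values are linearly
interpolated along arcs, so all critical points of the function lie at nodes.
The two geometric descriptors shipped here are the Euclidean (radial) distance
to the root and the geodesic (path-length) distance to the root; arbitrary
node-valued functions (branch angles, section radii, electrotonic measures
computed elsewhere) enter through :func:`descriptor_from_values`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import MissingValueError, NonFiniteValueError
from .swc_io import NeuronTree

__all__ = [
    "DescriptorField",
    "euclidean_descriptor",
    "geodesic_descriptor",
    "descriptor_from_values",
]


@dataclass(frozen=True)
class DescriptorField:
    """A real value per tree node, PL-extended along arcs."""

    tree: NeuronTree
    values: dict[int, float]
    name: str

    def __post_init__(self) -> None:
        missing = set(self.tree.positions) - set(self.values)
        if missing:
            raise MissingValueError(f"no descriptor value for nodes {sorted(missing)[:5]}")
        extra = set(self.values) - set(self.tree.positions)
        if extra:
            raise MissingValueError(f"descriptor values for unknown nodes {sorted(extra)[:5]}")
        for nid, v in self.values.items():
            if not math.isfinite(v):
                raise NonFiniteValueError(f"descriptor value at node {nid} is {v}")

    def __getitem__(self, nid: int) -> float:
        return self.values[nid]

    def min(self) -> float:
        return min(self.values.values())

    def max(self) -> float:
        return max(self.values.values())

    def negated(self) -> "DescriptorField":
        return DescriptorField(
            tree=self.tree,
            values={n: -v for n, v in self.values.items()},
            name=f"-{self.name}",
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(Path(path), "w") as fh:
            fh.write("node_id\tvalue\n")
            for nid in self.tree.node_ids:
                fh.write(f"{nid}\t{self.values[nid]:.17g}\n")


def euclidean_descriptor(tree: NeuronTree, negate: bool = False) -> DescriptorField:
    """Euclidean (radial) distance from each node to the root.

    With ``negate=True`` the sign is flipped so the root carries the highest
    value; the persistence sweep handles either sign, so the positive
    convention is the default.
    """
    root_pos = tree.positions[tree.root]
    sign = -1.0 if negate else 1.0
    values = {
        nid: sign * float(np.linalg.norm(pos - root_pos))
        for nid, pos in tree.positions.items()
    }
    name = "-euclidean" if negate else "euclidean"
    return DescriptorField(tree=tree, values=values, name=name)


def geodesic_descriptor(tree: NeuronTree) -> DescriptorField:
    """Geodesic distance from each node to the root: the total arc length of
    the unique root-to-node path.  Monotone non-decreasing along every
    root-to-leaf path, which the radial descriptor need not be."""
    values = {tree.root: 0.0}
    for nid in tree.topological_order():
        if nid == tree.root:
            continue
        values[nid] = values[tree.parents[nid]] + tree.arc_weights[nid]
    return DescriptorField(tree=tree, values=values, name="geodesic")


def descriptor_from_values(
    tree: NeuronTree, values: Mapping[int, float], name: str
) -> DescriptorField:
    """Wrap an arbitrary node-valued function for downstream persistence."""
    return DescriptorField(tree=tree, values={n: float(v) for n, v in values.items()}, name=name)
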