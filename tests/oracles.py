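"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the library's sweep/assignment code paths: the
diagram oracle recomputes connected components from scratch at every
threshold, and the matching oracles enumerate every partial matching.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np

from persimorph.descriptors import DescriptorField


def components_of(nodes: set[int], adj: dict[int, list[int]]) -> list[set[int]]:
    """Connected components of the induced subgraph on ``nodes``."""
    remaining = set(nodes)
    comps = []
    while remaining:
        start = remaining.pop()
        comp, stack = {start}, [start]
        while stack:
            v = stack.pop()
            for u in adj[v]:
                if u in remaining:
                    remaining.discard(u)
                    comp.add(u)
                    stack.append(u)
        comps.append(comp)
    return comps


def brute_force_diagram(field: DescriptorField, origin: str) -> list[tuple[float, float, str]]:
    """Recompute the one-sided diagram by tracking component generators over
    every prefix of the total node order; returns (birth, death, origin)
    triples with zero-persistence finite pairs dropped, essential included."""
    tree = field.tree
    adj = tree.neighbors()
    sign = -1.0 if origin == "superlevel" else 1.0
    key = {n: (sign * field.values[n], n) for n in tree.positions}
    order = sorted(tree.positions, key=key.__getitem__)

    def generator(comp: set[int]) -> int:
        return min(comp, key=key.__getitem__)

    points = []
    prev_gens: set[int] = set()
    active: set[int] = set()
    for v in order:
        active.add(v)
        comps = components_of(active, adj)
        gens = {generator(c) for c in comps}
        died = prev_gens - gens
        for g in died:
            if field.values[g] != field.values[v]:
                points.append((field.values[g], field.values[v], origin))
        prev_gens = gens
    min_node = min(tree.positions, key=lambda n: (field.values[n], n))
    max_node = min(tree.positions, key=lambda n: (-field.values[n], n))
    if origin == "superlevel":
        points.append((field.values[max_node], field.values[min_node], origin))
    else:
        points.append((field.values[min_node], field.values[max_node], origin))
    return sorted(points)


def brute_force_extended(field: DescriptorField) -> list[tuple[float, float, str]]:
    return sorted(
        brute_force_diagram(field, "sublevel") + brute_force_diagram(field, "superlevel")
    )


def _linf(p: Sequence[float], q: Sequence[float]) -> float:
    return max(abs(p[0] - q[0]), abs(p[1] - q[1]))


def _diag_cost(p: Sequence[float]) -> float:
    return abs(p[1] - p[0]) / 2.0


def enumerate_matching_cost(
    pts1: np.ndarray, pts2: np.ndarray, aggregate: str = "sum"
) -> float:
    """Minimum total (or maximum, for bottleneck) cost over every partial
    matching between two small diagrams; unmatched points pay their distance
    to the diagonal."""
    n1, n2 = len(pts1), len(pts2)
    best = None
    for r in range(min(n1, n2) + 1):
        for subset1 in itertools.combinations(range(n1), r):
            for subset2 in itertools.permutations(range(n2), r):
                matched_costs = [
                    _linf(pts1[i], pts2[j]) for i, j in zip(subset1, subset2)
                ]
                unmatched = [
                    _diag_cost(pts1[i]) for i in range(n1) if i not in subset1
                ] + [
                    _diag_cost(pts2[j]) for j in range(n2) if j not in set(subset2)
                ]
                costs = matched_costs + unmatched
                if aggregate == "sum":
                    total = sum(costs)
                else:
                    total = max(costs) if costs else 0.0
                if best is None or total < best:
                    best = total
    return best if best is not None else 0.0


def loocv_reimplementation(names, values, labels, k):
    """Straight-line re-implementation of the leave-one-out k-NN loop,
    independent of persimorph.analysis (same tie rule: smaller name wins)."""
    flags = {}
    for i, name in enumerate(names):
        ranked = sorted(
            (j for j in range(len(names)) if j != i),
            key=lambda j: (values[i][j], names[j]),
        )[:k]
        flags[name] = any(labels[names[j]] == labels[name] for j in ranked)
    return flags
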