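"""Random SWC-style geometric trees with class-structured branching statistics.

The generator grows a rooted tree tip by tip: at every step each active tip
either bifurcates (probability ``branch_prob``, while its branch depth is
below ``max_depth``) into two daughter tips, each extending by its own
segment, or extends by a single segment.  Segment lengths are log-normal
(strictly positive) with a given mean and coefficient of variation; segment
directions are drawn within a spherical cap of half-angle
``branch_angle_spread`` around the parent direction, so neurites meander
rather than random-walk.  Everything is deterministic given the seed.

Collections of labelled trees (several classes, several trees per class) are
produced with per-tree seeds spawned from the collection seed, and can be
written to disk as a directory of SWC files plus a ``labels.tsv`` map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateTreeError
from .swc_io import NeuronTree, write_swc

__all__ = [
    "GrowthParams",
    "generate_tree",
    "generate_labeled_collection",
    "write_collection",
]


@dataclass(frozen=True)
class GrowthParams:
    """Parameters controlling synthetic tree growth.

    branch_prob
        Per-tip, per-step bifurcation probability (0 < p <= 1).
    mean_segment_length
        Mean segment length in µm (> 0).
    segment_length_cv
        Coefficient of variation of segment length (0 for fixed lengths).
    max_depth
        Maximum number of bifurcations along any root-to-tip path.
    branch_angle_spread
        Half-angle (radians) of the spherical cap around the parent
        direction from which new segment directions are drawn.
    n_steps
        Number of growth iterations over the active tips.
    seed
        RNG seed; identical params + seed give identical trees.
    """

    branch_prob: float = 0.3
    mean_segment_length: float = 50.0
    segment_length_cv: float = 0.3
    max_depth: int = 6
    branch_angle_spread: float = 0.6
    n_steps: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ValueError("branch_prob must be in [0, 1]")
        if self.mean_segment_length <= 0:
            raise ValueError("mean_segment_length must be > 0")
        if self.segment_length_cv < 0:
            raise ValueError("segment_length_cv must be >= 0")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


def _segment_length(p: GrowthParams, rng: np.random.Generator) -> float:
    if p.segment_length_cv == 0.0:
        return p.mean_segment_length
    # log-normal with E[L] = mean and SD[L]/E[L] = cv
    sigma2 = math.log(1.0 + p.segment_length_cv**2)
    mu = math.log(p.mean_segment_length) - sigma2 / 2.0
    return float(rng.lognormal(mean=mu, sigma=math.sqrt(sigma2)))


def _cap_direction(axis: np.ndarray, half_angle: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform direction within the spherical cap of ``half_angle`` around ``axis``."""
    if half_angle <= 0.0:
        return axis.copy()
    cos_min = math.cos(min(half_angle, math.pi))
    c = rng.uniform(cos_min, 1.0)
    s = math.sqrt(max(0.0, 1.0 - c * c))
    phi = rng.uniform(0.0, 2.0 * math.pi)
    local = np.array([s * math.cos(phi), s * math.sin(phi), c])
    # rotate the z axis onto `axis`
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    if np.linalg.norm(v) < 1e-12:
        return local if axis[2] > 0 else -local
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    R = np.eye(3) + vx + vx @ vx * ((1 - axis @ z) / (np.linalg.norm(v) ** 2))
    out = R @ local
    return out / np.linalg.norm(out)


def _uniform_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def generate_tree(p: GrowthParams, name: str = "synthetic", _max_retries: int = 8) -> NeuronTree:
    """Grow one random tree; raises :class:`DegenerateTreeError` only if
    repeated attempts produce a single node (cannot happen for n_steps >= 1
    with positive segment lengths, but guarded for safety)."""
    for attempt in range(_max_retries):
        rng = np.random.default_rng(np.random.SeedSequence(p.seed).spawn(1)[0]) \
            if attempt else np.random.default_rng(p.seed)
        tree = _grow(p, rng, name)
        if tree.n_nodes > 1:
            return tree
    raise DegenerateTreeError(f"growth produced a single node after {p.n_steps} steps")


def _grow(p: GrowthParams, rng: np.random.Generator, name: str) -> NeuronTree:
    positions: dict[int, np.ndarray] = {1: np.zeros(3)}
    parents: dict[int, int] = {}
    next_id = 2
    # tips: (node id, direction, depth)
    tips: list[tuple[int, np.ndarray, int]] = [(1, _uniform_direction(rng), 0)]
    eligible_tip_steps = 0
    branch_events = 0

    def extend(node: int, direction: np.ndarray) -> tuple[int, np.ndarray]:
        nonlocal next_id
        d = _cap_direction(direction, p.branch_angle_spread, rng)
        length = _segment_length(p, rng)
        positions[next_id] = positions[node] + length * d
        parents[next_id] = node
        nid = next_id
        next_id += 1
        return nid, d

    for _ in range(p.n_steps):
        new_tips: list[tuple[int, np.ndarray, int]] = []
        for node, direction, depth in tips:
            branch = False
            if depth < p.max_depth:
                eligible_tip_steps += 1
                branch = bool(rng.random() < p.branch_prob)
            if branch:
                branch_events += 1
                for _ in range(2):
                    nid, d = extend(node, direction)
                    new_tips.append((nid, d, depth + 1))
            else:
                nid, d = extend(node, direction)
                new_tips.append((nid, d, depth))
        tips = new_tips

    tree = NeuronTree(
        name=name,
        root=1,
        positions=positions,
        parents=parents,
        type_codes={nid: (1 if nid == 1 else 3) for nid in positions},
        meta={
            "eligible_tip_steps": eligible_tip_steps,
            "branch_events": branch_events,
            "params": p,
        },
    )
    return tree


def _tree_seed(collection_seed: int, class_index: int, tree_index: int) -> int:
    """Deterministic per-tree seed, stable under re-ordering of the request."""
    ss = np.random.SeedSequence(collection_seed, spawn_key=(class_index, tree_index))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def generate_labeled_collection(
    class_params: Sequence[tuple[str, GrowthParams, int]],
    collection_seed: int = 0,
) -> tuple[list[NeuronTree], dict[str, str]]:
    """Generate ``count`` trees per (label, params) entry.

    Returns the trees and a map tree name -> class label.  Tree names are
    ``{label}_{index:03d}``; per-tree seeds are spawned deterministically from
    ``collection_seed`` and the (class, tree) indices so that regenerating a
    subset reproduces the same trees.
    """
    trees: list[NeuronTree] = []
    labels: dict[str, str] = {}
    for ci, (label, params, count) in enumerate(class_params):
        if count < 1:
            raise ValueError("count must be >= 1")
        for ti in range(count):
            seed = _tree_seed(collection_seed, ci, ti)
            tree = generate_tree(replace(params, seed=seed), name=f"{label}_{ti:03d}")
            trees.append(tree)
            labels[tree.name] = label
    return trees, labels


def write_collection(
    trees: Sequence[NeuronTree], labels: dict[str, str], out_dir: str | Path
) -> None:
    """Write SWC files and a ``labels.tsv`` (filename <TAB> class) map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "labels.tsv", "w") as fh:
        for tree in trees:
            write_swc(tree, out / f"{tree.name}.swc")
            fh.write(f"{tree.name}.swc\t{labels[tree.name]}\n")
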