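import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from persimorph.swc_io import NeuronTree
from persimorph.synthgen import GrowthParams, generate_tree


@pytest.fixture
def y_tree() -> NeuronTree:
    """Y-shaped tree: root -- branch -- two leaves, embedded on the x axis so
    that both geodesic and Euclidean root distances are 0, 1, 3, 2."""
    return NeuronTree(
        name="y",
        root=1,
        positions={
            1: np.array([0.0, 0.0, 0.0]),
            2: np.array([1.0, 0.0, 0.0]),
            3: np.array([3.0, 0.0, 0.0]),
            4: np.array([2.0, 0.0, 0.0]),
        },
        parents={2: 1, 3: 2, 4: 2},
    )


@pytest.fixture
def path_tree() -> NeuronTree:
    """Collinear unit-spaced 5-node path along x."""
    return NeuronTree(
        name="path5",
        root=1,
        positions={i: np.array([float(i - 1), 0.0, 0.0]) for i in range(1, 6)},
        parents={i: i - 1 for i in range(2, 6)},
    )


def make_path(values_len: int, name: str = "path") -> NeuronTree:
    return NeuronTree(
        name=name,
        root=1,
        positions={i: np.array([float(i - 1), 0.0, 0.0]) for i in range(1, values_len + 1)},
        parents={i: i - 1 for i in range(2, values_len + 1)},
    )


def random_tree(seed: int, small: bool = False) -> NeuronTree:
    """Random synthetic tree; ``small=True`` keeps it at <= 41 nodes, the
    default at <= 161."""
    if small:
        params = GrowthParams(
            branch_prob=0.35, mean_segment_length=20.0, max_depth=3,
            n_steps=5, seed=seed,
        )
    else:
        params = GrowthParams(
            branch_prob=0.35, mean_segment_length=20.0, max_depth=4,
            n_steps=10, seed=seed,
        )
    return generate_tree(params, name=f"rand{seed}")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230817)
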