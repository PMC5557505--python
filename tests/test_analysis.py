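import numpy as np
import pytest

from persimorph.analysis import (
    LabeledCollection,
    average_linkage_hct,
    knn_bootstrap,
    knn_loocv,
    laplacian_eigenmap_2d,
)
from persimorph.errors import ConfigError
from persimorph.metrics import DistanceMatrix
from oracles import loocv_reimplementation


def matrix(names, values):
    return DistanceMatrix(names=list(names), values=np.asarray(values, dtype=float))


def planted_two_class(n_per=5, gap=10.0, jitter=0.5, seed=0):
    """Distance matrix of two tight clusters separated by ``gap``."""
    rng = np.random.default_rng(seed)
    names = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
    labels = {n: n[0] for n in names}
    x = np.concatenate([
        rng.uniform(0, jitter, n_per), gap + rng.uniform(0, jitter, n_per)
    ])
    values = np.abs(x[:, None] - x[None, :])
    return LabeledCollection(distance=matrix(names, values), labels=labels)


class TestKnnLoocv:
    def test_twin_per_class_gives_perfect_sr1(self):
        names = ["a1", "a2", "b1", "b2"]
        v = np.array([
            [0, 0.1, 5, 5],
            [0.1, 0, 5, 5],
            [5, 5, 0, 0.1],
            [5, 5, 0.1, 0],
        ])
        c = LabeledCollection(distance=matrix(names, v), labels={n: n[0] for n in names})
        assert knn_loocv(c, 1).success_rate == 1.0

    def test_all_singleton_classes_never_hit(self):
        names = ["a", "b", "c"]
        v = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        c = LabeledCollection(distance=matrix(names, v), labels={n: n for n in names})
        for k in (1, 2):
            assert knn_loocv(c, k, min_class_size=1).success_rate == 0.0

    def test_small_classes_removed_entirely(self):
        names = ["a1", "a2", "solo", "b1", "b2"]
        v = np.zeros((5, 5))
        # 'solo' sits right next to a1; if it stayed in the candidate pool it
        # would change nothing, but it must not be evaluated either
        coords = {"a1": 0.0, "a2": 1.0, "solo": 0.1, "b1": 10.0, "b2": 11.0}
        xs = np.array([coords[n] for n in names])
        v = np.abs(xs[:, None] - xs[None, :])
        labels = {"a1": "a", "a2": "a", "solo": "s", "b1": "b", "b2": "b"}
        res = knn_loocv(LabeledCollection(distance=matrix(names, v), labels=labels), 1)
        assert res.n_evaluated == 4
        assert "solo" not in res.hit_flags
        assert res.success_rate == 1.0  # a1's nearest *remaining* item is a2

    def test_k_too_large_rejected(self):
        c = planted_two_class(n_per=2)
        with pytest.raises(ConfigError):
            knn_loocv(c, k=10)

    def test_agrees_with_independent_reimplementation(self):
        c = planted_two_class(n_per=10, gap=3.0, jitter=2.0, seed=5)
        for k in (1, 3, 5):
            res = knn_loocv(c, k)
            expect = loocv_reimplementation(
                c.names, c.distance.values, dict(c.labels), k
            )
            assert res.hit_flags == expect

    def test_hit_flags_invariant_to_rescaling(self):
        c = planted_two_class(seed=3)
        scaled = LabeledCollection(
            distance=matrix(c.names, 17.0 * c.distance.values), labels=c.labels
        )
        assert knn_loocv(c, 2).hit_flags == knn_loocv(scaled, 2).hit_flags

    def test_sr_monotone_in_k(self):
        c = planted_two_class(n_per=8, gap=2.0, jitter=1.9, seed=7)
        rates = [knn_loocv(c, k).success_rate for k in range(1, 6)]
        assert all(b >= a for a, b in zip(rates, rates[1:]))


class TestBootstrap:
    def test_full_subsample_has_zero_sd(self):
        c = planted_two_class()
        mean, sd = knn_bootstrap(c, k=1, n_rep=5, subsample=len(c.names), seed=0)
        assert sd == 0.0
        assert mean == knn_loocv(c, 1).success_rate

    def test_single_rep_zero_sd(self):
        c = planted_two_class()
        _, sd = knn_bootstrap(c, k=1, n_rep=1, subsample=6, seed=1)
        assert sd == 0.0

    def test_deterministic_given_seed(self):
        c = planted_two_class(n_per=8)
        out1 = knn_bootstrap(c, k=1, n_rep=10, subsample=10, seed=4)
        out2 = knn_bootstrap(c, k=1, n_rep=10, subsample=10, seed=4)
        assert out1 == out2


class TestHct:
    def test_two_items_single_merge(self):
        m = matrix(["a", "b"], [[0, 3], [3, 0]])
        root = average_linkage_hct(m)
        assert root.merge_height == pytest.approx(3.0)
        assert sorted(root.members) == ["a", "b"]

    def test_hand_upgma_on_three_items(self):
        m = matrix(["A", "B", "C"], [[0, 1, 4], [1, 0, 4], [4, 4, 0]])
        root = average_linkage_hct(m)
        assert root.merge_height == pytest.approx(4.0)
        inner = [c for c in root.children if not c.is_leaf]
        assert len(inner) == 1
        assert inner[0].merge_height == pytest.approx(1.0)
        assert inner[0].members == ["A", "B"]

    def test_planted_partition_splits_at_root(self):
        c = planted_two_class(n_per=6, seed=2)
        root = average_linkage_hct(c.distance)
        sides = [set(ch.members) for ch in root.children]
        expect = [
            {n for n in c.names if n.startswith("a")},
            {n for n in c.names if n.startswith("b")},
        ]
        assert sides == expect or sides == expect[::-1]

    def test_newick_has_all_leaves(self):
        c = planted_two_class(n_per=3, seed=1)
        nwk = average_linkage_hct(c.distance).newick()
        assert nwk.endswith(";")
        for name in c.names:
            assert name in nwk

    def test_heights_invariant_to_input_order(self):
        c = planted_two_class(n_per=5, seed=9)
        perm = np.random.default_rng(0).permutation(len(c.names))
        names_p = [c.names[i] for i in perm]
        m_p = matrix(names_p, c.distance.values[np.ix_(perm, perm)])
        h1 = sorted(_all_heights(average_linkage_hct(c.distance)))
        h2 = sorted(_all_heights(average_linkage_hct(m_p)))
        assert h1 == pytest.approx(h2)


def _all_heights(node):
    if node.is_leaf:
        return []
    return [node.merge_height] + [h for c in node.children for h in _all_heights(c)]


class TestEigenmap:
    def test_three_equidistant_items_embed_symmetrically(self):
        m = matrix(["a", "b", "c"], [[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        emb = laplacian_eigenmap_2d(m, n_neighbors=2)
        pts = np.array(list(emb.values()))
        dists = sorted(
            np.linalg.norm(pts[i] - pts[j])
            for i in range(3) for j in range(i + 1, 3)
        )
        assert dists[2] - dists[0] < 1e-9

    def test_planted_clusters_separated_by_first_coordinate(self):
        c = planted_two_class(n_per=6, gap=50.0, seed=11)
        # n_neighbors must reach across the gap for a connected graph
        emb = laplacian_eigenmap_2d(c.distance, n_neighbors=6)
        xs_a = [emb[n][0] for n in c.names if n.startswith("a")]
        xs_b = [emb[n][0] for n in c.names if n.startswith("b")]
        assert max(xs_a) < min(xs_b) or max(xs_b) < min(xs_a)

    def test_deterministic(self):
        c = planted_two_class(n_per=5, seed=13)
        e1 = laplacian_eigenmap_2d(c.distance, n_neighbors=5, seed=1)
        e2 = laplacian_eigenmap_2d(c.distance, n_neighbors=5, seed=1)
        assert e1 == e2

    def test_disconnected_graph_reported(self):
        from persimorph.errors import DisconnectedGraphError
        c = planted_two_class(n_per=6, gap=50.0, seed=11)
        with pytest.raises(DisconnectedGraphError):
            laplacian_eigenmap_2d(c.distance, n_neighbors=4)
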