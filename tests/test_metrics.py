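import numpy as np
import pytest

from persimorph.descriptors import geodesic_descriptor
from persimorph.errors import (
    ConfigMismatchError,
    GridMismatchError,
    MissingFeatureError,
    OrderMismatchError,
)
from persimorph.metrics import (
    DistanceMatrix,
    LMeasureVector,
    bottleneck,
    combined_distance,
    lmeasure_collection_stats,
    lmeasure_distance,
    lp_vector_distance,
    pairwise_matrix,
    sholl_distance,
    wasserstein1,
)
from persimorph.persistence import extended_diagram
from persimorph.sholl import sholl_vector
from persimorph.signatures import SignatureConfig, collection_range, vectorize
from conftest import random_tree
from test_signatures import diagram_from_pairs
from oracles import enumerate_matching_cost


class TestWasserstein:
    def test_identity(self, y_tree):
        dg = extended_diagram(geodesic_descriptor(y_tree))
        assert wasserstein1(dg, dg) == pytest.approx(0.0, abs=1e-12)

    def test_single_point_vs_empty(self):
        d1 = diagram_from_pairs([(0.0, 2.0)])
        d2 = diagram_from_pairs([])
        assert wasserstein1(d1, d2) == pytest.approx(1.0)

    def test_match_beats_double_diagonal(self):
        d1 = diagram_from_pairs([(0.0, 2.0)])
        d2 = diagram_from_pairs([(0.0, 3.0)])
        assert wasserstein1(d1, d2) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_exact_against_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        def small_diagram():
            k = int(rng.integers(0, 5))
            pts = []
            for _ in range(k):
                b = float(rng.uniform(-2, 2))
                pts.append((b, b + float(rng.uniform(0.05, 3))))
            return diagram_from_pairs(pts)
        d1, d2 = small_diagram(), small_diagram()
        expect = enumerate_matching_cost(d1.as_array(), d2.as_array(), "sum")
        assert wasserstein1(d1, d2) == pytest.approx(expect, abs=1e-9)


class TestBottleneck:
    def test_identity_and_single_point(self):
        d1 = diagram_from_pairs([(0.0, 2.0)])
        assert bottleneck(d1, d1) == pytest.approx(0.0, abs=1e-12)
        assert bottleneck(d1, diagram_from_pairs([])) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(15))
    def test_exact_against_enumeration(self, seed):
        rng = np.random.default_rng(seed + 100)
        def small_diagram():
            k = int(rng.integers(0, 4))
            return diagram_from_pairs([
                (b := float(rng.uniform(-2, 2)), b + float(rng.uniform(0.05, 3)))
                for _ in range(k)
            ])
        d1, d2 = small_diagram(), small_diagram()
        expect = enumerate_matching_cost(d1.as_array(), d2.as_array(), "max")
        assert bottleneck(d1, d2) == pytest.approx(expect, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_bounded_by_wasserstein(self, seed):
        d1 = extended_diagram(geodesic_descriptor(random_tree(seed, small=True)))
        d2 = extended_diagram(geodesic_descriptor(random_tree(seed + 50, small=True)))
        assert bottleneck(d1, d2) <= wasserstein1(d1, d2) + 1e-9


class TestVectorDistances:
    def _vec(self, values):
        cfg = SignatureConfig(kernel_width=1.0, dimension=len(values), a=0.0, b=1.0)
        from persimorph.signatures import PersistenceVector
        return PersistenceVector(values=np.asarray(values, dtype=float), config=cfg)

    def test_lp_arithmetic(self):
        v1, v2 = self._vec([1.0, 2.0]), self._vec([2.0, 4.0])
        assert lp_vector_distance(v1, v1) == 0.0
        assert lp_vector_distance(v1, v2, p=1) == pytest.approx(3.0)
        assert lp_vector_distance(v1, v2, p=2) == pytest.approx(np.sqrt(5))

    def test_config_mismatch_rejected(self):
        v1 = self._vec([1.0, 2.0])
        cfg = SignatureConfig(kernel_width=2.0, dimension=2, a=0.0, b=1.0)
        from persimorph.signatures import PersistenceVector
        v2 = PersistenceVector(values=np.array([1.0, 2.0]), config=cfg)
        with pytest.raises(ConfigMismatchError):
            lp_vector_distance(v1, v2)

    def test_dv_scales_with_kernel_mass(self, y_tree):
        dg = extended_diagram(geodesic_descriptor(y_tree))
        doubled = diagram_from_pairs(
            [(p.birth, p.birth + 2 * (p.death - p.birth)) for p in dg.points]
        )
        a, b = collection_range([dg, doubled])
        cfg = SignatureConfig(kernel_width=1.0, dimension=20, a=a, b=b)
        zero = diagram_from_pairs([(0.0, 0.0)])
        d1 = lp_vector_distance(vectorize(dg, cfg), vectorize(zero, cfg))
        d2 = lp_vector_distance(vectorize(doubled, cfg), vectorize(zero, cfg))
        assert d2 == pytest.approx(2 * d1, rel=1e-9)


class TestShollDistance:
    def test_identical_profiles(self, y_tree):
        p = sholl_vector(y_tree, 50, 3.0)
        assert sholl_distance(p, p) == 0.0

    def test_two_paths_differ_on_the_gap(self):
        from test_sholl import segment_tree
        long, short = segment_tree(10.0), segment_tree(5.0)
        p1 = sholl_vector(long, 100, 10.0)
        p2 = sholl_vector(short, 100, 10.0)
        assert sholl_distance(p1, p2) == pytest.approx(50.0)

    def test_grid_mismatch_rejected(self, y_tree):
        p1 = sholl_vector(y_tree, 50, 3.0)
        p2 = sholl_vector(y_tree, 50, 4.0)
        with pytest.raises(GridMismatchError):
            sholl_distance(p1, p2)


class TestLMeasure:
    def _collection(self):
        return [
            LMeasureVector("a", {"length": 10.0, "angle": 30.0, "flat": 1.0}),
            LMeasureVector("b", {"length": 20.0, "angle": 40.0, "flat": 1.0}),
            LMeasureVector("c", {"length": 30.0, "angle": 20.0, "flat": 1.0}),
        ]

    def test_zero_variance_feature_dropped(self):
        with pytest.warns(UserWarning, match="flat"):
            stats = lmeasure_collection_stats(self._collection())
        assert set(stats) == {"length", "angle"}

    def test_identity_and_one_sd_shift(self):
        vecs = self._collection()
        with pytest.warns(UserWarning):
            stats = lmeasure_collection_stats(vecs)
        assert lmeasure_distance(vecs[0], vecs[0], stats) == 0.0
        sd = stats["length"][1]
        shifted = LMeasureVector("d", {**dict(vecs[0].features), "length": vecs[0].features["length"] + sd})
        assert lmeasure_distance(vecs[0], shifted, stats) == pytest.approx(1.0)

    def test_invariant_to_affine_rescaling_of_a_feature(self):
        vecs = self._collection()
        rescaled = [
            LMeasureVector(v.name, {**dict(v.features), "length": 7.0 * v.features["length"] - 3.0})
            for v in vecs
        ]
        with pytest.warns(UserWarning):
            s1 = lmeasure_collection_stats(vecs)
        with pytest.warns(UserWarning):
            s2 = lmeasure_collection_stats(rescaled)
        assert lmeasure_distance(vecs[0], vecs[1], s1) == pytest.approx(
            lmeasure_distance(rescaled[0], rescaled[1], s2), rel=1e-12
        )

    def test_missing_feature_raises(self):
        vecs = self._collection()
        with pytest.warns(UserWarning):
            stats = lmeasure_collection_stats(vecs)
        with pytest.raises(MissingFeatureError):
            lmeasure_distance(vecs[0], LMeasureVector("e", {"length": 1.0}), stats)


class TestCombined:
    def _mat(self, values, names=("a", "b", "c")):
        return DistanceMatrix(names=list(names), values=np.asarray(values, dtype=float))

    def test_equal_inputs_are_a_fixed_point(self):
        m = self._mat([[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        out = combined_distance(m, m)
        assert np.allclose(out.values, m.values / m.values.max())

    def test_degenerate_weights_project(self):
        dv = self._mat([[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        dl = self._mat([[0, 5, 1], [5, 0, 2], [1, 2, 0]])
        out = combined_distance(dv, dl, weights=(1.0, 0.0))
        assert np.allclose(out.values, dv.values / dv.values.max())

    def test_hand_computed_mix(self):
        dv = self._mat([[0, 2, 4], [2, 0, 2], [4, 2, 0]])
        dl = self._mat([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        out = combined_distance(dv, dl)
        expect = 0.5 * dv.values / 4.0 + 0.5 * dl.values / 2.0
        assert np.allclose(out.values, expect)

    def test_order_mismatch_rejected(self):
        dv = self._mat([[0, 1], [1, 0]], names=("a", "b"))
        dl = self._mat([[0, 1], [1, 0]], names=("b", "a"))
        with pytest.raises(OrderMismatchError):
            combined_distance(dv, dl)


class TestPairwiseMatrix:
    def test_identical_items_give_zero_matrix(self, y_tree):
        dg = extended_diagram(geodesic_descriptor(y_tree))
        m = pairwise_matrix([dg, dg], wasserstein1, names=["a", "b"])
        assert np.allclose(m.values, 0.0)

    @pytest.mark.parametrize("metric_name", ["dP", "dV"])
    def test_metric_axioms_on_random_trees(self, metric_name):
        trees = [random_tree(s, small=True) for s in range(8)]
        diagrams = [extended_diagram(geodesic_descriptor(t)) for t in trees]
        if metric_name == "dP":
            m = pairwise_matrix(diagrams, wasserstein1, names=[t.name for t in trees])
        else:
            a, b = collection_range(diagrams)
            cfg = SignatureConfig(kernel_width=10.0, dimension=30, a=a, b=b)
            vecs = [vectorize(d, cfg) for d in diagrams]
            m = pairwise_matrix(vecs, lp_vector_distance, names=[t.name for t in trees])
        v = m.values
        assert np.allclose(v, v.T)
        assert np.all(np.diag(v) == 0)
        n = len(trees)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert v[i, j] <= v[i, k] + v[k, j] + 1e-9

    def test_csv_round_trip(self, tmp_path):
        m = DistanceMatrix(names=["a", "b"], values=np.array([[0.0, 2.5], [2.5, 0.0]]),
                           metric_name="dV")
        m.to_csv(tmp_path / "m.csv")
        back = DistanceMatrix.from_csv(tmp_path / "m.csv")
        assert back.names == m.names
        assert np.allclose(back.values, m.values)
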