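import numpy as np
import pandas as pd
import pytest

from oice.graph import CausalGraph
from oice.scm import LinearMechanism, StructuralCausalModel, mmd


class TestGenerate:
    def test_hand_evaluation(self, toy_scm):
        np.testing.assert_allclose(toy_scm.generate(np.array([1.0, 0.0])), [1.0, 2.0])

    def test_do_on_root_propagates(self, toy_scm):
        np.testing.assert_allclose(
            toy_scm.generate(np.array([1.0, 0.0]), {"X1": 5.0}), [5.0, 10.0])

    def test_do_on_leaf_leaves_rest_unchanged(self, toy_scm):
        u = np.array([0.3, -1.2])
        base = toy_scm.generate(u)
        pinned = toy_scm.generate(u, {"X2": 9.0})
        assert pinned[1] == 9.0
        assert pinned[0] == base[0]

    def test_batch_generation_matches_single(self, toy_scm):
        u = np.random.default_rng(0).standard_normal((5, 2))
        batch = toy_scm.generate(u)
        for i in range(5):
            np.testing.assert_allclose(batch[i], toy_scm.generate(u[i]))

    def test_do_semantics_nondescendants_fixed(self):
        """Pinned node changes only its descendants, over random SCMs/nodes."""
        rng = np.random.default_rng(11)
        for trial in range(20):
            d = int(rng.integers(3, 7))
            nodes = [f"N{i}" for i in range(d)]
            edges = [(nodes[i], nodes[j]) for i in range(d) for j in range(i + 1, d)
                     if rng.random() < 0.4]
            graph = CausalGraph(nodes, edges)
            mechs = {
                n: LinearMechanism(n, graph.parents(n),
                                   rng.normal(size=len(graph.parents(n))),
                                   rng.normal(), float(rng.uniform(0.5, 2.0)))
                for n in nodes
            }
            scm = StructuralCausalModel.from_mechanisms(graph, mechs)
            u = rng.standard_normal(d)
            k = nodes[int(rng.integers(d))]
            base = scm.generate(u)
            pinned = scm.generate(u, {k: 3.21})
            desc = graph.descendants(k)
            for i, n in enumerate(nodes):
                if n != k and n not in desc:
                    assert pinned[i] == base[i], (trial, n)


class TestAbduct:
    def test_invert_by_hand(self, toy_scm):
        np.testing.assert_allclose(toy_scm.abduct(np.array([1.0, 2.0])), [1.0, 0.0])

    def test_round_trip_identity(self, toy_scm):
        rng = np.random.default_rng(3)
        for _ in range(100):
            x = rng.normal(scale=3.0, size=2)
            u = toy_scm.abduct(x)
            np.testing.assert_allclose(toy_scm.generate(u), x, atol=1e-8)

    def test_root_only_closed_form(self):
        g = CausalGraph(["X"], [])
        scm = StructuralCausalModel.from_mechanisms(
            g, {"X": LinearMechanism("X", [], [], 4.0, 2.0)})
        np.testing.assert_allclose(scm.abduct(np.array([10.0])), [(10.0 - 4.0) / 2.0])

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            LinearMechanism("X", [], [], 0.0, 0.0)


class TestMMD:
    def test_identical_sets_zero(self):
        a = np.random.default_rng(0).normal(size=(100, 3))
        assert mmd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(50, 2)), rng.normal(loc=1.0, size=(60, 2))
        assert mmd(a, b) == pytest.approx(mmd(b, a), rel=1e-12)

    def test_separation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, size=(500, 1))
        a2 = rng.normal(0, 1, size=(500, 1))
        b = rng.normal(5, 1, size=(500, 1))
        bw = [1.0]
        assert mmd(a, b, bandwidths=bw) > mmd(a, a2, bandwidths=bw)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            mmd(np.zeros((3, 2)), np.zeros((3, 4)))


@pytest.fixture(scope="module")
def linear_data():
    rng = np.random.default_rng(42)
    x = rng.standard_normal(1000)
    y = 1.5 * x + 0.5 * rng.standard_normal(1000)
    return pd.DataFrame({"X": x, "Y": y})


@pytest.fixture(scope="module")
def fitted(linear_data):
    graph = CausalGraph(["X", "Y"], [("X", "Y")])
    return StructuralCausalModel(graph, epochs=300, seed=0).fit(linear_data)


class TestFit:
    def test_loss_decreases(self, fitted):
        assert fitted.loss_trace_[-1] < fitted.loss_trace_[0]

    def test_interventional_mean_recovered(self, fitted):
        u = np.random.default_rng(1).standard_normal((4000, 2))
        x_std = (2.0 - fitted.means_[0]) / fitted.scales_[0]
        raw = fitted.destandardize(fitted.generate(u, {"X": x_std}))
        assert raw[:, 1].mean() == pytest.approx(3.0, abs=0.3)

    def test_seeded_determinism(self, linear_data):
        graph = CausalGraph(["X", "Y"], [("X", "Y")])
        a = StructuralCausalModel(graph, epochs=30, seed=5).fit(linear_data)
        b = StructuralCausalModel(graph, epochs=30, seed=5).fit(linear_data)
        assert a.loss_trace_ == b.loss_trace_

    def test_checkpoint_round_trip(self, fitted, tmp_path):
        fitted.save(tmp_path / "scm.json")
        loaded = StructuralCausalModel.load(tmp_path / "scm.json")
        u = np.random.default_rng(2).standard_normal((10, 2))
        np.testing.assert_allclose(loaded.generate(u), fitted.generate(u), atol=1e-12)
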