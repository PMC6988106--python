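"""Potential-learning networks: similarity algebra, training, prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from learngc.nets import (NetConfig, NNet, TNet, TrainConfig, fit_n_net,
                          fit_t_net, label_similarity, load_checkpoint,
                          make_edge_training_set, make_training_set,
                          n_net_predict, save_checkpoint, similarity_features,
                          t_net_predict)

DIMS = (5, 5, 7)
SMALL = NetConfig(channels=(2, 4), feature_dim=4, hidden=8)

unit = st.floats(0.0, 1.0)


def make_tnet(seed=0, n_scales=1, cfg=SMALL):
    return TNet(DIMS, n_scales, cfg, np.random.default_rng(seed))


def make_nnet(seed=0, n_scales=1, cfg=SMALL):
    net = NNet(DIMS, n_scales, cfg, np.random.default_rng(seed))
    net.d_min, net.d_max = 0.0, 2.0
    return net


def two_class_patches(n, rng, n_scales=1):
    """Bright-vs-dark synthetic patches with 5 sigma mean separation."""
    y = rng.integers(0, 2, size=n).astype(float)
    x = rng.normal(0.0, 1.0, size=(n, n_scales) + DIMS)
    x += y[:, None, None, None, None] * 5.0
    return x, y


class TestSimilarityAlgebra:
    @pytest.mark.parametrize("li,lj,expected", [(1, 1, 1), (1, 0, 0),
                                                (0, 0, 1), (0.5, 0.5, 0.5)])
    def test_label_similarity_table(self, li, lj, expected):
        assert label_similarity(li, lj) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            label_similarity(1.5, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(unit, unit)
    def test_label_similarity_symmetric_bounded(self, a, b):
        m = label_similarity(a, b)
        assert m == pytest.approx(label_similarity(b, a))
        assert 0.0 <= m <= 1.0

    def test_feature_similarity_binary_identities(self):
        f = np.array([1.0, 0.0, 1.0, 0.0])
        assert np.allclose(similarity_features(f, f), 1.0)
        assert np.allclose(similarity_features(f, 1 - f), 0.0)
        half = np.full(4, 0.5)
        assert np.allclose(similarity_features(half, half), 0.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(unit, min_size=1, max_size=6))
    def test_feature_similarity_complement_invariant(self, vals):
        f = np.asarray(vals)
        g = similarity_features(f, f)
        assert np.allclose(similarity_features(1 - f, 1 - f), g)
        assert np.all((g >= 0) & (g <= 1))

    def test_feature_length_mismatch(self):
        with pytest.raises(ValueError):
            similarity_features(np.zeros(3), np.zeros(4))


class TestTNet:
    def test_zeroed_final_layer_predicts_half(self):
        net = make_tnet()
        net.head.layers[-2].w[:] = 0.0
        net.head.layers[-2].b[:] = 0.0
        x = np.random.default_rng(0).normal(size=(4, 1) + DIMS)
        assert np.allclose(net.forward(x), 0.5)

    def test_pure_function(self):
        net = make_tnet()
        x = np.random.default_rng(1).normal(size=(3, 1) + DIMS)
        assert np.array_equal(net.forward(x), net.forward(x))

    def test_dim_mismatch_raises(self):
        net = make_tnet()
        with pytest.raises(ValueError, match="expected patches"):
            net.forward(np.zeros((2, 1, 3, 3, 3)))

    def test_memorizes_single_sample(self):
        net = make_tnet(seed=2)
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 1) + DIMS)
        cfg = TrainConfig(lr=1.0, batch_size=1, weight_decay=0.0)
        losses = fit_t_net(net, x, np.array([1.0]), cfg, rng, epochs=200)
        assert losses[-1] < 1e-3

    def test_zero_lr_leaves_parameters_unchanged(self):
        net = make_tnet(seed=4)
        before = [np.copy(getattr(p["layer"], p["name"])) for p in net.params()]
        rng = np.random.default_rng(5)
        x, y = two_class_patches(20, rng)
        fit_t_net(net, x, y, TrainConfig(lr=0.0, weight_decay=0.0), rng, epochs=2)
        after = [getattr(p["layer"], p["name"]) for p in net.params()]
        for b, a in zip(before, after):
            assert np.array_equal(b, a)

    def test_learns_separable_patches(self):
        rng = np.random.default_rng(6)
        x, y = two_class_patches(2000, rng)
        net = make_tnet(seed=7)
        cfg = TrainConfig(lr=0.05, epochs_t=6)
        losses = fit_t_net(net, x[:1500], y[:1500], cfg, rng)
        pred = t_net_predict(net, x[1500:])
        acc = np.mean((pred > 0.5) == (y[1500:] > 0.5))
        assert acc >= 0.95
        # training curve decreases in >= 90% of epochs
        drops = sum(b < a for a, b in zip(losses, losses[1:]))
        assert drops >= 0.9 * (len(losses) - 1)

    def test_checkpoint_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        x, y = two_class_patches(60, rng)
        net = make_tnet(seed=9)
        fit_t_net(net, x, y, TrainConfig(lr=0.05), rng, epochs=2)
        path = str(tmp_path / "t_net.npz")
        save_checkpoint(net, path)
        clone = load_checkpoint(path)
        assert np.allclose(t_net_predict(clone, x), t_net_predict(net, x))


class TestNNet:
    def test_symmetric_under_swap(self):
        net = make_nnet()
        rng = np.random.default_rng(0)
        xi = rng.normal(size=(5, 1) + DIMS)
        xj = rng.normal(size=(5, 1) + DIMS)
        d = rng.uniform(0, 2, size=5)
        assert np.allclose(n_net_predict(net, xi, xj, d),
                           n_net_predict(net, xj, xi, d), atol=1e-12)

    def test_output_in_unit_interval(self):
        net = make_nnet(seed=1)
        rng = np.random.default_rng(2)
        xi = rng.normal(size=(100, 1) + DIMS) * 10
        out = n_net_predict(net, xi, xi[::-1], rng.uniform(0, 2, 100))
        assert np.all((out >= 0) & (out <= 1))

    def test_negative_distance_rejected(self):
        net = make_nnet()
        x = np.zeros((1, 1) + DIMS)
        with pytest.raises(ValueError, match="non-negative"):
            net.forward(x, x, np.array([-1.0]))

    def test_learns_pair_similarity(self):
        rng = np.random.default_rng(3)
        xi, yi = two_class_patches(1200, rng)
        xj, yj = two_class_patches(1200, rng)
        d = rng.uniform(0.5, 1.5, size=1200)
        m = label_similarity(yi, yj)
        net = make_nnet(seed=4)
        fit_n_net(net, xi[:900], xj[:900], d[:900], m[:900],
                  TrainConfig(lr=0.05, epochs_n=6), rng)
        pred = n_net_predict(net, xi[900:], xj[900:], d[900:])
        # held-out AUC of predicted similarity against true similarity
        order = np.argsort(pred)
        ranks = np.empty(len(pred))
        ranks[order] = np.arange(1, len(pred) + 1)
        pos = m[900:] == 1
        auc = (ranks[pos].sum() - pos.sum() * (pos.sum() + 1) / 2) / \
            (pos.sum() * (~pos).sum())
        assert auc >= 0.9


class TestTrainingSets:
    def _mesh_labels(self, tiny_mesh, n_scar=40, seed=0):
        labels = np.zeros(tiny_mesh.n_nodes)
        rng = np.random.default_rng(seed)
        start = int(rng.integers(tiny_mesh.n_nodes))
        from learngc.surface import geodesic_distances
        d = geodesic_distances(tiny_mesh, [start])[0]
        labels[np.argsort(d)[:n_scar]] = 1.0  # one geodesic blob of scar
        return labels

    def test_balanced_counts(self, tiny_mesh):
        labels = self._mesh_labels(tiny_mesh)
        sample = make_training_set(tiny_mesh, labels, np.random.default_rng(0))
        n_fg = len(sample.scar_nodes) + len(sample.boundary_nodes)
        assert len(sample.background_nodes) == n_fg
        assert len(sample.scar_nodes) == 40
        assert set(np.unique(labels[sample.scar_nodes])) == {1.0}
        # boundary nodes are background nodes adjacent to scar
        assert set(np.unique(labels[sample.boundary_nodes])) == {0.0}

    def test_reproducible_by_seed(self, tiny_mesh):
        labels = self._mesh_labels(tiny_mesh)
        a = make_training_set(tiny_mesh, labels, np.random.default_rng(5))
        b = make_training_set(tiny_mesh, labels, np.random.default_rng(5))
        assert np.array_equal(a.nodes, b.nodes)

    def test_no_scar_raises(self, tiny_mesh):
        with pytest.raises(ValueError, match="no scar"):
            make_training_set(tiny_mesh, np.zeros(tiny_mesh.n_nodes),
                              np.random.default_rng(0))

    def test_all_scar_raises(self, tiny_mesh):
        with pytest.raises(ValueError, match="background"):
            make_training_set(tiny_mesh, np.ones(tiny_mesh.n_nodes),
                              np.random.default_rng(0))

    def test_edge_set_labels(self, tiny_mesh):
        labels = self._mesh_labels(tiny_mesh)
        sample = make_training_set(tiny_mesh, labels, np.random.default_rng(1))
        edges, d, m = make_edge_training_set(tiny_mesh, labels, sample.nodes,
                                             np.random.default_rng(2))
        assert len(edges) == len(d) == len(m)
        assert np.all(d > 0)
        expect = label_similarity(labels[edges[:, 0]], labels[edges[:, 1]])
        assert np.allclose(m, expect)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        net = make_tnet(seed=1, n_scales=2,
                        cfg=NetConfig(channels=(2,), feature_dim=3, hidden=4))
        x = rng.normal(size=(2, 2) + DIMS)
        y = np.array([1.0, 0.0])

        def loss():
            return float(np.mean((net.forward(x) - y) ** 2))

        pred = net.forward(x)
        net.backward(2 * (pred - y) / len(y))
        for p in net.params():
            w = getattr(p["layer"], p["name"])
            g = getattr(p["layer"], "g" + p["name"])
            for _ in range(2):
                ix = tuple(rng.integers(0, s) for s in w.shape)
                old = w[ix]
                eps = 1e-6
                w[ix] = old + eps
                lp = loss()
                w[ix] = old - eps
                lm = loss()
                w[ix] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g[ix], abs=1e-6, rel=1e-3)
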