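"""Learned-optimizer adaptation: selection counts, preprocessing, contracts."""
from __future__ import annotations

import numpy as np
import pytest

from semgintent.adaptation import (
    CAEObjective,
    OptimizerNetwork,
    PredictorObjective,
    TunedParamSpec,
    adapt_online,
    conv4_quarter_spec,
    fc3_all_spec,
    fc3_even_rows_spec,
    fc4_all_spec,
    optimizer_step,
    preprocess_gradient,
    relative_growth_rate,
    train_optimizer,
)
from semgintent.cae import CAE
from semgintent.nn import Dense
from semgintent.predictor import Predictor

RNG = np.random.default_rng


class TestParamSelection:
    def test_fc3_count_matches_closed_form(self):
        p = Predictor(seed=0)
        spec = fc3_even_rows_spec(p.fc3)
        n_nodes = p.fc3.params["weight"].shape[1]
        n_rows = p.fc3.params["weight"].shape[0] // 2
        assert spec.count == n_nodes * (n_rows + 1)  # 100·(100+1)
        assert spec.count == 10_100

    def test_conv4_count_matches_closed_form(self):
        cae = CAE(seed=0)
        spec = conv4_quarter_spec(cae.adaptable_conv)
        out_ch, in_ch, kh, kw = cae.adaptable_conv.params["weight"].shape
        assert spec.count == (in_ch // 4) * out_ch * kh * kw + out_ch  # 20·40·16+40
        assert spec.count == 12_840

    def test_fc3_all_larger_than_even(self):
        p = Predictor(seed=0)
        assert fc3_all_spec(p.fc3).count == 20_100
        assert fc3_even_rows_spec(p.fc3).count < fc3_all_spec(p.fc3).count
        assert fc4_all_spec(p.fc4).count == 101

    def test_even_rows_toy_example(self):
        """6×2 weight matrix: 1-based even rows are indices 1, 3, 5."""
        layer = Dense(6, 2, RNG(0), np.float64)
        w = np.arange(12.0).reshape(6, 2)
        layer.params["weight"][:] = w
        layer.params["bias"][:] = [100.0, 200.0]
        spec = fc3_even_rows_spec(layer)
        # node 0: rows 1,3,5 column 0 then bias 0; node 1 likewise
        expected = [w[1, 0], w[3, 0], w[5, 0], 100.0, w[1, 1], w[3, 1], w[5, 1], 200.0]
        np.testing.assert_allclose(spec.gather(), expected)
        assert spec.count == 2 * (3 + 1)

    def test_gather_scatter_round_trip(self):
        p = Predictor(seed=1)
        spec = fc3_even_rows_spec(p.fc3)
        before_w = p.fc3.params["weight"].copy()
        vec = spec.gather()
        new = vec + 1.0
        spec.scatter(new)
        np.testing.assert_allclose(spec.gather(), new, rtol=1e-6)
        spec.scatter(vec)
        np.testing.assert_array_equal(p.fc3.params["weight"], before_w)

    def test_scatter_never_touches_complement(self):
        cae = CAE(seed=2)
        conv = cae.adaptable_conv
        spec = conv4_quarter_spec(conv)
        w_before = conv.params["weight"].copy()
        spec.scatter(spec.gather() + 5.0)
        changed = conv.params["weight"] != w_before
        # exactly the selected in-channels changed: 0-based 3, 7, ..., 79
        sel = np.zeros(80, dtype=bool)
        sel[3::4] = True
        assert changed[:, sel].all()
        assert not changed[:, ~sel].any()

    def test_wrong_length_rejected(self):
        p = Predictor(seed=0)
        spec = fc3_even_rows_spec(p.fc3)
        with pytest.raises(ValueError):
            spec.scatter(np.zeros(spec.count - 1))


class TestPreprocessGradient:
    def test_branch_values(self):
        out = preprocess_gradient(np.array([1.0, -1.0, 0.0]))
        np.testing.assert_allclose(out[0], [0.0, 1.0])   # log|1|/10, sign +
        np.testing.assert_allclose(out[1], [0.0, -1.0])
        np.testing.assert_allclose(out[2], [-1.0, 0.0])  # small branch

    def test_threshold_continuity(self):
        p = 10.0
        g = np.exp(-p)  # exactly at the threshold
        above = preprocess_gradient(np.array([g * 1.000001]), p)
        below = preprocess_gradient(np.array([g * 0.999999]), p)
        np.testing.assert_allclose(above[0], below[0], atol=1e-4)

    def test_first_component_bounded(self):
        g = RNG(0).standard_normal(1000) * np.logspace(-8, 3, 1000)
        out = preprocess_gradient(g, 10.0)
        assert np.all(out[:, 0] >= -1.0)
        assert np.all(out[:, 0] <= np.log(np.abs(g).max()) / 10.0 + 1e-12)

    def test_small_branch_scaling(self):
        g = np.array([1e-8])
        out = preprocess_gradient(g, 10.0)
        np.testing.assert_allclose(out[0], [-1.0, np.exp(10.0) * 1e-8])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            preprocess_gradient(np.array([np.nan]))


class TestOptimizerNetwork:
    def test_zero_weights_zero_update(self):
        net = OptimizerNetwork(seed=0)
        for layer in net.layers:
            for k in layer.params:
                layer.params[k][:] = 0.0
        theta = RNG(1).standard_normal(50)
        g = RNG(2).standard_normal(50)
        state = net.init_state(50)
        new_theta, _ = optimizer_step(theta, g, state, net)
        np.testing.assert_array_equal(new_theta, theta)

    def test_deterministic(self):
        theta = RNG(3).standard_normal(20)
        g = RNG(4).standard_normal(20)
        deltas = []
        for _ in range(2):
            net = OptimizerNetwork(seed=5)
            d, _, _ = net.step(theta, g, net.init_state(20))
            deltas.append(d)
        np.testing.assert_array_equal(deltas[0], deltas[1])

    def test_fresh_network_is_a_no_op(self):
        """Before meta-training the optimizer outputs zero updates."""
        net = OptimizerNetwork(seed=11)
        theta = RNG(12).standard_normal(25)
        g = RNG(13).standard_normal(25)
        new_theta, _ = optimizer_step(theta, g, net.init_state(25), net)
        np.testing.assert_array_equal(new_theta, theta)

    @staticmethod
    def _trained_like(seed):
        """Network with a non-zero output layer (as after meta-training)."""
        net = OptimizerNetwork(seed=seed)
        rng = RNG(seed + 1000)
        net.fc_out.params["weight"][:] = rng.standard_normal(
            net.fc_out.params["weight"].shape).astype(net.dtype) * 0.3
        net.fc_out.params["bias"][:] = 0.01
        return net

    def test_coordinatewise_sharing(self):
        """Identical (θ, g) coordinates receive identical updates."""
        net = self._trained_like(6)
        theta = np.array([0.5, 0.5, -0.2])
        g = np.array([0.1, 0.1, 0.3])
        d, _, _ = net.step(theta, g, net.init_state(3))
        assert d[0] == pytest.approx(d[1])
        assert d[0] != pytest.approx(d[2])

    def test_state_carries_information(self):
        net = self._trained_like(7)
        theta = RNG(8).standard_normal(10)
        g = RNG(9).standard_normal(10)
        s0 = net.init_state(10)
        d1, s1, _ = net.step(theta, g, s0)
        d2_fresh, _, _ = net.step(theta, g, s0)
        d2_cont, _, _ = net.step(theta, g, s1)
        np.testing.assert_array_equal(d1, d2_fresh)
        assert not np.allclose(d2_cont, d2_fresh)

    def test_length_mismatch_rejected(self):
        net = OptimizerNetwork(seed=0)
        with pytest.raises(ValueError):
            optimizer_step(np.zeros(3), np.zeros(4), net.init_state(3), net)


class QuadraticObjective:
    """f(θ) = ½‖θ − θ*‖²: analytic test bed for meta-training."""

    def __init__(self, n=30, seed=0):
        rng = RNG(seed)
        self.target = rng.standard_normal(n)
        self.theta = rng.standard_normal(n)
        self.rng = rng

    def gather(self):
        return self.theta.copy()

    def scatter(self, vec):
        self.theta = vec.copy()

    def loss_grad(self, batch=None):
        d = self.theta - self.target
        return 0.5 * float(d @ d), d


class TestMetaTraining:
    def test_meta_training_learns_descent_on_quadratic(self):
        obj = QuadraticObjective(n=30, seed=0)
        net = OptimizerNetwork(seed=1)
        hist = train_optimizer(net, obj, lambda e: [None] * 6, epochs=40,
                               unroll=5, lr=0.01, reset_every=10)
        assert np.isfinite(hist).all()
        # after meta-training, 5 optimizer steps beat the starting loss
        theta = obj.gather()
        loss0, g = obj.loss_grad()
        state = net.init_state(theta.size)
        for _ in range(5):
            theta, state = optimizer_step(theta, g, state, net)
            obj.scatter(theta)
            loss, g = obj.loss_grad()
        assert loss < loss0

    def test_restores_initial_parameters(self):
        obj = QuadraticObjective(n=10, seed=2)
        theta0 = obj.gather()
        net = OptimizerNetwork(seed=3)
        train_optimizer(net, obj, lambda e: [None] * 4, epochs=6, unroll=3,
                        lr=0.01, reset_every=2)
        np.testing.assert_array_equal(obj.gather(), theta0)

    def test_history_length(self):
        obj = QuadraticObjective(n=5, seed=4)
        net = OptimizerNetwork(seed=5)
        hist = train_optimizer(net, obj, lambda e: [None] * 4, epochs=7,
                               unroll=3, lr=0.01)
        assert len(hist) == 7

    def test_requires_trained_base(self):
        cae = CAE(seed=0)  # untrained
        obj = CAEObjective(cae)
        net = OptimizerNetwork(seed=0)
        with pytest.raises(RuntimeError):
            train_optimizer(net, obj, lambda e: [], epochs=1)


class TestAdaptOnline:
    def test_only_tuned_subset_changes(self):
        cae = CAE(seed=4)
        cae.trained = True
        obj = CAEObjective(cae)
        snap = {i: {k: v.copy() for k, v in l.params.items()}
                for i, l in enumerate(cae.layers)}
        net = OptimizerNetwork(seed=5)
        imgs = 0.3 * RNG(6).standard_normal((2, 20, 9, 200)).astype(np.float32)
        adapt_online(obj, net, [imgs[0], imgs[1]], n_iterations=2)
        conv4 = cae.adaptable_conv
        sel = np.zeros(80, dtype=bool)
        sel[3::4] = True
        for i, l in enumerate(cae.layers):
            for k, v in l.params.items():
                if l is conv4 and k == "bias":
                    continue  # tuned
                if l is conv4 and k == "weight":
                    np.testing.assert_array_equal(v[:, ~sel], snap[i][k][:, ~sel])
                else:
                    np.testing.assert_array_equal(v, snap[i][k])

    def test_independence_cae_vs_predictor(self):
        """Adapting the predictor never changes CAE parameters, and the
        predictor objective's gradients cannot reach the CAE."""
        cae = CAE(seed=7)
        cae.trained = True
        p = Predictor(seed=8)
        p.trained = True
        cae_snap = [{k: v.copy() for k, v in l.params.items()} for l in cae.layers]
        motion = RNG(9).standard_normal((10, 7, 5)).astype(np.float32)
        feat = RNG(10).standard_normal((10, 7, 120)).astype(np.float32)
        targets = RNG(11).standard_normal(10)
        obj = PredictorObjective(p)
        for l in cae.layers:
            l.zero_grad()
        obj.loss_grad((motion, feat, targets))
        for l in cae.layers:
            for g in l.grads.values():
                assert np.all(g == 0)  # gradient isolation
        net = OptimizerNetwork(seed=12)
        adapt_online(obj, net, [(motion, feat, targets)], n_iterations=2)
        for l, snap in zip(cae.layers, cae_snap):
            for k, v in l.params.items():
                np.testing.assert_array_equal(v, snap[k])

    def test_empty_stream_rejected(self):
        p = Predictor(seed=0)
        p.trained = True
        with pytest.raises(ValueError):
            adapt_online(PredictorObjective(p), OptimizerNetwork(seed=0), [])

    def test_returns_loss_trace(self):
        obj = QuadraticObjective(n=8, seed=13)
        net = OptimizerNetwork(seed=14)
        trace = adapt_online(obj, net, [None, None], n_iterations=3)
        # one iteration = one pass over the update batches
        assert len(trace) == 3 * 2
        assert np.isfinite(trace).all()


class TestRelativeGrowthRate:
    def test_full_recovery_is_one(self):
        assert relative_growth_rate(0.9, 0.7, 0.9) == pytest.approx(1.0)

    def test_half_recovery(self):
        assert relative_growth_rate(0.8, 0.7, 0.9) == pytest.approx(0.5)

    def test_no_drop_rejected(self):
        with pytest.raises(ZeroDivisionError):
            relative_growth_rate(0.9, 0.8, 0.8)


class TestTunedParamSpecGeneric:
    def test_segment_order_preserved(self):
        layer = Dense(3, 2, RNG(0), np.float64)
        layer.params["weight"][:] = np.arange(6.0).reshape(3, 2)
        spec = TunedParamSpec(layer, [("weight", [4, 0]), ("bias", [1])])
        np.testing.assert_allclose(spec.gather(), [4.0, 0.0, 0.0])
        assert spec.count == 3

    def test_gather_grads(self):
        layer = Dense(3, 2, RNG(0), np.float64)
        layer.grads["weight"][:] = np.arange(6.0).reshape(3, 2)
        spec = TunedParamSpec(layer, [("weight", [5, 1])])
        np.testing.assert_allclose(spec.gather_grads(), [5.0, 1.0])
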