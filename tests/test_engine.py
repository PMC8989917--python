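"""Training engine: gradient correctness, credit-assignment reductions,
modulation semantics, optimizer recursions, and the training loop."""

import numpy as np
import pytest

import grapesnn as g
from grapesnn import engine


def _grads_equal(ga, gb, exact=False):
    cmp = np.array_equal if exact else np.allclose
    return all(cmp(a, b)
               for ea, eb in zip(ga.updates, gb.updates)
               for a, b in zip(ea, eb))


def _finite_difference_worst(model, X, yt, n_coords=25, train=False):
    """Worst relative error between analytic and central-difference grads."""
    def loss():
        cache = g.forward_pass(model, X, train=train)
        return engine.cross_entropy(cache["y"], yt)

    cache = g.forward_pass(model, X, train=train)
    _, grads = g.backward_bp(model, cache, yt)
    eps, worst = 1e-6, 0.0
    pick = np.random.default_rng(0)
    for layer, entry in zip(model.trainable_layers(), grads.updates):
        for p, g_desc in zip(layer.params(), entry):
            analytic = -g_desc
            for f in pick.choice(p.size, min(n_coords, p.size), replace=False):
                mi = np.unravel_index(f, p.shape)
                orig = p[mi]
                p[mi] = orig + eps
                lp = loss()
                p[mi] = orig - eps
                lm = loss()
                p[mi] = orig
                num = (lp - lm) / (2 * eps)
                # floor shields exactly-zero gradients (e.g. a bias feeding
                # batchnorm) from finite-difference roundoff noise
                worst = max(worst, abs(num - analytic[mi])
                            / max(1e-4, abs(num), abs(analytic[mi])))
    return worst


class TestForward:
    def test_identity_linear_layer_passes_input_through(self):
        model = g.build_network([g.LayerSpec("dense", 4, "linear")], (4,),
                                np.random.default_rng(0))
        layer = model.layers[0]
        layer.W[:] = np.eye(4)
        layer.b[:] = 0
        x = np.random.default_rng(1).normal(size=(3, 4))
        cache = g.forward_pass(model, x)
        np.testing.assert_allclose(cache["logits"], x)

    def test_zero_weights_give_uniform_softmax(self):
        model = g.mlp([8], 6, 5, rng=np.random.default_rng(0))
        for layer in model.modulated_layers():
            layer.W[:] = 0
            layer.b[:] = 0
        cache = g.forward_pass(model, np.ones((2, 6)))
        np.testing.assert_allclose(cache["y"], 0.2)

    def test_matches_straight_line_recomputation(self, rng):
        model = g.mlp([10, 8], 12, 4, activation="tanh", rng=rng)
        x = rng.normal(size=(5, 12))
        cache = g.forward_pass(model, x)
        l1, l2, l3 = model.modulated_layers()
        h1 = np.tanh(x @ l1.W.T + l1.b)
        h2 = np.tanh(h1 @ l2.W.T + l2.b)
        ay = h2 @ l3.W.T + l3.b
        p = np.exp(ay - ay.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(cache["y"], p, rtol=1e-12)

    def test_softmax_rows_sum_to_one(self, rng):
        model = g.mlp([16], 10, 7, rng=rng)
        cache = g.forward_pass(model, rng.normal(size=(9, 10)))
        np.testing.assert_allclose(cache["y"].sum(axis=1), 1.0)

    def test_shape_mismatch_rejected(self, rng):
        model = g.mlp([4], 10, 3, rng=rng)
        with pytest.raises(ValueError):
            g.forward_pass(model, rng.normal(size=(2, 11)))


class TestGradients:
    def test_zero_loss_gives_zero_gradients(self):
        model = g.build_network([g.LayerSpec("dense", 2, "linear")], (2,),
                                np.random.default_rng(0))
        layer = model.layers[0]
        layer.W[:] = np.array([[50.0, 0.0], [0.0, 50.0]])
        layer.b[:] = 0
        x = np.eye(2)
        cache = g.forward_pass(model, x)
        _, grads = g.backward_bp(model, cache, np.array([0, 1]))
        for entry in grads.updates:
            for a in entry:
                np.testing.assert_allclose(a, 0.0, atol=1e-12)

    def test_single_linear_layer_closed_form(self, rng):
        model = g.build_network([g.LayerSpec("dense", 3, "linear")], (5,),
                                np.random.default_rng(2))
        x = rng.normal(size=(4, 5))
        t = rng.integers(0, 3, 4)
        cache = g.forward_pass(model, x)
        _, grads = g.backward_bp(model, cache, t)
        onehot = np.eye(3)[t]
        delta = (cache["y"] - onehot) / 4
        np.testing.assert_allclose(grads.updates[0][0], -(delta.T @ x))

    @pytest.mark.parametrize("specs, shape", [
        ([("dense", 12, "tanh"), ("dense", 9, "relu"), ("dense", 5, "linear")], (16,)),
        ([("dense", 10, "relu"), ("dense", 5, "linear")], (8,)),
        ([("conv", 3, "tanh"), ("flatten", 0, ""), ("dense", 4, "linear")], (1, 7, 7)),
    ])
    def test_bp_matches_finite_differences(self, specs, shape, rng):
        layer_specs = []
        for kind, units, act in specs:
            if kind == "flatten":
                layer_specs.append(g.LayerSpec("flatten"))
            else:
                layer_specs.append(g.LayerSpec(kind, units=units, activation=act))
        model = g.build_network(layer_specs, shape, rng)
        X = rng.normal(size=(4,) + shape)
        n_out = [u for k, u, a in specs if k != "flatten"][-1]
        yt = rng.integers(0, n_out, 4)
        assert _finite_difference_worst(model, X, yt) < 1e-5

    def test_batchnorm_gradients_match_finite_differences(self, rng):
        specs = [g.LayerSpec("dense", 8, "linear"), g.LayerSpec("batchnorm"),
                 g.LayerSpec("dense", 4, "linear")]
        model = g.build_network(specs, (10,), rng)
        X = rng.normal(size=(6, 10))
        yt = rng.integers(0, 4, 6)
        assert _finite_difference_worst(model, X, yt, train=True) < 1e-5

    def test_targets_out_of_range_rejected(self, rng):
        model = g.mlp([4], 6, 3, rng=rng)
        cache = g.forward_pass(model, rng.normal(size=(2, 6)))
        with pytest.raises(ValueError):
            g.backward_bp(model, cache, np.array([0, 3]))


class TestCreditAssignment:
    @pytest.fixture
    def net_and_batch(self, rng):
        model = g.mlp([12, 10], 16, 4, activation="tanh", rng=rng)
        X = rng.normal(size=(6, 16))
        yt = rng.integers(0, 4, 6)
        cache = g.forward_pass(model, X)
        return model, X, yt, cache

    def test_fa_with_transposed_weights_equals_bp(self, net_and_batch):
        model, _, yt, cache = net_and_batch
        dense = model.modulated_layers()
        fb = [dense[i + 1].W.T.copy() for i in range(len(dense) - 1)]
        _, gbp = g.backward_bp(model, cache, yt)
        _, gfa = g.backward_fa(model, cache, yt, fb)
        assert _grads_equal(gbp, gfa)

    def test_fa_random_feedback_matches_loop_oracle(self, net_and_batch, rng):
        model, X, yt, cache = net_and_batch
        fb = g.make_feedback_matrices(model, "fa", rng)
        errs, _ = g.backward_fa(model, cache, yt, fb)
        l1, l2, l3 = model.modulated_layers()
        d_out = errs.delta_out
        a2 = cache["records"][1]["a"]
        a1 = cache["records"][0]["a"]
        d2 = (d_out @ fb[1].T) * (1 - np.tanh(a2) ** 2)
        d1 = (d2 @ fb[0].T) * (1 - np.tanh(a1) ** 2)
        np.testing.assert_allclose(errs.deltas[1], d2)
        np.testing.assert_allclose(errs.deltas[0], d1)

    def test_dfa_single_hidden_with_w2t_equals_bp(self, rng):
        model = g.mlp([12], 16, 4, activation="tanh", rng=rng)
        X = rng.normal(size=(6, 16))
        yt = rng.integers(0, 4, 6)
        cache = g.forward_pass(model, X)
        dense = model.modulated_layers()
        _, gbp = g.backward_bp(model, cache, yt)
        _, gdfa = g.backward_dfa(model, cache, yt, [dense[1].W.T.copy()])
        assert _grads_equal(gbp, gdfa)

    def test_dfa_presynaptic_modulation_forced_values(self, rng):
        """With W2 = [[1,-1],[2,0],[0,3]] the presynaptic importance of the
        hidden layer is [3,4], so its modulation is [1.5, 2.0]."""
        model = g.mlp([2], 3, 3, activation="tanh", rng=rng)
        l1, l2 = model.modulated_layers()
        l2.W[:] = np.array([[1.0, -1.0], [2.0, 0.0], [0.0, 3.0]])
        cfg = g.GrapesConfig("local", "presynaptic")
        mods = g.refresh_modulation(model, cfg)
        np.testing.assert_allclose(mods[0], [1.5, 2.0])
        X = rng.normal(size=(4, 3))
        yt = rng.integers(0, 3, 4)
        cache = g.forward_pass(model, X)
        fb = g.make_feedback_matrices(model, "dfa", rng)
        _, gplain = g.backward_dfa(model, cache, yt, fb)
        _, gmod = g.backward_dfa(model, cache, yt, fb, cfg, mods)
        np.testing.assert_allclose(
            gmod.updates[0][0], gplain.updates[0][0] * np.array([[1.5], [2.0]]))

    def test_dfa_rejects_postsynaptic_grouping(self, rng):
        model = g.mlp([4], 6, 3, rng=rng)
        X = rng.normal(size=(2, 6))
        cache = g.forward_pass(model, X)
        fb = g.make_feedback_matrices(model, "dfa", rng)
        cfg = g.GrapesConfig("local", "postsynaptic")
        mods = g.refresh_modulation(model, cfg)
        with pytest.raises(ValueError):
            g.backward_dfa(model, cache, np.array([0, 1]), fb, cfg, mods)


class TestModulationSemantics:
    @pytest.fixture
    def deep_net(self, rng):
        model = g.mlp([10, 8, 6], 12, 4, activation="tanh", rng=rng)
        X = rng.normal(size=(5, 12))
        yt = rng.integers(0, 4, 5)
        return model, X, yt, g.forward_pass(model, X)

    def test_unit_modulation_reduces_to_bp_bitwise(self, deep_net):
        model, _, yt, cache = deep_net
        ones = [np.ones(l.W.shape[0]) for l in model.modulated_layers()]
        _, gbp = g.backward_bp(model, cache, yt)
        _, gloc = g.backward_bp(model, cache, yt, g.GrapesConfig("local"), ones)
        _, gprop = g.grapes_propagating_backward(
            model, cache, yt, g.GrapesConfig("propagating"), ones)
        assert _grads_equal(gbp, gloc, exact=True)
        assert _grads_equal(gbp, gprop, exact=True)

    def test_local_and_propagating_agree_on_single_hidden_layer(self, rng):
        model = g.mlp([9], 11, 3, activation="relu", rng=rng)
        X = rng.normal(size=(4, 11))
        yt = rng.integers(0, 3, 4)
        cache = g.forward_pass(model, X)
        mods_l = g.refresh_modulation(model, g.GrapesConfig("local"))
        mods_p = g.refresh_modulation(model, g.GrapesConfig("propagating"))
        _, gl = g.backward_bp(model, cache, yt, g.GrapesConfig("local"), mods_l)
        _, gp = g.grapes_propagating_backward(
            model, cache, yt, g.GrapesConfig("propagating"), mods_p)
        assert _grads_equal(gl, gp)

    def test_propagating_matches_symbolic_recursion(self):
        """2-2-2-2 tanh net: deltas follow da2 = (W3^T day) f'(a2) m2, then
        da1 = (W2^T da2) f'(a1) m1, with the output delta unmodulated."""
        rng = np.random.default_rng(3)
        model = g.mlp([2, 2], 2, 2, activation="tanh", rng=rng)
        X = rng.normal(size=(3, 2))
        yt = rng.integers(0, 2, 3)
        cache = g.forward_pass(model, X)
        cfg = g.GrapesConfig("propagating")
        mv = g.refresh_modulation(model, cfg)
        _, got = g.grapes_propagating_backward(model, cache, yt, cfg, mv)
        l1, l2, l3 = model.modulated_layers()
        a1 = X @ l1.W.T + l1.b
        h1 = np.tanh(a1)
        a2 = h1 @ l2.W.T + l2.b
        h2 = np.tanh(a2)
        ay = h2 @ l3.W.T + l3.b
        p = np.exp(ay - ay.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        day = (p - np.eye(2)[yt]) / 3
        da2 = (day @ l3.W) * (1 - h2 ** 2) * mv[1][None, :]
        da1 = (da2 @ l2.W) * (1 - h1 ** 2) * mv[0][None, :]
        np.testing.assert_allclose(got.updates[0][0], -(da1.T @ X))
        np.testing.assert_allclose(got.updates[1][0], -(da2.T @ h1))
        np.testing.assert_allclose(got.updates[2][0], -(day.T @ h2))

    def test_output_layer_not_modulated_by_default(self, deep_net):
        model, _, yt, cache = deep_net
        cfg = g.GrapesConfig("propagating")
        mv = g.refresh_modulation(model, cfg)
        np.testing.assert_array_equal(mv[-1], 1.0)
        _, gbp = g.backward_bp(model, cache, yt)
        _, gp = g.grapes_propagating_backward(model, cache, yt, cfg, mv)
        # output-layer delta unmodulated, so its bias update is unchanged
        np.testing.assert_array_equal(gbp.updates[-1][1], gp.updates[-1][1])

    def test_conv_modulation_scales_whole_filter_uniformly(self, rng):
        specs = [g.LayerSpec("conv", units=4, activation="relu"),
                 g.LayerSpec("flatten"),
                 g.LayerSpec("dense", units=3, activation="linear")]
        model = g.build_network(specs, (1, 6, 6), rng)
        X = rng.random((3, 1, 6, 6))
        yt = rng.integers(0, 3, 3)
        cache = g.forward_pass(model, X)
        cfg = g.GrapesConfig("local")
        mv = g.refresh_modulation(model, cfg)
        _, gplain = g.backward_bp(model, cache, yt)
        _, gmod = g.backward_bp(model, cache, yt, cfg, mv)
        ratio = gmod.updates[0][0] / np.where(
            gplain.updates[0][0] == 0, 1.0, gplain.updates[0][0])
        for o in range(4):
            vals = ratio[o][gplain.updates[0][0][o] != 0]
            np.testing.assert_allclose(vals, mv[0][o])


class TestOptimizers:
    @pytest.fixture
    def const_grads(self):
        def make(model, value=1.0):
            return engine.GradientSet(
                [[np.full_like(p, value) for p in l.params()]
                 for l in model.trainable_layers()])
        return make

    def test_sgd_update_is_literal(self, rng, const_grads):
        model = g.mlp([4], 5, 3, rng=rng)
        p0 = [p.copy() for p in model.parameters()]
        opt = g.OptimizerState(0.5)
        g.sgd_update_modulated(model, const_grads(model, 0.2), opt)
        for before, after in zip(p0, model.parameters()):
            np.testing.assert_allclose(after - before, 0.1)
        assert opt.t == 1

    def test_momentum_zero_equals_sgd(self, rng, const_grads):
        m_a = g.mlp([4], 5, 3, rng=np.random.default_rng(0))
        m_b = g.mlp([4], 5, 3, rng=np.random.default_rng(0))
        gs = const_grads(m_a, 0.3)
        g.optimizer_step(m_a, gs, g.OptimizerState(0.1, "momentum", momentum=0.0))
        g.optimizer_step(m_b, gs, g.OptimizerState(0.1, "sgd"))
        for pa, pb in zip(m_a.parameters(), m_b.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_momentum_two_steps_hand_recursion(self, rng, const_grads):
        model = g.mlp([4], 5, 3, rng=rng)
        p0 = [p.copy() for p in model.parameters()]
        opt = g.OptimizerState(0.1, "momentum", momentum=0.5)
        gs = const_grads(model, 1.0)
        g.optimizer_step(model, gs, opt)
        g.optimizer_step(model, gs, opt)
        # v1 = g, v2 = (1+mu) g  =>  displacement = eta g (1 + (1+mu))
        for before, after in zip(p0, model.parameters()):
            np.testing.assert_allclose(after - before, 0.1 * (1 + 1.5))

    def test_adam_first_step_hand_recursion(self, rng, const_grads):
        model = g.mlp([4], 5, 3, rng=rng)
        p0 = [p.copy() for p in model.parameters()]
        opt = g.OptimizerState(0.01, "adam")
        g.optimizer_step(model, const_grads(model, 0.3), opt)
        # mhat = g, vhat = g^2  =>  step = eta g/(|g|+eps) ~ eta sign(g)
        for before, after in zip(p0, model.parameters()):
            np.testing.assert_allclose(after - before,
                                       0.01 * 0.3 / (0.3 + 1e-8))

    def test_invalid_learning_rate_rejected(self):
        with pytest.raises(ValueError):
            g.OptimizerState(0.0)
        with pytest.raises(ValueError):
            g.OptimizerState(-1.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            g.OptimizerState(0.1, "adagrad")


class TestSchedule:
    def test_mode_off_gives_unit_vectors(self, rng):
        model = g.mlp([6, 5], 8, 3, rng=rng)
        for v in g.refresh_modulation(model, g.GrapesConfig("off")):
            np.testing.assert_array_equal(v, 1.0)

    def test_refresh_reflects_updated_weights(self, rng):
        model = g.mlp([6], 8, 3, rng=rng)
        cfg = g.GrapesConfig("local")
        before = g.refresh_modulation(model, cfg)
        model.modulated_layers()[0].W *= rng.uniform(0.1, 3.0, size=(6, 1))
        after = g.refresh_modulation(model, cfg)
        expected = g.modulation_vector(
            g.importance_postsynaptic(model.modulated_layers()[0].W))
        np.testing.assert_array_equal(after[0], expected)
        assert not np.array_equal(before[0], after[0])

    def test_modulation_constant_within_batch(self, rng):
        """Repeated backward calls between updates see identical vectors."""
        model = g.mlp([6], 8, 3, rng=rng)
        cfg = g.GrapesConfig("propagating")
        mv = g.refresh_modulation(model, cfg)
        X = rng.normal(size=(4, 8))
        yt = rng.integers(0, 3, 4)
        cache = g.forward_pass(model, X)
        _, g1 = g.grapes_propagating_backward(model, cache, yt, cfg, mv)
        _, g2 = g.grapes_propagating_backward(model, cache, yt, cfg, mv)
        assert _grads_equal(g1, g2, exact=True)


class TestTrainEpoch:
    def test_empty_dataset_rejected(self, rng):
        model = g.mlp([4], 784, 10, rng=rng)
        with pytest.raises(ValueError):
            g.train_epoch(model, np.empty((0, 784)), np.empty(0, dtype=int),
                          g.OptimizerState(0.1), g.GrapesConfig(), rng)

    def test_same_seed_runs_bit_identical(self, small_dataset):
        train, test = small_dataset
        logs = []
        finals = []
        for _ in range(2):
            rng = np.random.default_rng(9)
            model = g.mlp([16], 784, 10, rng=rng)
            opt = g.OptimizerState(0.01)
            log = g.train_epoch(model, train.flat(), train.labels, opt,
                                g.GrapesConfig("propagating"), rng,
                                test=(test.flat(), test.labels))
            logs.append((log["train_loss"], log["test_accuracy"]))
            finals.append([p.copy() for p in model.parameters()])
        assert logs[0] == logs[1]
        for pa, pb in zip(*finals):
            np.testing.assert_array_equal(pa, pb)

    def test_dropout_training_runs_and_evaluates_deterministically(self, small_dataset):
        train, test = small_dataset
        rng = np.random.default_rng(4)
        model = g.mlp([16], 784, 10, dropout=0.1, rng=rng)
        opt = g.OptimizerState(0.01)
        log = g.train_epoch(model, train.flat(), train.labels, opt,
                            g.GrapesConfig("off"), rng,
                            test=(test.flat(), test.labels))
        assert 0 <= log["test_accuracy"] <= 100
        a = g.evaluate(model, test.flat(), test.labels)
        b = g.evaluate(model, test.flat(), test.labels)
        assert a == b
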