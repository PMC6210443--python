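"""Schedules, initialization, gradients and solver update rules."""

import math

import numpy as np
import pytest

from sbcnn.net import ModelWeights, NetworkConfig
from sbcnn.synth import GeneratorConfig, generate_dataset
from sbcnn.training import (
    LRSchedule,
    SolverState,
    adagrad_step,
    init_weights,
    loss_and_gradients,
    lr_at,
    msra_init,
    repeat_and_average,
    sgd_step,
    train,
)


# ------------------------------------------------------------- schedules


class TestSchedules:
    def test_fixed_is_constant(self):
        s = LRSchedule(kind="fixed")
        assert all(lr_at(s, i) == 0.01 for i in (0, 1, 500, 15000))

    def test_boundary_identities(self):
        assert lr_at(LRSchedule(kind="step"), 0) == 0.01
        assert lr_at(LRSchedule(kind="exp"), 0) == 0.01
        assert lr_at(LRSchedule(kind="poly"), 15000) == 0.0

    def test_closed_form_values(self):
        # sigmoid at i = stepsize is exactly half the base rate
        assert lr_at(LRSchedule(kind="sigmoid"), 500) == pytest.approx(0.005)
        # step: 0.01 * 0.75^floor(1250/500) = 0.01 * 0.75^2
        assert lr_at(LRSchedule(kind="step"), 1250) == pytest.approx(0.005625)
        # poly halfway: 0.01 * (1 - 0.5)^2
        assert lr_at(LRSchedule(kind="poly"), 7500) == pytest.approx(0.0025)

    def test_monotonicity(self):
        iters = np.arange(0, 15001, 250)
        for kind in ("step", "exp", "poly"):
            vals = [lr_at(LRSchedule(kind=kind), int(i)) for i in iters]
            assert all(a >= b for a, b in zip(vals, vals[1:])), kind
        # the sigmoid form increases toward baseLr as iterations grow
        vals = [lr_at(LRSchedule(kind="sigmoid"), int(i)) for i in iters]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_exp_underflows_but_stays_finite(self):
        v = lr_at(LRSchedule(kind="exp"), 15000)
        assert v == 0.0 or (v > 0 and np.isfinite(v))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            LRSchedule(kind="cosine")


# -------------------------------------------------------- initialization


class TestMsraInit:
    def test_variance_is_two_over_fanin(self):
        draws = msra_init((100_000,), fan_in=2, seed=0)
        assert abs(draws.mean()) < 0.02
        assert draws.var() == pytest.approx(1.0, rel=0.05)

    def test_same_seed_identical(self):
        a = msra_init((50, 3), fan_in=10, seed=7)
        b = msra_init((50, 3), fan_in=10, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_std_halves_when_fanin_quadruples(self):
        s1 = msra_init((200_000,), fan_in=8, seed=1).std()
        s2 = msra_init((200_000,), fan_in=32, seed=2).std()
        assert s1 / s2 == pytest.approx(2.0, rel=0.02)

    def test_init_weights_opens_at_uniform_loss(self, mini_config, rng):
        """With a zero output layer the initial prediction is uniform, so the
        loss on any batch is exactly ln 3."""
        w = init_weights(mini_config, seed=0)
        x = rng.standard_normal((6, 3, 6))
        y = np.array([2, 3, 7, 2, 3, 7])
        loss, _ = loss_and_gradients(w, x, y, mini_config)
        assert loss == pytest.approx(math.log(3), abs=1e-12)


# ------------------------------------------------------ loss & gradients


class TestLossAndGradients:
    def test_zero_weights_loss_is_ln3(self, mini_config, rng):
        w = ModelWeights.zeros(mini_config)
        x = rng.standard_normal((4, 3, 6))
        loss, _ = loss_and_gradients(w, x, np.array([2, 2, 3, 7]), mini_config)
        assert loss == pytest.approx(math.log(3), abs=1e-12)

    def test_batch_duplication_leaves_loss_and_gradients_unchanged(self, mini_config, rng):
        w = init_weights(mini_config, seed=2)
        w.pl2_w = rng.standard_normal(w.pl2_w.shape)
        x = rng.standard_normal((3, 3, 6))
        y = np.array([2, 3, 7])
        loss1, g1 = loss_and_gradients(w, x, y, mini_config)
        loss2, g2 = loss_and_gradients(w, np.tile(x, (2, 1, 1)), np.tile(y, 2), mini_config)
        assert loss1 == pytest.approx(loss2, rel=1e-12)
        for name in g1:
            np.testing.assert_allclose(g1[name], g2[name], atol=1e-12)

    def test_label_outside_class_set_rejected(self, mini_config, rng):
        w = ModelWeights.zeros(mini_config)
        with pytest.raises(ValueError):
            loss_and_gradients(w, rng.standard_normal((1, 3, 6)), np.array([4]), mini_config)

    @pytest.mark.parametrize("padding", ["same", "valid"])
    def test_gradients_match_finite_differences(self, rng, padding):
        """Central finite differences (h=1e-5) agree with the analytic
        gradient to < 1e-4 relative error on every weight of a mini net."""
        cfg = NetworkConfig(n_channels=2, window=6, conv1_filters=3, conv1_size=3,
                            conv2_filters=2, conv2_size=3, pl1_outputs=4,
                            padding=padding)
        w = init_weights(cfg, seed=4)
        w.pl2_w = 0.5 * rng.standard_normal(w.pl2_w.shape)
        for name, arr in w.items():
            if name.endswith("_b"):
                setattr(w, name, 0.1 * rng.standard_normal(arr.shape))
        x = rng.standard_normal((3, 2, 6))
        y = np.array([2, 7, 3])
        _, grads = loss_and_gradients(w, x, y, cfg)
        h = 1e-5
        for name, g in grads.items():
            arr = getattr(w, name)
            flat_idx = rng.choice(arr.size, size=min(arr.size, 12), replace=False)
            for fi in flat_idx:
                ix = np.unravel_index(fi, arr.shape)
                orig = arr[ix]
                arr[ix] = orig + h
                lp, _ = loss_and_gradients(w, x, y, cfg)
                arr[ix] = orig - h
                lm, _ = loss_and_gradients(w, x, y, cfg)
                arr[ix] = orig
                fd = (lp - lm) / (2 * h)
                denom = max(abs(fd), abs(g[ix]), 1e-8)
                assert abs(fd - g[ix]) / denom < 1e-4, f"{name}{ix}"


# ---------------------------------------------------------------- solvers


class TestAdaGrad:
    def _one_weight(self, value=1.0):
        cfg = NetworkConfig(n_channels=1, window=4, conv1_filters=2, conv1_size=1,
                            conv2_filters=2, conv2_size=1, pl1_outputs=3, classes=(2, 3, 7))
        w = ModelWeights.zeros(cfg)
        w.pl2_b = np.array([value, 0.0, 0.0])
        return w

    def test_first_step_magnitude_is_lr(self):
        w = self._one_weight()
        state = SolverState(solver="adagrad", epsilon=0.0)
        g = {"pl2_b": np.array([0.4, -0.2, 0.0])}
        adagrad_step(state, w, g, lr=0.01)
        # g / sqrt(g^2) = sign(g): update is exactly -lr * sign(g)
        np.testing.assert_allclose(w.pl2_b, [1.0 - 0.01, 0.01, 0.0], atol=1e-15)

    def test_t_th_step_magnitude_is_lr_over_sqrt_t(self):
        w = self._one_weight(0.0)
        state = SolverState(solver="adagrad", epsilon=0.0)
        g = {"pl2_b": np.array([0.3, 0.0, 0.0])}
        prev = 0.0
        for t in range(1, 6):
            adagrad_step(state, w, g, lr=0.01)
            step = abs(w.pl2_b[0] - prev)
            assert step == pytest.approx(0.01 / math.sqrt(t), rel=1e-12)
            prev = w.pl2_b[0]

    def test_zero_gradient_leaves_weight_unchanged(self):
        w = self._one_weight()
        state = SolverState(solver="adagrad", epsilon=1e-8)
        adagrad_step(state, w, {"pl2_b": np.zeros(3)}, lr=0.01)
        np.testing.assert_array_equal(w.pl2_b, [1.0, 0.0, 0.0])

    def test_history_nondecreasing(self, rng):
        w = self._one_weight()
        state = SolverState(solver="adagrad")
        prev = np.zeros(3)
        for _ in range(5):
            adagrad_step(state, w, {"pl2_b": rng.standard_normal(3)}, lr=0.01)
            assert np.all(state.accum["pl2_b"] >= prev)
            prev = state.accum["pl2_b"].copy()


class TestSGD:
    def test_zero_momentum_is_plain_descent(self):
        w = TestAdaGrad()._one_weight()
        state = SolverState(solver="sgd", momentum=0.0)
        sgd_step(state, w, {"pl2_b": np.array([0.5, 0.0, 0.0])}, lr=0.1)
        assert w.pl2_b[0] == pytest.approx(1.0 - 0.05)

    def test_constant_gradient_buffer_geometric_series(self):
        mu, lr, g0 = 0.9, 0.1, 0.5
        w = TestAdaGrad()._one_weight()
        state = SolverState(solver="sgd", momentum=mu)
        g = {"pl2_b": np.array([g0, 0.0, 0.0])}
        for k in range(1, 8):
            sgd_step(state, w, g, lr=lr)
            expected = lr * g0 * (1 - mu**k) / (1 - mu)
            assert state.buffer["pl2_b"][0] == pytest.approx(expected, rel=1e-12)

    def test_zero_gradient_forever_keeps_weights(self):
        w = TestAdaGrad()._one_weight()
        state = SolverState(solver="sgd", momentum=0.5)
        for _ in range(10):
            sgd_step(state, w, {"pl2_b": np.zeros(3)}, lr=0.1)
        np.testing.assert_array_equal(w.pl2_b, [1.0, 0.0, 0.0])


# --------------------------------------------------------- training loop


def _tiny_dataset(seed=0):
    cfg = GeneratorConfig(session_minutes=0.5, block_seconds=5.0, seed=seed)
    return generate_dataset(cfg, 2, 1)


def _tiny_net():
    return NetworkConfig(window=8, conv1_filters=4, conv1_size=3, conv2_filters=2,
                         conv2_size=3, pl1_outputs=8)


class TestTrainLoop:
    def test_same_seed_identical_record(self):
        train_s, test_s = _tiny_dataset()
        cfg, sched = _tiny_net(), LRSchedule(kind="step")
        rec1 = train(train_s, test_s, cfg, sched, max_iter=30, batch_size=16,
                     eval_every=10, seed=5)
        rec2 = train(train_s, test_s, cfg, sched, max_iter=30, batch_size=16,
                     eval_every=10, seed=5)
        assert rec1.iterations == rec2.iterations
        assert rec1.losses == rec2.losses
        assert rec1.test_accuracy == rec2.test_accuracy
        for (_, a), (_, b) in zip(rec1.final_weights.items(), rec2.final_weights.items()):
            np.testing.assert_array_equal(a, b)

    def test_checkpoints_strictly_increasing(self):
        train_s, test_s = _tiny_dataset(1)
        rec = train(train_s, test_s, _tiny_net(), LRSchedule(), max_iter=25,
                    batch_size=16, eval_every=10, seed=0)
        assert rec.iterations == [10, 20, 25]
        assert all(np.isfinite(rec.losses))

    def test_no_training_sessions_rejected(self):
        with pytest.raises(ValueError):
            train([], [], _tiny_net(), LRSchedule(), max_iter=1)

    def test_record_csv_export(self, tmp_path):
        train_s, test_s = _tiny_dataset(2)
        rec = train(train_s, test_s, _tiny_net(), LRSchedule(), max_iter=10,
                    batch_size=16, eval_every=5, seed=0)
        p = tmp_path / "curve.csv"
        rec.to_csv(p)
        lines = p.read_text().splitlines()
        assert lines[0] == "iteration,loss,train_accuracy,test_accuracy"
        assert len(lines) == 1 + len(rec.iterations)


class TestRepeatAndAverage:
    def test_single_repeat_equals_single_run(self):
        out = repeat_and_average(lambda s: 0.7, n_repeats=1)
        assert out["mean"] == 0.7 and out["per_run"] == [0.7]

    def test_mean_matches_independent_arithmetic(self):
        accs = {0: 0.8, 1: 0.6, 2: 0.7, 3: 0.9, 4: 0.5}
        out = repeat_and_average(lambda s: accs[s], n_repeats=5, seeds=list(accs))
        assert out["mean"] == pytest.approx(sum(accs.values()) / 5)

    def test_seed_permutation_same_mean(self):
        f = lambda s: 0.1 * s
        a = repeat_and_average(f, n_repeats=3, seeds=[1, 2, 3])
        b = repeat_and_average(f, n_repeats=3, seeds=[3, 1, 2])
        assert a["mean"] == pytest.approx(b["mean"])
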