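"""Training contracts: loss values against hand arithmetic, BPTT gradients
against numerical differentiation, the fast time-major path against the
reference forward, CV-split geometry, determinism, equivalences, and the
sliding-window baselines."""

import dataclasses
import math

import numpy as np
import pytest

from tvrnn.data import ValidationError
from tvrnn.models import OutputTrajectory, RNNParams, TVWeights, rnn_forward, tvrnn_forward
from tvrnn.training import (
    TrainConfig,
    _fast_rnn_forward,
    _fast_tv_forward,
    _loss_and_dz,
    loss_s1,
    loss_s2,
    make_cv_splits,
    rnn_backward,
    train_model,
    train_sliding_baselines,
    tvrnn_backward,
)

from conftest import numerical_gradient, random_rnn, random_tv, separable_trials


class TestLosses:
    def test_s1_at_half_is_ln2(self):
        traj = OutputTrajectory(y=np.full((3, 4), 0.5))
        assert math.isclose(loss_s1(traj, np.array([1, 0, 1])), math.log(2), rel_tol=1e-12)

    def test_s1_hand_batch(self):
        traj = OutputTrajectory(y=np.array([[0.2, 0.9], [0.3, 0.1]]))
        expect = (-math.log(0.9) - math.log(0.9)) / 2
        assert math.isclose(loss_s1(traj, np.array([1, 0])), expect, rel_tol=1e-9)

    def test_s1_perfect_fit_limit(self):
        traj = OutputTrajectory(y=np.array([[1 - 1e-9], [1e-9]]))
        assert loss_s1(traj, np.array([1, 0])) < 1e-6

    def test_s2_constant_half_independent_of_T(self):
        for T in (1, 5, 50):
            traj = OutputTrajectory(y=np.full((2, T), 0.5))
            assert math.isclose(loss_s2(traj, np.array([1, 0])), math.log(2), rel_tol=1e-12)

    def test_s2_reduces_to_s1_at_T1(self, rng):
        y = rng.uniform(0.1, 0.9, size=(4, 1))
        traj = OutputTrajectory(y=y)
        labels = np.array([1, 0, 1, 0])
        assert math.isclose(loss_s2(traj, labels), loss_s1(traj, labels), rel_tol=1e-12)

    def test_s2_hand_example(self):
        traj = OutputTrajectory(y=np.array([[0.5, 0.9, 0.9]]))
        expect = np.mean([-math.log(0.5), -math.log(0.9), -math.log(0.9)])
        assert math.isclose(loss_s2(traj, np.array([1])), expect, rel_tol=1e-9)


class TestBPTTGradients:
    @pytest.mark.parametrize("strategy", ["s1", "s2"])
    def test_rnn_backward_matches_numerical(self, rng, strategy):
        p = random_rnn(rng)
        X = rng.standard_normal((3, 5, 2))
        labels = np.array([1.0, 0.0, 1.0])

        def loss():
            return _loss_and_dz(rnn_forward(p, X).y, labels, strategy)[0]

        traj = rnn_forward(p, X)
        _, dZ = _loss_and_dz(traj.y, labels, strategy)
        g = rnn_backward(p, X, traj.h, dZ)
        for name in ("W_x", "W_h", "W_y", "b_h"):
            num = numerical_gradient(loss, getattr(p, name))
            assert np.allclose(num, g[name], atol=1e-6), (strategy, name)

    def test_tvrnn_backward_matches_numerical(self, rng):
        tv = random_tv(rng, n_windows=3, window=2)
        X = rng.standard_normal((2, 6, 2))
        labels = np.array([1.0, 0.0])

        def loss():
            return _loss_and_dz(tvrnn_forward(tv, X).y, labels, "s2")[0]

        traj = tvrnn_forward(tv, X)
        _, dZ = _loss_and_dz(traj.y, labels, "s2")
        gs = tvrnn_backward(tv, X, traj.h, dZ)
        for k in range(3):
            for name in ("W_x", "W_h", "W_y", "b_h"):
                num = numerical_gradient(loss, getattr(tv.windows[k], name))
                assert np.allclose(num, gs[k][name], atol=1e-6), (k, name)

    def test_fast_path_equals_reference_forward(self, rng):
        p = random_rnn(rng, n_hidden=4, n_channels=3)
        tv = random_tv(rng, n_windows=3, window=4, n_hidden=4, n_channels=3)
        X = rng.standard_normal((5, 12, 3))
        XT = np.ascontiguousarray(X.transpose(1, 0, 2))
        _, y_fast = _fast_rnn_forward(p, XT)
        assert np.allclose(y_fast.T, rnn_forward(p, X).y, atol=1e-12)
        _, y_fast_tv = _fast_tv_forward(tv, XT)
        assert np.allclose(y_fast_tv.T, tvrnn_forward(tv, X).y, atol=1e-12)
        # single-precision training layout stays within float32 accuracy
        _, y32 = _fast_rnn_forward(p, XT.astype(np.float32))
        assert np.allclose(y32.T, rnn_forward(p, X).y, atol=1e-5)


class TestCVSplits:
    def test_fold_sizes_100_trials(self):
        labels = np.repeat([0, 1], 50)
        split = make_cv_splits(labels, n_folds=5, validation_rate=0.2, seed=0)
        for f in split.folds:
            assert len(f["test"]) == 20
            assert len(f["val"]) == 16
            assert len(f["train"]) == 64
            # stratified: both classes everywhere
            for role in ("train", "val", "test"):
                assert set(labels[f[role]]) == {0, 1}

    def test_partition_and_disjointness(self):
        labels = np.tile([0, 1], 60)
        split = make_cv_splits(labels, seed=3)
        tests = np.concatenate([f["test"] for f in split.folds])
        assert sorted(tests) == list(range(120))
        for f in split.folds:
            all_idx = np.concatenate([f["train"], f["val"], f["test"]])
            assert len(np.unique(all_idx)) == len(all_idx)

    def test_single_fold_rejected(self):
        with pytest.raises(ValidationError):
            make_cv_splits(np.repeat([0, 1], 10), n_folds=1)

    def test_stratification_error_with_rare_class(self):
        labels = np.array([0] * 29 + [1])  # one positive cannot stratify 5 folds
        with pytest.raises(ValidationError):
            make_cv_splits(labels, n_folds=5)


class TestTrainModel:
    def test_epochs_zero_returns_initialization(self):
        rng_expect = np.random.default_rng(42)
        expect = RNNParams.glorot(4, 3, rng_expect)
        X = np.random.default_rng(0).standard_normal((8, 5, 3))
        y = np.array([0, 1] * 4, dtype=float)
        res = train_model(TrainConfig(strategy="s1", epochs=0, hidden_size=4, seed=42), X, y)
        assert np.array_equal(res.params.W_x, expect.W_x)
        assert np.array_equal(res.params.W_h, expect.W_h)
        assert res.history == []

    def test_learns_separable_toy_data(self, rng):
        X, y = separable_trials(rng)
        cfg = TrainConfig(strategy="s1", epochs=200, learning_rate=0.01,
                          hidden_size=8, seed=0)
        train_idx = np.arange(150)
        res = train_model(cfg, X, y.astype(float), train_idx, np.arange(150, 200))
        held = rnn_forward(res.params, X[150:], return_hidden=False).y[:, -1]
        acc = ((held >= 0.5) == (y[150:] == 1)).mean()
        assert acc >= 0.95
        # checkpoint policy: best validation loss is no worse than epoch 1's
        assert min(h["val_loss"] for h in res.history) <= res.history[0]["val_loss"]

    def test_seed_determinism(self, rng):
        X, y = separable_trials(rng, n=40, T=10)
        cfg = TrainConfig(strategy="s2", epochs=5, hidden_size=4, seed=9)
        r1 = train_model(cfg, X, y.astype(float))
        r2 = train_model(cfg, X, y.astype(float))
        assert r1.history == r2.history
        assert np.array_equal(r1.params.W_h, r2.params.W_h)

    def test_single_window_tv_equals_s2_loss_trajectory(self, rng):
        """TV with w=T is a standard RNN under the aggregate loss: identical
        initialization and batch order give the same optimization path."""
        X, y = separable_trials(rng, n=40, T=10)
        kw = dict(epochs=3, hidden_size=4, seed=5, dtype="float64")
        r_tv = train_model(TrainConfig(strategy="tv", window_size=10, **kw),
                           X, y.astype(float))
        r_s2 = train_model(TrainConfig(strategy="s2", **kw), X, y.astype(float))
        tv_losses = [h["train_loss"] for h in r_tv.history]
        s2_losses = [h["train_loss"] for h in r_s2.history]
        assert np.allclose(tv_losses, s2_losses, rtol=1e-7)

    def test_gradient_trace_recorded_each_epoch(self, rng):
        X, y = separable_trials(rng, n=20, T=8)
        res = train_model(TrainConfig(strategy="tv", window_size=4, epochs=4,
                                      hidden_size=4, seed=1), X, y.astype(float))
        tr = res.trace
        assert len(tr.epochs) == 4
        assert all(np.isfinite(tr.grad_example))
        assert all(n >= 0 for n in tr.n_vanishing)
        assert len(tr.hist_counts[0]) == len(tr.hist_edges) - 1

    def test_warm_start_copies_s1_solution_into_windows(self, rng):
        X, y = separable_trials(rng, n=20, T=8)
        cfg = TrainConfig(strategy="tv", window_size=4, epochs=0,
                          hidden_size=4, seed=3, warm_start=True)
        res = train_model(cfg, X, y.astype(float))
        w0, w1 = res.params.windows
        assert np.array_equal(w0.W_h, w1.W_h)  # every window starts identical


class TestSlidingBaselines:
    def test_window_count(self, rng):
        X, y = separable_trials(rng, n=20, T=90)
        sb = train_sliding_baselines("svm", X, y, window_len=30)
        assert len(sb.models) == 3
        assert [s.stop - s.start for s in sb.window_slices] == [30, 30, 30]

    def test_uninformative_input_near_chance(self, rng):
        X = np.zeros((40, 20, 2))
        y = np.tile([0, 1], 20)
        sb = train_sliding_baselines("svm", X, y, window_len=10)
        accs = sb.window_accuracies(X, y)
        assert np.all(np.abs(accs - 0.5) <= 0.1)

    def test_svm_solves_separable_data(self, rng):
        X, y = separable_trials(rng, n=60, T=20)
        sb = train_sliding_baselines("svm", X, y, train_idx=np.arange(40), window_len=10)
        accs = sb.window_accuracies(X[40:], y[40:])
        assert np.all(accs >= 0.95)

    def test_independent_rnn_windows_reset_hidden_state(self, rng):
        """Perturbing inputs of window 1 must not change window-2 outputs
        (unlike the time-varying model, windows share no state)."""
        X, y = separable_trials(rng, n=20, T=8)
        cfg = TrainConfig(epochs=2, hidden_size=4, seed=0)
        sb = train_sliding_baselines("independent_rnn_s1", X, y, window_len=4, config=cfg)
        Xp = X.copy()
        Xp[:, :4] += 5.0
        assert np.array_equal(
            sb.predict_proba_trajectory(X)[:, 4:],
            sb.predict_proba_trajectory(Xp)[:, 4:],
        )

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ValidationError):
            train_sliding_baselines("kernel_perceptron", np.zeros((4, 6, 1)),
                                    np.array([0, 1, 0, 1]))
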