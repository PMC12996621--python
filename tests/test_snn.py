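"""Spiking classifier: forward-pass oracle, training behaviour, cross-validation."""

import numpy as np
import pytest

from engdecode.folds import make_folds
from engdecode.snn import (
    DecodeResult,
    SNNConfig,
    SNNModel,
    crossval,
    predict,
    snn_forward,
    train_snn,
)


def _model(W, thr=None, **cfg_kw):
    W = np.asarray(W, dtype=float)
    cfg = SNNConfig(n_inputs=W.shape[0], n_outputs=W.shape[1], **cfg_kw)
    thr = np.full(W.shape[1], cfg.u_thr) if thr is None else np.asarray(thr, float)
    return SNNModel(W, thr, cfg)


def scalar_forward(x, W, thr, alpha, beta):
    """Independent step-by-step scalar simulation of the layer dynamics."""
    T, n_in = x.shape
    n_out = W.shape[1]
    counts = np.zeros(n_out)
    for j in range(n_out):
        I = 0.0
        U = 0.0
        S = 0.0
        for t in range(T):
            inj = sum(W[i, j] * x[t, i] for i in range(n_in))
            I = alpha * I + inj
            U = beta * U + I - S * thr[j]
            S = 1.0 if U >= thr[j] else 0.0
            counts[j] += S
    return counts


class TestForward:
    def test_zero_weights_zero_counts(self, rng):
        m = _model(np.zeros((4, 3)))
        x = rng.poisson(1.0, size=(10, 4))
        assert np.all(snn_forward(x, m) == 0)

    def test_three_step_hand_simulation(self):
        """One input spike, weight 1, U_thr=0.5: spike at t=0, soft reset.

        t=0: I=1, U=1 >= 0.5 -> spike. t=1: I=.95, U=.98*1+.95-.5=1.43 ->
        spike (membrane dropped by exactly U_thr before leak). t=2 ...
        """
        m = _model([[1.0]])
        x = np.zeros((3, 1))
        x[0, 0] = 1.0
        counts = snn_forward(x, m)
        # hand: t0 U=1.0 S=1; t1 U=0.98*1.0+0.95-0.5=1.43 S=1; t2 U=0.98*1.43+0.9025-0.5=1.804 S=1
        assert counts[0] == 3

    def test_matches_scalar_oracle_random_instances(self, rng):
        """Vectorised forward equals independent scalar simulation, 100 cases."""
        for _ in range(100):
            n_in = rng.integers(1, 5)
            n_out = rng.integers(1, 4)
            T = rng.integers(1, 11)
            W = rng.normal(size=(n_in, n_out))
            thr = rng.uniform(0.2, 1.5, size=n_out)
            x = rng.poisson(0.8, size=(T, n_in)).astype(float)
            m = _model(W, thr)
            got = snn_forward(x, m)
            want = scalar_forward(x, W, thr, 0.95, 0.98)
            assert np.allclose(got, want, atol=1e-10)

    def test_soft_reset_drops_membrane_by_threshold(self):
        """After a spike the next membrane is beta*U + I - U_thr exactly."""
        from engdecode.snn import _forward_batch

        W = np.array([[2.0]])
        x = np.zeros((1, 3, 1))
        x[0, 0, 0] = 1.0
        _, Us, Ss = _forward_batch(x, W, np.array([0.5]), 0.95, 0.98, record=True)
        assert Ss[0, 0, 0] == 1.0
        # U[1] = 0.98 * U[0] + I[1] - 1 * 0.5
        assert Us[1, 0, 0] == pytest.approx(0.98 * Us[0, 0, 0] + 0.95 * 2.0 - 0.5)

    def test_width_mismatch_errors(self, rng):
        m = _model(np.zeros((4, 2)))
        with pytest.raises(ValueError, match="expected"):
            snn_forward(rng.poisson(1, (10, 5)), m)


class TestPredict:
    def test_argmax(self):
        m = _model(np.eye(6) * 10.0)
        x = np.zeros((8, 6))
        x[:, 2] = 3.0
        cls, tie = predict(m, x)
        assert cls == 2 and not tie

    def test_tie_breaks_to_lowest_index(self):
        m = _model(np.zeros((3, 4)))  # all counts zero -> 4-way tie
        cls, tie = predict(m, np.zeros((5, 3)))
        assert cls == 0 and tie

    def test_matches_exhaustive_argmax(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 5, size=6)
            best = min(i for i in range(6) if counts[i] == counts.max())
            assert best == int(np.argmax(counts))


def _separable_tensors(rng, n_per_class=30, n_classes=3, T=20, n_in=12, rate=2.0):
    """Each class drives a distinct block of input channels."""
    X, labels = [], []
    block = n_in // n_classes
    for c in range(n_classes):
        for _ in range(n_per_class):
            x = rng.poisson(0.05, size=(T, n_in)).astype(float)
            x[:, c * block : (c + 1) * block] += rng.poisson(rate, size=(T, block))
            X.append(x)
            labels.append(f"class_{c}")
    return np.stack(X), labels


class TestTraining:
    def test_single_class_degenerate_optimum(self, rng):
        X = rng.poisson(1.0, size=(10, 20, 4)).astype(float)
        cfg = SNNConfig(n_inputs=4, n_outputs=1, epochs=5, steps=20, batch=10)
        model = train_snn(X, cfg, labels=["only"] * 10)
        preds = [predict(model, x)[0] for x in X]
        assert preds == [0] * 10

    def test_missing_class_errors(self, rng):
        X = rng.poisson(1.0, size=(10, 20, 4)).astype(float)
        cfg = SNNConfig(n_inputs=4, n_outputs=3, epochs=2, steps=20)
        with pytest.raises(ValueError, match="classes"):
            train_snn(X, cfg, labels=["a"] * 5 + ["b"] * 5)

    def test_separable_data_learned(self, rng):
        X, labels = _separable_tensors(rng)
        cfg = SNNConfig(n_inputs=12, n_outputs=3, epochs=60, steps=20,
                        batch=32, seed=3)
        res = crossval(X, cfg, n_folds=5, labels=labels)
        assert res.mean >= 0.9
        assert res.chance == pytest.approx(1 / 3)

    def test_loss_decreases_early(self, rng):
        X, labels = _separable_tensors(rng)
        cfg = SNNConfig(n_inputs=12, n_outputs=3, epochs=50, steps=20,
                        batch=32, seed=0)
        model = train_snn(X, cfg, labels=labels)
        h = model.loss_history
        viol = np.mean(np.diff(h) > 0)
        assert h[-1] < h[0]
        assert viol <= 0.05 or h[-1] < 0.5 * h[0]

    def test_permuted_labels_at_chance(self, rng):
        X, labels = _separable_tensors(rng, n_per_class=20)
        perm = rng.permutation(len(labels))
        shuffled = [labels[i] for i in perm]
        cfg = SNNConfig(n_inputs=12, n_outputs=3, epochs=30, steps=20,
                        batch=32, seed=1)
        res = crossval(X, cfg, n_folds=5, labels=shuffled)
        n_test = len(labels) / 5
        sd_null = np.sqrt((1 / 3) * (2 / 3) / n_test)
        assert abs(res.mean - 1 / 3) < 3 * sd_null

    def test_reproducible_given_seed(self, rng):
        X, labels = _separable_tensors(rng, n_per_class=10)
        cfg = SNNConfig(n_inputs=12, n_outputs=3, epochs=10, steps=20, seed=7)
        r1 = crossval(X, cfg, labels=labels)
        r2 = crossval(X, cfg, labels=labels)
        assert np.array_equal(r1.fold_accuracies, r2.fold_accuracies)


class TestCrossval:
    def test_fold_partition(self, rng):
        y = rng.integers(0, 3, size=60)
        folds = make_folds(y, 5, seed=0)
        assert sorted(np.unique(folds)) == [0, 1, 2, 3, 4]
        for c in np.unique(y):
            counts = np.bincount(folds[y == c], minlength=5)
            assert counts.max() - counts.min() <= 1  # stratified
        # every sample tested exactly once by construction
        assert len(folds) == 60

    def test_small_class_errors(self):
        with pytest.raises(ValueError, match="folds"):
            make_folds(np.array([0, 0, 0, 1, 1]), 5)

    def test_confusion_rows_sum_to_one(self, rng):
        X, labels = _separable_tensors(rng, n_per_class=10)
        cfg = SNNConfig(n_inputs=12, n_outputs=3, epochs=5, steps=20, seed=0)
        res = crossval(X, cfg, labels=labels)
        assert np.allclose(res.confusion.sum(axis=1), 1.0)
        assert "SNN" in res.summary()


class TestElectrodeSubsets:
    def test_combination_counts_and_widths(self, rng):
        from engdecode.snn import electrode_subset_eval

        n_base = 28  # 2 electrode groups of 14
        groups = {1: np.arange(14), 2: np.arange(14, 28)}
        X, labels = [], []
        for c in range(2):
            for _ in range(10):
                x = rng.poisson(0.1, size=(10, n_base)).astype(float)
                x[:, c * 14 : (c + 1) * 14] += rng.poisson(2.0, size=(10, 14))
                X.append(x)
                labels.append(f"c{c}")
        X = np.stack(X)
        cfg = SNNConfig(n_inputs=n_base, n_outputs=2, epochs=3, steps=10, seed=0)
        out = electrode_subset_eval(
            X, groups, cfg, sizes=(1, 2), n_folds=2, labels=labels,
            n_base_channels=n_base,
        )
        sizes = [r["size"] for r in out["per_combination"]]
        assert sizes.count(1) == 2 and sizes.count(2) == 1  # C(2,1), C(2,2)
        assert set(out["mean_by_size"]) == {1, 2}

    def test_bad_group_size_errors(self, rng):
        from engdecode.snn import electrode_subset_eval

        cfg = SNNConfig(n_inputs=10, n_outputs=2, epochs=1, steps=5)
        with pytest.raises(ValueError, match="14"):
            electrode_subset_eval(
                np.zeros((4, 5, 10)), {1: np.arange(10)}, cfg,
                sizes=(1,), n_folds=2, labels=["a", "a", "b", "b"],
            )
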