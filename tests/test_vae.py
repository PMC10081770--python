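"""Windowing, VAE training mechanics, latent codes, task classification."""
import numpy as np
import pandas as pd
import pytest

from wristpd.core import AccelRecording
from wristpd.vae import (VaeModel, _init_params, _loss_and_grads, encode_latent,
                         evaluate_task_classification, evaluate_transfer,
                         family_confusion_contrast, reconstruct, train_vae,
                         window_10s, windows_from_array)


def _structured_windows(n=160, d=60, seed=0):
    """Low-dimensional structured data the VAE can compress."""
    rng = np.random.default_rng(seed)
    basis = rng.normal(size=(4, d))
    codes = rng.normal(size=(n, 4))
    return codes @ basis + 0.1 * rng.normal(size=(n, d))


class TestWindowing:
    def test_non_overlapping_count(self):
        n = int(25 * 50)
        rec = AccelRecording("S", "unknown", 50.0, np.arange(n) / 50.0,
                             np.random.default_rng(0).normal(size=(n, 3)))
        w, t0 = window_10s(rec)
        assert w.shape == (2, 1500)
        np.testing.assert_allclose(t0, [0.0, 10.0])

    def test_constant_channel_becomes_zeros(self):
        xyz = np.ones((500, 3))
        w = windows_from_array(xyz, 50.0)
        np.testing.assert_array_equal(w, 0.0)

    def test_window_standardisation(self):
        rng = np.random.default_rng(1)
        w = windows_from_array(rng.normal(2.0, 3.0, size=(1000, 3)), 50.0)
        per_channel = w.reshape(2, 3, 500)
        np.testing.assert_allclose(per_channel.mean(axis=2), 0.0, atol=1e-12)
        np.testing.assert_allclose(per_channel.std(axis=2), 1.0, atol=1e-12)

    def test_window_crossing_gap_dropped(self):
        n = int(30 * 50)
        t = np.arange(n) / 50.0
        t[800:] += 5.0  # gap inside the second window
        rec = AccelRecording("S", "unknown", 50.0, t,
                             np.random.default_rng(0).normal(size=(n, 3)))
        w, t0 = window_10s(rec)
        # first run: samples 0..799 -> one full window; second run restarts
        assert 0.0 in t0
        assert not np.any((t0 > 10.0 - 1e-9) & (t0 < 16.0 + 5.0 - 1e-9))

    def test_short_recording_empty(self):
        rec = AccelRecording("S", "unknown", 50.0, np.arange(100) / 50.0,
                             np.zeros((100, 3)))
        w, _ = window_10s(rec)
        assert w.shape[0] == 0


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        d, h, k, B = 8, 5, 3, 4
        p = _init_params(rng, d, h, k)
        x = rng.normal(size=(B, d))
        eps = rng.normal(size=(B, k))
        recon, kl, grads = _loss_and_grads(p, x, eps)
        delta = 1e-6
        for key in p:
            flat = p[key].reshape(-1)
            for idx in [0, flat.size // 2, flat.size - 1]:
                orig = flat[idx]
                flat[idx] = orig + delta
                rp, kp, _ = _loss_and_grads(p, x, eps)
                flat[idx] = orig - delta
                rm, km, _ = _loss_and_grads(p, x, eps)
                flat[idx] = orig
                numeric = ((rp + kp) - (rm + km)) / (2 * delta)
                assert grads[key].reshape(-1)[idx] == pytest.approx(numeric, abs=1e-4)


class TestTraining:
    @pytest.fixture(scope="class")
    def trained(self):
        X = _structured_windows()
        return X, train_vae(X, epochs=40, lr=2e-3, batch=32, seed=0)

    def test_elbo_improves(self, trained):
        _, model = trained
        elbo = model.elbo_trace["elbo"].to_numpy()
        smooth = np.convolve(elbo, np.ones(5) / 5, mode="valid")
        assert smooth[-1] > smooth[0]

    def test_elbo_decomposes(self, trained):
        _, model = trained
        tr = model.elbo_trace
        np.testing.assert_allclose(tr["elbo"], -(tr["recon"] + tr["kl"]), atol=1e-6)

    def test_reconstruction_beats_zero_predictor(self, trained):
        X, model = trained
        mse = np.mean((X - reconstruct(model, X)) ** 2)
        assert mse < np.mean(X**2)

    def test_training_is_deterministic(self):
        X = _structured_windows(n=64)
        a = train_vae(X, epochs=3, batch=16, seed=7)
        b = train_vae(X, epochs=3, batch=16, seed=7)
        for key in a.params:
            np.testing.assert_array_equal(a.params[key], b.params[key])

    def test_encoding_deterministic_and_20d_by_default(self, trained):
        X, model = trained
        mu1, lv1 = encode_latent(model, X[:10])
        mu2, _ = encode_latent(model, X[:10])
        np.testing.assert_array_equal(mu1, mu2)
        assert mu1.shape[1] == model.latent_dim == 20
        assert np.all(np.isfinite(mu1)) and np.all(np.isfinite(lv1))

    def test_no_full_posterior_collapse(self, trained):
        X, model = trained
        mu, _ = encode_latent(model, X)
        assert np.all(mu.var(axis=0) > 1e-8)

    def test_encoding_order_invariance(self, trained):
        X, model = trained
        perm = np.random.default_rng(3).permutation(X.shape[0])
        mu, _ = encode_latent(model, X)
        mu_perm, _ = encode_latent(model, X[perm])
        np.testing.assert_array_equal(mu_perm, mu[perm])

    def test_dimension_mismatch_rejected(self, trained):
        _, model = trained
        with pytest.raises(ValueError):
            encode_latent(model, np.zeros((4, 17)))


class TestClassification:
    def _codes(self, n_per=40, n_classes=3, n_subjects=6, sep=3.0, seed=0):
        centers = np.random.default_rng(99).normal(0, sep, (n_classes, 8))
        rng = np.random.default_rng(seed)
        X, y, g = [], [], []
        for c in range(n_classes):
            X.append(centers[c] + rng.normal(size=(n_per, 8)))
            y += [f"task{c}"] * n_per
            g += [f"S{i % n_subjects}" for i in range(n_per)]
        return np.vstack(X), np.array(y), np.array(g)

    def test_separable_codes_classified(self):
        X, y, g = self._codes()
        res = evaluate_task_classification(X, y, g, seed=0)
        assert res.accuracy > 0.9
        np.testing.assert_allclose(res.confusion.sum(axis=1), 1.0, atol=1e-9)
        assert res.chance == pytest.approx(1 / 3)

    def test_missing_class_in_training_fold_raises(self):
        X, y, g = self._codes(n_subjects=2)
        g[y == "task0"] = "S0"  # task0 exists only in one group
        g[y != "task0"] = "S1"
        with pytest.raises(ValueError, match="stratification"):
            evaluate_task_classification(X, y, g, n_folds=2, seed=0)

    def test_transfer_between_cohorts(self):
        Xa, ya, _ = self._codes(seed=1)
        Xb, yb, _ = self._codes(seed=2)
        res = evaluate_transfer(Xa, ya, Xb, yb, seed=0)
        assert res.accuracy > 0.8

    def test_family_confusion_contrast(self):
        conf = pd.DataFrame(
            [[0.8, 0.15, 0.05], [0.2, 0.7, 0.1], [0.05, 0.05, 0.9]],
            index=["walk", "walk2", "sit"], columns=["walk", "walk2", "sit"])
        fams = {"walk": "walking", "walk2": "walking", "sit": "stationary"}
        same, cross = family_confusion_contrast(conf, fams)
        assert same == pytest.approx((0.15 + 0.2) / 2)
        assert cross == pytest.approx((0.05 + 0.1 + 0.05 + 0.05) / 4)
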