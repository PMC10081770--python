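"""Movement-state representation learning with a fully connected VAE.

Ten-second windows of tri-axial accelerometry (3 x 500 samples at 50 Hz,
standardised per channel and flattened channel-major to 1500 values) are
encoded by a 1500-400-(20, 20) fully connected network into a 20-dim
Gaussian posterior; a symmetric decoder reconstructs the window.  Training
maximises the ELBO (unit-variance Gaussian likelihood, i.e. an MSE
reconstruction term, minus the KL divergence to a standard normal prior)
with the reparameterisation trick and Adam.

The network and its gradients are implemented directly in NumPy; the
model is small enough that a deep-learning framework is unnecessary.

Downstream, a two-hidden-layer MLP (50 nodes each) classifies movement
tasks from the latent means, with grouped five-fold cross-validation or
with cross-cohort transfer (encoder and classifier fitted on one cohort,
evaluated on another).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score
from sklearn.model_selection import GroupKFold
from sklearn.neural_network import MLPClassifier

from .core import AccelRecording

WINDOW_SECONDS = 10.0
LATENT_DIM = 20
HIDDEN_DIM = 400


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------


def windows_from_array(xyz: np.ndarray, fs: float = 50.0,
                       window_seconds: float = WINDOW_SECONDS) -> np.ndarray:
    """Non-overlapping standardized windows from a gap-free signal.

    Each window is standardised per channel (zero mean, unit variance;
    constant channels become zeros) and flattened channel-major, giving
    1500 values for 10 s at 50 Hz.
    """
    xyz = np.asarray(xyz, dtype=float)
    wlen = int(round(window_seconds * fs))
    n_win = xyz.shape[0] // wlen
    if n_win == 0:
        return np.empty((0, 3 * wlen))
    w = xyz[:n_win * wlen].reshape(n_win, wlen, 3)
    mean = w.mean(axis=1, keepdims=True)
    sd = w.std(axis=1, keepdims=True)
    w = np.where(sd > 1e-12, (w - mean) / np.where(sd > 1e-12, sd, 1.0), 0.0)
    return w.transpose(0, 2, 1).reshape(n_win, 3 * wlen)


def window_10s(recording: AccelRecording,
               window_seconds: float = WINDOW_SECONDS) -> tuple[np.ndarray, np.ndarray]:
    """Windows of a recording, dropping any window that crosses a gap.

    The recording is split at timestamp discontinuities (interval larger
    than 1.5 nominal sample periods) and windowed within contiguous runs.
    Returns ``(windows, start_times)``.
    """
    fs = recording.sampling_rate
    wlen = int(round(window_seconds * fs))
    if recording.n_samples < wlen:
        return np.empty((0, 3 * wlen)), np.empty(0)
    dt = np.diff(recording.t)
    breaks = np.nonzero(dt > 1.5 / fs)[0] + 1
    pieces, times = [], []
    for seg in np.split(np.arange(recording.n_samples), breaks):
        if seg.size < wlen:
            continue
        w = windows_from_array(recording.xyz[seg], fs, window_seconds)
        pieces.append(w)
        times.append(recording.t[seg[0]] + np.arange(w.shape[0]) * window_seconds)
    if not pieces:
        return np.empty((0, 3 * wlen)), np.empty(0)
    return np.concatenate(pieces), np.concatenate(times)


# ---------------------------------------------------------------------------
# the VAE itself
# ---------------------------------------------------------------------------


@dataclass
class VaeModel:
    """Fully connected VAE with a mirrored encoder/decoder."""

    params: dict[str, np.ndarray]
    input_dim: int
    hidden_dim: int
    latent_dim: int
    epochs: int
    lr: float
    batch: int
    seed: int
    elbo_trace: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def final_elbo(self) -> float:
        return float(self.elbo_trace["elbo"].iloc[-1])


def _init_params(rng: np.random.Generator, d: int, h: int, k: int) -> dict[str, np.ndarray]:
    def he(n_in, n_out):
        return rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)

    return {
        "W1": he(d, h), "b1": np.zeros(h),
        "Wm": he(h, k), "bm": np.zeros(k),
        "Wv": he(h, k) * 0.1, "bv": np.zeros(k),
        "W4": he(k, h), "b4": np.zeros(h),
        "W5": he(h, d), "b5": np.zeros(d),
    }


def _loss_and_grads(p: dict[str, np.ndarray], x: np.ndarray,
                    eps: np.ndarray) -> tuple[float, float, dict[str, np.ndarray]]:
    """Per-window mean reconstruction and KL terms plus parameter gradients."""
    B = x.shape[0]
    h1a = x @ p["W1"] + p["b1"]
    h1 = np.maximum(h1a, 0.0)
    mu = h1 @ p["Wm"] + p["bm"]
    lv = np.clip(h1 @ p["Wv"] + p["bv"], -15.0, 15.0)
    std = np.exp(0.5 * lv)
    z = mu + std * eps
    h2a = z @ p["W4"] + p["b4"]
    h2 = np.maximum(h2a, 0.0)
    xr = h2 @ p["W5"] + p["b5"]

    recon = 0.5 * np.sum((x - xr) ** 2) / B
    kl = -0.5 * np.sum(1.0 + lv - mu**2 - np.exp(lv)) / B

    dxr = (xr - x) / B
    g = {"W5": h2.T @ dxr, "b5": dxr.sum(axis=0)}
    dh2 = (dxr @ p["W5"].T) * (h2a > 0)
    g["W4"] = z.T @ dh2
    g["b4"] = dh2.sum(axis=0)
    dz = dh2 @ p["W4"].T
    dmu = dz + mu / B
    dlv = dz * eps * 0.5 * std + 0.5 * (np.exp(lv) - 1.0) / B
    g["Wm"] = h1.T @ dmu
    g["bm"] = dmu.sum(axis=0)
    g["Wv"] = h1.T @ dlv
    g["bv"] = dlv.sum(axis=0)
    dh1 = (dmu @ p["Wm"].T + dlv @ p["Wv"].T) * (h1a > 0)
    g["W1"] = x.T @ dh1
    g["b1"] = dh1.sum(axis=0)
    return recon, kl, g


def train_vae(windows: np.ndarray, epochs: int = 30, lr: float = 1e-3,
              batch: int = 128, seed: int = 0,
              hidden_dim: int = HIDDEN_DIM,
              latent_dim: int = LATENT_DIM) -> VaeModel:
    """Train the VAE with Adam; deterministic given the seed.

    The per-epoch trace records the mean reconstruction term, KL term and
    their (negated) sum, the ELBO.  A NaN loss aborts with diagnostics.
    """
    X = np.asarray(windows, dtype=float)
    if X.ndim != 2:
        raise ValueError("windows must be (n, input_dim)")
    n, d = X.shape
    if n < batch:
        batch = max(1, n)
    rng = np.random.default_rng(seed)
    p = _init_params(rng, d, hidden_dim, latent_dim)
    m = {k: np.zeros_like(v) for k, v in p.items()}
    v = {k: np.zeros_like(v) for k, v in p.items()}
    b1, b2, eps_adam = 0.9, 0.999, 1e-8
    step = 0
    trace = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        rec_sum = kl_sum = 0.0
        n_batches = 0
        for lo in range(0, n, batch):
            idx = order[lo:lo + batch]
            xb = X[idx]
            eps = rng.standard_normal((xb.shape[0], latent_dim))
            recon, kl, grads = _loss_and_grads(p, xb, eps)
            if not np.isfinite(recon + kl):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {step}: "
                    f"recon={recon}, kl={kl}; try a lower learning rate")
            step += 1
            for key, gval in grads.items():
                m[key] = b1 * m[key] + (1 - b1) * gval
                v[key] = b2 * v[key] + (1 - b2) * gval**2
                mhat = m[key] / (1 - b1**step)
                vhat = v[key] / (1 - b2**step)
                p[key] = p[key] - lr * mhat / (np.sqrt(vhat) + eps_adam)
            rec_sum += recon
            kl_sum += kl
            n_batches += 1
        rec_mean = rec_sum / n_batches
        kl_mean = kl_sum / n_batches
        trace.append({"epoch": epoch, "recon": rec_mean, "kl": kl_mean,
                      "elbo": -(rec_mean + kl_mean)})
    return VaeModel(p, d, hidden_dim, latent_dim, epochs, lr, batch, seed,
                    pd.DataFrame(trace))


def encode_latent(model: VaeModel, windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior means and log-variances; deterministic (no sampling)."""
    X = np.asarray(windows, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ValueError(f"windows must be (n, {model.input_dim})")
    p = model.params
    h1 = np.maximum(X @ p["W1"] + p["b1"], 0.0)
    mu = h1 @ p["Wm"] + p["bm"]
    lv = h1 @ p["Wv"] + p["bv"]
    return mu, lv


def reconstruct(model: VaeModel, windows: np.ndarray) -> np.ndarray:
    """Deterministic reconstruction through the posterior mean."""
    mu, _ = encode_latent(model, windows)
    p = model.params
    h2 = np.maximum(mu @ p["W4"] + p["b4"], 0.0)
    return h2 @ p["W5"] + p["b5"]


# ---------------------------------------------------------------------------
# downstream task classification
# ---------------------------------------------------------------------------


@dataclass
class TaskClassificationResult:
    """Grouped-CV (or transfer) accuracy with a row-normalised confusion."""

    accuracy: float
    fold_accuracies: list[float]
    confusion: pd.DataFrame  # rows: true task, columns: predicted
    chance: float


def _confusion(y_true: Sequence, y_pred: Sequence, classes: Sequence) -> pd.DataFrame:
    mat = pd.crosstab(pd.Series(y_true, name="true"),
                      pd.Series(y_pred, name="pred"))
    mat = mat.reindex(index=classes, columns=classes, fill_value=0).astype(float)
    sums = mat.sum(axis=1)
    if (sums == 0).any():
        raise ValueError("a true class has no evaluated windows")
    return mat.div(sums, axis=0)


def _mlp(seed: int):
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    return make_pipeline(
        StandardScaler(),
        MLPClassifier(hidden_layer_sizes=(50, 50), max_iter=800,
                      random_state=seed))


def evaluate_task_classification(codes: np.ndarray, task_labels: Sequence,
                                 groups: Sequence, n_folds: int = 5,
                                 seed: int = 0) -> TaskClassificationResult:
    """Grouped five-fold CV of an MLP(50, 50) on latent means."""
    X = np.asarray(codes, dtype=float)
    y = np.asarray(task_labels)
    g = np.asarray(groups)
    classes = sorted(np.unique(y))
    if len(classes) < 2:
        raise ValueError("need at least two task classes")
    accs, yt_all, yp_all = [], [], []
    splitter = GroupKFold(n_splits=min(n_folds, len(np.unique(g))))
    for tr, te in splitter.split(X, y, g):
        if len(np.unique(y[tr])) < len(classes):
            raise ValueError("a task class is absent from a training fold "
                             "(stratification error)")
        clf = _mlp(seed)
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        accs.append(accuracy_score(y[te], pred))
        yt_all.extend(y[te])
        yp_all.extend(pred)
    return TaskClassificationResult(float(np.mean(accs)), [float(a) for a in accs],
                                    _confusion(yt_all, yp_all, classes),
                                    1.0 / len(classes))


def evaluate_transfer(train_codes: np.ndarray, train_labels: Sequence,
                      test_codes: np.ndarray, test_labels: Sequence,
                      seed: int = 0) -> TaskClassificationResult:
    """Classifier fitted on one cohort's codes, evaluated on another's."""
    classes = sorted(set(np.asarray(train_labels)) | set(np.asarray(test_labels)))
    clf = _mlp(seed)
    clf.fit(np.asarray(train_codes, dtype=float), np.asarray(train_labels))
    pred = clf.predict(np.asarray(test_codes, dtype=float))
    acc = accuracy_score(np.asarray(test_labels), pred)
    return TaskClassificationResult(float(acc), [float(acc)],
                                    _confusion(test_labels, pred, classes),
                                    1.0 / len(classes))


def family_confusion_contrast(confusion: pd.DataFrame,
                              families: dict[str, str]) -> tuple[float, float]:
    """Mean off-diagonal confusion within vs across task families."""
    same, cross = [], []
    for a in confusion.index:
        for b in confusion.columns:
            if a == b:
                continue
            (same if families[a] == families[b] else cross).append(confusion.loc[a, b])
    return float(np.mean(same)), float(np.mean(cross))
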