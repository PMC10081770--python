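"""Ordinal "accelerometer scores" and per-task drug-effect contrasts.

For each symptom (tremor, bradykinesia, dyskinesia) an L2-regularised
proportional-odds model maps spectral features of a task replicate to the
0-4 observer score; the model's linear predictor, standardised across the
scored set, is the *accelerometer score* — a scalar symptom indicator
that is a function of accelerometer data only.

Drug and task effects on those scores are then estimated with a linear
mixed model (score ~ task * drug, random intercepts for subject and
session, REML) with subject-level bootstrap confidence intervals — a
deliberately simpler surrogate for a full Bayesian hierarchical fit that
preserves the replication structure (subject, task, drug state, session).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from sklearn.model_selection import GroupKFold

SYMPTOM_POLARITY = {"tremor": -1, "bradykinesia": -1, "dyskinesia": +1}
"""Expected sign of the ON-OFF accelerometer-score contrast per symptom:
levodopa attenuates tremor and bradykinesia and amplifies dyskinesia."""


# ---------------------------------------------------------------------------
# penalized proportional-odds (cumulative logit) regression
# ---------------------------------------------------------------------------


@dataclass
class OrdinalModel:
    """Fitted proportional-odds scorer for one symptom."""

    weights: np.ndarray  # per standardized feature
    cutpoints: np.ndarray  # K-1 strictly increasing thresholds
    lam: float  # L2 strength on weights
    levels: np.ndarray  # ordinal levels seen in training
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    cv_table: pd.DataFrame  # lambda -> mean held-out NLL
    nll: float  # final training penalized NLL

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_scale
        return Xs @ self.weights


def _unpack(params: np.ndarray, p: int, K: int):
    w = params[:p]
    c0 = params[p]
    gaps = np.exp(params[p + 1:])
    cut = c0 + np.concatenate([[0.0], np.cumsum(gaps)])
    assert cut.size == K - 1
    return w, cut, gaps


def _nll_grad(params: np.ndarray, X: np.ndarray, y: np.ndarray,
              K: int, lam: float) -> tuple[float, np.ndarray]:
    """Penalized negative log-likelihood of the cumulative-logit model.

    Cutpoints are parametrised as (c_0, log-gaps) so monotonicity holds by
    construction; the L2 penalty applies to the weights only.
    """
    n, p = X.shape
    w, cut, gaps = _unpack(params, p, K)
    eta = X @ w
    # F[i, k] = P(Y <= k | x_i) for k = 0..K-2; boundaries handled implicitly
    F = expit(cut[None, :] - eta[:, None])  # (n, K-1)
    Fy = np.where(y < K - 1, F[np.arange(n), np.minimum(y, K - 2)], 1.0)
    Fy1 = np.where(y > 0, F[np.arange(n), np.maximum(y - 1, 0)], 0.0)
    lik = np.clip(Fy - Fy1, 1e-12, None)
    nll = -np.log(lik).sum() + lam * np.dot(w, w)

    # derivatives of the sigmoid terms
    dFy = np.where(y < K - 1, Fy * (1 - Fy), 0.0)  # d/d(c_y)
    dFy1 = np.where(y > 0, Fy1 * (1 - Fy1), 0.0)  # d/d(c_{y-1})
    # eta enters with opposite sign
    dnll_deta = (dFy - dFy1) / lik
    grad_w = X.T @ dnll_deta + 2 * lam * w

    grad_c = np.zeros(K - 1)
    np.add.at(grad_c, np.minimum(y, K - 2), np.where(y < K - 1, -dFy / lik, 0.0))
    np.add.at(grad_c, np.maximum(y - 1, 0), np.where(y > 0, dFy1 / lik, 0.0))
    # chain rule to (c_0, log-gaps): c_k = c_0 + sum_{j<=k} gap_j
    grad_c0 = grad_c.sum()
    grad_gaps = np.array([grad_c[j + 1:].sum() * gaps[j] for j in range(K - 2)])
    grad = np.concatenate([grad_w, [grad_c0], grad_gaps])
    return nll, grad


def _fit_penalized(X: np.ndarray, y: np.ndarray, K: int, lam: float,
                   x0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    n, p = X.shape
    if x0 is None:
        # cutpoints from marginal frequencies, zero weights
        freq = np.bincount(y, minlength=K) + 0.5
        cum = np.cumsum(freq)[:-1] / freq.sum()
        cuts = np.log(cum / (1 - cum))
        gaps = np.maximum(np.diff(cuts), 1e-3)
        x0 = np.concatenate([np.zeros(p), [cuts[0]], np.log(gaps)])
    res = optimize.minimize(_nll_grad, x0, args=(X, y, K, lam),
                            jac=True, method="L-BFGS-B",
                            options={"maxiter": 2000, "ftol": 1e-12})
    w, cut, _ = _unpack(res.x, p, K)
    return w, cut, float(res.fun)


def _heldout_nll(w, cut, X, y, K) -> float:
    eta = X @ w
    F = expit(cut[None, :] - eta[:, None])
    n = len(y)
    Fy = np.where(y < K - 1, F[np.arange(n), np.minimum(y, K - 2)], 1.0)
    Fy1 = np.where(y > 0, F[np.arange(n), np.maximum(y - 1, 0)], 0.0)
    return float(-np.log(np.clip(Fy - Fy1, 1e-12, None)).mean())


def fit_ordinal_scorer(features: pd.DataFrame | np.ndarray,
                       labels: Sequence[int],
                       groups: Sequence | None = None,
                       lambda_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0),
                       n_folds: int = 5, seed: int = 0) -> OrdinalModel:
    """Cross-validated L2 proportional-odds fit on spectral features.

    The regularisation strength is chosen by grouped (per-subject)
    cross-validated held-out negative log-likelihood; features are
    standardised internally.  Deterministic given the fold assignment.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"f{j}" for j in range(X.shape[1])]
    y = np.asarray(labels, dtype=int)
    uniq = np.unique(y)
    if uniq.size < 2:
        raise ValueError("labels contain a single ordinal level")
    # map observed levels to 0..K-1 for the likelihood
    level_of = {v: k for k, v in enumerate(uniq)}
    yk = np.array([level_of[v] for v in y])
    K = uniq.size

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale < 1e-12] = 1.0
    Xs = (X - mean) / scale

    if groups is None:
        groups = np.arange(len(y))
    groups = np.asarray(groups)
    n_folds = min(n_folds, len(np.unique(groups)))
    cv_rows = []
    for lam in lambda_grid:
        losses = []
        splitter = GroupKFold(n_splits=n_folds)
        for tr, te in splitter.split(Xs, yk, groups):
            if np.unique(yk[tr]).size < 2:
                continue
            # refit with the training fold's own level set
            tr_levels = np.unique(yk[tr])
            remap = {v: k for k, v in enumerate(tr_levels)}
            ytr = np.array([remap[v] for v in yk[tr]])
            w, cut, _ = _fit_penalized(Xs[tr], ytr, tr_levels.size, lam)
            # evaluate on held-out labels clipped into the training range
            yte = np.array([remap[min(tr_levels, key=lambda l: abs(l - v))] for v in yk[te]])
            losses.append(_heldout_nll(w, cut, Xs[te], yte, tr_levels.size))
        cv_rows.append({"lambda": lam, "heldout_nll": float(np.mean(losses))})
    cv_table = pd.DataFrame(cv_rows)
    best_lam = float(cv_table.loc[cv_table["heldout_nll"].idxmin(), "lambda"])
    w, cut, nll = _fit_penalized(Xs, yk, K, best_lam)
    if np.any(np.diff(cut) <= 0):  # unreachable by construction; guard anyway
        raise RuntimeError("fitted cutpoints are not increasing")
    return OrdinalModel(w, cut, best_lam, uniq, names, mean, scale, cv_table, nll)


def accelerometer_scores(model: OrdinalModel,
                         features: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Standardised linear-predictor scores (cutpoints unused).

    The scale of the raw predictor is arbitrary, so scores are reduced to
    zero mean and unit variance over the scored set; a constant predictor
    (e.g. fully shrunk weights) yields all-zero scores with a warning.
    """
    if isinstance(features, pd.DataFrame):
        if list(features.columns) != model.feature_names:
            raise ValueError("feature columns do not match the training features")
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.shape[1] != len(model.feature_names):
            raise ValueError("feature dimension does not match the training features")
    eta = model.linear_predictor(X)
    sd = eta.std()
    if sd < 1e-5:  # numerically constant, e.g. fully shrunk weights
        warnings.warn("constant accelerometer scores (weights fully shrunk)")
        return np.zeros_like(eta)
    return (eta - eta.mean()) / sd


# ---------------------------------------------------------------------------
# drug / task effect contrasts
# ---------------------------------------------------------------------------


OVERALL = "(all tasks)"


def _fixed_effect_deltas(df: pd.DataFrame, method: str = "reml") -> pd.Series:
    """Per-task ON-OFF contrast from the fixed part of score ~ task * drug."""
    import statsmodels.formula.api as smf

    tasks = sorted(df["task"].unique())
    data = df.copy()
    data["drug01"] = (data["drug_state"] == "ON").astype(float)
    formula = "score ~ C(task) * drug01"
    fit = None
    if method == "reml" and data["subject"].nunique() > 1:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, data, groups=data["subject"],
                                    re_formula="1",
                                    vc_formula={"session": "0 + C(session_id)"})
                fit = model.fit(reml=True)
            if not np.all(np.isfinite(fit.fe_params)):
                fit = None
        except Exception:
            fit = None
    if fit is None:  # OLS fallback / explicit request
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.ols(formula, data).fit()

    grid_on = pd.DataFrame({"task": tasks, "drug01": 1.0})
    grid_off = pd.DataFrame({"task": tasks, "drug01": 0.0})
    if hasattr(fit, "fe_params"):  # MixedLM: predict uses fixed effects only
        pred_on = fit.predict(exog=grid_on)
        pred_off = fit.predict(exog=grid_off)
    else:
        pred_on = fit.predict(grid_on)
        pred_off = fit.predict(grid_off)
    return pd.Series(np.asarray(pred_on) - np.asarray(pred_off), index=tasks)


def estimate_task_drug_effects(scores: pd.DataFrame, n_boot: int = 200,
                               seed: int = 0,
                               method: str = "reml") -> pd.DataFrame:
    """ON-OFF score contrast and signal strength per task, with bootstrap CIs.

    ``scores`` needs columns subject, session_id, task, drug_state, score.
    ``drug_delta`` is the task-specific fixed-effect ON-OFF contrast;
    ``signal_strength`` is the standard deviation of observed scores
    within the task (how much symptom signal the task exposes).  CIs are
    percentile intervals over ``n_boot`` subject-level resamples.  A task
    observed under a single drug state gets a missing delta.  The row
    labelled ``(all tasks)`` averages the per-task deltas.
    """
    required = {"subject", "session_id", "task", "drug_state", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"scores frame must have columns {sorted(required)}")
    if scores["subject"].nunique() < 2:
        raise ValueError("need at least two subjects")
    both_states = scores.groupby("task")["drug_state"].nunique()
    if not (both_states >= 2).any():
        raise ValueError("no task observed under both drug states")
    usable = both_states[both_states >= 2].index
    df = scores[scores["task"].isin(usable)]

    point = _fixed_effect_deltas(df, method=method)
    strength = df.groupby("task")["score"].std()

    rng = np.random.default_rng(seed)
    subjects = np.array(sorted(df["subject"].unique()))
    by_subject = {s: g for s, g in df.groupby("subject")}
    boot = np.full((n_boot, len(point) + 1), np.nan)
    tasks = list(point.index)
    for bi in range(n_boot):
        chosen = rng.choice(subjects, size=len(subjects), replace=True)
        parts = []
        for j, s in enumerate(chosen):
            g = by_subject[s].copy()
            g["subject"] = f"bs{j}"  # resampled copies are distinct subjects
            g["session_id"] = g["session_id"].astype(str) + f"-bs{j}"
            parts.append(g)
        sample = pd.concat(parts, ignore_index=True)
        if sample.groupby("task")["drug_state"].nunique().min() < 2:
            continue
        try:
            d = _fixed_effect_deltas(sample, method=method)
        except Exception:
            continue
        boot[bi, :-1] = d.reindex(tasks).to_numpy()
        boot[bi, -1] = d.mean()

    rows = []
    for j, task in enumerate(tasks):
        col = boot[:, j]
        col = col[np.isfinite(col)]
        lo, hi = (np.quantile(col, [0.025, 0.975]) if col.size else (np.nan, np.nan))
        rows.append({"task": task, "drug_delta": float(point[task]),
                     "signal_strength": float(strength.get(task, np.nan)),
                     "ci_low": float(lo), "ci_high": float(hi),
                     "missing": False})
    col = boot[:, -1]
    col = col[np.isfinite(col)]
    lo, hi = (np.quantile(col, [0.025, 0.975]) if col.size else (np.nan, np.nan))
    rows.append({"task": OVERALL, "drug_delta": float(point.mean()),
                 "signal_strength": float(df["score"].std()),
                 "ci_low": float(lo), "ci_high": float(hi), "missing": False})
    for task in sorted(set(scores["task"]) - set(usable)):
        rows.append({"task": task, "drug_delta": np.nan,
                     "signal_strength": float(scores[scores["task"] == task]["score"].std()),
                     "ci_low": np.nan, "ci_high": np.nan, "missing": True})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature extraction for task replicates
# ---------------------------------------------------------------------------


def spectral_feature_matrix(signals: Sequence[np.ndarray], fs: float = 50.0,
                            binning=None) -> pd.DataFrame:
    """Device + gravity-channel log-bin features, one row per replicate."""
    from .spectra import G_CHANNELS, DEVICE_CHANNELS, channel_signals, default_binning, spectrum_db

    bn = binning or default_binning(fs)
    names = list(DEVICE_CHANNELS) + list(G_CHANNELS)
    cols = [f"{ch}_bin{j}" for ch in names for j in range(bn.n_bins)]
    rows = np.empty((len(signals), len(cols)))
    for i, sig in enumerate(signals):
        sigs = channel_signals(np.asarray(sig), fs, ("device", "g"))
        stacked = np.stack([sigs[ch] for ch in names], axis=1)
        rows[i] = spectrum_db(stacked, fs, bn).ravel()
    return pd.DataFrame(rows, columns=cols)
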