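"""Patient-vs-control spectral contrast and leave-one-subject-out ROC.

The cohort contrast uses a Welch-type standard score per (channel, bin),
computed over pooled blocks (subjects are deliberately not treated as the
replication unit).  Separation is then quantified by training an
L2-regularised logistic model on per-subject mean x-channel spectra under
leave-one-subject-out cross-validation and summarising the held-out
scores with a ROC curve and its Mann-Whitney AUC.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .core import CONTROL, PATIENT
from .spectra import bin_columns

log = logging.getLogger(__name__)


def subject_mean_spectrum(features: pd.DataFrame, channel: str) -> pd.DataFrame:
    """Per-subject arithmetic mean of dB bin values over accepted blocks.

    Subjects without any accepted block on the channel are simply absent
    (their exclusion is logged by the caller's bookkeeping).
    """
    sel = features[features["channel"] == channel]
    if sel.empty:
        raise ValueError(f"no rows for channel {channel!r}")
    cols = bin_columns(features)
    grouped = sel.groupby(["subject", "cohort"], as_index=False)[cols].mean()
    missing = set(features["subject"].unique()) - set(grouped["subject"])
    if missing:
        log.warning("subjects with no accepted %s-channel blocks excluded: %s",
                    channel, sorted(missing))
    return grouped


def cohort_zscores(features: pd.DataFrame,
                   patient_label: str = PATIENT,
                   control_label: str = CONTROL) -> pd.DataFrame:
    """Welch-type z-score per (channel, bin) over pooled blocks.

    z = (mean_P - mean_C) / sqrt(var_P / n_P + var_C / n_C), with unbiased
    variances and block counts n; blocks are pooled regardless of subject.
    Bins where both cohort variances vanish get ``undefined`` flagged and a
    NaN z.
    """
    cols = bin_columns(features)
    pats = features[features["cohort"] == patient_label]
    ctls = features[features["cohort"] == control_label]
    if pats.empty or ctls.empty:
        raise ValueError("both cohorts must contribute blocks")
    rows = []
    for channel in sorted(features["channel"].unique()):
        p = pats[pats["channel"] == channel][cols].to_numpy()
        c = ctls[ctls["channel"] == channel][cols].to_numpy()
        if p.shape[0] < 2 or c.shape[0] < 2:
            raise ValueError("need at least two blocks per cohort per channel")
        mean_p, mean_c = p.mean(axis=0), c.mean(axis=0)
        var_p, var_c = p.var(axis=0, ddof=1), c.var(axis=0, ddof=1)
        n_p, n_c = p.shape[0], c.shape[0]
        se = np.sqrt(var_p / n_p + var_c / n_c)
        undefined = se == 0
        z = np.where(undefined, np.nan, (mean_p - mean_c) / np.where(undefined, 1.0, se))
        for j, col in enumerate(cols):
            rows.append({
                "channel": channel, "bin": j,
                "mean_p": mean_p[j], "mean_c": mean_c[j],
                "var_p": var_p[j], "var_c": var_c[j],
                "n_p": n_p, "n_c": n_c,
                "z": z[j], "undefined": bool(undefined[j]),
            })
    return pd.DataFrame(rows)


@dataclass
class LooRocResult:
    """Held-out subject scores and the ROC they induce."""

    subjects: np.ndarray
    scores: np.ndarray
    labels: np.ndarray  # 1 = patient
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected AUC (probability a patient outscores a control)."""
    return float(roc_auc_score(labels, scores))


def loo_roc(subject_features: pd.DataFrame | np.ndarray,
            labels: np.ndarray, subjects: np.ndarray | None = None,
            l2_lambda: float = 1.0) -> LooRocResult:
    """Leave-one-subject-out logistic classification with ROC/AUC.

    For each subject, an L2 logistic model (fixed penalty, standardised
    features) is fitted on all other subjects and scores the held-out one;
    AUC is the Mann-Whitney statistic of the held-out scores.
    """
    X = np.asarray(subject_features, dtype=float)
    y = np.asarray([1 if l in (1, True, PATIENT) else 0 for l in np.asarray(labels)])
    if subjects is None:
        subjects = np.arange(len(y))
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    if min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise ValueError("need at least two subjects per class")
    scores = np.empty(len(y), dtype=float)
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        model = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=1.0 / l2_lambda, max_iter=2000),  # L2 penalty
        )
        model.fit(X[mask], y[mask])
        scores[i] = model.decision_function(X[i:i + 1])[0]
    fpr, tpr, _ = roc_curve(y, scores)
    return LooRocResult(np.asarray(subjects), scores, y, fpr, tpr,
                        auc_mann_whitney(scores, y))


def loo_permutation_null(subject_features, labels, n_perm: int = 200,
                         alpha: float = 0.05, seed: int = 0,
                         l2_lambda: float = 1.0) -> tuple[float, float, np.ndarray]:
    """Null distribution of the LOO AUC under label permutation.

    Each permutation reruns the full leave-one-subject-out loop, so the
    band reflects the (pessimistic) bias of held-out scoring under the
    null rather than a band around 0.5 for fixed scores.  Returns
    ``(lo, hi, aucs)`` with the central (1 - alpha) band.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations for a stable band")
    rng = np.random.default_rng(seed)
    y = np.asarray(labels)
    aucs = np.empty(n_perm)
    for i in range(n_perm):
        aucs[i] = loo_roc(subject_features, rng.permutation(y),
                          l2_lambda=l2_lambda).auc
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi), aucs
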