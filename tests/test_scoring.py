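"""Ordinal accelerometer scoring and drug/task effect contrasts."""
import numpy as np
import pandas as pd
import pytest
from scipy.optimize import check_grad
from scipy.stats import spearmanr

from wristpd.scoring import (OVERALL, _fit_penalized, _nll_grad,
                             accelerometer_scores, estimate_task_drug_effects,
                             fit_ordinal_scorer)


def _ordinal_data(n=160, p=4, seed=0, noise=0.0):
    """Labels from thresholding a linear severity in the first feature."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    severity = 2.0 * X[:, 0] + noise * rng.normal(size=n)
    y = np.digitize(severity, [-2.0, -0.7, 0.7, 2.0])  # 5 ordinal levels
    groups = np.arange(n) % 10
    return X, y, groups


class TestOrdinalLikelihood:
    def test_gradient_matches_finite_differences(self):
        X, y, _ = _ordinal_data(n=40, p=3, seed=1, noise=0.5)
        K = len(np.unique(y))
        rng = np.random.default_rng(2)
        x0 = np.concatenate([rng.normal(0, 0.3, 3), [-1.0],
                             np.log(np.full(K - 2, 0.8))])
        err = check_grad(lambda t: _nll_grad(t, X, y, K, 0.5)[0],
                         lambda t: _nll_grad(t, X, y, K, 0.5)[1], x0)
        assert err < 1e-5 * max(1.0, np.abs(_nll_grad(x0, X, y, K, 0.5)[1]).max())

    def test_agreement_with_statsmodels_ordered_model(self):
        """At vanishing penalty the fit coincides with the unpenalised
        proportional-odds maximum likelihood from statsmodels."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        X, y, _ = _ordinal_data(n=200, p=3, seed=3, noise=1.0)
        K = len(np.unique(y))
        w, cut, _ = _fit_penalized(X, y, K, lam=1e-10)
        sm_fit = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=False)
        np.testing.assert_allclose(w, sm_fit.params[:3], atol=2e-2)

    def test_fitted_cutpoints_increasing(self):
        X, y, _ = _ordinal_data(seed=4, noise=1.0)
        w, cut, _ = _fit_penalized(X, y, len(np.unique(y)), lam=0.1)
        assert np.all(np.diff(cut) > 0)


class TestScorer:
    def test_noiseless_recovery_heldout_spearman(self):
        X, y, groups = _ordinal_data(seed=5)
        train = groups < 8
        model = fit_ordinal_scorer(X[train], y[train], groups[train],
                                   lambda_grid=(0.01, 0.1, 1.0))
        rho = spearmanr(accelerometer_scores(model, X[~train]), y[~train]).statistic
        assert rho >= 0.95

    def test_single_level_labels_rejected(self):
        X, y, groups = _ordinal_data()
        with pytest.raises(ValueError):
            fit_ordinal_scorer(X, np.ones_like(y), groups)

    def test_huge_penalty_shrinks_weights_to_zero(self):
        X, y, groups = _ordinal_data(seed=6)
        model = fit_ordinal_scorer(X, y, groups, lambda_grid=(1e7,))
        assert np.linalg.norm(model.weights) < 1e-3
        with pytest.warns(UserWarning):
            scores = accelerometer_scores(model, X)
        assert np.allclose(scores, 0.0)

    def test_permuted_labels_score_at_chance(self):
        X, y, groups = _ordinal_data(seed=7, noise=0.5)
        rng = np.random.default_rng(8)
        y_perm = rng.permutation(y)
        train = groups < 8
        model = fit_ordinal_scorer(X[train], y_perm[train], groups[train],
                                   lambda_grid=(0.1, 1.0))
        scores = accelerometer_scores(model, X[~train])
        rho = spearmanr(scores, y_perm[~train]).statistic
        null = [abs(spearmanr(rng.permutation(scores), y_perm[~train]).statistic)
                for _ in range(200)]
        assert abs(rho) <= np.quantile(null, 0.95) + 0.05

    def test_weight_scale_invariance_of_scores(self):
        X, y, groups = _ordinal_data(seed=9)
        model = fit_ordinal_scorer(X, y, groups, lambda_grid=(0.1,))
        base = accelerometer_scores(model, X)
        model.weights = 2.0 * model.weights
        np.testing.assert_allclose(accelerometer_scores(model, X), base, atol=1e-9)

    def test_feature_mismatch_rejected(self):
        X, y, groups = _ordinal_data()
        model = fit_ordinal_scorer(X, y, groups, lambda_grid=(0.1,))
        with pytest.raises(ValueError):
            accelerometer_scores(model, X[:, :2])


def _score_frame(n_subjects=8, drug_shift=0.0, seed=0, subject_sd=0.5):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        base = rng.normal(0, subject_sd)
        for session in range(1, 5):
            drug = "ON" if session % 2 == 0 else "OFF"
            for task in ("sitting", "walking", "finger-to-nose"):
                score = base + (drug_shift if drug == "ON" else 0.0) + rng.normal(0, 0.3)
                rows.append({"subject": f"S{s}", "session_id": f"S{s}-{session}",
                             "task": task, "drug_state": drug, "score": score})
    return pd.DataFrame(rows)


class TestDrugEffects:
    def test_null_scores_cover_zero(self):
        df = _score_frame(drug_shift=0.0, seed=1)
        eff = estimate_task_drug_effects(df, n_boot=120, seed=0)
        overall = eff[eff["task"] == OVERALL].iloc[0]
        assert overall["ci_low"] <= 0.0 <= overall["ci_high"]

    def test_injected_shift_recovered_with_ci(self):
        df = _score_frame(n_subjects=12, drug_shift=-1.0, seed=2)
        eff = estimate_task_drug_effects(df, n_boot=120, seed=0)
        overall = eff[eff["task"] == OVERALL].iloc[0]
        assert overall["drug_delta"] == pytest.approx(-1.0, abs=0.25)
        assert overall["ci_high"] < 0.0

    def test_swapping_drug_labels_flips_delta(self):
        df = _score_frame(n_subjects=6, drug_shift=-0.8, seed=3)
        eff = estimate_task_drug_effects(df, n_boot=0, seed=0)
        swapped = df.copy()
        swapped["drug_state"] = swapped["drug_state"].map({"ON": "OFF", "OFF": "ON"})
        eff2 = estimate_task_drug_effects(swapped, n_boot=0, seed=0)
        merged = eff.merge(eff2, on="task", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["drug_delta_a"],
                                   -merged["drug_delta_b"], atol=1e-4)

    def test_ols_method_matches_cell_mean_contrast(self):
        """With no random effects the saturated task*drug fit reduces to
        differences of cell means — an exact closed-form oracle."""
        df = _score_frame(n_subjects=5, drug_shift=-0.5, seed=4, subject_sd=0.0)
        eff = estimate_task_drug_effects(df, n_boot=0, seed=0, method="ols")
        cell = df.groupby(["task", "drug_state"])["score"].mean().unstack()
        for _, row in eff[eff["task"] != OVERALL].iterrows():
            expected = cell.loc[row["task"], "ON"] - cell.loc[row["task"], "OFF"]
            assert row["drug_delta"] == pytest.approx(expected, abs=1e-8)

    def test_single_drug_state_task_flagged_missing(self):
        df = _score_frame(n_subjects=4, seed=5)
        extra = df[df["task"] == "sitting"].copy()
        extra["task"] = "lying"
        extra = extra[extra["drug_state"] == "OFF"]
        eff = estimate_task_drug_effects(pd.concat([df, extra]), n_boot=0, seed=0)
        row = eff[eff["task"] == "lying"].iloc[0]
        assert row["missing"] and np.isnan(row["drug_delta"])
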