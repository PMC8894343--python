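"""One-factor FIML CFA: recovery, likelihood, indices, scores."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from sleepcog import factor_scores, fit_cfa, fit_indices, orient_tasks
from sleepcog.cfa import fiml_loglik
from sleepcog.errors import SleepcogError

LAM = np.array([0.8, 0.7, 0.6, 0.5, 0.4])


def one_factor_sample(n, rng, lam=LAM, missing=0.0):
    f = rng.normal(size=n)
    psi = np.sqrt(1 - lam**2)
    X = f[:, None] * lam[None, :] + rng.normal(size=(n, 5)) * psi[None, :]
    if missing:
        X[rng.random((n, 5)) < missing] = np.nan
    return X, f


def exact_model_sample(n, rng, lam=LAM):
    """Data whose sample covariance is exactly the model-implied matrix."""
    sigma0 = np.outer(lam, lam) + np.diag(1 - lam**2)
    X = rng.normal(size=(n, 5))
    X = X - X.mean(axis=0)
    S = X.T @ X / n
    X = X @ np.linalg.inv(np.linalg.cholesky(S)).T @ np.linalg.cholesky(sigma0).T
    return X


class TestFitCfa:
    def test_loading_recovery_complete_data(self, rng):
        X, _ = one_factor_sample(8000, rng)
        model = fit_cfa(X)
        assert np.max(np.abs(model.loadings - LAM)) < 0.04

    def test_loading_recovery_under_mcar_missingness(self, rng):
        X, _ = one_factor_sample(8000, rng, missing=0.1)
        model = fit_cfa(X)
        assert np.max(np.abs(model.loadings - LAM)) < 0.05

    def test_fiml_equals_complete_data_gaussian_loglik(self, rng):
        X, _ = one_factor_sample(2000, rng)
        model = fit_cfa(X)
        Z = (X - model.col_means) / model.col_sds
        direct = multivariate_normal(
            mean=model.intercepts, cov=model.implied_covariance()).logpdf(Z).sum()
        assert fiml_loglik(model, X) == pytest.approx(direct, abs=1e-6)

    def test_likelihood_not_worse_than_start(self, rng):
        X, _ = one_factor_sample(1000, rng)
        model = fit_cfa(X)
        sigma_start = np.outer(np.full(5, 0.5), np.full(5, 0.5)) + np.diag(np.full(5, 0.5))
        mu = np.nanmean((X - model.col_means) / model.col_sds, axis=0)
        start_ll = multivariate_normal(mean=mu, cov=sigma_start).logpdf(
            (X - model.col_means) / model.col_sds).sum()
        assert model.loglik >= start_ll

    def test_requires_variance_and_enough_rows(self, rng):
        X = np.tile([1.0, 2, 3, 4, 5], (100, 1))
        with pytest.raises(SleepcogError):
            fit_cfa(X)
        with pytest.raises(SleepcogError):
            fit_cfa(rng.normal(size=(20, 5)))


class TestFitIndices:
    def test_exactly_fitting_model_gives_cfi_one_rmsea_zero(self, rng):
        X = exact_model_sample(3000, rng)
        model = fit_cfa(X)
        fit = fit_indices(model, X)
        assert fit["cfi"] == pytest.approx(1.0, abs=1e-6)
        assert fit["rmsea"] == pytest.approx(0.0, abs=1e-6)
        assert fit["srmr"] < 1e-5

    def test_well_specified_model_fits_well(self, rng):
        X, _ = one_factor_sample(20_000, rng)
        model = fit_cfa(X)
        fit = fit_indices(model, X)
        assert fit["cfi"] > 0.99
        assert fit["rmsea"] < 0.01
        assert fit["srmr"] < 0.02

    def test_independent_data_model_chi2_tracks_baseline_chi2(self, rng):
        # with true loadings 0 the factor adds nothing: the model chi-square
        # sits within a chi2_5 improvement of the baseline chi-square
        X = rng.normal(size=(5000, 5))
        model = fit_cfa(X)
        fit = fit_indices(model, X)
        assert fit["chi2_baseline"] - fit["chi2_model"] < 21  # chi2_5 99.9th pct
        assert fit["chi2_baseline"] < 30  # baseline itself not rejected

    def test_reference_implementation_agreement(self, rng, tmp_path):
        """Cross-check loadings and chi-squares against R's factanal ML fit."""
        X, _ = one_factor_sample(2000, rng)
        csv = tmp_path / "tasks.csv"
        pd.DataFrame(X, columns=list("abcde")).to_csv(csv, index=False)
        rscript = shutil.which("Rscript")
        assert rscript, "Rscript is required for the reference CFA oracle"
        code = (
            'd <- read.csv(commandArgs(trailingOnly=TRUE)[1]); n <- nrow(d);'
            'fa <- factanal(d, factors=1, rotation="none");'
            'R <- cor(d);'
            'cat(jsonlite::toJSON(list(loadings=as.numeric(fa$loadings),'
            ' chisq_m=n*fa$criteria[["objective"]], chisq_b=-n*log(det(R))),'
            ' digits=12))'
        )
        out = subprocess.run([rscript, "-e", code, str(csv)],
                             capture_output=True, text=True, check=True)
        ref = json.loads(out.stdout)
        model = fit_cfa(X)
        fit = fit_indices(model, X)
        assert np.max(np.abs(np.abs(model.loadings) - np.abs(ref["loadings"]))) < 0.02
        assert fit["chi2_model"] == pytest.approx(ref["chisq_m"][0], abs=0.2)
        # indices recomputed from the reference chi-squares
        c_m, c_b = ref["chisq_m"][0], ref["chisq_b"][0]
        cfi_ref = 1 - max(0, c_m - 5) / max(c_m - 5, c_b - 10, 1e-12)
        rmsea_ref = np.sqrt(max(0.0, c_m - 5) / (5 * (len(X) - 1)))
        assert fit["cfi"] == pytest.approx(min(1.0, cfi_ref), abs=0.005)
        assert fit["rmsea"] == pytest.approx(rmsea_ref, abs=0.005)


class TestFactorScores:
    def test_scores_standardized(self, rng):
        X, _ = one_factor_sample(3000, rng, missing=0.1)
        model = fit_cfa(X)
        s = factor_scores(model, X)
        ok = np.isfinite(s)
        assert np.nanmean(s[ok]) == pytest.approx(0.0, abs=1e-8)
        assert np.nanstd(s[ok]) == pytest.approx(1.0, abs=1e-8)

    def test_scores_track_generating_latent(self, rng):
        X, f = one_factor_sample(20_000, rng)
        model = fit_cfa(X)
        s = factor_scores(model, X)
        assert np.corrcoef(s, f)[0, 1] > 0.85

    def test_rows_with_all_tasks_missing_get_nan(self, rng):
        X, _ = one_factor_sample(500, rng)
        X[3] = np.nan
        model = fit_cfa(X)
        s = factor_scores(model, X)
        assert np.isnan(s[3]) and np.isfinite(np.delete(s, 3)).all()

    def test_monotone_in_positively_loaded_tasks(self, rng):
        X, _ = one_factor_sample(2000, rng)
        model = fit_cfa(X)
        base = X.copy()
        for j in range(5):
            bumped = base.copy()
            bumped[:, j] += 1.0
            assert (factor_scores(model, np.vstack([base, bumped]))[len(base):]
                    >= factor_scores(model, np.vstack([base, bumped]))[:len(base)]).all()

    def test_mcar_scores_match_complete_scores(self, rng):
        X, _ = one_factor_sample(10_000, rng)
        model_c = fit_cfa(X)
        s_complete = factor_scores(model_c, X)
        Xm = X.copy()
        Xm[rng.random(Xm.shape) < 0.1] = np.nan
        model_m = fit_cfa(Xm)
        s_mcar = factor_scores(model_m, Xm)
        # rows whose observed set is complete score from the same data
        full = np.isfinite(Xm).all(axis=1)
        assert np.corrcoef(s_mcar[full], s_complete[full])[0, 1] > 0.99


def test_orientation_negates_error_and_time_columns(small_cohort):
    from sleepcog import transform_cognitive
    ph, _, _ = small_cohort
    tr = transform_cognitive(ph)
    orn = orient_tasks(tr)
    assert np.allclose(orn["task_pairs_errors"].dropna(),
                       -tr["task_pairs_errors"].dropna())
    assert np.allclose(orn["task_tower_accuracy"].dropna(),
                       tr["task_tower_accuracy"].dropna())
    with pytest.raises(SleepcogError):
        orient_tasks(orn)
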