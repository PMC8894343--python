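"""One-factor confirmatory factor analysis with full-information ML.

Fits the measurement model

    x_i = mu + lambda * f_i + e_i,   f_i ~ N(0, 1),  e_i ~ N(0, diag(psi))

to the five transformed cognitive task scores, where rows may have missing
entries. The likelihood is the casewise (pattern-wise) Gaussian likelihood
over each row's observed subset -- full-information maximum likelihood
(FIML) -- which is consistent under missing-at-random data without
imputation. Identification fixes the factor variance at 1 so all five
loadings are free and reported.

Rows are grouped by missingness pattern and summarized by pattern-wise
sufficient statistics (count, mean, scatter), so one likelihood/gradient
evaluation costs O(2^p) matrix operations regardless of n; the optimizer is
L-BFGS-B on a log parameterization of the residual variances with analytic
gradients and fixed starting values for determinism.

Fit indices (CFI, TLI, RMSEA, SRMR) compare the model chi-square against a
saturated model -- estimated by EM for the unstructured Gaussian under
missingness -- and an independence baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import ConvergenceError, SleepcogError
from .simulate import TASK_COLUMNS

logger = logging.getLogger(__name__)

#: tasks where a higher raw (transformed) value means worse performance;
#: these are negated before fitting so higher always means better.
WORSE_DIRECTION_COLUMNS = ["task_pairs_errors", "task_trail_diff", "task_reaction_time"]

_LOGPSI_FLOOR = np.log(1e-4)
_LOG2PI = np.log(2 * np.pi)


def orient_tasks(table: pd.DataFrame) -> pd.DataFrame:
    """Negate error/time task columns so higher score = better performance.

    Deterministic orientation applied after the skew transforms and before
    CFA; stamps the ``tasks_oriented`` provenance flag.
    """
    if table.attrs.get("tasks_oriented"):
        raise SleepcogError("tasks already oriented (provenance flag 'tasks_oriented')")
    out = table.copy()
    for col in WORSE_DIRECTION_COLUMNS:
        if col in out.columns:
            out[col] = -out[col].to_numpy(dtype=float)
    out.attrs = dict(table.attrs)
    out.attrs["tasks_oriented"] = True
    return out


@dataclass
class FactorModel:
    """Fitted one-factor model on the standardized task scale."""

    loadings: np.ndarray
    residual_variances: np.ndarray
    intercepts: np.ndarray
    loglik: float
    n_used: int
    columns: list[str]
    col_means: np.ndarray
    col_sds: np.ndarray
    factor_variance: float = 1.0
    fit: dict = field(default_factory=dict)
    converged: bool = True
    grad_max: float = np.nan
    n_iter: int = 0
    heywood: bool = False

    def implied_covariance(self) -> np.ndarray:
        lam = self.loadings
        return np.outer(lam, lam) + np.diag(self.residual_variances)


def _as_task_matrix(tasks, columns=None):
    if isinstance(tasks, pd.DataFrame):
        cols = columns or [c for c in TASK_COLUMNS if c in tasks.columns]
        if len(cols) != 5:
            cols = list(tasks.columns)
        X = tasks[cols].to_numpy(dtype=float)
        return X, list(cols)
    X = np.asarray(tasks, dtype=float)
    return X, [f"task_{j}" for j in range(X.shape[1])]


def _pattern_stats(X: np.ndarray):
    """Group rows by missingness pattern -> list of (obs_idx, n, mean, scatter).

    ``scatter`` is the MLE (divide-by-n) covariance of the pattern's rows
    over its observed columns; rows with no observed entries are dropped.
    """
    obs = np.isfinite(X)
    keep = obs.any(axis=1)
    X, obs = X[keep], obs[keep]
    codes = obs @ (1 << np.arange(X.shape[1]))
    patterns = []
    for code in np.unique(codes):
        rows = X[codes == code]
        o = np.flatnonzero(obs[codes == code][0])
        sub = rows[:, o]
        mean = sub.mean(axis=0)
        dev = sub - mean
        scatter = dev.T @ dev / len(sub)
        patterns.append((o, len(sub), mean, scatter))
    return patterns, int(keep.sum())


def _neg_loglik_grad(params, patterns, n_total, p):
    lam = params[:p]
    psi = np.exp(params[p:2 * p])
    mu = params[2 * p:]
    sigma = np.outer(lam, lam) + np.diag(psi)

    ll = 0.0
    G = np.zeros((p, p))
    gmu = np.zeros(p)
    for o, n_p, xbar, S in patterns:
        sub = sigma[np.ix_(o, o)]
        sign, logdet = np.linalg.slogdet(sub)
        if sign <= 0:
            return np.inf, np.zeros_like(params)
        A = np.linalg.inv(sub)
        d = xbar - mu[o]
        W = S + np.outer(d, d)
        ll += -0.5 * n_p * (len(o) * _LOG2PI + logdet + np.trace(A @ W))
        Gp = 0.5 * n_p * (A @ W @ A - A)
        G[np.ix_(o, o)] += Gp
        gmu[o] += n_p * (A @ d)

    grad_lam = 2.0 * G @ lam
    grad_logpsi = np.diag(G) * psi
    grad = np.concatenate([grad_lam, grad_logpsi, gmu])
    return -ll / n_total, -grad / n_total


def fit_cfa(tasks, standardize: bool = True, tol: float = 1e-6,
            max_iter: int = 500) -> FactorModel:
    """Fit the one-factor FIML model.

    Parameters
    ----------
    tasks : DataFrame or (n, 5) array
        Transformed, oriented task scores; NaN marks missing cells.
    standardize : bool
        Z-score each column on its observed cells before fitting (default),
        so loadings are on the standardized metric.
    tol : float
        Convergence tolerance on the max-norm of the mean log-likelihood
        gradient.
    """
    X, cols = _as_task_matrix(tasks)
    p = X.shape[1]
    obs_any = np.isfinite(X).any(axis=1)
    if obs_any.sum() < 50:
        raise SleepcogError("fit_cfa requires >= 50 rows with observed tasks")
    col_means = np.nanmean(X, axis=0)
    col_sds = np.nanstd(X, axis=0)
    if np.any(col_sds <= 0) or not np.all(np.isfinite(col_sds)):
        raise SleepcogError("every task needs nonzero variance")
    Z = (X - col_means) / col_sds if standardize else X.copy()
    if not standardize:
        col_means, col_sds = np.zeros(p), np.ones(p)

    patterns, n_used = _pattern_stats(Z)

    start_mu = np.array([np.nanmean(Z[:, j]) for j in range(p)])
    x0 = np.concatenate([np.full(p, 0.5), np.full(p, np.log(0.5)), start_mu])
    bounds = [(None, None)] * p + [(_LOGPSI_FLOOR, None)] * p + [(None, None)] * p
    trace: list[float] = []

    res = minimize(
        _neg_loglik_grad, x0, args=(patterns, n_used, p),
        method="L-BFGS-B", jac=True, bounds=bounds,
        callback=lambda xk: trace.append(
            float(_neg_loglik_grad(xk, patterns, n_used, p)[0])),
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-12},
    )
    _, grad = _neg_loglik_grad(res.x, patterns, n_used, p)
    grad_max = float(np.max(np.abs(grad)))
    if not np.isfinite(grad_max) or grad_max > tol:
        raise ConvergenceError(
            f"FIML optimizer did not converge (max|grad| = {grad_max:.3g} > {tol:g})",
            trace=trace,
        )

    lam = res.x[:p].copy()
    psi = np.exp(res.x[p:2 * p])
    mu = res.x[2 * p:].copy()
    if lam.sum() < 0:  # deterministic global sign
        lam = -lam
    heywood = bool(np.any(res.x[p:2 * p] <= _LOGPSI_FLOOR + 1e-9))
    if heywood:
        logger.warning("Heywood case: residual variance at floor %.1e", np.exp(_LOGPSI_FLOOR))

    ll = -res.fun * n_used
    return FactorModel(
        loadings=lam, residual_variances=psi, intercepts=mu,
        loglik=float(ll), n_used=n_used, columns=cols,
        col_means=col_means, col_sds=col_sds,
        converged=True, grad_max=grad_max, n_iter=int(res.nit), heywood=heywood,
    )


def fiml_loglik(model: FactorModel, tasks) -> float:
    """Casewise Gaussian log-likelihood of ``tasks`` at the model's parameters."""
    X, _ = _as_task_matrix(tasks, model.columns)
    Z = (X - model.col_means) / model.col_sds
    patterns, _ = _pattern_stats(Z)
    sigma = model.implied_covariance()
    mu = model.intercepts
    ll = 0.0
    for o, n_p, xbar, S in patterns:
        sub = sigma[np.ix_(o, o)]
        _, logdet = np.linalg.slogdet(sub)
        A = np.linalg.inv(sub)
        d = xbar - mu[o]
        ll += -0.5 * n_p * (len(o) * _LOG2PI + logdet
                            + np.trace(A @ S) + d @ A @ d)
    return float(ll)


def _pattern_loglik(patterns, mu, sigma):
    ll = 0.0
    for o, n_p, xbar, S in patterns:
        sub = sigma[np.ix_(o, o)]
        _, logdet = np.linalg.slogdet(sub)
        A = np.linalg.inv(sub)
        d = xbar - mu[o]
        ll += -0.5 * n_p * (len(o) * _LOG2PI + logdet + np.trace(A @ S) + d @ A @ d)
    return ll


def _saturated_em(patterns, n, p, tol=1e-10, max_iter=1000):
    """EM for the unstructured Gaussian (mu, Sigma) under missingness."""
    mu = np.zeros(p)
    diag = np.zeros(p)
    counts = np.zeros(p)
    for o, n_p, xbar, S in patterns:
        mu[o] += n_p * xbar
        diag[o] += n_p * (np.diag(S) + xbar**2)
        counts[o] += n_p
    mu = mu / np.maximum(counts, 1)
    sigma = np.diag(np.maximum(diag / np.maximum(counts, 1) - mu**2, 1e-8))

    ll_old = -np.inf
    for _ in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        for o, n_p, xbar, S in patterns:
            mset = np.setdiff1d(np.arange(p), o)
            dbar = xbar - mu[o]
            sum_x[o] += n_p * xbar
            sum_xx[np.ix_(o, o)] += n_p * (S + np.outer(xbar, xbar))
            if len(mset):
                A = np.linalg.inv(sigma[np.ix_(o, o)])
                B = sigma[np.ix_(mset, o)] @ A
                C = sigma[np.ix_(mset, mset)] - B @ sigma[np.ix_(o, mset)]
                bd = B @ dbar
                sum_x[mset] += n_p * (mu[mset] + bd)
                # X_o' Xhat_m = n (xbar mu_m' + (S + xbar dbar') B')
                om = n_p * (np.outer(xbar, mu[mset])
                            + (S + np.outer(xbar, dbar)) @ B.T)
                sum_xx[np.ix_(o, mset)] += om
                sum_xx[np.ix_(mset, o)] += om.T
                # Xhat_m' Xhat_m + n C
                dtd = S + np.outer(dbar, dbar)
                sum_xx[np.ix_(mset, mset)] += n_p * (
                    np.outer(mu[mset], mu[mset])
                    + np.outer(mu[mset], bd) + np.outer(bd, mu[mset])
                    + B @ dtd @ B.T + C
                )
        mu_new = sum_x / n
        sigma_new = sum_xx / n - np.outer(mu_new, mu_new)
        sigma_new = (sigma_new + sigma_new.T) / 2
        mu, sigma = mu_new, sigma_new
        ll = _pattern_loglik(patterns, mu, sigma)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1):
            break
        ll_old = ll
    return mu, sigma, _pattern_loglik(patterns, mu, sigma)


def _baseline_fit(patterns, n, p):
    """Independence baseline: free means and variances, zero covariances."""
    mu = np.zeros(p)
    m2 = np.zeros(p)
    counts = np.zeros(p)
    for o, n_p, xbar, S in patterns:
        mu[o] += n_p * xbar
        m2[o] += n_p * (np.diag(S) + xbar**2)
        counts[o] += n_p
    mu = mu / counts
    var = m2 / counts - mu**2
    return mu, np.diag(var), _pattern_loglik(patterns, mu, np.diag(var))


def fit_indices(model: FactorModel, tasks) -> dict:
    """CFI, TLI, RMSEA and SRMR for the fitted model on the same rows.

    chi2_model = 2(ll_saturated - ll_model); the saturated model is the
    unstructured Gaussian estimated by EM, the baseline is the independence
    model. CFI/TLI are clamped to [0, 1].
    """
    X, _ = _as_task_matrix(tasks, model.columns)
    Z = (X - model.col_means) / model.col_sds
    patterns, n = _pattern_stats(Z)
    p = Z.shape[1]

    _, S_sat, ll_sat = _saturated_em(patterns, n, p)
    _, _, ll_base = _baseline_fit(patterns, n, p)
    ll_model = _pattern_loglik(patterns, model.intercepts, model.implied_covariance())

    n_moments = p * (p + 3) // 2
    df_m = n_moments - 3 * p
    df_b = n_moments - 2 * p
    chi2_m = max(0.0, 2.0 * (ll_sat - ll_model))
    chi2_b = max(0.0, 2.0 * (ll_sat - ll_base))

    num = max(0.0, chi2_m - df_m)
    den = max(chi2_m - df_m, chi2_b - df_b, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    if df_b <= 1:
        tli = np.nan
    else:
        denom = chi2_b / df_b - 1.0
        tli = np.nan if denom == 0 else (chi2_b / df_b - chi2_m / df_m) / denom
        tli = float(np.clip(tli, 0.0, 1.0))
    cfi = float(np.clip(cfi, 0.0, 1.0))
    rmsea = float(np.sqrt(max(0.0, chi2_m - df_m) / (df_m * (n - 1))))

    d = np.sqrt(np.diag(S_sat))
    denom_mat = np.outer(d, d)
    resid = S_sat / denom_mat - model.implied_covariance() / denom_mat
    tri = np.tril_indices(p)
    srmr = float(np.sqrt(np.mean(resid[tri] ** 2)))

    fit = {"cfi": cfi, "tli": tli, "rmsea": rmsea, "srmr": srmr,
           "chi2_model": chi2_m, "df_model": df_m,
           "chi2_baseline": chi2_b, "df_baseline": df_b, "n": n}
    model.fit = fit
    return fit


def factor_scores(model: FactorModel, tasks) -> np.ndarray:
    """Regression-method (Thomson) factor scores, standardized to z-scores.

    Each row's score uses its observed subset: E[f | x_o] =
    lambda_o' Sigma_oo^{-1} (x_o - mu_o). Rows with all five tasks missing
    get NaN. Output has mean 0, SD 1 over scored rows.
    """
    X, _ = _as_task_matrix(tasks, model.columns)
    Z = (X - model.col_means) / model.col_sds
    sigma = model.implied_covariance()
    lam, mu = model.loadings, model.intercepts
    obs = np.isfinite(Z)
    codes = obs @ (1 << np.arange(Z.shape[1]))
    scores = np.full(len(Z), np.nan)
    for code in np.unique(codes):
        if code == 0:
            continue
        rows = codes == code
        o = np.flatnonzero(obs[rows][0])
        w = np.linalg.solve(sigma[np.ix_(o, o)], lam[o])
        scores[rows] = (Z[np.ix_(rows, o)] - mu[o]) @ w
    ok = np.isfinite(scores)
    scores[ok] = (scores[ok] - scores[ok].mean()) / scores[ok].std()
    return scores
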