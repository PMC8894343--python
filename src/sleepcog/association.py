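"""Sleep-band regression on executive function, variance comparison, VIF.

The key exposure is a binary indicator for sleeping six-to-eight hours
inclusive (the optimum of seven plus one hour either side for
self-reporting bias). EF is regressed on that band plus age, sleep
characteristics (chronotype as two dummies against the intermediate
baseline, insomnia, daytime sleepiness, snoring), smoking pack-years,
vascular comorbidity count, APOE e4 dose, BMI and the Townsend
socioeconomic index -- ordinary least squares with classical standard
errors, multicollinearity checked by variance inflation factors. Age
sub-groups are compared with a two-sample F-test for equal variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import RankDeficiencyError, SleepcogError

#: term order mirrors the published regression table
REGRESSION_TERMS = [
    "intercept", "age", "sleep_band", "chronotype_morning", "chronotype_evening",
    "insomnia", "daytime_sleepiness", "snoring", "pack_years",
    "vascular_comorbidity", "apoe_e4_dose", "bmi", "townsend",
]


@dataclass
class RegressionReport:
    table: pd.DataFrame  # term, beta, se, t, p, vif
    n_used: int

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.set_index("term").loc[term]


def sleep_band_indicator(sleep, low: float = 6, high: float = 8):
    """1 iff low <= sleep <= high (inclusive); missing stays missing."""
    s = np.asarray(sleep, dtype=float)
    out = np.where((s >= low) & (s <= high), 1.0, 0.0)
    out[~np.isfinite(s)] = np.nan
    return out


def build_design(table: pd.DataFrame, ef, band_low: float = 6,
                 band_high: float = 8) -> pd.DataFrame:
    """Complete-case design matrix in published term order, plus the EF column."""
    chron = table["chronotype"].astype(str)
    design = pd.DataFrame(
        {
            "intercept": 1.0,
            "age": table["age"].astype(float),
            "sleep_band": sleep_band_indicator(table["sleep_hours"], band_low, band_high),
            "chronotype_morning": (chron == "morning").astype(float),
            "chronotype_evening": (chron == "evening").astype(float),
            "insomnia": table["insomnia"].astype(float),
            "daytime_sleepiness": table["daytime_sleepiness"].astype(float),
            "snoring": table["snoring"].astype(float),
            "pack_years": table["pack_years"].astype(float),
            "vascular_comorbidity": table["vascular_comorbidity"].astype(float),
            "apoe_e4_dose": table["apoe_e4_dose"].astype(float),
            "bmi": table["bmi"].astype(float),
            "townsend": table["townsend"].astype(float),
        },
        index=table.index,
    )
    design["ef"] = np.asarray(ef, dtype=float)
    return design.dropna()


def fit_ef_regression(ef, table: pd.DataFrame, band_low: float = 6,
                      band_high: float = 8) -> RegressionReport:
    """OLS of EF on the sleep band and covariates, classical SEs, VIFs."""
    design = build_design(table, ef, band_low, band_high)
    X = design[REGRESSION_TERMS].to_numpy()
    y = design["ef"].to_numpy()
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _find_aliased(X, REGRESSION_TERMS)
        raise RankDeficiencyError(
            f"design matrix rank deficient; aliased terms: {aliased}", aliased)

    res = sm.OLS(y, X).fit()
    vifs = vif(X[:, 1:])  # exclude intercept from VIF reporting
    out = pd.DataFrame(
        {
            "term": REGRESSION_TERMS,
            "beta": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
            "vif": [np.nan] + list(vifs),
        }
    )
    return RegressionReport(table=out, n_used=int(res.nobs))


def _find_aliased(X: np.ndarray, names) -> list[str]:
    aliased = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ beta
        scale = np.linalg.norm(X[:, j]) or 1.0
        if np.linalg.norm(resid) / scale < 1e-10:
            aliased.append(names[j])
    return aliased


def vif(X) -> np.ndarray:
    """Variance inflation factor per predictor column.

    VIF_j = 1 / (1 - R^2_j), R^2_j from regressing column j on the other
    columns plus an intercept. Perfect collinearity reports inf.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        tss = np.sum((yj - yj.mean()) ** 2)
        if tss == 0:
            out[j] = np.nan
            continue
        r2 = 1.0 - resid @ resid / tss
        out[j] = np.inf if r2 >= 1.0 - 1e-14 else 1.0 / (1.0 - r2)
    return out


def variance_ratio_test(a, b, alpha: float = 0.05):
    """Two-sample F-test for equal variances: F = var(a)/var(b).

    Returns (F, (ci_low, ci_high), p) with the CI from F-distribution
    quantiles on (n_a - 1, n_b - 1) degrees of freedom and a two-sided p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise SleepcogError("each group needs >= 2 values")
    vb = b.var(ddof=1)
    if vb == 0:
        raise SleepcogError("zero variance in the denominator group")
    F = a.var(ddof=1) / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    dist = stats.f(dfa, dfb)
    p = 2.0 * min(dist.cdf(F), dist.sf(F))
    p = min(p, 1.0)
    ci = (F / dist.ppf(1 - alpha / 2), F / dist.ppf(alpha / 2))
    return F, ci, p
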