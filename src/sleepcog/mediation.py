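"""Bootstrap mediation and the sleep-effect / EF-effect region comparison.

The mediation model asks whether the association between the 6-8 h sleep
band (x) and executive function (y) runs through the summary volume of the
sleep-related brain regions (m):

    a : OLS slope of m ~ x            (exposure -> mediator)
    b : slope of m in y ~ x + m       (mediator -> outcome, adjusted)
    c : OLS slope of y ~ x            (total effect)
    c': slope of x in y ~ x + m       (direct effect)

The indirect effect is a*b (= c - c' exactly in the linear model); its
uncertainty comes from nonparametric case-resampling bootstrap with a
percentile interval. The module also regresses EF on each region's volume
separately (Bonferroni-corrected) and compares, across regions, the
percent volume difference of the sleep band with the strength of the
volume -> EF association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SleepcogError


@dataclass
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    ab: float
    ab_ci95: tuple[float, float]
    ab_p: float
    n_boot: int
    n_used: int


@dataclass
class EffectMapComparison:
    betas_ef: pd.Series           # per-region EF ~ z-volume slope
    percent_diffs: pd.Series      # per-region band vs other % difference
    r_squared: float
    overlap_count: int
    significant_ef_regions: set
    significant_sleep_regions: set


def _paths_from_sums(n, sx, sm, sy, sxx, sxm, sxy, smm, smy):
    """Closed-form OLS paths from (possibly per-replicate) moment sums."""
    mx, mm_, my = sx / n, sm / n, sy / n
    cxx = sxx / n - mx**2
    cxm = sxm / n - mx * mm_
    cxy = sxy / n - mx * my
    cmm = smm / n - mm_**2
    cmy = smy / n - mm_ * my
    a = cxm / cxx
    det = cmm * cxx - cxm**2
    b = (cmy * cxx - cxy * cxm) / det
    c_prime = (cxy * cmm - cmy * cxm) / det
    c = cxy / cxx
    return a, b, c, c_prime


def fit_mediation(x, m, y, n_boot: int = 1000, seed: int | None = 0) -> MediationResult:
    """Point estimates plus case-resampling bootstrap for the indirect effect.

    The percentile 95% interval and the two-sided bootstrap p
    (2 * min(P(ab* <= 0), P(ab* >= 0))) come from ``n_boot`` resamples of
    complete (x, m, y) triples. Point estimates are deterministic; only the
    interval depends on the bootstrap seed.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(m) & np.isfinite(y)
    x, m, y = x[ok], m[ok], y[ok]
    n = len(x)
    if n < 50:
        raise SleepcogError("fit_mediation needs >= 50 complete triples")
    if np.var(x) == 0:
        raise SleepcogError("zero variance in x (all one group)")

    a, b, c, c_prime = _paths_from_sums(
        n, x.sum(), m.sum(), y.sum(), (x * x).sum(), (x * m).sum(),
        (x * y).sum(), (m * m).sum(), (m * y).sum())
    ab = a * b

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, mb, yb = x[idx], m[idx], y[idx]
    ab_boot = []
    a_r, b_r, _, _ = _paths_from_sums(
        n, xb.sum(1), mb.sum(1), yb.sum(1), (xb * xb).sum(1), (xb * mb).sum(1),
        (xb * yb).sum(1), (mb * mb).sum(1), (mb * yb).sum(1))
    ab_boot = a_r * b_r
    lo, hi = np.percentile(ab_boot, [2.5, 97.5])
    p = 2.0 * min(np.mean(ab_boot <= 0), np.mean(ab_boot >= 0))
    return MediationResult(
        a=float(a), b=float(b), c=float(c), c_prime=float(c_prime),
        ab=float(ab), ab_ci95=(float(lo), float(hi)), ab_p=float(min(p, 1.0)),
        n_boot=n_boot, n_used=n,
    )


def region_ef_association(volumes: pd.DataFrame, ef, alpha: float = 0.05):
    """Per-region OLS of EF on the z-scored region volume, Bonferroni over regions.

    Returns (betas, pvals, significant_ids); zero-variance regions are
    excluded.
    """
    ef = np.asarray(ef, dtype=float)
    ok = np.isfinite(ef)
    X = volumes.to_numpy(dtype=float)[ok]
    ef = ef[ok]
    n = len(ef)
    sds = X.std(axis=0)
    usable = sds > 0
    Z = (X[:, usable] - X[:, usable].mean(axis=0)) / sds[usable]
    efc = ef - ef.mean()
    beta = Z.T @ efc / (Z**2).sum(axis=0)
    resid_ss = (efc**2).sum() - beta**2 * (Z**2).sum(axis=0)
    se = np.sqrt(resid_ss / (n - 2) / (Z**2).sum(axis=0))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    ids = np.asarray(volumes.columns)[usable]
    m = len(ids)
    significant = set(ids[p <= alpha / m])
    betas = pd.Series(beta, index=ids, name="beta_ef")
    pvals = pd.Series(p, index=ids, name="p")
    return betas, pvals, significant


def overlap_and_correlation(percent_diffs: pd.Series, betas_ef: pd.Series,
                            significant_sleep: set, significant_ef: set) -> EffectMapComparison:
    """Region-set overlap and the % difference vs EF-beta correlation.

    ``r_squared`` is the squared Pearson correlation between the per-region
    percent volume differences and the per-region EF betas across all
    regions present in both inputs (aligned on region_id).
    """
    common = percent_diffs.index.intersection(betas_ef.index)
    if len(common) < 3:
        raise SleepcogError("need >= 3 aligned regions for a correlation")
    x = percent_diffs.loc[common].to_numpy(dtype=float)
    y = betas_ef.loc[common].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    r = np.corrcoef(x[ok], y[ok])[0, 1]
    overlap = set(significant_sleep) & set(significant_ef)
    return EffectMapComparison(
        betas_ef=betas_ef, percent_diffs=percent_diffs,
        r_squared=float(r**2), overlap_count=len(overlap),
        significant_ef_regions=set(significant_ef),
        significant_sleep_regions=set(significant_sleep),
    )
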