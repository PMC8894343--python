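"""Region-wise permutation inference on grey-matter volumes.

Compares the 6-8 h sleep group against other durations per region with a
Welch two-sample t statistic whose null distribution is built by label
permutation: the same shuffle sequence is applied to every region per
permutation index (preserving cross-region dependence in the null), and
the p-value uses the add-one rule p = (k + 1)/(n_perm + 1) where k counts
permutations with |t| >= |t_observed|. When the total number of label
arrangements is small the null is enumerated exhaustively instead of
sampled. Multiple comparisons are Bonferroni-corrected (0.05/140 for the
139 regions plus WMH in the published configuration).
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import SleepcogError

logger = logging.getLogger(__name__)

ENUMERATION_LIMIT = 20_000
_PERM_CHUNK = 256


def bonferroni_threshold(alpha: float = 0.05, m: int = 140) -> float:
    """Corrected per-test threshold alpha / m."""
    if m < 1:
        raise SleepcogError("m must be >= 1")
    return alpha / m


def percent_difference(mean_band, mean_other):
    """100 * (band - other) / mean-of-means; NaN when the average is zero."""
    mean_band = np.asarray(mean_band, dtype=float)
    mean_other = np.asarray(mean_other, dtype=float)
    avg = (mean_band + mean_other) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (mean_band - mean_other) / avg
    out = np.where(avg == 0, np.nan, out)
    return out if out.ndim else float(out)


def welch_t(x1_sum, x1_sqsum, n1, x2_sum, x2_sqsum, n2):
    """Welch t from group sums/sum-of-squares (vectorized)."""
    m1 = x1_sum / n1
    m2 = x2_sum / n2
    v1 = (x1_sqsum - n1 * m1**2) / (n1 - 1)
    v2 = (x2_sqsum - n2 * m2**2) / (n2 - 1)
    denom = np.sqrt(np.clip(v1 / n1 + v2 / n2, 1e-300, None))
    return (m1 - m2) / denom


def permutation_region_test(volumes, in_band, n_perm: int = 1000,
                            seed: int | None = 0, alpha: float = 0.05,
                            n_comparisons: int | None = None,
                            method: str = "auto",
                            mean_offsets=None) -> pd.DataFrame:
    """Permutation Welch t-test of band vs other, per region column.

    Parameters
    ----------
    volumes : DataFrame (n x m) or array
        Confound-regressed volumes, one column per region.
    in_band : boolean array
        True for the 6-8 h sleep group.
    n_perm : int
        Number of sampled label shuffles (ignored on the exhaustive path).
    method : {"auto", "exhaustive", "sampling"}
        "auto" enumerates all label arrangements when there are at most
        20,000 of them.
    mean_offsets : array of m, optional
        Added to both group means before the percent-difference computation
        (used to restore the original volume scale after residualization);
        the t statistic is shift-invariant so it is unaffected.

    Returns a DataFrame with region_id, t_observed, p_perm, percent_diff,
    significant (p <= alpha / n_comparisons) and n_perm.
    """
    if isinstance(volumes, pd.DataFrame):
        ids = list(volumes.columns)
        V = volumes.to_numpy(dtype=float)
    else:
        V = np.asarray(volumes, dtype=float)
        if V.ndim == 1:
            V = V[:, None]
        ids = [f"region_{j}" for j in range(V.shape[1])]
    labels = np.asarray(in_band, dtype=bool)
    n, m = V.shape
    n1 = int(labels.sum())
    n2 = n - n1
    if n1 < 2 or n2 < 2:
        raise SleepcogError("both groups need >= 2 members")
    if n_perm < 100:
        logger.warning("n_perm = %d is very small; p-values will be coarse", n_perm)
    if n_comparisons is None:
        n_comparisons = m + 1  # convention: region set plus the WMH contrast
    threshold = bonferroni_threshold(alpha, n_comparisons)

    V2 = V**2
    tot_s = V.sum(axis=0)
    tot_ss = V2.sum(axis=0)
    s1 = V[labels].sum(axis=0)
    ss1 = V2[labels].sum(axis=0)
    t_obs = welch_t(s1, ss1, n1, tot_s - s1, tot_ss - ss1, n2)

    n_arrangements = math.comb(n, n1)
    use_exhaustive = (method == "exhaustive"
                      or (method == "auto" and n_arrangements <= ENUMERATION_LIMIT))
    if use_exhaustive:
        count = np.zeros(m, dtype=int)
        for idx in combinations(range(n), n1):
            sel = np.asarray(idx)
            cs = V[sel].sum(axis=0)
            css = V2[sel].sum(axis=0)
            t = welch_t(cs, css, n1, tot_s - cs, tot_ss - css, n2)
            count += np.abs(t) >= np.abs(t_obs) - 1e-12
        p = count / n_arrangements
        n_perm_used = n_arrangements
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(m, dtype=int)
        done = 0
        while done < n_perm:
            chunk = min(_PERM_CHUNK, n_perm - done)
            # same shuffle per permutation index across every region
            L = np.zeros((chunk, n))
            for r in range(chunk):
                L[r, rng.permutation(n)[:n1]] = 1.0
            cs = L @ V
            css = L @ V2
            t = welch_t(cs, css, n1, tot_s - cs, tot_ss - css, n2)
            count += (np.abs(t) >= np.abs(t_obs)[None, :] - 1e-12).sum(axis=0)
            done += chunk
        p = (count + 1) / (n_perm + 1)
        n_perm_used = n_perm

    offs = np.zeros(m) if mean_offsets is None else np.asarray(mean_offsets, dtype=float)
    pdiff = percent_difference(s1 / n1 + offs, (tot_s - s1) / n2 + offs)
    return pd.DataFrame(
        {
            "region_id": ids,
            "t_observed": t_obs,
            "p_perm": p,
            "percent_diff": np.atleast_1d(pdiff),
            "significant": p <= threshold,
            "n_perm": n_perm_used,
        }
    )


def split_contrasts(volumes, sleep, n_perm: int = 1000, seed: int | None = 0,
                    alpha: float = 0.05, n_comparisons: int | None = None,
                    band: tuple[float, float] = (6, 8),
                    mean_offsets=None) -> dict[str, pd.DataFrame | None]:
    """Band vs short (<6 h) and band vs long (>8 h) permutation contrasts.

    Runs ``permutation_region_test`` on the two sub-cohorts separately with
    the same Bonferroni correction; an empty short or long group yields
    None for that contrast (with a warning).
    """
    sleep = np.asarray(sleep, dtype=float)
    lo, hi = band
    in_band = (sleep >= lo) & (sleep <= hi)
    out: dict[str, pd.DataFrame | None] = {}
    for name, other in (("short", sleep < lo), ("long", sleep > hi)):
        if other.sum() < 2:
            logger.warning("%s-sleep group too small; contrast skipped", name)
            out[name] = None
            continue
        sel = in_band | other
        sub = volumes[sel] if isinstance(volumes, pd.DataFrame) else volumes[sel]
        out[name] = permutation_region_test(
            sub, in_band[sel], n_perm=n_perm, seed=seed, alpha=alpha,
            n_comparisons=n_comparisons, mean_offsets=mean_offsets,
        )
    return out


def summary_volume(volumes: pd.DataFrame, significant_region_ids) -> np.ndarray:
    """Per-participant average of z-scored significant-region volumes.

    Zero-variance regions are excluded with a warning; at least one usable
    region is required.
    """
    ids = [r for r in significant_region_ids if r in volumes.columns]
    if not ids:
        raise SleepcogError("summary_volume needs >= 1 significant region")
    X = volumes[ids].to_numpy(dtype=float)
    sds = X.std(axis=0)
    usable = sds > 0
    if not usable.all():
        logger.warning("%d zero-variance regions excluded from summary volume",
                       int((~usable).sum()))
    if not usable.any():
        raise SleepcogError("all candidate regions have zero variance")
    X = X[:, usable]
    z = (X - X.mean(axis=0)) / X.std(axis=0)
    return z.mean(axis=1)
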