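"""Age deconfounding and conditional visual summaries.

Age is by far the strongest confounder of executive function, so EF is
expressed relative to peers of matched age: participants are cut into
fixed-width age-quantile bins (default 20%) and each person's residual is
their EF minus their own bin's mean. The module also provides the
sliding-quantile-window conditional curve (EF or sleep vs age) and the
smoothed sleep x age heatmap grid used for the cohort-level visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SleepcogError

AGE_SPLIT_YEARS = 60  # younger 38-59 vs older 60-73 sub-groups


@dataclass
class ResidualSeries:
    residual: np.ndarray
    bin_id: np.ndarray
    bin_edges: np.ndarray


@dataclass
class SlidingWindowCurve:
    window_centers: np.ndarray
    smoothed_mean: np.ndarray
    standard_error: np.ndarray
    window_quantile_width: float
    raw_mean: np.ndarray


def quantile_age_residuals(ef, age, bin_fraction: float = 0.2) -> ResidualSeries:
    """EF residuals within fixed-width age-quantile bins.

    Bins are defined by rank cut-points at multiples of ``bin_fraction``;
    ties at a bin edge are resolved by stable input order (integer ages
    guarantee heavy ties). Residual = EF minus the mean EF of the
    participant's own bin, so within-bin (and grand) residual means are 0.
    """
    ef = np.asarray(ef, dtype=float)
    age = np.asarray(age, dtype=float)
    if not 0 < bin_fraction <= 1:
        raise SleepcogError("bin_fraction must be in (0, 1]")
    n = len(age)
    nbins = int(round(1.0 / bin_fraction))
    order = np.argsort(age, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    # rank cut-points at multiples of bin_fraction: bin b covers ranks
    # [floor(b n / nbins), floor((b+1) n / nbins))
    cuts = (np.arange(1, nbins + 1) * n) // nbins
    bin_id = np.searchsorted(cuts, ranks, side="right")
    counts = np.bincount(bin_id, minlength=nbins)
    if np.any(counts < 2):
        raise SleepcogError(
            f"age bin with < 2 members (counts {counts.tolist()}); use a larger bin_fraction"
        )
    residual = ef.copy()
    for b in range(nbins):
        sel = bin_id == b
        m = np.nanmean(ef[sel])
        residual[sel] = ef[sel] - m
    edges = np.concatenate(
        [[age[order[0]]],
         [age[order[np.searchsorted(bin_id[order], b)]] for b in range(1, nbins)],
         [age[order[-1]]]]
    )
    return ResidualSeries(residual=residual, bin_id=bin_id, bin_edges=edges)


def sliding_window_curve(x, y, quantile_width: float = 0.2,
                         kernel_width: float = 5.0,
                         n_windows: int = 100) -> SlidingWindowCurve:
    """Conditional mean of y along x using sliding quantile windows.

    Window k covers the [q_k, q_k + width] quantile slice of x, with q_k
    equally spaced; per-window means are smoothed across windows with a
    unit-mass Gaussian kernel (SD = ``kernel_width`` windows, truncated at
    +-3 SD and renormalized at the edges). Makes no linearity assumption.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < n_windows:
        raise SleepcogError("need at least n_windows observations")
    if not 0 < quantile_width < 1:
        raise SleepcogError("quantile_width must be in (0, 1)")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    starts = np.linspace(0.0, 1.0 - quantile_width, n_windows)
    centers, means, ses = [], [], []
    prev = (-1, -1)
    for q in starts:
        i0 = int(np.floor(q * n))
        i1 = max(i0 + 1, int(np.floor((q + quantile_width) * n)))
        i1 = min(i1, n)
        if (i0, i1) == prev:  # identical membership -> duplicate window
            continue
        prev = (i0, i1)
        w_y = ys[i0:i1]
        centers.append(xs[i0:i1].mean())
        means.append(w_y.mean())
        ses.append(w_y.std(ddof=1) / np.sqrt(len(w_y)) if len(w_y) > 1 else 0.0)
    centers = np.asarray(centers)
    means = np.asarray(means)
    ses = np.asarray(ses)

    half = int(np.ceil(3 * kernel_width))
    offsets = np.arange(-half, half + 1)
    kern = np.exp(-0.5 * (offsets / kernel_width) ** 2)
    smoothed = np.empty_like(means)
    for i in range(len(means)):
        lo = max(0, i - half)
        hi = min(len(means), i + half + 1)
        w = kern[(lo - i) + half:(hi - i) + half]
        smoothed[i] = (means[lo:hi] * w).sum() / w.sum()
    return SlidingWindowCurve(
        window_centers=centers, smoothed_mean=smoothed, standard_error=ses,
        window_quantile_width=quantile_width, raw_mean=means,
    )


def heatmap_grid(sleep, age, ef):
    """Smoothed EF surface over (sleep hour, age year).

    Cell (s, a) averages EF over participants with sleep in [s-1, s+1] and
    age in [a-2, a+2]; empty cells are NaN. Returns (values, counts) as
    DataFrames indexed by sleep hour 1-12 with one column per age year.
    """
    sleep = np.asarray(sleep, dtype=float)
    age = np.asarray(age, dtype=float)
    ef = np.asarray(ef, dtype=float)
    ok = np.isfinite(sleep) & np.isfinite(age) & np.isfinite(ef)
    sleep, age, ef = sleep[ok], age[ok], ef[ok]
    sleep_axis = np.arange(1, 13)
    if len(age):
        # extend by the 2-year smoothing radius so edge neighbourhoods appear
        age_axis = np.arange(int(np.floor(age.min())) - 2, int(np.ceil(age.max())) + 3)
    else:
        age_axis = np.arange(0)
    values = np.full((len(sleep_axis), len(age_axis)), np.nan)
    counts = np.zeros((len(sleep_axis), len(age_axis)), dtype=int)
    for i, s in enumerate(sleep_axis):
        in_s = np.abs(sleep - s) <= 1
        if not in_s.any():
            continue
        a_sel = age[in_s]
        e_sel = ef[in_s]
        for j, a in enumerate(age_axis):
            cell = np.abs(a_sel - a) <= 2
            c = int(cell.sum())
            counts[i, j] = c
            if c:
                values[i, j] = e_sel[cell].mean()
    idx = pd.Index(sleep_axis, name="sleep_hours")
    cols = pd.Index(age_axis, name="age")
    return (pd.DataFrame(values, index=idx, columns=cols),
            pd.DataFrame(counts, index=idx, columns=cols))


def profile_by_sleep(residual, sleep) -> pd.DataFrame:
    """Mean age-residual EF (with SE) at each discrete sleep duration."""
    residual = np.asarray(residual, dtype=float)
    sleep = np.asarray(sleep)
    rows = []
    for s in np.arange(1, 13):
        sel = (sleep == s) & np.isfinite(residual)
        n = int(sel.sum())
        if n == 0:
            rows.append((s, np.nan, np.nan, 0))
            continue
        vals = residual[sel]
        se = vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        rows.append((s, vals.mean(), se, n))
    return pd.DataFrame(rows, columns=["sleep_hours", "mean_ef_residual", "se", "n"])
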