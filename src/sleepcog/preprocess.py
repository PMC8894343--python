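"""Variable transforms, outlier exclusion and imaging confound regression.

The cognitive transforms correct heavily skewed raw task distributions
before latent-factor modelling: reaction time and the trail-making B-A
difference are natural-log transformed, pairs-matching errors are cube-root
transformed. White-matter-hyperintensity volume is log transformed.
Imaging-derived phenotypes are residualized on a standard confound set
(age, age^2, head-size scaling, scanner table position, scan date) with an
ordinary least squares fit per volume column.

Each transform stamps a provenance flag in ``DataFrame.attrs`` so that a
double application is rejected rather than silently compounding.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import RankDeficiencyError, SleepcogError

logger = logging.getLogger(__name__)

LOG_COLUMNS = ["task_trail_diff", "task_reaction_time"]
CBRT_COLUMNS = ["task_pairs_errors"]
CONFOUND_COLUMNS = ["conf_age", "conf_head_size", "conf_table_position", "conf_scan_date"]


def _require_flag_absent(table: pd.DataFrame, flag: str, what: str) -> None:
    if table.attrs.get(flag):
        raise SleepcogError(f"{what} already applied to this table (provenance flag '{flag}')")


def transform_cognitive(table: pd.DataFrame) -> pd.DataFrame:
    """Skew-correcting transforms of the raw cognitive task columns.

    Log columns with non-positive values after the shift policy are set
    missing per cell (counted in ``attrs['transform_warnings']``). The
    trail-making difference may legitimately be <= 0 (fast alphanumeric
    performers); the whole column is then shifted by (1 - min) before the
    log and the shift recorded in ``attrs['trail_shift']``.
    """
    _require_flag_absent(table, "cognitive_transformed", "cognitive transform")
    out = table.copy()
    warnings = {}

    trail = out["task_trail_diff"].to_numpy(dtype=float, copy=True)
    finite = np.isfinite(trail)
    shift = 0.0
    if finite.any() and np.nanmin(trail[finite]) <= 0:
        shift = 1.0 - np.nanmin(trail[finite])
        trail = trail + shift
        logger.warning("trail-making difference shifted by %+.6g before log", shift)
    bad = finite & (trail <= 0)
    if bad.any():
        warnings["task_trail_diff_nonpositive"] = int(bad.sum())
        trail[bad] = np.nan
    with np.errstate(invalid="ignore"):
        out["task_trail_diff"] = np.log(trail)

    rt = out["task_reaction_time"].to_numpy(dtype=float, copy=True)
    bad = np.isfinite(rt) & (rt <= 0)
    if bad.any():
        warnings["task_reaction_time_nonpositive"] = int(bad.sum())
        logger.warning("%d non-positive reaction times set missing", bad.sum())
        rt[bad] = np.nan
    with np.errstate(invalid="ignore"):
        out["task_reaction_time"] = np.log(rt)

    out["task_pairs_errors"] = np.cbrt(out["task_pairs_errors"].to_numpy(dtype=float))

    out.attrs = dict(table.attrs)
    out.attrs["cognitive_transformed"] = True
    out.attrs["trail_shift"] = shift
    out.attrs["transform_warnings"] = warnings
    return out


def mad_outlier_mask(values, k: float = 5.0) -> np.ndarray:
    """Boolean mask flagging |x - median| > k * scaled MAD.

    The MAD (median absolute deviation from the median) is scaled by 1.4826
    so that k counts approximate standard deviations under normality.
    Missing entries are never flagged. When the MAD is zero the mask falls
    back to flagging values unequal to the median (if any exist; a constant
    vector yields no flags, with a logged warning).
    """
    x = np.asarray(values, dtype=float)
    obs = np.isfinite(x)
    if obs.sum() < 3:
        raise SleepcogError("mad_outlier_mask requires >= 3 non-missing values")
    med = np.median(x[obs])
    absdev = np.abs(x[obs] - med)
    mad = np.median(absdev) * 1.4826
    mask = np.zeros_like(x, dtype=bool)
    if mad == 0:
        logger.warning("MAD is zero; falling back to flagging values unequal to the median")
        if np.isfinite(k):
            mask[obs] = x[obs] != med
    else:
        mask[obs] = absdev > k * mad
    return mask


def _volume_columns(imaging: pd.DataFrame) -> list[str]:
    skip = {"participant_id", *CONFOUND_COLUMNS}
    return [c for c in imaging.columns if c not in skip]


def regress_confounds(imaging: pd.DataFrame) -> pd.DataFrame:
    """Residualize every volume column on the imaging confound set.

    Fits, per column, OLS on [1, age, age^2, head size, table position,
    scan date] and replaces the column by its residuals (massively
    univariate, the usual IDP convention). Rows with a missing confound are
    dropped (complete-case) and tallied in ``attrs['confound_exclusions']``.
    """
    _require_flag_absent(imaging, "confound_regressed", "confound regression")
    out = imaging.copy()
    conf = out[CONFOUND_COLUMNS].to_numpy(dtype=float)
    complete = np.isfinite(conf).all(axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.warning("%d rows with missing confounds excluded from imaging analyses", n_excluded)
        out = out.loc[complete].reset_index(drop=True)
        conf = conf[complete]

    age = conf[:, 0] - conf[:, 0].mean()
    design = np.column_stack(
        [np.ones(len(out)), age, age**2, conf[:, 1], conf[:, 2], conf[:, 3]]
    )
    names = ["intercept", "age", "age_sq", "head_size", "table_position", "scan_date"]
    if len(out) < design.shape[1] + 2:
        raise SleepcogError("too few complete rows for confound regression")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        aliased = _aliased_columns(design, names)
        raise RankDeficiencyError(
            f"confound matrix rank deficient; collinear columns: {aliased}", aliased
        )

    cols = _volume_columns(out)
    y = out[cols].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    # columns with missing cells get a complete-case fit of their own
    for j, col in enumerate(cols):
        if np.isnan(y[:, j]).any():
            obs = np.isfinite(y[:, j])
            bj, *_ = np.linalg.lstsq(design[obs], y[obs, j], rcond=None)
            resid[:, j] = y[:, j] - design @ bj
    out[cols] = resid

    out.attrs = dict(imaging.attrs)
    out.attrs["confound_regressed"] = True
    out.attrs["confound_exclusions"] = n_excluded
    # pre-residualization column means, kept so percent differences can be
    # expressed on the original volume scale downstream
    out.attrs["volume_column_means"] = {c: float(np.nanmean(y[:, j]))
                                        for j, c in enumerate(cols)}
    return out


def _aliased_columns(design: np.ndarray, names: list[str]) -> list[str]:
    aliased = []
    for j in range(design.shape[1]):
        others = np.delete(design, j, axis=1)
        resid = design[:, j] - others @ np.linalg.lstsq(others, design[:, j], rcond=None)[0]
        scale = np.linalg.norm(design[:, j]) or 1.0
        if np.linalg.norm(resid) / scale < 1e-10:
            aliased.append(names[j])
    return aliased


def log_wmh(imaging: pd.DataFrame) -> pd.DataFrame:
    """Natural-log transform of white-matter-hyperintensity volume.

    Non-positive WMH rows are excluded from WMH analyses: the cell is set
    missing and the count recorded in ``attrs['wmh_exclusions']``.
    """
    _require_flag_absent(imaging, "wmh_logged", "WMH log transform")
    out = imaging.copy()
    w = out["wmh_volume"].to_numpy(dtype=float, copy=True)
    bad = np.isfinite(w) & (w <= 0)
    if bad.any():
        logger.warning("%d non-positive WMH volumes set missing", bad.sum())
        w[bad] = np.nan
    with np.errstate(invalid="ignore"):
        out["wmh_volume"] = np.log(w)
    out.attrs = dict(imaging.attrs)
    out.attrs["wmh_logged"] = True
    out.attrs["wmh_exclusions"] = int(bad.sum())
    return out
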