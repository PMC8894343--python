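"""End-to-end orchestration: simulate/load -> preprocess -> CFA -> residualize
-> associate -> volumetrics -> mediation, with a machine-readable bundle.

Every stage writes its artifact into the output directory and the manifest
records seeds, versions, row counts and exclusion tallies, so that an
identical (config, seed) pair reproduces a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .age_adjust import (AGE_SPLIT_YEARS, heatmap_grid, profile_by_sleep,
                         quantile_age_residuals, sliding_window_curve)
from .association import fit_ef_regression, sleep_band_indicator, variance_ratio_test
from .atlas import load_atlas_registry
from .cfa import factor_scores, fit_cfa, fit_indices, orient_tasks
from .errors import ConfigurationError, SchemaError
from .mediation import fit_mediation, overlap_and_correlation, region_ef_association
from .preprocess import (CONFOUND_COLUMNS, log_wmh, mad_outlier_mask,
                         regress_confounds, transform_cognitive)
from .simulate import TASK_COLUMNS, SimulationConfig, generate_cohort
from .volumetrics import (bonferroni_threshold, permutation_region_test,
                          split_contrasts, summary_volume)

logger = logging.getLogger(__name__)

REQUIRED_PHENOTYPE_COLUMNS = [
    "participant_id", "age", "sleep_hours", *TASK_COLUMNS,
    "chronotype", "insomnia", "snoring", "daytime_sleepiness",
    "vascular_comorbidity", "bmi", "pack_years", "apoe_e4_dose", "townsend",
]
_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Single document controlling a full run.

    ``n_perm`` defaults to 5000: with the add-one permutation p-value the
    smallest achievable p is 1/(n_perm + 1), which must undercut the
    Bonferroni threshold alpha/140 for any region to be callable.
    """

    mode: str = "simulate"  # "simulate" or "tables"
    seed: int = 0
    outdir: str = "sleepcog_out"
    phenotype_path: str | None = None
    imaging_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    bin_fraction: float = 0.2
    n_windows: int = 100
    window_width: float = 0.2
    kernel_width: float = 5.0
    n_perm: int = 5000
    n_boot: int = 1000
    alpha: float = 0.05
    n_comparisons: int | None = None   # default: n_regions + 1 (WMH)
    band_low: float = 6.0
    band_high: float = 8.0
    age_split: float = AGE_SPLIT_YEARS
    mad_k: float = 5.0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("simulate", "tables"):
            raise ConfigurationError("mode must be 'simulate' or 'tables'")
        if self.mode == "tables" and not (self.phenotype_path and self.imaging_path):
            raise ConfigurationError("tables mode requires phenotype_path and imaging_path")
        if not 0 < self.bin_fraction <= 1:
            raise ConfigurationError("bin_fraction must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.band_low > self.band_high:
            raise ConfigurationError("band_low must be <= band_high")
        if self.n_perm < 1 or self.n_boot < 1:
            raise ConfigurationError("n_perm and n_boot must be >= 1")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        sim = doc.pop("simulation", {})
        analysis = doc.pop("analysis", {})
        tables = doc.pop("tables", {})
        kwargs = {**doc, **analysis}
        if "phenotype" in tables:
            kwargs["phenotype_path"] = tables["phenotype"]
        if "imaging" in tables:
            kwargs["imaging_path"] = tables["imaging"]
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**kwargs)
        if sim:
            cfg.simulation = SimulationConfig(**sim)
        cfg.simulation.seed = cfg.seed
        return cfg


def _check_phenotype_schema(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_PHENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"phenotype table missing columns: {missing}")
    s = table["sleep_hours"].dropna()
    frac = s.to_numpy(dtype=float) % 1
    bad = np.flatnonzero(frac != 0)
    if len(bad):
        raise SchemaError(
            f"sleep_hours must be whole hours; first offending row {int(bad[0])}")


def _check_imaging_schema(table: pd.DataFrame) -> list[str]:
    missing = [c for c in ("participant_id", "wmh_volume", *CONFOUND_COLUMNS)
               if c not in table.columns]
    if missing:
        raise SchemaError(f"imaging table missing columns: {missing}")
    region_cols = [c for c in table.columns
                   if c not in ("participant_id", "wmh_volume", *CONFOUND_COLUMNS)]
    if not region_cols:
        raise SchemaError("imaging table has no region volume columns")
    return region_cols


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=True) + "\n")


def _tsv(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the results bundle; returns the results."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "stages": {},
        "exclusions": {},
    }

    # --- stage: input
    if config.mode == "simulate":
        config.simulation.seed = config.seed
        phenotype, imaging, truth = generate_cohort(config.simulation)
        results["ground_truth"] = truth
        (outdir / "ground_truth.json").write_text(truth.to_json())
    else:
        phenotype = pd.read_csv(config.phenotype_path, sep="\t")
        imaging = pd.read_csv(config.imaging_path, sep="\t")
        truth = None
    _check_phenotype_schema(phenotype)
    region_cols = _check_imaging_schema(imaging)
    manifest["stages"]["input"] = {
        "phenotype_rows": int(len(phenotype)),
        "imaging_rows": int(len(imaging)),
        "n_regions": len(region_cols),
    }

    # --- stage: cognitive preprocessing + CFA
    transformed = transform_cognitive(phenotype)
    oriented = orient_tasks(transformed)
    model = fit_cfa(oriented[TASK_COLUMNS])
    fit = fit_indices(model, oriented[TASK_COLUMNS])
    ef = factor_scores(model, oriented[TASK_COLUMNS])
    results["factor_model"] = model
    _json_dump(
        {
            "loadings": dict(zip(model.columns, np.round(model.loadings, 10))),
            "residual_variances": dict(zip(model.columns, np.round(model.residual_variances, 10))),
            "intercepts": dict(zip(model.columns, np.round(model.intercepts, 10))),
            "loglik": round(model.loglik, 6),
            "n_used": model.n_used,
            "fit": {k: (None if isinstance(v, float) and np.isnan(v) else round(float(v), 8))
                    for k, v in fit.items()},
        },
        outdir / "factor_model.json",
    )
    manifest["stages"]["cfa"] = {"n_used": model.n_used,
                                 "n_unscored": int(np.isnan(ef).sum())}
    manifest["exclusions"]["cfa_all_tasks_missing"] = int(np.isnan(ef).sum())

    # --- stage: age residualization + conditional summaries
    age = phenotype["age"].to_numpy(dtype=float)
    sleep = phenotype["sleep_hours"].to_numpy(dtype=float)
    resid = quantile_age_residuals(ef, age, config.bin_fraction)
    scores = pd.DataFrame(
        {"participant_id": phenotype["participant_id"], "ef": ef,
         "ef_age_residual": resid.residual, "age_bin": resid.bin_id}
    )
    _tsv(scores, outdir / "ef_scores.tsv")

    curve_ef = sliding_window_curve(age, ef, config.window_width,
                                    config.kernel_width, config.n_windows)
    curve_sleep = sliding_window_curve(age, sleep, config.window_width,
                                       config.kernel_width, config.n_windows)
    for name, curve in (("age_ef_curve", curve_ef), ("age_sleep_curve", curve_sleep)):
        _tsv(pd.DataFrame({
            "window_center": curve.window_centers,
            "smoothed_mean": curve.smoothed_mean,
            "standard_error": curve.standard_error,
        }), outdir / f"{name}.tsv")

    grid, grid_counts = heatmap_grid(sleep, age, ef)
    _tsv(grid, outdir / "heatmap_ef.tsv", index=True)
    _tsv(grid_counts, outdir / "heatmap_counts.tsv", index=True)

    profile = profile_by_sleep(resid.residual, sleep)
    young = age < config.age_split
    profiles = {"all": profile,
                "younger": profile_by_sleep(resid.residual[young], sleep[young]),
                "older": profile_by_sleep(resid.residual[~young], sleep[~young])}
    prof_out = pd.concat(
        [p.assign(group=g) for g, p in profiles.items()], ignore_index=True)
    _tsv(prof_out, outdir / "ef_sleep_profile.tsv")
    results["profile"] = profile
    peak_hour = int(profile.loc[profile["mean_ef_residual"].idxmax(), "sleep_hours"])
    results["peak_sleep_hour"] = peak_hour

    ok = np.isfinite(resid.residual)
    F, ci, p_f = variance_ratio_test(resid.residual[young & ok], resid.residual[~young & ok])
    results["variance_ratio"] = (F, ci, p_f)
    _json_dump({"F": F, "ci95": list(ci), "p": p_f,
                "n_younger": int((young & ok).sum()), "n_older": int((~young & ok).sum())},
               outdir / "variance_test.json")
    manifest["stages"]["age_residuals"] = {"peak_sleep_hour": peak_hour,
                                           "n_scored": int(ok.sum())}

    # --- stage: EF regression (published table structure)
    report = fit_ef_regression(ef, phenotype, config.band_low, config.band_high)
    results["regression"] = report
    _tsv(report.table, outdir / "ef_regression.tsv")
    manifest["stages"]["regression"] = {"n_used": report.n_used}
    manifest["exclusions"]["regression_incomplete_covariates"] = int(len(phenotype) - report.n_used)

    # --- stage: imaging preprocessing
    merged = imaging.merge(
        phenotype[["participant_id", "sleep_hours"]], on="participant_id", how="inner")
    ef_by_id = pd.Series(ef, index=phenotype["participant_id"])
    merged["_ef"] = ef_by_id.reindex(merged["participant_id"]).to_numpy()

    img = merged[["participant_id", *region_cols, "wmh_volume",
                  *CONFOUND_COLUMNS]].copy()
    img = log_wmh(img)
    n_wmh_bad = img.attrs["wmh_exclusions"]
    manifest["exclusions"]["nonpositive_wmh"] = n_wmh_bad

    mad_flags = np.zeros(len(img), dtype=bool)
    for col in [*region_cols, "wmh_volume"]:
        mad_flags |= mad_outlier_mask(img[col].to_numpy(dtype=float), config.mad_k)
    n_mad = int(mad_flags.sum())
    attrs = dict(img.attrs)
    img = img.loc[~mad_flags].reset_index(drop=True)
    img.attrs = attrs
    manifest["exclusions"]["mad_outliers"] = n_mad

    deconf = regress_confounds(img)
    manifest["exclusions"]["missing_confounds"] = deconf.attrs["confound_exclusions"]
    col_means = deconf.attrs["volume_column_means"]
    attrs = dict(deconf.attrs)
    deconf = deconf.merge(
        merged.loc[~mad_flags, ["participant_id", "sleep_hours", "_ef"]],
        on="participant_id", how="left")
    deconf.attrs = attrs
    manifest["stages"]["imaging_preprocess"] = {"rows_analyzed": int(len(deconf))}

    # --- stage: permutation volumetrics
    sleep_img = deconf["sleep_hours"].to_numpy(dtype=float)
    in_band = (sleep_img >= config.band_low) & (sleep_img <= config.band_high)
    n_comp = config.n_comparisons or (len(region_cols) + 1)
    offsets = np.array([col_means[c] for c in region_cols])
    region_results = permutation_region_test(
        deconf[region_cols], in_band, n_perm=config.n_perm,
        seed=config.seed + 1, alpha=config.alpha, n_comparisons=n_comp,
        mean_offsets=offsets)
    registry = load_atlas_registry()
    region_results = region_results.merge(registry, on="region_id", how="left")
    _tsv(region_results, outdir / "region_results.tsv")
    sig_ids = region_results.loc[region_results["significant"], "region_id"].tolist()
    results["region_results"] = region_results
    results["significant_regions"] = sig_ids

    wmh_ok = np.isfinite(deconf["wmh_volume"].to_numpy(dtype=float))
    wmh_res = permutation_region_test(
        deconf.loc[wmh_ok, ["wmh_volume"]], in_band[wmh_ok], n_perm=config.n_perm,
        seed=config.seed + 2, alpha=config.alpha, n_comparisons=n_comp,
        mean_offsets=np.array([col_means["wmh_volume"]]))
    results["wmh_contrast"] = wmh_res
    _json_dump(
        {"t": float(wmh_res["t_observed"][0]), "p_perm": float(wmh_res["p_perm"][0]),
         "significant": bool(wmh_res["significant"][0]),
         "band_mean_log_wmh_lower": bool(wmh_res["t_observed"][0] < 0)},
        outdir / "wmh_contrast.json")

    splits = split_contrasts(
        deconf[region_cols], sleep_img, n_perm=config.n_perm, seed=config.seed + 3,
        alpha=config.alpha, n_comparisons=n_comp,
        band=(config.band_low, config.band_high), mean_offsets=offsets)
    for name, df in splits.items():
        if df is not None:
            _tsv(df, outdir / f"split_contrast_{name}.tsv")
    results["split_contrasts"] = splits
    manifest["stages"]["volumetrics"] = {
        "n_perm": config.n_perm,
        "bonferroni_threshold": bonferroni_threshold(config.alpha, n_comp),
        "n_significant_regions": len(sig_ids),
        "wmh_significant": bool(wmh_res["significant"][0]),
    }

    # --- stage: mediation + overlap
    ef_img = deconf["_ef"].to_numpy(dtype=float)
    betas, pvals, sig_ef = region_ef_association(deconf[region_cols], ef_img,
                                                 alpha=config.alpha)
    pdiffs = region_results.set_index("region_id")["percent_diff"]
    comparison = overlap_and_correlation(pdiffs, betas, set(sig_ids), sig_ef)
    results["effect_map"] = comparison
    effect_map = pd.DataFrame({
        "region_id": betas.index,
        "beta_ef": betas.to_numpy(),
        "p_ef": pvals.to_numpy(),
        "percent_diff": pdiffs.reindex(betas.index).to_numpy(),
        "significant_ef": [r in sig_ef for r in betas.index],
        "significant_sleep": [r in set(sig_ids) for r in betas.index],
    })
    _tsv(effect_map, outdir / "effect_map.tsv")
    _json_dump({"overlap_count": comparison.overlap_count,
                "r_squared": round(comparison.r_squared, 8),
                "n_significant_sleep": len(sig_ids),
                "n_significant_ef": len(sig_ef)},
               outdir / "overlap.json")

    if sig_ids:
        msum = summary_volume(deconf[region_cols], sig_ids)
        trip_ok = np.isfinite(ef_img)
        mstd = (msum - msum.mean()) / msum.std()
        ystd = ef_img.copy()
        ystd[trip_ok] = (ef_img[trip_ok] - ef_img[trip_ok].mean()) / ef_img[trip_ok].std()
        med = fit_mediation(in_band.astype(float), mstd, ystd,
                            n_boot=config.n_boot, seed=config.seed + 4)
        results["mediation"] = med
        _json_dump(
            {"status": "ok", "a": med.a, "b": med.b, "c": med.c,
             "c_prime": med.c_prime, "ab": med.ab, "ab_ci95": list(med.ab_ci95),
             "ab_p": med.ab_p, "n_boot": med.n_boot, "n_used": med.n_used},
            outdir / "mediation.json")
    else:
        logger.warning("no Bonferroni-significant regions; mediation skipped")
        results["mediation"] = None
        _json_dump({"status": "skipped", "reason": "no significant regions"},
                   outdir / "mediation.json")

    manifest["stages"]["mediation"] = {
        "ran": bool(sig_ids), "overlap_count": comparison.overlap_count,
        "r_squared": round(comparison.r_squared, 8),
    }
    manifest["row_accounting"] = {
        "imaging_input_rows": int(len(imaging)),
        "imaging_analyzed_rows": int(len(deconf)),
        "imaging_excluded_rows": int(len(imaging) - len(deconf)),
    }
    manifest["config"] = _config_dict(config)
    _json_dump(manifest, outdir / "manifest.json")
    results["manifest"] = manifest
    return results


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    sim = d["simulation"]
    for key, val in sim.items():
        if isinstance(val, np.ndarray):
            sim[key] = val.tolist()
    if isinstance(sim.get("age_range"), tuple):
        sim["age_range"] = list(sim["age_range"])
    return d
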