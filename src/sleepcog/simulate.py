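"""Synthetic cohort generator.

Produces a phenotype table and an imaging table with the statistical
structure the downstream stages assume, together with the ground-truth
parameters used to generate them, so that every stage of the analysis
(latent-factor estimation, age residualization, permutation volumetrics,
mediation) can be exercised against known answers.

What the generator emulates, at the population level:

* integer self-reported sleep durations (1-12 h) with median 7;
* integer ages 38-73 with a linear decline of executive function (EF);
* a one-factor measurement model over five cognitive tasks -- the latent
  EF enters every task only through its loading;
* an inverted-U (quadratic, peak at 7 h) effect of sleep duration on EF
  and on a configurable subset of regional volumes;
* an asymmetric, long-sleep-only volume deficit in a second subset of
  regions (volume falls linearly beyond 8 h);
* additive imaging confounds (age, age^2, head-size scaling, scanner
  table position, scan date) on every regional volume;
* a per-person "structural integrity" factor that couples EF with the
  affected regions' volumes, so that mediation has a true indirect path;
* white-matter-hyperintensity volume, lognormal with a minimum near 8 h;
* missing-completely-at-random cognitive cells.

All draws flow from a single seed via deterministic sub-streams, so a
given (seed, config) reproduces tables bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import region_ids
from .errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort",
    "write_cohort",
    "make_mediation_data",
    "DEFAULT_SLEEP_PROBS",
    "TASK_COLUMNS",
]

# P(sleep = h), h = 1..12. Centered on 7 h with median 7, thin tails at the
# extremes; the 6-8 h band carries ~78% of the mass.
DEFAULT_SLEEP_PROBS = np.array(
    [0.002, 0.003, 0.005, 0.020, 0.060, 0.190, 0.340, 0.250,
     0.080, 0.030, 0.012, 0.008]
)

TASK_COLUMNS = [
    "task_pairs_errors",
    "task_trail_diff",
    "task_tower_accuracy",
    "task_reaction_time",
    "task_symbol_digit",
]

# Order in which the latent loadings apply to the five tasks.
_TASK_ORDER = [
    "task_pairs_errors",
    "task_trail_diff",
    "task_tower_accuracy",
    "task_reaction_time",
    "task_symbol_digit",
]

# Mapping from the linear (transformed, higher-is-better) task scale t to the
# raw observable. "neg" tasks are scored so that higher raw value = worse.
#   pairs errors: raw = (off - sc*t)^3            (cube-root transform inverts)
#   trail diff:   raw = exp(off - sc*t) seconds   (log inverts)
#   reaction t.:  raw = exp(off - sc*t) ms        (log inverts)
#   tower/symbol: raw = off + sc*t counts         (identity)
_RAW_MAPS = {
    "task_pairs_errors": ("cube_neg", 2.2, 0.3),
    "task_trail_diff": ("exp_neg", 3.0, 0.25),
    "task_reaction_time": ("exp_neg", 6.3, 0.1),
    "task_tower_accuracy": ("linear", 7.0, 1.5),
    "task_symbol_digit": ("linear", 19.0, 4.0),
}

# Category probabilities for the covariates (frequencies of the source cohort).
_CHRONOTYPE_PROBS = {"intermediate": 0.640, "morning": 0.271, "evening": 0.089}
_INSOMNIA_PROBS = np.array([0.242, 0.478, 0.280])
_SNORING_PROBS = np.array([0.627, 0.373])           # no / yes
_SLEEPINESS_PROBS = np.array([0.763, 0.210, 0.027])  # no / sometimes / often
_VASCULAR_PROBS = np.array([0.70, 0.25, 0.045, 0.005])
_APOE_PROBS = np.array([0.72, 0.27, 0.01])
_TOWNSEND_SD = 3.0
_BMI_MEAN, _BMI_SD = 27.4, 4.5
_SMOKER_FRAC, _PACK_SHAPE, _PACK_SCALE = 0.23, 2.0, 10.0

# Small true covariate effects on latent EF (z-units per unit covariate).
_COVARIATE_EFFECTS = {
    "daytime_sleepiness": -0.020,
    "vascular_comorbidity": -0.014,
    "apoe_e4_dose": -0.009,
    "townsend": -0.010,
    "pack_years": -0.001,
}
_STRUCT_COUPLING = 0.15  # latent EF loading on the shared brain factor g


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic cohort.

    ``sleep_curvature`` is the coefficient on (sleep - sleep_peak)^2 in the
    latent EF equation; a negative value gives the inverted-U with maximum
    at ``sleep_peak``. ``noise_sds`` may override per-variable residual SDs:
    keys ``tasks`` (length-5 array; default sqrt(1 - loading^2) so each task
    has unit variance), ``region_frac`` (regional volume noise as a fraction
    of the region's base volume, default 0.03) and ``log_wmh`` (default 0.4).
    """

    n_participants: int = 20_000
    seed: int = 0
    age_range: tuple[int, int] = (38, 73)
    sleep_probs: np.ndarray = field(default_factory=lambda: DEFAULT_SLEEP_PROBS.copy())
    loadings: np.ndarray = field(default_factory=lambda: np.array([0.8, 0.7, 0.6, 0.5, 0.4]))
    ef_age_slope: float = -0.02
    sleep_peak: float = 7.0
    sleep_curvature: float = -0.03
    n_regions: int = 139
    quadratic_region_frac: float = 7 / 139
    long_only_region_frac: float = 39 / 139
    missing_rate: float = 0.10
    noise_sds: dict = field(default_factory=dict)

    def validate(self) -> None:
        probs = np.asarray(self.sleep_probs, dtype=float)
        if probs.shape != (12,):
            raise ConfigurationError("sleep_probs must have 12 entries (hours 1-12)")
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
            raise ConfigurationError("sleep_probs must be nonnegative and sum to 1 within 1e-12")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be >= 1")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range.low must be < age_range.high")
        if np.asarray(self.loadings).shape != (5,):
            raise ConfigurationError("loadings must have 5 entries")
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be >= 0")
        for frac in (self.quadratic_region_frac, self.long_only_region_frac):
            if not 0 <= frac <= 1:
                raise ConfigurationError("region fractions must be in [0, 1]")
        if self.quadratic_region_frac + self.long_only_region_frac > 1 + 1e-12:
            raise ConfigurationError("region effect fractions must sum to <= 1")

    def task_residual_sds(self) -> np.ndarray:
        sds = self.noise_sds.get("tasks")
        if sds is None:
            lam = np.asarray(self.loadings, dtype=float)
            sds = np.sqrt(np.clip(1.0 - lam**2, 1e-6, None))
        return np.asarray(sds, dtype=float)


@dataclass
class GroundTruth:
    """What the generator actually used, for recovery tests."""

    loadings: np.ndarray
    region_effect_class: pd.Series  # index region_id, values {null, quadratic, long_only}
    true_indirect: float
    ef_by_sleep: pd.Series  # index sleep hour 1..12, expected latent EF
    region_params: pd.DataFrame | None = None  # per-region generating coefficients

    def to_json(self) -> str:
        payload = {
            "loadings": np.asarray(self.loadings, float).tolist(),
            "region_effect_class": self.region_effect_class.to_dict(),
            "true_indirect": float(self.true_indirect),
            "ef_by_sleep": {int(k): float(v) for k, v in self.ef_by_sleep.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _sleep_moments(probs: np.ndarray, peak: float):
    hours = np.arange(1, 13, dtype=float)
    q = (hours - peak) ** 2
    q_mean = float(q @ probs)
    q_var = float(((q - q_mean) ** 2) @ probs)
    return hours, q, q_mean, q_var


def _categorical(rng: np.random.Generator, probs: np.ndarray, n: int) -> np.ndarray:
    return rng.choice(len(probs), size=n, p=probs / probs.sum())


def _discrete_var(probs: np.ndarray) -> float:
    vals = np.arange(len(probs), dtype=float)
    p = probs / probs.sum()
    mu = vals @ p
    return float(((vals - mu) ** 2) @ p)


def generate_cohort(config: SimulationConfig):
    """Generate (PhenotypeTable, ImagingTable, GroundTruth).

    Both tables have ``n_participants`` rows keyed by ``participant_id``.
    The latent EF has population variance 1 by construction (the residual
    latent noise absorbs whatever the structural terms do not explain), so
    standardized CFA loadings recover ``config.loadings`` directly.
    """
    config.validate()
    n = config.n_participants
    ss = np.random.SeedSequence(config.seed)
    rng_pheno, rng_imaging, rng_missing, rng_regions, rng_mc = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    lo, hi = config.age_range
    probs = np.asarray(config.sleep_probs, dtype=float)
    hours, qvals, q_mean, q_var = _sleep_moments(probs, config.sleep_peak)
    age_mid = (lo + hi) / 2.0
    n_ages = hi - lo + 1
    age_var = (n_ages**2 - 1) / 12.0

    # --- variance budget so Var(latent EF) = 1 exactly in the population
    struct_var = (
        config.ef_age_slope**2 * age_var
        + config.sleep_curvature**2 * q_var
        + _STRUCT_COUPLING**2
        + _COVARIATE_EFFECTS["daytime_sleepiness"] ** 2 * _discrete_var(_SLEEPINESS_PROBS)
        + _COVARIATE_EFFECTS["vascular_comorbidity"] ** 2 * _discrete_var(_VASCULAR_PROBS)
        + _COVARIATE_EFFECTS["apoe_e4_dose"] ** 2 * _discrete_var(_APOE_PROBS)
        + _COVARIATE_EFFECTS["townsend"] ** 2 * _TOWNSEND_SD**2
        + _COVARIATE_EFFECTS["pack_years"] ** 2
        * (_SMOKER_FRAC * (_PACK_SHAPE * _PACK_SCALE**2 + (_PACK_SHAPE * _PACK_SCALE) ** 2)
           - (_SMOKER_FRAC * _PACK_SHAPE * _PACK_SCALE) ** 2)
    )
    if struct_var >= 1.0:
        raise ConfigurationError(
            f"structural terms already explain variance {struct_var:.3f} >= 1; "
            "reduce effect sizes"
        )
    latent_noise_sd = float(np.sqrt(1.0 - struct_var))

    # --- phenotype draws
    age = rng_pheno.integers(lo, hi + 1, size=n)
    sleep = rng_pheno.choice(np.arange(1, 13), size=n, p=probs)
    chrono_levels = list(_CHRONOTYPE_PROBS)
    chronotype = np.array(chrono_levels)[
        _categorical(rng_pheno, np.array(list(_CHRONOTYPE_PROBS.values())), n)
    ]
    insomnia = _categorical(rng_pheno, _INSOMNIA_PROBS, n)
    snoring = _categorical(rng_pheno, _SNORING_PROBS, n)
    sleepiness = _categorical(rng_pheno, _SLEEPINESS_PROBS, n)
    vascular = _categorical(rng_pheno, _VASCULAR_PROBS, n)
    apoe = _categorical(rng_pheno, _APOE_PROBS, n)
    bmi = rng_pheno.normal(_BMI_MEAN, _BMI_SD, size=n)
    townsend = rng_pheno.normal(0.0, _TOWNSEND_SD, size=n)
    smoker = rng_pheno.random(n) < _SMOKER_FRAC
    pack_years = np.where(
        smoker, rng_pheno.gamma(_PACK_SHAPE, _PACK_SCALE, size=n), 0.0
    )
    g = rng_pheno.normal(size=n)  # shared brain-structure factor

    q = (sleep - config.sleep_peak) ** 2
    latent = (
        config.ef_age_slope * (age - age_mid)
        + config.sleep_curvature * (q - q_mean)
        + _STRUCT_COUPLING * g
        + _COVARIATE_EFFECTS["daytime_sleepiness"] * (sleepiness - _SLEEPINESS_PROBS @ np.arange(3) / _SLEEPINESS_PROBS.sum())
        + _COVARIATE_EFFECTS["vascular_comorbidity"] * vascular
        + _COVARIATE_EFFECTS["apoe_e4_dose"] * apoe
        + _COVARIATE_EFFECTS["townsend"] * townsend
        + _COVARIATE_EFFECTS["pack_years"] * pack_years
        + latent_noise_sd * rng_pheno.normal(size=n)
    )

    lam = np.asarray(config.loadings, dtype=float)
    psi_sd = config.task_residual_sds()
    task_linear = latent[:, None] * lam[None, :] + rng_pheno.normal(size=(n, 5)) * psi_sd[None, :]

    raw = {}
    for j, col in enumerate(_TASK_ORDER):
        kind, off, sc = _RAW_MAPS[col]
        t = task_linear[:, j]
        if kind == "cube_neg":
            raw[col] = np.clip(off - sc * t, 0.05, None) ** 3
        elif kind == "exp_neg":
            raw[col] = np.exp(off - sc * t)
        else:
            raw[col] = off + sc * t

    if config.missing_rate > 0 and n > 0:
        mask = rng_missing.random((n, 5)) < config.missing_rate
        for j, col in enumerate(_TASK_ORDER):
            vals = raw[col]
            vals[mask[:, j]] = np.nan
            raw[col] = vals

    pid = np.array([f"P{i:07d}" for i in range(n)])
    phenotype = pd.DataFrame(
        {
            "participant_id": pid,
            "age": age,
            "sleep_hours": sleep,
            **{col: raw[col] for col in TASK_COLUMNS},
            "chronotype": chronotype,
            "insomnia": insomnia,
            "snoring": snoring,
            "daytime_sleepiness": sleepiness,
            "vascular_comorbidity": vascular,
            "bmi": bmi,
            "pack_years": pack_years,
            "apoe_e4_dose": apoe,
            "townsend": townsend,
        }
    )

    # --- imaging table
    m = config.n_regions
    ids = region_ids(m)
    n_quad = int(round(config.quadratic_region_frac * m))
    n_long = int(round(config.long_only_region_frac * m))
    classes = np.array(["null"] * m, dtype=object)
    order = rng_regions.permutation(m)
    classes[order[:n_quad]] = "quadratic"
    classes[order[n_quad:n_quad + n_long]] = "long_only"

    base = np.exp(rng_regions.normal(np.log(6000.0), 0.6, size=m))
    noise_frac = float(config.noise_sds.get("region_frac", 0.03))
    region_params = pd.DataFrame(
        {
            "region_id": ids,
            "effect_class": classes,
            "base": base,
            "c_age": rng_regions.normal(-0.003, 0.001, size=m) * base,
            "c_age2": rng_regions.normal(-5e-5, 2e-5, size=m) * base,
            "c_head": rng_regions.normal(0.5, 0.1, size=m) * base,
            "c_table": rng_regions.normal(0.0, 0.002, size=m) * base,
            "c_date": rng_regions.normal(0.0, 2e-5, size=m) * base,
            "quad_coef": np.where(classes == "quadratic", 8e-4, 0.0) * base,
            "long_coef": np.where(classes == "long_only", 4e-3, 0.0) * base,
            "g_coef": np.where(classes != "null", 1e-2, 0.0) * base,
            "noise_sd": noise_frac * base,
        }
    ).set_index("region_id")

    head = rng_imaging.normal(1.0, 0.08, size=n)
    table_pos = rng_imaging.normal(0.0, 4.0, size=n)
    scan_date = rng_imaging.integers(0, 2000, size=n)
    h = np.maximum(0.0, sleep - 8.0)
    h_mean = float(np.maximum(0.0, hours - 8.0) @ probs)

    rp = region_params
    vol = (
        rp["base"].to_numpy()[None, :]
        + np.outer(age - age_mid, rp["c_age"])
        + np.outer((age - age_mid) ** 2 - age_var, rp["c_age2"])
        + np.outer(head - 1.0, rp["c_head"])
        + np.outer(table_pos, rp["c_table"])
        + np.outer(scan_date - 1000.0, rp["c_date"])
        - np.outer(q - q_mean, rp["quad_coef"])
        - np.outer(h - h_mean, rp["long_coef"])
        + np.outer(g, rp["g_coef"])
        + rng_imaging.normal(size=(n, m)) * rp["noise_sd"].to_numpy()[None, :]
    )

    wmh_sd = float(config.noise_sds.get("log_wmh", 0.4))
    w2 = (sleep - 8.0) ** 2
    w2_mean = float(((hours - 8.0) ** 2) @ probs)
    log_wmh = (
        np.log(4000.0)
        + 0.02 * (age - age_mid)
        + 0.02 * (w2 - w2_mean)
        + wmh_sd * rng_imaging.normal(size=n)
    )

    imaging = pd.DataFrame({"participant_id": pid})
    imaging = pd.concat([imaging, pd.DataFrame(vol, columns=ids)], axis=1)
    imaging["wmh_volume"] = np.exp(log_wmh)
    imaging["conf_age"] = age
    imaging["conf_head_size"] = head
    imaging["conf_table_position"] = table_pos
    imaging["conf_scan_date"] = scan_date

    ef_by_sleep = pd.Series(
        config.sleep_curvature * (qvals - q_mean), index=np.arange(1, 13), name="ef"
    )
    true_indirect = _true_indirect_mc(config, region_params, latent_noise_sd, rng_mc)

    truth = GroundTruth(
        loadings=lam.copy(),
        region_effect_class=pd.Series(classes, index=ids, name="effect_class"),
        true_indirect=true_indirect,
        ef_by_sleep=ef_by_sleep,
        region_params=region_params,
    )
    return phenotype, imaging, truth


def _true_indirect_mc(config, region_params, latent_noise_sd, rng, n_mc=200_000):
    """Population indirect effect a*b by deterministic Monte Carlo.

    Uses the generating equations for the latent EF, the 6-8 h band
    indicator and the affected regions' confound-free volumes (confounds are
    independent of sleep and are removed upstream in the pipeline). Sample
    size 200k keeps the MC error around 1e-3.
    """
    affected = region_params[region_params["effect_class"] != "null"]
    if affected.empty:
        return 0.0
    probs = np.asarray(config.sleep_probs, dtype=float)
    hours, qvals, q_mean, _ = _sleep_moments(probs, config.sleep_peak)
    h_mean = float(np.maximum(0.0, hours - 8.0) @ probs)

    sleep = rng.choice(np.arange(1, 13), size=n_mc, p=probs)
    g = rng.normal(size=n_mc)
    q = (sleep - config.sleep_peak) ** 2
    h = np.maximum(0.0, sleep - 8.0)
    y = (
        config.sleep_curvature * (q - q_mean)
        + _STRUCT_COUPLING * g
        + latent_noise_sd * rng.normal(size=n_mc)
    )
    vols = (
        -np.outer(q - q_mean, affected["quad_coef"])
        - np.outer(h - h_mean, affected["long_coef"])
        + np.outer(g, affected["g_coef"])
        + rng.normal(size=(n_mc, len(affected))) * affected["noise_sd"].to_numpy()[None, :]
    )
    z = (vols - vols.mean(axis=0)) / vols.std(axis=0)
    mvec = z.mean(axis=1)
    mvec = (mvec - mvec.mean()) / mvec.std()
    y = (y - y.mean()) / y.std()
    x = ((sleep >= 6) & (sleep <= 8)).astype(float)

    sxx = np.var(x)
    sxm = np.cov(x, mvec, ddof=0)[0, 1]
    sxy = np.cov(x, y, ddof=0)[0, 1]
    smy = np.cov(mvec, y, ddof=0)[0, 1]
    smm = np.var(mvec)
    a = sxm / sxx
    b = (smy * sxx - sxy * sxm) / (smm * sxx - sxm**2)
    return float(a * b)


def write_cohort(phenotype: pd.DataFrame, imaging: pd.DataFrame,
                 truth: GroundTruth, outdir) -> dict:
    """Write tables as TSV and ground truth as JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotype": outdir / "phenotype.tsv",
        "imaging": outdir / "imaging.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    phenotype.to_csv(paths["phenotype"], sep="\t", index=False, float_format="%.10g")
    imaging.to_csv(paths["imaging"], sep="\t", index=False, float_format="%.10g")
    paths["ground_truth"].write_text(truth.to_json())
    return paths


def make_mediation_data(a: float = 0.2, b: float = 0.3, c_prime: float = 0.1,
                        n: int = 10_000, seed: int = 0, binary_x: bool = False):
    """Linear-Gaussian mediation triple with known standardized paths.

    With continuous x ~ N(0,1) the population OLS coefficients of m ~ x and
    y ~ x + m are exactly ``a`` and ``b``; with ``binary_x`` the x variable
    is Bernoulli(0.5) rescaled to unit variance so the same holds.
    """
    rng = np.random.default_rng(seed)
    if binary_x:
        x = (rng.random(n) < 0.5).astype(float)
        x = (x - 0.5) / 0.5
    else:
        x = rng.normal(size=n)
    m = a * x + np.sqrt(max(1e-12, 1 - a**2)) * rng.normal(size=n)
    var_y = b**2 + c_prime**2 + 2 * a * b * c_prime
    sd_eps = np.sqrt(max(1e-12, 1.0 - var_y))
    y = c_prime * x + b * m + sd_eps * rng.normal(size=n)
    return x, m, y
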