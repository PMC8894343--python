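"""Does brain volume mediate the sleep-cognition association?

Builds the summary volume of the sleep-related regions, fits the bootstrap
mediation model band -> volume -> EF, and compares the per-region sleep
effect map with the per-region volume->EF association strengths.
"""

import numpy as np

from sleepcog import (SimulationConfig, factor_scores, fit_cfa, fit_mediation,
                      generate_cohort, log_wmh, orient_tasks,
                      overlap_and_correlation, permutation_region_test,
                      region_ef_association, regress_confounds, summary_volume,
                      transform_cognitive)
from sleepcog.simulate import TASK_COLUMNS

phenotype, imaging, truth = generate_cohort(SimulationConfig(n_participants=20_000, seed=6))
tasks = orient_tasks(transform_cognitive(phenotype))[TASK_COLUMNS]
ef = factor_scores(fit_cfa(tasks), tasks)
imaging = regress_confounds(log_wmh(imaging))
region_cols = truth.region_effect_class.index.tolist()
sleep = phenotype["sleep_hours"].to_numpy(dtype=float)
in_band = ((sleep >= 6) & (sleep <= 8)).astype(float)

offsets = [imaging.attrs["volume_column_means"][c] for c in region_cols]
res = permutation_region_test(imaging[region_cols], in_band.astype(bool),
                              n_perm=5000, seed=6, n_comparisons=140,
                              mean_offsets=offsets)
sig_sleep = res.loc[res.significant, "region_id"].tolist()
msum = summary_volume(imaging[region_cols], sig_sleep)
mstd = (msum - msum.mean()) / msum.std()
ystd = (ef - np.nanmean(ef)) / np.nanstd(ef)

med = fit_mediation(in_band, mstd, ystd, n_boot=1000, seed=6)
print(f"paths: a={med.a:.3f}  b={med.b:.3f}  c={med.c:.3f}  c'={med.c_prime:.3f}")
print(f"indirect effect a*b = {med.ab:.4f} "
      f"CI95=({med.ab_ci95[0]:.4f}, {med.ab_ci95[1]:.4f}) p={med.ab_p:.3g}")
print(f"true generated indirect effect: {truth.true_indirect:.4f}")

betas, pvals, sig_ef = region_ef_association(imaging[region_cols], ef)
comp = overlap_and_correlation(res.set_index("region_id")["percent_diff"],
                               betas, set(sig_sleep), sig_ef)
print(f"{len(sig_sleep)} sleep-related regions, {len(sig_ef)} EF-related regions, "
      f"{comp.overlap_count} overlap")
print(f"r^2 between sleep %-difference and EF beta across regions: {comp.r_squared:.2f}")
# A positive a*b with a CI excluding zero says part of the sleep-EF link
# runs through the volume of the sleep-related regions.
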