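"""One-call pipeline run producing the machine-readable results bundle.

Equivalent to `sleepcog run --mode simulate --seed 8 --outdir bundle_out`.
"""

from sleepcog import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(
    mode="simulate", seed=8, outdir="scratch/bundle_example",
    simulation=SimulationConfig(n_participants=20_000),
    n_perm=5000, n_boot=1000)
results = run_pipeline(cfg)

man = results["manifest"]
print(f"bundle written to {cfg.outdir}")
print(f"EF peak at {results['peak_sleep_hour']} h of sleep")
print(f"significant regions: {man['stages']['volumetrics']['n_significant_regions']}")
print(f"exclusions: {man['exclusions']}")
med = results["mediation"]
if med is not None:
    print(f"mediation a*b = {med.ab:.4f} (p = {med.ab_p:.3g})")
print(f"effect-map r^2 = {results['effect_map'].r_squared:.2f}, "
      f"overlap = {results['effect_map'].overlap_count} regions")
# Every artifact (factor model, curves, region table, mediation JSON,
# manifest) is a TSV/JSON file under the output directory.
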