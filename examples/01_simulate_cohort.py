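"""Generate a synthetic episignature cohort and inspect what it contains.

Builds the default study-scale fixture — 5 cases and 20 controls, a
203-probe v1 signature of which 179 survive to the v2 manifest, ~30x
pooled nanopore coverage — and writes manifest, probe set, array reference
matrix, per-sample bedMethyl files and truth records to ./example_cohort.
"""

from pathlib import Path

import nanoepisig as ne

out = Path("example_cohort")
config = ne.SimulationConfig(n_probes_total=1000, delta=0.15, mean_depth=30.0, seed=7)
cohort = ne.simulate_cohort(config, out_dir=out)

print(f"wrote fixture to {out}/")
print(f"manifest probes:        {len(cohort.manifest)}")
print(f"v1 signature probes:    {len(cohort.signature_v1)}")
print(f"v2-mappable signature:  {len(cohort.signature_v2)} "
      f"({len(cohort.dropped_probes)} lost to manifest version drift)")
print(f"array reference matrix: {cohort.reference.n_probes} probes x "
      f"{cohort.reference.n_samples} samples")
print(f"bedMethyl files:        {len(cohort.bedmethyl_paths)}")
mean_depth = cohort.truth_records["depth"].mean()
print(f"mean pooled depth:      {mean_depth:.1f}x  (Poisson around {config.mean_depth})")
# the truth records are the oracle: every simulated read is recounted there,
# so downstream beta extraction can be checked probe for probe
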