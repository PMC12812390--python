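"""From bedMethyl files to an array-compatible beta matrix.

Parses each sample's methylation calls, pools the forward- and
reverse-strand reads of every CpG, harmonizes the v1 signature probe list
onto the v2 manifest, and computes per-probe beta values (methylated reads
over total valid reads).  Run 01_simulate_cohort.py first.
"""

from pathlib import Path

import pandas as pd

import nanoepisig as ne
from nanoepisig.pipeline import run_extract

fix = Path("example_cohort")
if not fix.exists():
    raise SystemExit("run 01_simulate_cohort.py first")

groups = pd.read_csv(fix / "reference_betas.samples.csv")
sheet = pd.DataFrame({
    "sample_id": groups["sample_id"].str.removesuffix(".array"),
    "group": groups["group"],
})
sheet["path"] = [str(fix / f"{s}.bedmethyl") for s in sheet["sample_id"]]
sheet.to_csv(fix / "samples.csv", index=False)

matrix = run_extract(fix / "manifest.csv", fix / "signature_v1.txt",
                     fix / "samples.csv", Path("example_extract"), min_valid=5)
print(f"beta matrix: {matrix.n_probes} signature probes x {matrix.n_samples} samples")
print("first probes of case1 vs control1 (fractions in [0,1]):")
print(matrix.values.iloc[:5, [0, 5]].round(3))
# betas near 0.1 are unmethylated CpGs, near 0.85 methylated ones; case
# columns are shifted upward at signature probes relative to controls
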