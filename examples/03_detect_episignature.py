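"""Episignature detection: concordance, embeddings, clustering, classification.

Merges the nanopore beta matrix with the labelled array reference, then
computes per-individual cross-platform Pearson correlations, UMAP and MDS
embeddings, a complete-linkage dendrogram, bias-corrected centroid scores
and linear-SVM margins for every query sample.  Run 01 and 02 first.
"""

from pathlib import Path

import nanoepisig as ne
from nanoepisig.pipeline import run_classify

fix = Path("example_cohort")
matrix = ne.BetaMatrix.from_csv(Path("example_extract") / "beta_matrix.csv")
reference = ne.BetaMatrix.from_csv(fix / "reference_betas.csv")
manifest = ne.load_manifest(fix / "manifest.csv")
signature_v1 = ne.load_probe_set(fix / "signature_v1.txt")
signature_v2, dropped = ne.map_probe_set_v1_to_v2(signature_v1, manifest)

results = run_classify(matrix, reference, signature_v2, Path("example_classify"), seed=15)

cls = results["classification"]
print("per-sample decisions (centroid score > 0 => episignature positive):")
print(cls[["centroid_score", "svm_margin", "label"]].round(3).to_string())
print()
r = results["correlations"]["r"]
print(f"cross-platform Pearson r over {len(signature_v2)} signature probes: "
      f"median {r.median():.3f}, range {r.min():.3f}-{r.max():.3f}")
for name, sil in results["silhouettes"].items():
    print(f"{name} case/control silhouette: {sil:.3f}  (> 0 means the groups separate)")
print(f"reference SVM leave-one-out accuracy: {results['svm_loo_accuracy']:.2f}")
# a positive silhouette on both embeddings plus all-positive cases and
# all-negative controls is the synthetic analogue of a confirmed episignature
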