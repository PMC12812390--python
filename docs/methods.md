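# Methods

## Problem and model

An episignature test asks whether a patient's DNA methylation profile at a
curated set of CpG probes matches the pattern of known affected reference
samples. Arrays report one beta value per probe; nanopore sequencing
reports per-strand read counts at every CpG. The pipeline converts the
latter into the former and then measures case/control separation on the
combined data.

**Beta extraction.** bedMethyl rows (0-based, half-open; one row per
modified-base position per strand) are validated (`n_mod <= n_valid`,
non-negative counts) and strand-collapsed: the forward-strand C at
position *p* and the reverse-strand C at *p+1* of one CpG pool into a
single site keyed at *p*; a lone minus-strand call still keys at *p−1*.
For a probe whose CpG site carries at least `min_valid` pooled valid reads,

  β = n_mod_total / n_valid_total.

No array-style normalization (background, dye-bias, BMIQ) is applied:
nanopore fractions are compared with array betas as-is. Percent-modified
columns are auto-normalized — if any value exceeds 1 the whole column is
treated as percentages and divided by 100 (idempotent).

**Probe harmonization.** Episignatures defined on the v1 array manifest are
mapped onto v2: each probe present with `in_v2` true maps to its v2
identifier (possibly renamed); the rest are dropped. Mapped ∪ dropped
always equals the input set. One-to-many v1→v2 mappings are rejected at
manifest load. Coordinates are converted 1-based→0-based only at I/O
boundaries; chromosome names are stored bare.

**Separation statistics.** Over the harmonized signature probes of the
merged (nanopore + array, intersection of defined probes, no imputation)
matrix:

- per-individual cross-platform Pearson correlation;
- classical (metric) MDS: eigendecomposition of the double-centered
  squared Euclidean distance matrix, top-2 coordinates, axes sign-fixed so
  the largest-magnitude loading is positive;
- UMAP (2 components, `n_neighbors = min(15, n−1)`, `min_dist 0.1`,
  fixed `random_state`, default 15 — bit-reproducible per seed);
- complete-linkage hierarchical clustering on Euclidean distances
  (scipy linkage; heights are monotone by construction);
- mean silhouette of the case/control labels on 2-D embedding coordinates
  as the fixed, scalar separation read-out (the original positivity
  criterion is visual).

**Classification.** Two read-outs of the same geometry:

- *Bias-corrected nearest-centroid score* (primary, parameter-free).
  For group *g* with n_g reference columns, the squared distance to the
  sample centroid over-estimates the distance to the population centroid
  by tr(Σ_g)/n_g; we use d̃_g² = max(‖x − μ̂_g‖² − tr(Σ̂_g)/n_g, 0)
  (correction skipped when n_g < 2) and score
  s = (d̃_control − d̃_case)/(d̃_control + d̃_case) ∈ [−1, 1],
  label positive iff s > 0 (ties → negative, the conservative diagnostic
  choice). Without the correction the score has a deterministic negative
  tilt whenever the case reference group is smaller than the control group
  (the usual rare-disease design), so a null cohort would not classify at
  chance. The correction restores exact null symmetry while leaving the
  boundary cases untouched (s = 1 at the case centroid, −1 at the control
  centroid, antisymmetric under label swap).
- *Linear soft-margin SVM* (C = 1, balanced class weights) with
  leave-one-out validation on the references, reporting per-sample signed
  case-ward margins, raw accuracy and balanced accuracy. Balanced class
  weights and balanced accuracy are used because reference panels are
  typically 4:1 control-heavy: the chance level of balanced accuracy is
  0.5 regardless of class priors, whereas raw accuracy's chance level is
  the majority rate.

When an individual contributes both a nanopore query and an array
reference column, the matching reference column is excluded from the
centroids before scoring (leave-one-individual-out).

**Specificity.** Case/control silhouette on MDS coordinates restricted to
the target signature versus size-matched decoy probe sets. A genuine
episignature separates at its own probes only.

## Tunable parameters

| Parameter | Default | Meaning / rationale |
|---|---|---|
| `min_valid` | 5 reads | minimum pooled depth per probe; keeps low-coverage synthetic tests meaningful while bounding binomial noise; recorded per run |
| `mod_code` | `"m"` | 5mC rows only; 5hmC (`h`) rows are ignored, never merged |
| UMAP seed | 15 | fixed for reproducibility; recorded in outputs |
| SVM | linear, C=1, balanced weights | see above |
| centroid tie | negative | conservative diagnostic label |

Strand collapsing is on by default (array probes are strand-agnostic;
pooling maximizes depth). No hemimethylation-discordance filter is applied
by default.

## The synthetic cohort generator

`SimulationConfig` defaults encode the study scale: 5 cases vs 20
controls, mean pooled depth 30×, a 179-probe harmonized signature
(`n_signature_probes`) plus 24 v1-only probes (203 on v1), case shift
`delta = 0.15`.

- *Population means*: per probe, one draw from an equal-weight mixture of
  Beta(2, 18) (unmethylated mode, mean ≈ 0.1) and Beta(17, 3)
  (methylated mode, mean ≈ 0.85) — the genome-scale bimodality of CpG
  methylation.
- *Samples*: every individual gets the probe mean plus N(0, 0.03) noise;
  case individuals add `delta` at signature probes. All probabilities are
  clipped to [0.01, 0.99] before read sampling, so the realized mean shift
  at hypermethylated signature probes saturates slightly below `delta`
  (the moment tests use the clipping-aware expectation).
- *Reads*: pooled depth ~ Poisson(mean_depth), split Binomial(depth, ½)
  between strands; methylated counts Binomial(strand depth, β), so pooled
  counts are exactly Binomial(depth, β). Zero-depth probes produce no rows
  and surface downstream as missing.
- *Truth records* retain each sample × probe's true β, realized depth and
  methylated count; recomputing n_mod/depth reproduces the pipeline's β̂
  exactly, which is what the extraction oracle tests check.
- The whole generator is deterministic in one seed (spawned child streams
  per stage); identical seeds give byte-identical files.

What the generator does **not** emulate: basecalling error profiles,
read-length structure, mapping artefacts, array chemistry (detection
p-values, bead counts), batch effects, per-probe effect-size heterogeneity
(the shift is uniform unless a per-probe delta vector is supplied), and
cell-composition variation. Passing tests therefore demonstrate that the
analysis machinery is correct and well-calibrated under the stated
statistical model — not that real nanopore and array data agree to any
particular degree.

## Numerical and design choices

- Internal coordinates 0-based half-open everywhere; conversion only at
  I/O. Probe strand (`strand_design`) is a design attribute, not a filter:
  minus-design probes read the same pooled site.
- Merge policy is intersection-with-logging; a probe missing from any
  column is dropped, never imputed (imputation would fabricate signal).
- MDS treats eigenvalues within numerical tolerance of zero as zero
  coordinates (identical samples embed at the origin); a significantly
  negative top-k eigenvalue (non-Euclidean input) is an error.
- Clustering ties follow scipy's deterministic index order with columns in
  input order; on continuous beta data exact ties occur only for duplicate
  columns, which merge first at height 0.
- Matrix CSVs round-trip exactly at 6 decimals; every result CSV carries a
  header with tool version, seed and a config hash, and identical runs are
  byte-identical (figures excepted).

## Problem sizes used by the test and acceptance runs

End-to-end and extraction-oracle runs use the full 1000-probe, 25-sample
cohort with real file I/O. Replicated null and specificity simulations
(100 replicates each) restrict the cohort to the signature probes plus a
small background (220 and 500 total probes respectively) — the statistics
involved use only signature-sized probe sets, so the restriction is
distribution-identical and keeps a replicate under a second. Calibration
checks sample 20,000 probes per depth so the empirical coverage rate has
negligible sampling error relative to the 99% bound. The specificity
decoy threshold (0.16) is the 95th percentile of a 200-replicate null
oracle run on disjoint seeds: with only five case samples, chance grouping
on 2-D MDS coordinates regularly reaches silhouettes near 0.1, so the
null-calibrated bound is the meaningful one.

## Known limitations

- The centroid and SVM classifiers are re-implementations against
  user-supplied references, not a clinical database; scores are not
  calibrated probabilities.
- Only an explicit `v2_id` mapping column is supported for probe
  harmonization (no external liftover or vendor manifest parsing).
- The uniform-shift signature is the minimal structure supporting the
  analyses; real episignatures mix hyper- and hypomethylated probes with
  heterogeneous effect sizes (supply a per-probe delta vector to emulate
  that).
- Correlation between platforms in the simulator is limited only by
  binomial read noise; real cross-platform agreement is further reduced by
  probe chemistry and mapping differences the generator does not model.
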