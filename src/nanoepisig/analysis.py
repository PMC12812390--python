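"""Concordance, embedding, clustering and episignature classification.

Operates on :class:`~nanoepisig.betas.BetaMatrix` objects containing
case/control-labelled samples from one or both platforms.  The positivity
decision re-implemented here is geometric: a sample is episignature-positive
when its methylation profile over the signature probes sits closer to the
case reference centroid than to the control centroid.  A linear
support-vector machine with leave-one-out validation provides an
independent, margin-based read-out of the same separation, and embeddings
(classical MDS, UMAP) plus complete-linkage hierarchical clustering give
the visual case-control separation criterion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from sklearn.metrics import silhouette_score
from sklearn.svm import SVC

from .betas import BetaMatrix, BetaProfile
from .manifest import ProbeSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    sample_a: str
    sample_b: str
    r: float
    n_probes: int


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two beta vectors.

    Requires equal length >= 3 and non-constant inputs (the coefficient is
    undefined for a constant vector).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations for a correlation")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("undefined correlation: constant input vector")
    return float(scipy.stats.pearsonr(x, y).statistic)


def pairwise_platform_correlations(
    matrix: BetaMatrix, pairs: Sequence[tuple[str, str]]
) -> list[CorrelationResult]:
    """Pearson r for each named sample pair over the matrix's probe rows.

    Used to quantify cross-platform concordance between an individual's
    array and nanopore beta profiles at the signature probes.
    """
    results: list[CorrelationResult] = []
    for a, b in pairs:
        xa = matrix.column(a).to_numpy()
        xb = matrix.column(b).to_numpy()
        results.append(CorrelationResult(a, b, pearson_correlation(xa, xb), matrix.n_probes))
    return results


def matched_platform_pairs(matrix: BetaMatrix) -> list[tuple[str, str]]:
    """Pair array/nanopore columns of the same individual.

    Convention: sample IDs are ``<base>.<platform>``; a pair is emitted for
    every base present on both platforms.
    """
    by_base: dict[str, dict[str, str]] = {}
    for sid in matrix.sample_ids:
        platform = str(matrix.samples.loc[sid, "platform"])
        base = sid[: -len("." + platform)] if sid.endswith("." + platform) else sid
        by_base.setdefault(base, {})[platform] = sid
    return [
        (m["array"], m["nanopore"])
        for base, m in by_base.items()
        if "array" in m and "nanopore" in m
    ]


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Complete-linkage merge sequence over sample columns.

    ``linkage`` is the scipy (n-1) x 4 linkage matrix; ``sample_ids`` maps
    leaf indices to sample names.  Heights are non-decreasing (complete
    linkage is monotone).
    """

    linkage: np.ndarray
    sample_ids: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def merges(self) -> list[tuple[frozenset[str], frozenset[str], float]]:
        """Merge sequence as (members of cluster A, members of cluster B, height)."""
        n = len(self.sample_ids)
        clusters: dict[int, frozenset[str]] = {i: frozenset([s]) for i, s in enumerate(self.sample_ids)}
        out = []
        for k, (a, b, h, _) in enumerate(self.linkage):
            ca, cb = clusters[int(a)], clusters[int(b)]
            out.append((ca, cb, float(h)))
            clusters[n + k] = ca | cb
        return out

    def leaf_order(self) -> list[str]:
        return [self.sample_ids[i] for i in sch.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Serialize with branch lengths derived from merge heights."""
        tree = sch.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        root = tree
        left = walk(root.left, root.dist)
        right = walk(root.right, root.dist)
        return f"({left},{right});"


def hierarchical_clustering(matrix: BetaMatrix) -> Dendrogram:
    """Agglomerative clustering of samples: Euclidean distance, complete linkage.

    Deterministic for a fixed column order; the BetaMatrix constructor has
    already rejected undefined entries.
    """
    if matrix.n_samples < 2:
        raise ValueError("clustering requires at least 2 samples")
    X = matrix.values.to_numpy().T  # samples x probes
    Z = sch.linkage(X, method="complete", metric="euclidean")
    return Dendrogram(linkage=Z, sample_ids=matrix.sample_ids)


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingResult:
    method: str  # "umap" | "mds"
    coordinates: pd.DataFrame  # samples x (dim1, dim2, ...)
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.coordinates.to_numpy()).all():
            raise ValueError("embedding produced non-finite coordinates")


def classical_mds(matrix: BetaMatrix, k: int = 2) -> EmbeddingResult:
    """Metric multidimensional scaling by eigendecomposition.

    Double-centers the squared Euclidean distance matrix between sample
    columns and takes the top-``k`` spectral coordinates.  Axes are
    sign-fixed so the largest-magnitude loading on each axis is positive.
    Eigenvalues within numerical tolerance of zero yield zero coordinates
    (e.g. identical samples); a significantly negative eigenvalue among the
    top ``k`` means the input distances are not Euclidean and is an error.
    """
    if matrix.n_samples < 2:
        raise ValueError("MDS requires at least 2 samples")
    X = matrix.values.to_numpy().T
    n = X.shape[0]
    if k > n - 1:
        raise ValueError(f"k={k} exceeds the {n - 1} dimensions spanned by {n} samples")
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ sq @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-9, 1e-9 * abs(eigval).max()) if eigval.size else 1e-9
    top = eigval[:k]
    if (top < -tol).any():
        raise ValueError(f"only {(eigval > tol).sum()} positive eigenvalues; cannot embed in {k} dimensions")
    coords = eigvec[:, :k] * np.sqrt(np.clip(top, 0.0, None))[None, :]
    for j in range(k):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    frame = pd.DataFrame(coords, index=matrix.sample_ids,
                         columns=[f"dim{j + 1}" for j in range(k)])
    return EmbeddingResult(method="mds", coordinates=frame, params={"k": k})


def umap_embed(
    matrix: BetaMatrix,
    seed: int = 15,
    n_neighbors: int | None = None,
    min_dist: float = 0.1,
) -> EmbeddingResult:
    """2-D UMAP embedding of the sample columns, reproducible for a fixed seed.

    ``n_neighbors`` defaults to min(15, n_samples - 1).  Cohorts smaller
    than 4 samples cannot support a neighbor graph; use classical MDS there.
    """
    n = matrix.n_samples
    if n < 4:
        raise ValueError("UMAP requires at least 4 samples; use classical_mds for smaller cohorts")
    if n_neighbors is None:
        n_neighbors = min(15, n - 1)
    if not (1 < n_neighbors < n):
        raise ValueError(f"n_neighbors must be in (1, {n}), got {n_neighbors}")
    import umap  # deferred: numba compilation makes this import expensive

    X = matrix.values.to_numpy().T
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)  # n_jobs override notice
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            min_dist=min_dist, random_state=seed)
        coords = reducer.fit_transform(X)
    frame = pd.DataFrame(np.asarray(coords, dtype=float), index=matrix.sample_ids,
                         columns=["dim1", "dim2"])
    return EmbeddingResult(method="umap", coordinates=frame, seed=seed,
                           params={"n_neighbors": n_neighbors, "min_dist": min_dist})


def group_silhouette(embedding: EmbeddingResult, matrix: BetaMatrix) -> float:
    """Mean silhouette of case vs control labels on 2-D embedding coordinates."""
    labels = matrix.groups().loc[embedding.coordinates.index]
    if labels.nunique() < 2:
        raise ValueError("silhouette requires both case and control labels")
    return float(silhouette_score(embedding.coordinates.to_numpy(), labels.to_numpy()))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpisignatureResult:
    """Per-sample episignature decision.

    ``centroid_score`` s = (d_control - d_case) / (d_control + d_case) over
    the signature probes, where d_g is the bias-corrected Euclidean distance
    to the group-g reference centroid; s in [-1, 1], positive when the
    profile is closer to the case centroid.  The label is positive iff
    s > 0 (ties resolve to negative — conservative for a diagnostic-style
    call).  ``svm_margin`` is the signed linear-SVM decision value when
    computed.
    """

    sample_id: str
    centroid_score: float
    label: str
    probe_set_name: str
    svm_margin: float | None = None


def _reference_split(references: BetaMatrix) -> tuple[list[str], list[str]]:
    groups = references.groups()
    cases = [s for s in references.sample_ids if groups[s] == "case"]
    controls = [s for s in references.sample_ids if groups[s] == "control"]
    return cases, controls


def _corrected_distance(x: np.ndarray, ref_cols: np.ndarray) -> float:
    """Euclidean distance to the centroid, corrected for centroid noise.

    The squared distance to a sample mean of n reference columns
    over-estimates the distance to the population centroid by
    tr(within-group covariance)/n.  Subtracting that term (clamped at zero,
    skipped when n < 2 leaves the variance inestimable) equalizes the
    expected squared distance to both group centroids under the null, so
    the score has no systematic tilt when the two reference groups differ
    in size — e.g. the typical few-cases/many-controls design.
    """
    n = ref_cols.shape[1]
    d2 = float(((x - ref_cols.mean(axis=1)) ** 2).sum())
    if n >= 2:
        d2 -= float(ref_cols.var(axis=1, ddof=1).sum()) / n
    return float(np.sqrt(max(d2, 0.0)))


def centroid_classify(
    profile: BetaProfile,
    references: BetaMatrix,
    probe_set: ProbeSet,
    exclude: Sequence[str] = (),
) -> EpisignatureResult:
    """Score a profile against labelled reference centroids over a probe set.

    ``exclude`` removes reference columns before computing centroids —
    used for leave-one-out scoring when the queried individual also
    contributes a reference column.  The profile must cover at least 90% of
    the probe set (after intersecting with the reference probes); anything
    less is a hard error listing the missing probes.
    """
    ref = references
    if exclude:
        keep = [s for s in ref.sample_ids if s not in set(exclude)]
        ref = ref.subset_samples(keep)
    cases, controls = _reference_split(ref)
    if not cases or not controls:
        raise ValueError("references must contain both case and control samples")

    base = [p for p in probe_set.probe_ids if p in set(ref.probe_ids)]
    if not base:
        raise ValueError(f"no probes of set {probe_set.name!r} present in references")
    covered = [p for p in base if p in profile.betas]
    missing = [p for p in base if p not in profile.betas]
    if len(covered) < 0.9 * len(base):
        raise ValueError(
            f"sample {profile.sample_id}: only {len(covered)}/{len(base)} signature probes "
            f"covered (<90%); missing e.g. {missing[:10]}"
        )

    x = np.array([profile.betas[p] for p in covered])
    d_case = _corrected_distance(x, ref.values.loc[covered, cases].to_numpy())
    d_control = _corrected_distance(x, ref.values.loc[covered, controls].to_numpy())
    denom = d_case + d_control
    score = 0.0 if denom == 0.0 else (d_control - d_case) / denom
    label = "positive" if score > 0.0 else "negative"
    return EpisignatureResult(sample_id=profile.sample_id, centroid_score=score,
                              label=label, probe_set_name=probe_set.name)


def _case_margin(clf: SVC, X: np.ndarray) -> np.ndarray:
    # decision_function is positive toward classes_[1]; orient toward "case"
    f = clf.decision_function(X)
    return f if clf.classes_[1] == "case" else -f


def balanced_accuracy(table: pd.DataFrame) -> float:
    """Mean of per-class recalls from a LOO prediction table.

    Its chance level is 0.5 regardless of the case/control ratio, which
    makes it the meaningful null statistic for the usual imbalanced
    reference panels (raw accuracy's chance level is the majority rate).
    """
    recalls = [
        float((table.loc[table["group"] == g, "predicted"] == g).mean())
        for g in sorted(table["group"].unique())
    ]
    return float(np.mean(recalls))


def svm_loo_validate(references: BetaMatrix, probe_set: ProbeSet) -> tuple[pd.DataFrame, float]:
    """Leave-one-out validation of a linear soft-margin SVM on reference betas.

    Each reference sample is classified by an SVM trained on all others over
    the probe-set rows (balanced class weights, so the minority case class
    is not drowned out).  Returns a per-sample table (true group, predicted
    group, signed case-ward margin) and the overall LOO accuracy; see
    :func:`balanced_accuracy` for the imbalance-robust summary.  Requires
    at least 3 samples per class; deterministic for a fixed input.
    """
    cases, controls = _reference_split(references)
    if len(set(references.groups())) < 2:
        raise ValueError("references contain a single class; cannot validate")
    if min(len(cases), len(controls)) < 3:
        raise ValueError(
            f"need >= 3 samples per class, got {len(cases)} case / {len(controls)} control"
        )
    sub = references.subset_probes(list(probe_set.probe_ids))
    X = sub.values.to_numpy().T
    y = sub.groups().to_numpy()
    n = X.shape[0]
    rows = []
    for i in range(n):
        mask = np.arange(n) != i
        clf = SVC(kernel="linear", C=1.0, class_weight="balanced")
        clf.fit(X[mask], y[mask])
        pred = clf.predict(X[i : i + 1])[0]
        margin = float(_case_margin(clf, X[i : i + 1])[0])
        rows.append({"sample_id": sub.sample_ids[i], "group": y[i],
                     "predicted": pred, "svm_margin": margin})
    table = pd.DataFrame(rows).set_index("sample_id")
    accuracy = float((table["predicted"] == table["group"]).mean())
    return table, accuracy


def svm_classify(
    profiles: Sequence[BetaProfile],
    references: BetaMatrix,
    probe_set: ProbeSet,
) -> pd.DataFrame:
    """Train a linear SVM on the references and score external profiles.

    Returns a table of signed case-ward margins and positive/negative labels
    for each query profile over the shared signature probes.
    """
    cases, controls = _reference_split(references)
    if not cases or not controls:
        raise ValueError("references must contain both case and control samples")
    sub = references.subset_probes(list(probe_set.probe_ids))
    clf = SVC(kernel="linear", C=1.0, class_weight="balanced")
    clf.fit(sub.values.to_numpy().T, sub.groups().to_numpy())
    rows = []
    for prof in profiles:
        missing = [p for p in sub.probe_ids if p not in prof.betas]
        if missing:
            raise ValueError(f"sample {prof.sample_id}: {len(missing)} signature probes missing")
        x = np.array([[prof.betas[p] for p in sub.probe_ids]])
        margin = float(_case_margin(clf, x)[0])
        rows.append({"sample_id": prof.sample_id, "svm_margin": margin,
                     "label": "positive" if margin > 0 else "negative"})
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# specificity
# ---------------------------------------------------------------------------

def specificity_check(
    matrix: BetaMatrix,
    target_set: ProbeSet,
    decoy_sets: Sequence[ProbeSet],
) -> pd.DataFrame:
    """Case/control separation at the target probe set versus decoy sets.

    For each probe set, samples are embedded by classical MDS on the set's
    probe rows and the case/control silhouette is reported.  A specific
    episignature separates at its own probes and not at probe sets of other
    disorders (decoys).  Decoys overlapping the target are allowed but
    warned about.
    """
    rows = []
    for pset, is_target in [(target_set, True)] + [(d, False) for d in decoy_sets]:
        if not is_target:
            overlap = set(pset.probe_ids) & set(target_set.probe_ids)
            if overlap:
                warnings.warn(
                    f"decoy set {pset.name!r} overlaps target at {len(overlap)} probe(s)"
                )
        sub = matrix.subset_probes(list(pset.probe_ids))
        emb = classical_mds(sub, k=2)
        sil = group_silhouette(emb, sub)
        rows.append({"probe_set": pset.name, "n_probes": sub.n_probes,
                     "silhouette": sil, "is_target": is_target})
    return pd.DataFrame(rows).set_index("probe_set")
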