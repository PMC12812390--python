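"""End-to-end orchestration: the extract and classify runs behind the CLI.

Kept separate from the CLI so the full pipeline is drivable from Python
(and from tests) without going through argument parsing.  Every result CSV
starts with a comment header recording the tool version, the seed and a
hash of the effective configuration, so identical runs produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .analysis import (
    centroid_classify,
    classical_mds,
    group_silhouette,
    hierarchical_clustering,
    matched_platform_pairs,
    pairwise_platform_correlations,
    specificity_check,
    svm_classify,
    svm_loo_validate,
    umap_embed,
)
from .bedmethyl import collapse_strands, read_bedmethyl
from .betas import BetaMatrix, BetaProfile, extract_probe_betas, merge_beta_profiles
from .manifest import Manifest, ProbeSet, load_manifest, load_probe_set, map_probe_set_v1_to_v2

logger = logging.getLogger(__name__)


def config_hash(config: Mapping[str, object]) -> str:
    canon = ";".join(f"{k}={config[k]}" for k in sorted(config))
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def output_header(seed: int | None, config: Mapping[str, object]) -> str:
    return f"nanoepisig v{__version__} seed={seed} config={config_hash(config)}"


def _write_frame(frame: pd.DataFrame, path: Path, header: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        frame.to_csv(fh, index=index, float_format="%.6f")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Sample sheet: CSV/TSV with columns sample_id, group, path."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table = pd.read_csv(path, sep=sep, comment="#")
    required = {"sample_id", "group", "path"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: sample table missing column(s) {sorted(missing)}")
    if table["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id in sample table")
    return table


def run_extract(
    manifest_path: str | Path,
    probe_set_path: str | Path,
    samples_path: str | Path,
    out_dir: str | Path,
    min_valid: int = 5,
    mod_code: str = "m",
    seed: int | None = None,
) -> BetaMatrix:
    """bedMethyl -> strand-collapsed sites -> probe betas -> merged matrix.

    A v1-version probe set is harmonized onto v2 identifiers first.  Writes
    ``beta_matrix.csv`` (+ sample sidecar) and ``missing_probes.csv`` under
    ``out_dir`` and returns the merged nanopore matrix.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = load_manifest(manifest_path)
    probe_set = load_probe_set(probe_set_path)
    if probe_set.source_version == "v1":
        probe_set, dropped = map_probe_set_v1_to_v2(probe_set, manifest)
        if dropped:
            logger.info("extract: %d signature probes not mappable to v2", len(dropped))

    table = read_sample_table(samples_path)
    profiles: list[BetaProfile] = []
    missing_rows = []
    for row in table.itertuples(index=False):
        calls = read_bedmethyl(row.path, mod_code=mod_code)
        if not calls:
            raise ValueError(f"sample {row.sample_id}: no usable methylation calls in {row.path}")
        sites = collapse_strands(calls)
        prof = extract_probe_betas(
            sites, manifest, probe_set, min_valid=min_valid,
            sample_id=f"{row.sample_id}.nanopore", platform="nanopore", group=row.group,
        )
        profiles.append(prof)
        for pid in prof.missing_probes:
            missing_rows.append({"sample_id": prof.sample_id, "probe_id": pid})

    matrix = merge_beta_profiles(profiles)
    cfg = {"manifest": str(manifest_path), "probe_set": str(probe_set_path),
           "samples": str(samples_path), "min_valid": min_valid, "mod_code": mod_code}
    header = output_header(seed, cfg)
    matrix.to_csv(out_dir / "beta_matrix.csv", header_comment=header)
    _write_frame(pd.DataFrame(missing_rows, columns=["sample_id", "probe_id"]),
                 out_dir / "missing_probes.csv", header, index=False)
    return matrix


def _profiles_from_matrix(matrix: BetaMatrix) -> list[BetaProfile]:
    profiles = []
    for sid in matrix.sample_ids:
        ann = matrix.samples.loc[sid]
        profiles.append(
            BetaProfile(sample_id=sid, platform=str(ann["platform"]), group=str(ann["group"]),
                        betas=matrix.values[sid].to_dict())
        )
    return profiles


def _loo_exclusion(profile_id: str, reference: BetaMatrix) -> list[str]:
    # an individual measured on both platforms must not sit in its own
    # reference centroid: drop the matching array column
    base = profile_id[: -len(".nanopore")] if profile_id.endswith(".nanopore") else profile_id
    twin = f"{base}.array"
    return [twin] if twin in reference.sample_ids else []


def run_classify(
    matrix: BetaMatrix,
    reference: BetaMatrix,
    probe_set: ProbeSet,
    out_dir: str | Path,
    decoy_sets: Sequence[ProbeSet] = (),
    seed: int = 15,
    make_figures: bool = True,
) -> dict[str, object]:
    """Concordance, embeddings, clustering and classification in one run.

    ``matrix`` holds the query (nanopore) samples, ``reference`` the
    labelled array samples; both are restricted to ``probe_set``.  Writes
    correlations.csv, embedding CSVs, dendrogram.nwk, classification.csv,
    svm_loo.csv (and specificity.csv when decoys are given) plus basic
    embedding figures under ``out_dir``; returns the in-memory results.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = {"probe_set": probe_set.name, "seed": seed,
           "n_query": matrix.n_samples, "n_reference": reference.n_samples}
    header = output_header(seed, cfg)

    profiles = _profiles_from_matrix(matrix)
    # full merge keeps every shared probe (needed for decoy probe sets);
    # signature-restricted view drives embeddings, clustering, correlations
    merged_full = merge_beta_profiles(profiles, reference=reference)
    merged = merged_full.subset_probes(list(probe_set.probe_ids))

    # cross-platform concordance for individuals measured on both platforms
    pairs = matched_platform_pairs(merged)
    correlations = pairwise_platform_correlations(merged, pairs) if pairs else []
    corr_frame = pd.DataFrame(
        [{"sample_a": c.sample_a, "sample_b": c.sample_b, "r": c.r, "n_probes": c.n_probes}
         for c in correlations],
        columns=["sample_a", "sample_b", "r", "n_probes"],
    )
    _write_frame(corr_frame, out_dir / "correlations.csv", header, index=False)

    # embeddings + clustering
    mds = classical_mds(merged, k=2)
    embeddings = {"mds": mds}
    if merged.n_samples >= 4:
        embeddings["umap"] = umap_embed(merged, seed=seed)
    for name, emb in embeddings.items():
        frame = emb.coordinates.copy()
        frame["method"] = name
        frame["seed"] = emb.seed if emb.seed is not None else ""
        frame.index.name = "sample_id"
        _write_frame(frame, out_dir / f"embedding_{name}.csv", header)
    dendro = hierarchical_clustering(merged)
    with open(out_dir / "dendrogram.nwk", "w") as fh:
        fh.write(f"# {header}\n{dendro.to_newick()}\n")

    # classification: centroid score (primary) + SVM margin
    results = []
    for prof in profiles:
        res = centroid_classify(prof, reference, probe_set,
                                exclude=_loo_exclusion(prof.sample_id, reference))
        results.append(res)
    svm_table = svm_classify(profiles, reference, probe_set)
    cls_frame = pd.DataFrame(
        [{"sample_id": r.sample_id, "centroid_score": r.centroid_score,
          "svm_margin": float(svm_table.loc[r.sample_id, "svm_margin"]),
          "label": r.label, "probe_set": r.probe_set_name}
         for r in results]
    ).set_index("sample_id")
    _write_frame(cls_frame, out_dir / "classification.csv", header)

    loo_table, loo_accuracy = svm_loo_validate(reference, probe_set)
    _write_frame(loo_table, out_dir / "svm_loo.csv", header)

    specificity = None
    if decoy_sets:
        specificity = specificity_check(merged_full, probe_set, decoy_sets)
        _write_frame(specificity, out_dir / "specificity.csv", header)

    silhouettes = {name: group_silhouette(emb, merged) for name, emb in embeddings.items()}
    if make_figures:
        _plot_embeddings(embeddings, merged, out_dir)

    return {
        "merged": merged,
        "correlations": corr_frame,
        "embeddings": embeddings,
        "silhouettes": silhouettes,
        "dendrogram": dendro,
        "classification": cls_frame,
        "svm_loo": loo_table,
        "svm_loo_accuracy": loo_accuracy,
        "specificity": specificity,
    }


def _plot_embeddings(embeddings, merged: BetaMatrix, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"case": "tab:red", "control": "tab:blue", "unknown": "tab:gray"}
    markers = {"array": "o", "nanopore": "^"}
    for name, emb in embeddings.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        for sid in emb.coordinates.index:
            g = str(merged.samples.loc[sid, "group"])
            p = str(merged.samples.loc[sid, "platform"])
            ax.scatter(*emb.coordinates.loc[sid, ["dim1", "dim2"]],
                       c=colors.get(g, "k"), marker=markers.get(p, "s"), s=40)
        ax.set_xlabel("dim 1")
        ax.set_ylabel("dim 2")
        ax.set_title(f"{name.upper()} of signature betas (red=case, blue=control; ^=nanopore)")
        fig.tight_layout()
        fig.savefig(out_dir / f"embedding_{name}.png", dpi=120)
        plt.close(fig)
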