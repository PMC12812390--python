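"""Probe-level beta values: extraction from CpG sites, per-sample profiles,
multi-sample matrices and their CSV serialization.

The beta value of a probe is the fraction of methylated reads over the total
valid reads at the probe's CpG, computed from strand-pooled counts.  No
array-style normalization (background correction, dye bias, BMIQ) is
applied: nanopore fractions are compared with array betas as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bedmethyl import CpGSite
from .manifest import Manifest, ProbeSet

logger = logging.getLogger(__name__)

GROUPS = ("case", "control", "unknown")
PLATFORMS = ("nanopore", "array")


@dataclass
class BetaProfile:
    """One sample's probe -> beta mapping with coverage metadata.

    ``betas`` and ``missing_probes`` are disjoint and together cover the
    probe set the profile was extracted against.  ``coverage`` carries the
    pooled valid read depth per probe (nanopore profiles only).
    """

    sample_id: str
    platform: str
    group: str
    betas: dict[str, float]
    coverage: dict[str, int] = field(default_factory=dict)
    missing_probes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"platform must be one of {PLATFORMS}, got {self.platform!r}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        bad = {p: b for p, b in self.betas.items() if not (0.0 <= b <= 1.0)}
        if bad:
            raise ValueError(f"sample {self.sample_id}: beta out of [0,1] at {sorted(bad)[:5]}")
        overlap = set(self.betas) & set(self.missing_probes)
        if overlap:
            raise ValueError(f"sample {self.sample_id}: probes both measured and missing: {sorted(overlap)[:5]}")


class BetaMatrix:
    """Probes x samples beta matrix with per-sample group/platform annotations.

    Thin wrapper over two aligned pandas frames: ``values`` (index probe_id,
    one float column per sample) and ``samples`` (index sample_id, columns
    ``group`` and ``platform``).
    """

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame):
        if list(values.columns) != list(samples.index):
            raise ValueError("sample annotation index must match value columns, in order")
        if values.index.has_duplicates or values.columns.has_duplicates:
            raise ValueError("duplicate probe or sample identifiers in matrix")
        vals = values.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("beta matrix contains undefined entries")
        if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
            raise ValueError("beta matrix contains values outside [0, 1]")
        for col in ("group", "platform"):
            if col not in samples.columns:
                raise ValueError(f"sample annotations missing column {col!r}")
        self.values = values.astype(float)
        self.samples = samples.copy()

    # -- basic introspection -------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def column(self, sample_id: str) -> pd.Series:
        if sample_id not in self.values.columns:
            raise KeyError(f"unknown sample {sample_id!r}")
        return self.values[sample_id]

    def groups(self) -> pd.Series:
        return self.samples["group"]

    def subset_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        """Restrict to the given probes, keeping only those present, in order."""
        present = [p for p in probe_ids if p in self.values.index]
        if not present:
            raise ValueError("no requested probes present in matrix")
        return BetaMatrix(self.values.loc[present], self.samples)

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown sample(s): {missing}")
        return BetaMatrix(self.values[list(sample_ids)], self.samples.loc[list(sample_ids)])

    # -- serialization -------------------------------------------------------
    def to_csv(self, path: str | Path, annotations_path: str | Path | None = None,
               header_comment: str | None = None) -> None:
        """Write the matrix (6-decimal betas) and a sidecar annotation CSV."""
        path = Path(path)
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            fh.write("probe_id," + ",".join(self.sample_ids) + "\n")
            for probe, row in zip(self.probe_ids, self.values.to_numpy()):
                fh.write(probe + "," + ",".join(f"{v:.6f}" for v in row) + "\n")
        if annotations_path is None:
            annotations_path = path.with_name(path.stem + ".samples.csv")
        ann = self.samples.reset_index().rename(columns={"index": "sample_id"})
        if ann.columns[0] != "sample_id":
            ann = ann.rename(columns={ann.columns[0]: "sample_id"})
        ann.to_csv(annotations_path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, annotations_path: str | Path | None = None) -> "BetaMatrix":
        path = Path(path)
        values = pd.read_csv(path, comment="#", index_col="probe_id")
        if annotations_path is None:
            annotations_path = path.with_name(path.stem + ".samples.csv")
        samples = pd.read_csv(annotations_path, comment="#", index_col="sample_id")
        samples.index = samples.index.astype(str)
        values.columns = values.columns.astype(str)
        return cls(values, samples.loc[list(values.columns)])


def extract_probe_betas(
    sites: Sequence[CpGSite],
    manifest: Manifest,
    probe_set: ProbeSet,
    min_valid: int = 5,
    sample_id: str = "sample",
    platform: str = "nanopore",
    group: str = "unknown",
) -> BetaProfile:
    """Intersect strand-collapsed CpG sites with probe coordinates.

    For each probe in ``probe_set`` whose CpG site is covered with at least
    ``min_valid`` pooled valid reads, beta = n_mod_total / n_valid_total;
    uncovered or under-covered probes are listed in ``missing_probes``.
    Probe IDs that cannot be resolved in the manifest (by primary or v2
    identifier) are a hard error.
    """
    lookup: dict[tuple[str, int], CpGSite] = {(s.chrom, s.cpg_pos): s for s in sites}
    betas: dict[str, float] = {}
    coverage: dict[str, int] = {}
    missing: list[str] = []
    for pid in probe_set.probe_ids:
        rec = manifest.resolve(pid)
        if rec is None:
            raise KeyError(f"probe {pid!r} not found in manifest")
        site = lookup.get((rec.chrom, rec.cpg_pos))
        if site is not None and site.n_valid_total >= min_valid:
            betas[pid] = site.beta
            coverage[pid] = site.n_valid_total
        else:
            missing.append(pid)
    if missing:
        logger.info("sample %s: %d of %d probes missing (coverage < %d or no site)",
                    sample_id, len(missing), len(probe_set), min_valid)
    return BetaProfile(sample_id=sample_id, platform=platform, group=group,
                       betas=betas, coverage=coverage, missing_probes=missing)


def merge_beta_profiles(
    profiles: Sequence[BetaProfile],
    reference: BetaMatrix | None = None,
    impute_mean: bool = False,
) -> BetaMatrix:
    """Merge per-sample profiles (and optionally a reference matrix) into one
    beta matrix over the intersection of probes defined in every column.

    Probes missing from any column are dropped with per-sample attribution in
    the log; an empty intersection or fewer than two columns is an error.
    With ``impute_mean`` (off by default, and deliberately so — imputation
    can fabricate signal) a probe defined in at least two columns is kept
    and its missing entries filled with the probe's cross-sample mean.
    """
    columns: list[tuple[str, pd.Series, str, str]] = []
    for prof in profiles:
        columns.append((prof.sample_id, pd.Series(prof.betas, dtype=float), prof.group, prof.platform))
    if reference is not None:
        for sid in reference.sample_ids:
            ann = reference.samples.loc[sid]
            columns.append((sid, reference.values[sid], str(ann["group"]), str(ann["platform"])))
    if len(columns) < 2:
        raise ValueError("merge requires at least two columns (profiles plus reference)")
    ids = [c[0] for c in columns]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample identifiers in merge: {sorted({i for i in ids if ids.count(i) > 1})}")

    # probe order follows the first column; intersection policy, no imputation
    common = list(columns[0][1].index)
    universe: set[str] = set()
    for _, series, _, _ in columns:
        universe |= set(series.index)
    common_set = set(common)
    for sid, series, _, _ in columns:
        common_set &= set(series.index)
    for sid, series, _, _ in columns:
        lost = universe - set(series.index)
        if lost:
            logger.warning("merge: sample %s lacks %d probe(s), e.g. %s",
                           sid, len(lost), sorted(lost)[:3])
    if impute_mean:
        counts: dict[str, int] = {}
        for _, series, _, _ in columns:
            for p in series.index:
                counts[p] = counts.get(p, 0) + 1
        ordered = list(columns[0][1].index) + [
            p for _, series, _, _ in columns[1:] for p in series.index
        ]
        seen: set[str] = set()
        probes = [p for p in ordered if counts.get(p, 0) >= 2
                  and not (p in seen or seen.add(p))]
    else:
        probes = [p for p in common if p in common_set]
    if not probes:
        raise ValueError("merge produced an empty probe intersection")
    dropped = len(universe) - len(probes)
    if dropped:
        logger.info("merge: intersection kept %d probes, dropped %d", len(probes), dropped)

    values = pd.DataFrame(
        {sid: series.reindex(probes) for sid, series, _, _ in columns}, index=probes
    )
    if impute_mean:
        row_means = values.mean(axis=1, skipna=True)
        values = values.apply(lambda col: col.fillna(row_means))
    samples = pd.DataFrame(
        {"group": [g for _, _, g, _ in columns], "platform": [p for _, _, _, p in columns]},
        index=pd.Index(ids, name="sample_id"),
    )
    return BetaMatrix(values, samples)
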