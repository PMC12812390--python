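"""Probe manifests and episignature probe sets.

Methylation-array manifests map probe identifiers (cg numbers) to genomic
CpG coordinates.  Successive manifest versions (v1, v2) drop and rename
probes, so an episignature defined on the v1 array must be harmonized
before it can be scored against v2-era data.  This module reads and
writes a plain-table manifest schema, resolves identifiers across
versions, and provides the probe-set container used throughout the
pipeline.

Coordinate convention: positions are 0-based half-open internally;
manifest files carry 1-based positions (the vendor-manifest convention).
Chromosome names are stored bare ("1", "X"); a leading "chr" is stripped
on input and never re-added.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("probe_id", "chrom", "position", "strand", "in_v1", "in_v2", "v2_id")

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix; internal names are bare."""
    name = str(name).strip()
    return name[3:] if name.lower().startswith("chr") else name


def _parse_bool(token: str, column: str, lineno: int) -> bool:
    t = token.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"line {lineno}: cannot parse {column}={token!r} as a boolean")


@dataclass(frozen=True)
class ProbeRecord:
    """One array probe: identity, CpG coordinate and manifest-version presence.

    ``cpg_pos`` is the 0-based position of the forward-strand C of the CpG
    dinucleotide.  ``strand_design`` records which strand the probe was
    designed against; it is a design attribute, not a data filter.
    ``v2_id`` is the identifier on the v2 manifest and is set iff ``in_v2``.
    """

    probe_id: str
    chrom: str
    cpg_pos: int
    strand_design: str
    in_v1: bool
    in_v2: bool
    v2_id: str | None = None

    def __post_init__(self) -> None:
        if self.cpg_pos < 0:
            raise ValueError(f"probe {self.probe_id}: cpg_pos must be >= 0, got {self.cpg_pos}")
        if self.strand_design not in {"+", "-"}:
            raise ValueError(
                f"probe {self.probe_id}: strand_design must be '+' or '-', got {self.strand_design!r}"
            )
        if self.in_v2 and self.v2_id is None:
            object.__setattr__(self, "v2_id", self.probe_id)
        if not self.in_v2 and self.v2_id is not None:
            raise ValueError(f"probe {self.probe_id}: v2_id set but in_v2 is false")


class Manifest:
    """Ordered collection of :class:`ProbeRecord`, keyed by probe identifier.

    Lookup resolves both the primary (v1-era) ``probe_id`` and, where it
    differs, the ``v2_id``, so downstream code can work with harmonized
    identifiers transparently.
    """

    def __init__(self, records: Iterable[ProbeRecord]):
        self.records: list[ProbeRecord] = list(records)
        self._by_id: dict[str, ProbeRecord] = {}
        for rec in self.records:
            if rec.probe_id in self._by_id:
                raise ValueError(f"duplicate probe_id {rec.probe_id!r} in manifest")
            self._by_id[rec.probe_id] = rec
        # v2 aliases never shadow a primary ID; a v2_id colliding with a
        # different probe's primary ID is a one-to-many mapping and rejected.
        for rec in self.records:
            if rec.v2_id is not None and rec.v2_id != rec.probe_id:
                if rec.v2_id in self._by_id:
                    raise ValueError(
                        f"v2_id {rec.v2_id!r} of probe {rec.probe_id!r} collides with another probe"
                    )
                self._by_id[rec.v2_id] = rec

    def __iter__(self) -> Iterator[ProbeRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, probe_id: str) -> ProbeRecord | None:
        """Look up by primary probe_id only."""
        rec = self._by_id.get(probe_id)
        if rec is not None and rec.probe_id != probe_id:
            return None
        return rec

    def resolve(self, any_id: str) -> ProbeRecord | None:
        """Look up by primary probe_id or v2 identifier."""
        return self._by_id.get(any_id)


@dataclass(frozen=True)
class ProbeSet:
    """Named, ordered, duplicate-free set of probe identifiers."""

    name: str
    probe_ids: tuple[str, ...]
    source_version: str = "v1"

    def __post_init__(self) -> None:
        if len(self.probe_ids) == 0:
            raise ValueError(f"probe set {self.name!r} is empty")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError(f"probe set {self.name!r} contains duplicate IDs")
        if self.source_version not in {"v1", "v2"}:
            raise ValueError(f"source_version must be 'v1' or 'v2', got {self.source_version!r}")

    def __len__(self) -> int:
        return len(self.probe_ids)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in set(self.probe_ids)


def _detect_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def load_manifest(path: str | Path) -> Manifest:
    """Read a probe manifest table (CSV or TSV by extension).

    Required columns: probe_id, chrom, position (1-based), strand, in_v1,
    in_v2; optional v2_id (empty allowed).  Positions are converted to the
    internal 0-based convention and chromosome names normalized.  Duplicate
    probe IDs, missing columns and non-integer positions are hard errors.
    """
    path = Path(path)
    sep = _detect_sep(path)
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"{path}: empty manifest file")
        header = [h.strip() for h in header_line.rstrip("\n").split(sep)]
        required = [c for c in MANIFEST_COLUMNS if c != "v2_id"]
        missing = [c for c in required if c not in header]
        if missing:
            raise ValueError(f"{path}: missing manifest column(s): {', '.join(missing)}")
        idx = {c: header.index(c) for c in header}
        has_v2id = "v2_id" in idx

        records: list[ProbeRecord] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(sep)
            if len(fields) < len(required):
                raise ValueError(f"{path} line {lineno}: expected {len(header)} fields, got {len(fields)}")
            raw_pos = fields[idx["position"]].strip()
            try:
                pos_1based = int(raw_pos)
            except ValueError:
                raise ValueError(f"{path} line {lineno}: non-integer position {raw_pos!r}") from None
            v2_id_raw = fields[idx["v2_id"]].strip() if has_v2id and len(fields) > idx["v2_id"] else ""
            in_v2 = _parse_bool(fields[idx["in_v2"]], "in_v2", lineno)
            records.append(
                ProbeRecord(
                    probe_id=fields[idx["probe_id"]].strip(),
                    chrom=normalize_chrom(fields[idx["chrom"]]),
                    cpg_pos=pos_1based - 1,
                    strand_design=fields[idx["strand"]].strip(),
                    in_v1=_parse_bool(fields[idx["in_v1"]], "in_v1", lineno),
                    in_v2=in_v2,
                    v2_id=(v2_id_raw or None) if in_v2 else None,
                )
            )
    return Manifest(records)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    """Write a manifest back to the normalized table schema (inverse of load)."""
    path = Path(path)
    sep = _detect_sep(path)
    with open(path, "w") as fh:
        fh.write(sep.join(MANIFEST_COLUMNS) + "\n")
        for rec in manifest:
            v2_id = "" if rec.v2_id is None or rec.v2_id == rec.probe_id else rec.v2_id
            fh.write(
                sep.join(
                    [
                        rec.probe_id,
                        rec.chrom,
                        str(rec.cpg_pos + 1),
                        rec.strand_design,
                        "true" if rec.in_v1 else "false",
                        "true" if rec.in_v2 else "false",
                        v2_id,
                    ]
                )
                + "\n"
            )


def load_probe_set(path: str | Path, name: str | None = None, source_version: str = "v1") -> ProbeSet:
    """Read a probe set: one ID per line, blank lines and ``#`` comments skipped.

    Duplicate occurrences are dropped with a warning; an empty file is an error.
    """
    path = Path(path)
    seen: dict[str, None] = {}
    dupes: list[str] = []
    with open(path) as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if not token:
                continue
            # single-column table convenience: ignore a header cell "probe_id"
            token = token.split(",")[0].split("\t")[0].strip()
            if token == "probe_id":
                continue
            if token in seen:
                dupes.append(token)
            else:
                seen[token] = None
    if dupes:
        warnings.warn(f"probe set {path.name}: dropped {len(dupes)} duplicate ID(s): {sorted(set(dupes))}")
    if not seen:
        raise ValueError(f"{path}: probe set file contains no probe IDs")
    return ProbeSet(name=name or path.stem, probe_ids=tuple(seen), source_version=source_version)


def write_probe_set(probe_set: ProbeSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# probe set: {probe_set.name} ({probe_set.source_version})\n")
        for pid in probe_set.probe_ids:
            fh.write(pid + "\n")


def map_probe_set_v1_to_v2(probe_set: ProbeSet, manifest: Manifest) -> tuple[ProbeSet, list[str]]:
    """Harmonize a v1-era probe set onto the v2 manifest.

    Every input ID present in the manifest with ``in_v2`` true is mapped to
    its v2 identifier (the original ID when unchanged); IDs absent from the
    manifest or absent from v2 are returned in ``dropped``.  The mapped and
    dropped sets partition the input exactly.
    """
    if probe_set.source_version != "v1":
        raise ValueError(f"probe set {probe_set.name!r} is already {probe_set.source_version}")
    mapped: list[str] = []
    dropped: list[str] = []
    for pid in probe_set.probe_ids:
        rec = manifest.get(pid)
        if rec is not None and rec.in_v2:
            mapped.append(rec.v2_id if rec.v2_id is not None else pid)
        else:
            dropped.append(pid)
    if not mapped:
        raise ValueError(f"probe set {probe_set.name!r}: no probes could be mapped to v2")
    if dropped:
        logger.info("probe set %s: %d of %d probes not on v2, dropped", probe_set.name, len(dropped), len(probe_set))
    mapped_set = ProbeSet(name=f"{probe_set.name}.v2", probe_ids=tuple(mapped), source_version="v2")
    return mapped_set, dropped
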