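"""bedMethyl (modkit dialect) parsing, validation, strand collapsing and writing.

bedMethyl is the BED9+ tab-separated format emitted by nanopore methylation
callers: one row per modified-base position per strand, carrying the valid
read coverage, the modified-read count and a percent-modified column.
Coordinates are 0-based half-open.

A CpG dinucleotide is covered by two rows — the forward-strand C at position
p and the reverse-strand C at p+1.  Array probes interrogate the CpG
regardless of read strand, so :func:`collapse_strands` pools the two rows
into one site keyed at p, maximizing usable depth.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

from .manifest import normalize_chrom

logger = logging.getLogger(__name__)

# modkit "traditional" rows carry 18 columns; the ones the pipeline reads
# (1-based): 1 chrom, 2 start, 4 mod code, 5 valid coverage, 6 strand,
# 11 percent modified, 12 n_mod.
_MIN_FIELDS = 12


@dataclass(frozen=True)
class MethylationCall:
    """One bedMethyl row after validation and percent normalization."""

    chrom: str
    start: int
    mod_code: str
    strand: str
    n_valid: int
    n_mod: int
    percent_mod: float  # fraction in [0, 1]

    @property
    def end(self) -> int:
        return self.start + 1

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r} at {self.chrom}:{self.start}")
        if self.n_valid < 0 or self.n_mod < 0:
            raise ValueError(f"negative count at {self.chrom}:{self.start}")
        if self.n_mod > self.n_valid:
            raise ValueError(f"n_mod > n_valid at {self.chrom}:{self.start}")


@dataclass
class CpGSite:
    """Strand-collapsed CpG: pooled counts keyed at the forward-strand C.

    Calls on the '.' (strand-unresolved) row are accounted on the plus slot.
    """

    chrom: str
    cpg_pos: int
    n_valid_plus: int = 0
    n_mod_plus: int = 0
    n_valid_minus: int = 0
    n_mod_minus: int = 0

    @property
    def n_valid_total(self) -> int:
        return self.n_valid_plus + self.n_valid_minus

    @property
    def n_mod_total(self) -> int:
        return self.n_mod_plus + self.n_mod_minus

    @property
    def beta(self) -> float:
        """Methylation fraction: modified reads over total valid reads."""
        if self.n_valid_total == 0:
            raise ValueError(f"site {self.chrom}:{self.cpg_pos} has zero coverage")
        return self.n_mod_total / self.n_valid_total

    def validate(self) -> None:
        if min(self.n_valid_plus, self.n_mod_plus, self.n_valid_minus, self.n_mod_minus) < 0:
            raise ValueError(f"negative count at site {self.chrom}:{self.cpg_pos}")
        if self.n_mod_plus > self.n_valid_plus or self.n_mod_minus > self.n_valid_minus:
            raise ValueError(f"n_mod exceeds n_valid at site {self.chrom}:{self.cpg_pos}")


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_bedmethyl(path: str | Path, mod_code: str = "m") -> list[MethylationCall]:
    """Parse a bedMethyl file, keeping rows with the requested mod code.

    The percent-modified column is normalized to a fraction: if any retained
    value exceeds 1, the whole column is interpreted as percentages and
    divided by 100 (idempotent on already-fractional files).  Count
    inconsistencies (n_mod > n_valid, negatives, short rows) are hard errors
    with the offending line number.
    """
    raw: list[tuple[str, int, str, str, int, int, float]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < _MIN_FIELDS:
                raise ValueError(f"{path} line {lineno}: expected >= {_MIN_FIELDS} fields, got {len(fields)}")
            code = fields[3]
            if code != mod_code:
                continue
            try:
                start = int(fields[1])
                n_valid = int(fields[4])
                percent = float(fields[10])
                n_mod = int(fields[11])
            except ValueError:
                raise ValueError(f"{path} line {lineno}: malformed numeric field") from None
            if n_valid < 0 or n_mod < 0:
                raise ValueError(f"{path} line {lineno}: negative count")
            if n_mod > n_valid:
                raise ValueError(f"{path} line {lineno}: n_mod ({n_mod}) > n_valid ({n_valid})")
            raw.append((normalize_chrom(fields[0]), start, code, fields[5], n_valid, n_mod, percent))

    # file-level percent normalization: percentages and fractions never mix
    scale = 0.01 if any(r[6] > 1.0 for r in raw) else 1.0
    calls = [
        MethylationCall(
            chrom=chrom, start=start, mod_code=code, strand=strand,
            n_valid=n_valid, n_mod=n_mod, percent_mod=percent * scale,
        )
        for chrom, start, code, strand, n_valid, n_mod, percent in raw
    ]
    for call in calls:
        if call.n_valid > 0 and abs(call.percent_mod - call.n_mod / call.n_valid) > 0.011:
            logger.warning(
                "%s: percent column (%.4f) inconsistent with counts %d/%d at %s:%d",
                path, call.percent_mod, call.n_mod, call.n_valid, call.chrom, call.start,
            )
    return calls


def collapse_strands(calls: Iterable[MethylationCall]) -> list[CpGSite]:
    """Pool per-strand calls into CpG sites keyed at the forward-strand C.

    A '+' (or '.') call at position p contributes to the site at p; a '-'
    call at p belongs to the CpG whose forward C is at p-1 and contributes
    there whether or not a '+' partner exists.  Counts sum exactly.  Two
    calls claiming the same strand slot of one site are duplicate input and
    a hard error.
    """
    sites: dict[tuple[str, int], CpGSite] = {}
    for call in calls:
        if call.strand == "-":
            key = (call.chrom, call.start - 1)
        else:
            key = (call.chrom, call.start)
        if key[1] < 0:
            raise ValueError(f"minus-strand call at {call.chrom}:{call.start} has no forward partner position")
        site = sites.get(key)
        if site is None:
            site = sites[key] = CpGSite(chrom=key[0], cpg_pos=key[1])
        if call.strand == "-":
            if site.n_valid_minus or site.n_mod_minus:
                raise ValueError(f"duplicate minus-strand call at {call.chrom}:{call.start}")
            site.n_valid_minus = call.n_valid
            site.n_mod_minus = call.n_mod
        else:
            if site.n_valid_plus or site.n_mod_plus:
                raise ValueError(f"duplicate plus-strand call at {call.chrom}:{call.start}")
            site.n_valid_plus = call.n_valid
            site.n_mod_plus = call.n_mod
    out = sorted(sites.values(), key=lambda s: (s.chrom, s.cpg_pos))
    for site in out:
        site.validate()
    return out


def filter_coverage(sites: Sequence[CpGSite], min_valid: int) -> list[CpGSite]:
    """Drop sites with pooled valid coverage below ``min_valid``."""
    if min_valid < 0:
        raise ValueError("min_valid must be >= 0")
    kept = [s for s in sites if s.n_valid_total >= min_valid]
    removed = len(sites) - len(kept)
    if removed:
        logger.info("coverage filter (>=%d): removed %d of %d sites", min_valid, removed, len(sites))
    return kept


def filter_discordant(sites: Sequence[CpGSite], threshold: float = 0.5) -> list[CpGSite]:
    """Optionally drop hemimethylation-discordant sites.

    Removes sites where both strands are covered and the plus/minus
    methylation fractions differ by more than ``threshold``.  Off by
    default in the pipeline: strand-discordant CpGs are rare and no such
    filter is part of the standard probe-beta computation.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    kept = []
    for s in sites:
        if s.n_valid_plus > 0 and s.n_valid_minus > 0:
            gap = abs(s.n_mod_plus / s.n_valid_plus - s.n_mod_minus / s.n_valid_minus)
            if gap > threshold:
                continue
        kept.append(s)
    removed = len(sites) - len(kept)
    if removed:
        logger.info("discordance filter (>%.2f): removed %d of %d sites", threshold, removed, len(sites))
    return kept


def _format_row(chrom: str, start: int, strand: str, n_valid: int, n_mod: int, mod_code: str) -> str:
    percent = 100.0 * n_mod / n_valid if n_valid > 0 else 0.0
    n_canonical = n_valid - n_mod
    fields = [
        chrom, str(start), str(start + 1), mod_code, str(n_valid), strand,
        str(start), str(start + 1), "255,0,0",
        str(n_valid), f"{percent:.2f}", str(n_mod), str(n_canonical),
        "0", "0", "0", "0", "0",
    ]
    return "\t".join(fields)


def write_bedmethyl(records: Iterable[MethylationCall | CpGSite], path: str | Path, mod_code: str = "m") -> None:
    """Write calls or strand-collapsed sites as modkit-dialect bedMethyl rows.

    A :class:`CpGSite` expands to one '+' row at its position and one '-'
    row at position+1, each with the per-strand counts; zero-coverage strand
    rows are omitted (and a fully uncovered site writes nothing), so
    ``collapse_strands(read_bedmethyl(...))`` is the identity on counts.
    """
    path = Path(path)
    opener = gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "w")
    with opener as fh:
        for rec in records:
            if isinstance(rec, CpGSite):
                rec.validate()
                if rec.n_valid_plus > 0:
                    fh.write(_format_row(rec.chrom, rec.cpg_pos, "+", rec.n_valid_plus, rec.n_mod_plus, mod_code) + "\n")
                if rec.n_valid_minus > 0:
                    fh.write(_format_row(rec.chrom, rec.cpg_pos + 1, "-", rec.n_valid_minus, rec.n_mod_minus, mod_code) + "\n")
            else:
                fh.write(_format_row(rec.chrom, rec.start, rec.strand, rec.n_valid, rec.n_mod, rec.mod_code) + "\n")
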