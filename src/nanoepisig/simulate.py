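"""Synthetic cohorts with the statistical structure the pipeline assumes.

Real episignature cohorts are protected patient data, so every stage of the
pipeline is exercised on generated inputs that emulate the study design:

* a probe manifest whose signature probes undergo v1 -> v2 version drift
  (a configurable number of signature probes absent from v2, emulating the
  203 -> 179 reduction of the Hao-Fountain signature, with a fraction of
  surviving probes renamed);
* an array-platform reference beta matrix: per-probe population means drawn
  from a bimodal beta mixture (hypo-/hyper-methylated modes), per-sample
  Gaussian noise, and a uniform mean shift ``delta`` at the signature
  probes in case samples;
* per-sample bedMethyl files: pooled read depth Poisson around a target
  coverage, reads split binomially between strands, methylated counts
  binomial in the sample's true beta — together with truth records that
  let tests recount every read.

All randomness flows from a single seed; generation is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bedmethyl import CpGSite, write_bedmethyl
from .betas import BetaMatrix
from .manifest import Manifest, ProbeRecord, ProbeSet, write_manifest, write_probe_set

logger = logging.getLogger(__name__)

_CONTIGS = ("1", "2", "3", "16")  # synthetic contigs; "16" nods to the locus
_POSITION_SPAN = 50_000_000
_BETA_CLIP = (0.01, 0.99)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: 5 cases vs 20 controls, depth ~30x, a 179-probe
    harmonized signature (203 on v1, 24 lost to v2), case shift 0.15.

    The control beta mixture places probes near 0.1 (unmethylated mode,
    Beta(2,18)) or 0.85 (methylated mode, Beta(17,3)) with equal weight;
    per-sample biological/technical noise is Gaussian with sd 0.03 and all
    probabilities are clipped to [0.01, 0.99] before read sampling.
    """

    n_probes_total: int = 1000
    n_signature_probes: int = 179      # harmonized (v2-mappable) signature size
    n_v1_only_probes: int = 24         # signature probes lost in v1 -> v2 drift
    delta: float = 0.15                # case mean shift at signature probes
    mean_depth: float = 30.0           # expected pooled reads per CpG
    n_controls: int = 20
    n_cases: int = 5
    mix_a0: float = 2.0
    mix_b0: float = 18.0
    mix_a1: float = 17.0
    mix_b1: float = 3.0
    mix_weight: float = 0.5            # probability of the unmethylated mode
    noise_sd: float = 0.03
    renamed_fraction: float = 0.1      # v2-surviving signature probes given a new ID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signature_probes + self.n_v1_only_probes > self.n_probes_total:
            raise ValueError("signature (incl. v1-only probes) cannot exceed n_probes_total")
        if not (-1.0 <= self.delta <= 1.0):
            raise ValueError("delta must lie in [-1, 1]")
        if min(self.n_controls, self.n_cases) < 1:
            raise ValueError("need at least one case and one control")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")

    @property
    def sample_bases(self) -> list[str]:
        return [f"case{i + 1}" for i in range(self.n_cases)] + [
            f"control{i + 1}" for i in range(self.n_controls)
        ]

    @property
    def groups(self) -> list[str]:
        return ["case"] * self.n_cases + ["control"] * self.n_controls


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def _draw_positions(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Distinct CpG positions with pairwise gaps >= 2 per contig.

    Collisions (duplicates or adjacent positions, whose strand rows would
    interleave) are re-drawn; persistent failure after 100 rounds is an error.
    """
    chroms = rng.choice(len(_CONTIGS), size=n)
    positions = rng.integers(1, _POSITION_SPAN, size=n)
    for _ in range(100):
        bad = np.zeros(n, dtype=bool)
        for c in range(len(_CONTIGS)):
            idx = np.flatnonzero(chroms == c)
            order = idx[np.argsort(positions[idx])]
            close = np.diff(positions[order]) < 2
            bad[order[1:][close]] = True
        if not bad.any():
            return chroms, positions
        positions[bad] = rng.integers(1, _POSITION_SPAN, size=int(bad.sum()))
    raise RuntimeError("could not place probes without collisions after 100 re-draws")


def simulate_manifest(config: SimulationConfig, rng: np.random.Generator | None = None) -> tuple[Manifest, ProbeSet]:
    """Generate a probe manifest and the v1-version signature probe set.

    The signature has ``n_signature_probes + n_v1_only_probes`` entries on
    v1; exactly ``n_v1_only_probes`` of them are absent from v2, and a
    fraction of the survivors carry a renamed v2 identifier.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_probes_total
    chroms, positions = _draw_positions(n, rng)
    probe_ids = [f"cg{i:08d}" for i in rng.permutation(n)]

    sig_total = config.n_signature_probes + config.n_v1_only_probes
    sig_idx = rng.choice(n, size=sig_total, replace=False)
    v1_only = set(sig_idx[rng.choice(sig_total, size=config.n_v1_only_probes, replace=False)])
    renamed = {
        i for i in sig_idx
        if i not in v1_only and rng.random() < config.renamed_fraction
    }

    records = []
    for i in range(n):
        in_v2 = i not in v1_only
        pid = probe_ids[i]
        records.append(
            ProbeRecord(
                probe_id=pid,
                chrom=_CONTIGS[chroms[i]],
                cpg_pos=int(positions[i]),
                strand_design="+" if rng.random() < 0.5 else "-",
                in_v1=True,
                in_v2=in_v2,
                v2_id=(f"{pid}_v2" if i in renamed else pid) if in_v2 else None,
            )
        )
    signature = ProbeSet(
        name="signature",
        probe_ids=tuple(probe_ids[i] for i in sig_idx),
        source_version="v1",
    )
    return Manifest(records), signature


# ---------------------------------------------------------------------------
# reference betas
# ---------------------------------------------------------------------------

def _population_means(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    low = rng.random(n) < config.mix_weight
    mu = np.where(
        low,
        rng.beta(config.mix_a0, config.mix_b0, size=n),
        rng.beta(config.mix_a1, config.mix_b1, size=n),
    )
    return np.clip(mu, *_BETA_CLIP)


def simulate_reference_betas(
    config: SimulationConfig,
    manifest: Manifest,
    signature_v1: ProbeSet,
    rng: np.random.Generator | None = None,
    delta_per_probe: dict[str, float] | None = None,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Array-platform reference matrix plus the per-individual truth betas.

    Every probe gets one population mean from the bimodal mixture, shared by
    all samples; each sample adds Gaussian noise (sd ``noise_sd``), and case
    samples add ``delta`` at the signature probes.  The returned reference
    matrix is indexed by v2 identifiers and restricted to v2-present probes
    (what an array run would deliver); the truth frame is indexed by v1
    probe_id over *all* probes and drives the nanopore read simulator, so
    each individual's nanopore truth equals their array beta.

    ``delta_per_probe`` (v1 probe_id -> signed shift) overrides the uniform
    ``config.delta`` to emulate heterogeneous per-probe effect sizes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    probes = [rec.probe_id for rec in manifest]
    n = len(probes)
    mu = _population_means(config, n, rng)

    sig = set(signature_v1.probe_ids)
    if delta_per_probe is not None:
        shift = np.array([delta_per_probe.get(p, 0.0) for p in probes])
    else:
        shift = np.array([config.delta if p in sig else 0.0 for p in probes])

    bases = config.sample_bases
    groups = config.groups
    truth = np.empty((n, len(bases)))
    for j, group in enumerate(groups):
        mean = mu + (shift if group == "case" else 0.0)
        truth[:, j] = np.clip(mean + rng.normal(0.0, config.noise_sd, size=n), *_BETA_CLIP)
    truth_frame = pd.DataFrame(truth, index=pd.Index(probes, name="probe_id"), columns=bases)

    v2_rows = [rec for rec in manifest if rec.in_v2]
    values = pd.DataFrame(
        truth_frame.loc[[r.probe_id for r in v2_rows]].to_numpy(),
        index=pd.Index([r.v2_id for r in v2_rows], name="probe_id"),
        columns=[f"{b}.array" for b in bases],
    )
    samples = pd.DataFrame(
        {"group": groups, "platform": "array"},
        index=pd.Index([f"{b}.array" for b in bases], name="sample_id"),
    )
    return BetaMatrix(values, samples), truth_frame


# ---------------------------------------------------------------------------
# nanopore reads
# ---------------------------------------------------------------------------

def sample_read_counts(
    true_beta: np.ndarray,
    mean_depth: float,
    rng: np.random.Generator,
    dispersion: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw per-CpG strand-split read counts for one sample.

    Pooled depth is Poisson(mean_depth) by default, split Binomial(depth,
    1/2) between strands; methylated counts are Binomial(strand depth,
    true beta), so the pooled methylated count is Binomial(depth, beta)
    exactly.  With ``dispersion`` set, depth is negative binomial with the
    same mean and variance mean + mean^2/dispersion (gamma-Poisson
    mixture), emulating over-dispersed long-read coverage.
    Returns (depth_plus, n_mod_plus, depth_minus, n_mod_minus).
    """
    true_beta = np.asarray(true_beta, dtype=float)
    if dispersion is None:
        depth = rng.poisson(mean_depth, size=true_beta.shape)
    else:
        if dispersion <= 0:
            raise ValueError("dispersion must be positive")
        lam = rng.gamma(dispersion, mean_depth / dispersion, size=true_beta.shape)
        depth = rng.poisson(lam)
    depth_plus = rng.binomial(depth, 0.5)
    depth_minus = depth - depth_plus
    n_mod_plus = rng.binomial(depth_plus, true_beta)
    n_mod_minus = rng.binomial(depth_minus, true_beta)
    return depth_plus, n_mod_plus, depth_minus, n_mod_minus


def simulate_bedmethyl(
    truth: pd.DataFrame,
    manifest: Manifest,
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[CpGSite]], pd.DataFrame]:
    """Simulate nanopore methylation calls for every sample in ``truth``.

    ``truth`` is the probes x samples true-beta frame from
    :func:`simulate_reference_betas` (v1 probe_id index).  Returns the
    per-sample strand-resolved CpG sites (written as modkit-dialect
    bedMethyl under ``out_dir`` when given, one ``<sample>.bedmethyl`` per
    column) and a long-format truth-record frame with the realized depth
    and methylated count per sample x probe — the oracle against which
    beta extraction is checked.  Zero-depth draws produce no rows and the
    probe is later reported missing.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    by_probe = {rec.probe_id: rec for rec in manifest}
    missing = [p for p in truth.index if p not in by_probe]
    if missing:
        raise KeyError(f"truth frame contains probes absent from manifest, e.g. {missing[:5]}")

    sites_by_sample: dict[str, list[CpGSite]] = {}
    records: list[dict] = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    probe_list = list(truth.index)
    recs = [by_probe[p] for p in probe_list]
    for base in truth.columns:
        beta = truth[base].to_numpy()
        dp, mp, dm, mm = sample_read_counts(beta, config.mean_depth, rng)
        sites = []
        for i, rec in enumerate(recs):
            total = int(dp[i] + dm[i])
            records.append(
                {
                    "sample": base,
                    "probe_id": rec.probe_id,
                    "chrom": rec.chrom,
                    "cpg_pos": rec.cpg_pos,
                    "true_beta": beta[i],
                    "depth": total,
                    "n_mod": int(mp[i] + mm[i]),
                }
            )
            if total == 0:
                continue
            sites.append(
                CpGSite(
                    chrom=rec.chrom, cpg_pos=rec.cpg_pos,
                    n_valid_plus=int(dp[i]), n_mod_plus=int(mp[i]),
                    n_valid_minus=int(dm[i]), n_mod_minus=int(mm[i]),
                )
            )
        sites.sort(key=lambda s: (s.chrom, s.cpg_pos))
        sites_by_sample[base] = sites
        if out_dir is not None:
            write_bedmethyl(sites, out_dir / f"{base}.bedmethyl")
    truth_records = pd.DataFrame.from_records(records)
    return sites_by_sample, truth_records


# ---------------------------------------------------------------------------
# whole cohort
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    """Everything one study run produces, plus the truth needed by oracles."""

    config: SimulationConfig
    manifest: Manifest
    signature_v1: ProbeSet
    signature_v2: ProbeSet
    dropped_probes: list[str]
    reference: BetaMatrix          # array platform, v2 probe IDs
    truth_betas: pd.DataFrame      # all probes (v1 IDs) x individuals
    nanopore_sites: dict[str, list[CpGSite]]
    truth_records: pd.DataFrame    # long: sample, probe, true beta, depth, n_mod
    bedmethyl_paths: dict[str, Path] = field(default_factory=dict)


def simulate_cohort(config: SimulationConfig, out_dir: str | Path | None = None) -> SimulatedCohort:
    """Run the full generator: manifest, signature, reference matrix, reads.

    With ``out_dir`` set, writes manifest.csv, signature_v1.txt,
    reference_betas.csv (+ sample annotations), truth_records.csv and one
    bedMethyl file per simulated individual.  Deterministic in ``config.seed``.
    """
    from .manifest import map_probe_set_v1_to_v2

    root = np.random.default_rng(config.seed)
    rngs = root.spawn(3)
    manifest, signature_v1 = simulate_manifest(config, rngs[0])
    signature_v2, dropped = map_probe_set_v1_to_v2(signature_v1, manifest)
    reference, truth = simulate_reference_betas(config, manifest, signature_v1, rngs[1])
    out_dir = Path(out_dir) if out_dir is not None else None
    sites, truth_records = simulate_bedmethyl(truth, manifest, config, out_dir, rngs[2])

    paths: dict[str, Path] = {}
    if out_dir is not None:
        write_manifest(manifest, out_dir / "manifest.csv")
        write_probe_set(signature_v1, out_dir / "signature_v1.txt")
        reference.to_csv(out_dir / "reference_betas.csv")
        truth_records.to_csv(out_dir / "truth_records.csv", index=False)
        paths = {b: out_dir / f"{b}.bedmethyl" for b in truth.columns}
        logger.info("wrote cohort fixture to %s (%d probes, %d samples)",
                    out_dir, config.n_probes_total, len(truth.columns))
    return SimulatedCohort(
        config=config, manifest=manifest, signature_v1=signature_v1,
        signature_v2=signature_v2, dropped_probes=dropped, reference=reference,
        truth_betas=truth, nanopore_sites=sites, truth_records=truth_records,
        bedmethyl_paths=paths,
    )
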