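"""Validation experiments: oracle comparisons and planted-signal studies.

These are the package's own end-to-end checks, shared by the test suite and
by ``scripts/acceptance.py``: worked examples on the published numbers,
exact-agreement comparisons between the optimized kernels and the naive
reference implementations, and recovery studies on synthetic loci with
planted ground truth.  Every function takes an explicit seed and is fully
deterministic given it.
"""

from __future__ import annotations

import filecmp
from dataclasses import dataclass

import numpy as np

from .controls import derive_seed, run_screen_with_controls
from .cpg import detect_cpg_islands
from .model import ScreenParams, interval_distance, promoter_region
from .pipeline import run_screen_on_dataset
from .published import LNC140240_LOCUS, PRSS21_TSS
from .reference import (
    brute_force_cpg_islands,
    brute_force_scan,
    enumerate_punp,
)
from .simulate import SimConfig, simulate_locus_set
from .structure import (
    EnergyModel,
    accessible_regions,
    overlap_hits_accessible,
    pair_probabilities,
    unpaired_profile,
)
from .triplex import TriplexHit, scan_triplexes, select_tfo1


def published_distance_bp() -> int:
    """TSS-to-locus distance of the strongest published pair (PRSS21)."""
    return interval_distance(PRSS21_TSS, LNC140240_LOCUS)


def _hit_key(h: TriplexHit) -> tuple:
    return (
        h.tfo,
        (h.tts.chrom, h.tts.start, h.tts.end),
        h.orientation,
        h.dna_strand,
        h.length,
        round(h.identity, 9),
        round(h.stability, 9),
    )


def scan_oracle_agreement(
    n: int = 100, seed: int = 0, max_len: int = 120
) -> float:
    """Fraction of random RNA/DNA pairs where the scan equals brute force."""
    params = ScreenParams()
    rng = np.random.default_rng(derive_seed(seed, "scan_oracle"))
    agree = 0
    for _ in range(n):
        rna = "".join(rng.choice(list("ACGU"), int(rng.integers(50, max_len + 1))))
        dna = "".join(rng.choice(list("ACGT"), int(rng.integers(50, max_len + 1))))
        fast = [_hit_key(h) for h in scan_triplexes(rna, dna, params)]
        slow = [_hit_key(h) for h in brute_force_scan(rna, dna, params)]
        agree += fast == slow
    return agree / n


def punp_oracle_max_error(n: int = 100, seed: int = 0, max_len: int = 25) -> float:
    """Largest per-base |P_unp| deviation from Boltzmann enumeration."""
    model = EnergyModel()
    rng = np.random.default_rng(derive_seed(seed, "punp_oracle"))
    worst = 0.0
    for _ in range(n):
        seq = "".join(rng.choice(list("ACGU"), int(rng.integers(8, max_len + 1))))
        bp = model.boltzmann_matrix(seq)
        punp_dp = 1.0 - pair_probabilities(seq, model).sum(axis=1)
        worst = max(worst, float(np.abs(punp_dp - enumerate_punp(seq, bp)).max()))
    return worst


def cpg_oracle_agreement(n: int = 50, seed: int = 0) -> float:
    """Fraction of random 1-kb sequences with identical island boundaries."""
    rng = np.random.default_rng(derive_seed(seed, "cpg_oracle"))
    agree = 0
    cases = n - 2
    for _ in range(cases):
        seq = "".join(rng.choice(list("ACGT"), 1000, p=[0.15, 0.35, 0.35, 0.15]))
        fast = [
            (isl.interval.start - 1, isl.interval.end - 1)
            for isl in detect_cpg_islands(seq)
        ]
        agree += fast == brute_force_cpg_islands(seq)
    # the two degenerate constructs: saturated CpG repeat, CpG-free repeat
    cg = detect_cpg_islands("CG" * 150)
    agree += (
        len(cg) == 1
        and (cg[0].interval.start, cg[0].interval.end) == (1, 300)
        and abs(cg[0].obs_exp_cpg - 2.0) < 1e-12
    )
    agree += detect_cpg_islands("AT" * 150) == []
    return agree / n


@dataclass
class PlantedRecovery:
    """Outcome of the planted-signal permutation study."""

    n: int
    n_dominant: int          # target count above all three nulls
    min_jaccard: float       # worst plant-boundary recovery among replicates
    mean_jaccard: float

    @property
    def dominance_pct(self) -> float:
        return 100.0 * self.n_dominant / self.n


def _one_locus(seed: int, accessibility: str, tts_length: int):
    config = SimConfig(
        n_genes=1,
        n_planted=1,
        planted_tts_length=(tts_length, tts_length),
        transcript_length=300,
        accessibility_class=accessibility,
        snp_plant="none",
        seed=seed,
    )
    ds = simulate_locus_set(config)
    gene, lnc = ds.genes[0], ds.lncrnas[0]
    region = promoter_region(gene, ds.params)
    prom = ds.genome[region.chrom][region.start - 1 : region.end]
    return ds, gene, lnc, region, prom


def planted_recovery_study(
    n: int = 100, seed: int = 0, tts_length: int = 60
) -> PlantedRecovery:
    """Exposed perfect plants: null dominance and TTS boundary recovery."""
    dominant = 0
    jaccards = []
    for rep in range(n):
        ds, gene, lnc, region, prom = _one_locus(
            derive_seed(seed, "recovery", str(rep)), "exposed", tts_length
        )
        counts = run_screen_with_controls(
            gene.gene_id,
            lnc.transcript_id,
            prom,
            lnc.transcript_seq,
            ds.control_promoter_seq,
            ds.params,
        )
        dominant += counts.target > max(
            counts.shuffled_lncrna, counts.shuffled_target, counts.control
        )
        hits = scan_triplexes(
            lnc.transcript_seq, prom, ds.params, chrom=region.chrom, origin=region.start
        )
        cluster = select_tfo1(hits)
        truth = ds.truths[0].tts_interval
        if cluster.member_hits:
            best = max(cluster.member_hits, key=lambda h: (h.stability, h.length))
            inter = max(
                0, min(best.tts.end, truth.end) - max(best.tts.start, truth.start) + 1
            )
            union = best.tts.length + truth.length - inter
            jaccards.append(inter / union)
        else:
            jaccards.append(0.0)
    return PlantedRecovery(
        n=n,
        n_dominant=dominant,
        min_jaccard=float(min(jaccards)),
        mean_jaccard=float(np.mean(jaccards)),
    )


@dataclass
class AccessibilityDiscrimination:
    """Outcome of the exposed-vs-buried accessibility study."""

    n: int
    n_exposed_accessible: int   # exposed plants with >= 1 accessible hit
    n_buried_inaccessible: int  # buried plants with 0 accessible hits

    @property
    def exposed_pct(self) -> float:
        return 100.0 * self.n_exposed_accessible / self.n

    @property
    def buried_pct(self) -> float:
        return 100.0 * self.n_buried_inaccessible / self.n


def accessibility_discrimination_study(
    n: int = 100, seed: int = 0, tts_length: int = 60
) -> AccessibilityDiscrimination:
    """Accessible-hit counts for exposed vs buried plants under defaults."""

    def accessible_count(rep_seed: int, accessibility: str) -> int:
        ds, gene, lnc, region, prom = _one_locus(rep_seed, accessibility, tts_length)
        hits = scan_triplexes(
            lnc.transcript_seq, prom, ds.params, chrom=region.chrom, origin=region.start
        )
        cluster = select_tfo1(hits)
        profile = unpaired_profile(lnc.transcript_seq, ds.params)
        regions = accessible_regions(profile, ds.params.punp_threshold)
        count, _ = overlap_hits_accessible(list(cluster.member_hits), regions)
        return count

    exposed_ok = 0
    buried_ok = 0
    for rep in range(n):
        exposed_ok += (
            accessible_count(derive_seed(seed, "acc_exposed", str(rep)), "exposed") >= 1
        )
        buried_ok += (
            accessible_count(derive_seed(seed, "acc_buried", str(rep)), "buried") == 0
        )
    return AccessibilityDiscrimination(
        n=n, n_exposed_accessible=exposed_ok, n_buried_inaccessible=buried_ok
    )


def determinism_check(workdir, seed: int = 0) -> bool:
    """Run the full screen twice on one simulated locus set; compare reports."""
    from pathlib import Path

    workdir = Path(workdir)
    config = SimConfig(
        n_genes=2, n_planted=1, planted_tts_length=(60, 60), seed=derive_seed(seed, "e2e")
    )
    ds = simulate_locus_set(config)
    run_screen_on_dataset(ds, outdir=workdir / "run1")
    run_screen_on_dataset(ds, outdir=workdir / "run2")
    names = sorted(p.relative_to(workdir / "run1").as_posix()
                   for p in (workdir / "run1").rglob("*") if p.is_file())
    match, mismatch, errors = filecmp.cmpfiles(
        workdir / "run1", workdir / "run2", names, shallow=False
    )
    return not mismatch and not errors and len(match) == len(names)
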