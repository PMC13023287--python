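"""Synthetic locus sets with planted ground truth.

The generator emulates the screen's real inputs — promoters carrying
triplex target sites, CpG-enriched islands near the TSS, lncRNA loci
within +/-50 kb, transcripts whose triplex-forming stretch is either
structurally exposed or buried, and markers placed inside or outside
lncRNA loci — so every stage can be tested end to end without downloads.

Design of the plants (see docs/methods.md for the rationale):

* TTS patterns are low-complexity tracts, so a planted site produces a
  dense cluster of overlapping hits on shifted diagonals — the signature
  the TFO1 density statistic rewards.
* Both classes plant a G-homopolymer TTS (its minus strand, all C
  columns, supports no triad at all, which keeps the tract's channel
  surface small).
* *Exposed* plants use the canonical parallel TFO — a C-run, which cannot
  base-pair with itself: the transcript stretch stays single-stranded.
* *Buried* plants use a (C5G5)n TFO — still 100% identity against the
  G-run (C scores weight 2, G weight 1) — and the whole buried-class
  transcript is that repeat, folding into strong short-span G:C stems in
  every register: every base, and hence every possible hit, is
  double-stranded (the fold is sequence-deterministic, max P_unp ~0.29).
* Islands are GC-enriched i.i.d. segments planted around the TTS.
* The transcript background composition is chosen so that no
  (orientation, strand) triad channel of the planted tract is attractive
  to random RNA (see TRANSCRIPT_BASE_PROBS).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tsio
from .model import (
    GenomicInterval,
    GeneRecord,
    LncRnaRecord,
    ScreenParams,
    SnpRecord,
    promoter_region,
)
from .triads import TriadTable
from .triplex import TranscriptInterval

logger = logging.getLogger(__name__)

# highest-weight triad partner of each duplex base, and the zero-weight
# substitutes used to place identity mismatches
_MATCH = {
    "parallel": {"A": "U", "G": "C", "T": "G"},
    "antiparallel": {"A": "A", "G": "G"},
}
_MISMATCH = {
    "parallel": {"A": "ACG", "G": "AU", "T": "ACU"},
    "antiparallel": {"A": "G", "G": "ACU"},
}

#: Both plant classes use a G-homopolymer TTS.  Its minus strand is all C
#: columns, and a C:G duplex column supports no triad in either
#: orientation, so the planted tract has exactly two live triad channels
#: (parallel: C weight 2 / G weight 1; antiparallel: G weight 2) — easy to
#: keep quiet against random transcript sequence.
TTS_PATTERN = "G" * 10
#: Buried TFO: C scores weight 2 and G weight 1 against a G:C column, so a
#: (C5G5)n third strand matches the G-run at 100% identity with mean
#: stability 1.5 while folding into strong short-span G:C stems in every
#: register.
BURIED_TFO_PATTERN = "CCCCCGGGGG"
PLANT_PERIOD = 10

#: written into the promoter immediately 5' and 3' of a planted tract:
#: C:G columns support no triad, so hits can neither extend past the plant
#: nor shift into adjacent island G's — the planted boundaries are exact
TTS_BOUNDARY = "CCC"

#: Transcript background base probabilities (A, C, G, U).  A long target
#: tract is a triad-channel magnet: against a G:C column both C (weight 2)
#: and G (weight 1) score in the parallel motif and G (weight 2) in the
#: antiparallel one.  The A/U-rich, C/G-poor background keeps the
#: per-position match rate of every channel well below the 60% identity
#: threshold — otherwise random transcript windows pile up on the planted
#: tract and swamp the permutation contrast.
TRANSCRIPT_BASE_PROBS = (0.45, 0.10, 0.05, 0.40)

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def _revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one synthetic locus set."""

    n_genes: int = 4
    n_lncrnas_per_gene: int = 1
    n_planted: int = 1
    chrom_length: int = 240_000
    #: genomic background GC.  Promoter-proximal DNA is GC-rich, and the
    #: default keeps A/T-rich patches (antiparallel-channel magnets that
    #: attract any transcript) vanishingly rare in scanned regions.
    background_gc: float = 0.60
    #: long enough that even a 150-nt planted pyrimidine TFO leaves the
    #: transcript's overall C fraction too low to feed the parallel channel
    #: of the target tract after shuffling
    transcript_length: int = 700
    planted_tts_length: tuple[int, int] = (51, 150)
    planted_identity: float = 100.0
    accessibility_class: str = "exposed"  # exposed | buried
    orientation: str = "parallel"
    island_plant: bool = True
    snp_plant: str = "inside"  # inside | outside | none
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 < self.background_gc < 1.0:
            raise ValueError("background_gc must be in (0, 1)")
        if self.accessibility_class not in ("exposed", "buried"):
            raise ValueError("accessibility_class must be 'exposed' or 'buried'")
        if self.snp_plant not in ("inside", "outside", "none"):
            raise ValueError("snp_plant must be inside/outside/none")
        lo, hi = self.planted_tts_length
        if lo > hi or lo < 1:
            raise ValueError("invalid planted_tts_length range")


@dataclass(frozen=True)
class TruthRecord:
    """Planted ground truth for one synthetic gene–lncRNA pair."""

    pair_id: str
    planted: bool
    tts_interval: GenomicInterval | None
    tfo_interval: TranscriptInterval | None
    accessibility_class: str | None
    island_interval: GenomicInterval | None
    snp_position: int | None
    intended_tier: str


@dataclass
class SimulatedLocusSet:
    """In-memory result of one simulation (plus optional on-disk copies)."""

    config: SimConfig
    params: ScreenParams
    genome: dict[str, str]
    genes: list[GeneRecord]
    lncrnas: list[LncRnaRecord]
    snps: list[SnpRecord]
    island_intervals: list[GenomicInterval]
    control_chrom: str
    truths: list[TruthRecord] = field(default_factory=list)

    @property
    def control_promoter_seq(self) -> str:
        return self.genome[self.control_chrom]

    def promoter_seq(self, gene: GeneRecord) -> tuple[str, int]:
        """Promoter sequence and its 1-based genomic origin."""
        region = promoter_region(gene, self.params)
        seq = self.genome[region.chrom][region.start - 1 : region.end]
        return seq, region.start


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length, p=list(TRANSCRIPT_BASE_PROBS)))


def _gc_rich_dna(rng: np.random.Generator, length: int) -> str:
    # i.i.d. GC-enriched: obs/exp CpG ~ 1, GC ~ 70% -> robustly detected
    return "".join(rng.choice(list("ACGT"), size=length, p=[0.15, 0.35, 0.35, 0.15]))


def _pick_nonadjacent(rng: np.random.Generator, length: int, k: int) -> list[int]:
    chosen: list[int] = []
    for pos in rng.permutation(length):
        if len(chosen) == k:
            break
        if all(abs(pos - c) > 1 for c in chosen):
            chosen.append(int(pos))
    return sorted(chosen)


def plant_tts(
    promoter_seq: str,
    position: int,
    length: int,
    identity: float,
    orientation: str,
    table: TriadTable | None = None,
    *,
    rng: np.random.Generator | None = None,
    pattern: str = TTS_PATTERN,
    tfo_pattern: str | None = None,
    min_identity: float = 60.0,
) -> tuple[str, str]:
    """Write a TTS repeat into a promoter and return (new promoter, TFO RNA).

    ``position`` is a 0-based offset into ``promoter_seq``.  The returned
    TFO is, by default, the highest-weight triad partner of each duplex
    base for the requested orientation; ``tfo_pattern`` substitutes an
    explicit third-strand repeat (every base of which must form a positive-
    weight triad with its duplex position).  Mismatches bringing identity
    down to the requested value are placed at seeded non-adjacent positions
    and score weight zero.
    """
    if position < 0 or position + length > len(promoter_seq):
        raise ValueError("TTS does not fit inside the promoter sequence")
    if identity < min_identity:
        logger.warning(
            "planted identity %.0f%% is below the scan threshold %.0f%%: "
            "the plant is undetectable by design",
            identity,
            min_identity,
        )
    rng = rng or np.random.default_rng(0)
    table = table or TriadTable.default()
    match = _MATCH[orientation]
    mism = _MISMATCH[orientation]
    tts = (pattern * (length // len(pattern) + 1))[:length]
    if any(b not in match for b in set(tts)):
        raise ValueError(f"pattern {pattern!r} unsupported for {orientation} plants")
    if tfo_pattern is None:
        tfo = [match[b] for b in tts]
    else:
        tfo = list((tfo_pattern * (length // len(tfo_pattern) + 1))[:length])
        for rna_base, duplex_base in zip(tfo, tts):
            if table.weights[(rna_base, duplex_base, orientation)] == 0:
                raise ValueError(
                    f"tfo_pattern base {rna_base} forms no triad with {duplex_base}"
                )
    n_mismatch = round(length * (1.0 - identity / 100.0))
    for pos in _pick_nonadjacent(rng, length, n_mismatch):
        options = mism[tts[pos]]
        tfo[pos] = options[rng.integers(len(options))]
    tfo_seq = "".join(tfo)
    if orientation == "antiparallel":
        tfo_seq = tfo_seq[::-1]
    new_seq = promoter_seq[:position] + tts + promoter_seq[position + length :]
    return new_seq, tfo_seq


def expected_plant_hits(length: int, params: ScreenParams) -> int:
    """Guaranteed minimum TFO1 depth a perfect plant produces.

    Against the G-homopolymer TTS both TFO designs match fully at every
    alignment shift (one reduced hit per diagonal with at least
    ``min_triplex_len`` overlap); the TFO1 count is bounded below by the
    number of shifted hits that still cover the tract's central base.
    """
    if length < params.min_triplex_len:
        return 0
    return 2 * min(length - params.min_triplex_len, (length - 1) // 2) + 1


def _intended_tier(
    planted: bool,
    exposed: bool,
    island: bool,
    detectable: bool,
    expected_hits: int,
    params: ScreenParams,
) -> str:
    if not (planted and detectable):
        return "rejected"
    if exposed and island and expected_hits >= params.min_target_hits:
        return "high_confidence"
    return "partial"


def simulate_locus_set(
    config: SimConfig,
    params: ScreenParams | None = None,
    outdir: str | Path | None = None,
) -> SimulatedLocusSet:
    """Generate a synthetic locus set (and optionally write it to disk).

    One chromosome per gene; the first ``n_planted`` genes carry a TTS
    plant in their promoter, a triad-matched TFO in their lncRNA
    transcript, and (optionally) a CpG island around the TTS.  A separate
    chromosome provides the unrelated control promoter.  Output is fully
    deterministic in (config, params).
    """
    params = params or ScreenParams(seed=config.seed)
    rng = np.random.default_rng(config.seed)
    lo, hi = config.planted_tts_length
    if hi > params.promoter_upstream + params.promoter_downstream:
        raise ValueError("planted TTS longer than the promoter region")

    genome: dict[str, str] = {}
    genes: list[GeneRecord] = []
    lncrnas: list[LncRnaRecord] = []
    snps: list[SnpRecord] = []
    islands: list[GenomicInterval] = []
    truths: list[TruthRecord] = []

    tss = config.chrom_length // 2
    for gi in range(config.n_genes):
        chrom = f"chr{gi + 1}"
        gene_id = f"GENE{gi + 1}"
        planted = gi < config.n_planted
        seq = _random_dna(rng, config.chrom_length, config.background_gc)
        gene = GeneRecord(
            gene_id=gene_id,
            symbol=f"SYN{gi + 1}",
            locus=GenomicInterval(chrom, tss, min(config.chrom_length, tss + 20_000), "+"),
            tss=tss,
        )
        promoter = promoter_region(gene, params)

        tts_iv = None
        tfo_iv = None
        island_iv = None
        tfo_seq = None
        length = 0
        if planted:
            length = int(rng.integers(lo, hi + 1))
            tfo_pattern = (
                None if config.accessibility_class == "exposed" else BURIED_TFO_PATTERN
            )
            # TTS placed mid-promoter (0-based offset within the promoter)
            offset = (promoter.length - length) // 2
            tts_start = promoter.start + offset
            tts_iv = GenomicInterval(chrom, tts_start, tts_start + length - 1, "+")
            if config.island_plant:
                margin = 200
                isl_start = max(1, tts_start - margin)
                isl_end = tts_start + length - 1 + margin
                island_iv = GenomicInterval(chrom, isl_start, isl_end, ".")
                gc_block = _gc_rich_dna(rng, island_iv.length)
                seq = (
                    seq[: isl_start - 1] + gc_block + seq[isl_end:]
                )
            prom_seq = seq[promoter.start - 1 : promoter.end]
            nb = len(TTS_BOUNDARY)
            prom_seq = (
                prom_seq[: offset - nb]
                + TTS_BOUNDARY
                + prom_seq[offset : offset + length]
                + TTS_BOUNDARY
                + prom_seq[offset + length + nb :]
            )
            prom_seq, tfo_seq = plant_tts(
                prom_seq,
                offset,
                length,
                config.planted_identity,
                config.orientation,
                rng=rng,
                tfo_pattern=tfo_pattern,
                min_identity=params.min_identity,
            )
            seq = seq[: promoter.start - 1] + prom_seq + seq[promoter.end :]
        genome[chrom] = seq
        genes.append(gene)

        for li in range(config.n_lncrnas_per_gene):
            transcript_id = f"LNCT{gi + 1}_{li + 1}"
            lnc_gene_id = f"LNCG{gi + 1}_{li + 1}"
            dist = int(rng.integers(5_000, 40_000))
            locus_end = tss - dist
            locus = GenomicInterval(chrom, locus_end - 1_999, locus_end, "+")
            transcript = _random_rna(rng, config.transcript_length)
            this_tfo_iv = None
            if planted and li == 0 and tfo_seq is not None:
                if len(tfo_seq) > config.transcript_length:
                    raise ValueError(
                        f"planted TFO of {len(tfo_seq)} nt does not fit a "
                        f"{config.transcript_length}-nt transcript"
                    )
                if config.accessibility_class == "buried":
                    # the whole buried-class transcript is the self-pairing
                    # repeat, so every possible hit lies in paired sequence
                    n_rep = config.transcript_length // len(BURIED_TFO_PATTERN) + 1
                    transcript = (BURIED_TFO_PATTERN * n_rep)[
                        : config.transcript_length
                    ]
                t_off = (config.transcript_length - len(tfo_seq)) // 2
                transcript = (
                    transcript[:t_off] + tfo_seq + transcript[t_off + len(tfo_seq) :]
                )
                this_tfo_iv = TranscriptInterval(t_off + 1, t_off + len(tfo_seq))
                tfo_iv = this_tfo_iv
            lncrnas.append(
                LncRnaRecord(
                    gene_id=lnc_gene_id,
                    transcript_id=transcript_id,
                    label=f"lncS{gi + 1}_{li + 1}",
                    locus=locus,
                    transcript_seq=transcript,
                )
            )
            if li == 0 and config.snp_plant != "none":
                if config.snp_plant == "inside":
                    pos = (locus.start + locus.end) // 2
                else:
                    pos = locus.end + 5_000
                snps.append(SnpRecord(snp_id=f"SNP{gi + 1}", chrom=chrom, pos=pos))

        if island_iv is not None:
            islands.append(island_iv)
        detectable = config.planted_identity >= params.min_identity
        truths.append(
            TruthRecord(
                pair_id=f"{gene_id}:LNCT{gi + 1}_1",
                planted=planted,
                tts_interval=tts_iv,
                tfo_interval=tfo_iv,
                accessibility_class=config.accessibility_class if planted else None,
                island_interval=island_iv,
                snp_position=snps[-1].pos if config.snp_plant != "none" else None,
                intended_tier=_intended_tier(
                    planted,
                    config.accessibility_class == "exposed",
                    config.island_plant,
                    detectable,
                    expected_plant_hits(length, params),
                    params,
                ),
            )
        )

    control_chrom = "chr_control"
    genome[control_chrom] = _random_dna(
        rng, params.promoter_upstream + params.promoter_downstream + 1, config.background_gc
    )

    dataset = SimulatedLocusSet(
        config=config,
        params=params,
        genome=genome,
        genes=genes,
        lncrnas=lncrnas,
        snps=snps,
        island_intervals=islands,
        control_chrom=control_chrom,
        truths=truths,
    )
    if outdir is not None:
        _write_dataset(dataset, Path(outdir))
    return dataset


def _write_dataset(ds: SimulatedLocusSet, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tsio.write_fasta(outdir / "genome.fasta", ds.genome)
    tsio.write_fasta(
        outdir / "transcripts.fasta",
        {l.transcript_id: l.transcript_seq for l in ds.lncrnas},
    )
    tsio.write_fasta(
        outdir / "control_promoter.fasta", {ds.control_chrom: ds.control_promoter_seq}
    )
    tsio.write_gff3(outdir / "annotation.gff3", ds.genes, ds.lncrnas)
    tsio.write_bed_intervals(
        outdir / "islands.bed",
        [(iv, f"island_{i + 1}") for i, iv in enumerate(ds.island_intervals)],
    )
    tsio.write_vcf_positions(
        outdir / "snps.vcf", ds.snps, {c: len(s) for c, s in ds.genome.items()}
    )
    rows = []
    for t in ds.truths:
        rows.append(
            {
                "pair_id": t.pair_id,
                "planted": t.planted,
                "tts_start": t.tts_interval.start if t.tts_interval else "",
                "tts_end": t.tts_interval.end if t.tts_interval else "",
                "tfo_start": t.tfo_interval.start if t.tfo_interval else "",
                "tfo_end": t.tfo_interval.end if t.tfo_interval else "",
                "accessibility_class": t.accessibility_class or "",
                "island_start": t.island_interval.start if t.island_interval else "",
                "island_end": t.island_interval.end if t.island_interval else "",
                "snp_position": t.snp_position if t.snp_position else "",
                "intended_tier": t.intended_tier,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(json.dumps(rows, indent=2) + "\n")
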