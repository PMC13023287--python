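"""Core coordinate types and screen-wide parameters.

All external coordinates are 1-based inclusive (Ensembl/GFF3 convention):
an interval [start, end] has length ``end - start + 1`` and contains both
endpoints.  Every positional computation in the screen — cis windows,
promoters, SNP co-localization, CpG/TTS overlap — goes through the types
and operations defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")


class ChromosomeMismatchError(ValueError):
    """Raised when a positional comparison is requested across chromosomes."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Strand-aware 1-based inclusive coordinate span.

    Parameters
    ----------
    chrom : str
        Chromosome label (any non-empty string; compared verbatim).
    start, end : int
        1-based inclusive bounds, ``1 <= start <= end``.
    strand : str
        ``"+"``, ``"-"``, or ``"."`` for unstranded.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class GeneRecord:
    """A target gene with its locus and transcription start site."""

    gene_id: str
    symbol: str
    locus: GenomicInterval
    tss: int

    def __post_init__(self) -> None:
        if not self.locus.contains(self.tss):
            raise ValueError(
                f"TSS {self.tss} of {self.gene_id} outside locus "
                f"[{self.locus.start}, {self.locus.end}]"
            )
        if self.locus.strand == ".":
            # Fail-soft on sparse annotations: orient as forward.
            logger.warning("gene %s has no strand; assuming '+'", self.gene_id)
            object.__setattr__(self, "locus", replace(self.locus, strand="+"))

    @property
    def strand(self) -> str:
        return self.locus.strand


@dataclass(frozen=True)
class LncRnaRecord:
    """A lncRNA locus together with its (canonical) transcript sequence."""

    gene_id: str
    transcript_id: str
    label: str
    locus: GenomicInterval
    transcript_seq: str
    validate_length: bool = True

    def __post_init__(self) -> None:
        if not self.transcript_seq:
            raise ValueError(f"{self.transcript_id}: empty transcript sequence")
        seq = self.transcript_seq.upper().replace("T", "U")
        object.__setattr__(self, "transcript_seq", seq)
        if self.validate_length and len(seq) <= 200:
            raise ValueError(
                f"{self.transcript_id}: transcript of {len(seq)} nt is not a lncRNA "
                "(must exceed 200 nt); pass validate_length=False to override"
            )


@dataclass(frozen=True)
class SnpRecord:
    """A significant marker position (e.g. a GWAS hit)."""

    snp_id: str
    chrom: str
    pos: int
    alleles: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class ScreenParams:
    """All tunable parameters of the screen.

    Defaults follow the published operating point: a +/-50 kb cis window
    around each TSS, promoters from 3500 bp upstream to 1500 bp downstream,
    triplex thresholds lg=50 nt / identity 60% / mean stability 1.0,
    accessibility from 70-nt folding windows cut at P_unp >= 0.5, and a
    2-fold enrichment floor over the biological negative control.
    ``min_target_hits`` is the TFO1 density floor of the hierarchical
    filter's primary criterion (see docs/methods.md).
    """

    window_flank: int = 50_000
    promoter_upstream: int = 3_500
    promoter_downstream: int = 1_500
    min_triplex_len: int = 50          # LongTarget-style -lg
    min_identity: float = 60.0         # -i, percent
    min_stability: float = 1.0         # -S, mean triad weight
    punp_threshold: float = 0.5
    fold_window: int = 70              # -W
    fold_span: int = 70                # -L
    enrichment_min_fold: float = 2.0
    min_target_hits: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window_flank", "promoter_upstream", "promoter_downstream"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("min_triplex_len", "fold_window", "fold_span"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")
        if not 0 <= self.punp_threshold <= 1:
            raise ValueError("punp_threshold must be in [0, 1]")
        if self.fold_span > self.fold_window:
            raise ValueError("fold_span (L) must not exceed fold_window (W)")


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base (strand-agnostic)."""
    return a.chrom == b.chrom and max(a.start, b.start) <= min(a.end, b.end)


def interval_distance(point: int, iv: GenomicInterval, *, chrom: str | None = None) -> int:
    """Distance in bp from a point to the nearest edge of an interval.

    0 if the point lies inside the interval.  If ``chrom`` is given it must
    match the interval's chromosome; loci on different chromosomes are
    incomparable.
    """
    if chrom is not None and chrom != iv.chrom:
        raise ChromosomeMismatchError(
            f"cannot measure distance between {chrom} and {iv.chrom}"
        )
    if iv.contains(point):
        return 0
    return min(abs(point - iv.start), abs(point - iv.end))


def promoter_region(gene: GeneRecord, params: ScreenParams) -> GenomicInterval:
    """Strand-aware promoter interval around the TSS, clipped at position 1.

    Upstream/downstream are oriented along the gene: on the minus strand the
    upstream extent runs toward higher coordinates.
    """
    if gene.strand == "+":
        lo = gene.tss - params.promoter_upstream
        hi = gene.tss + params.promoter_downstream
    else:
        lo = gene.tss - params.promoter_downstream
        hi = gene.tss + params.promoter_upstream
    return GenomicInterval(gene.locus.chrom, max(1, lo), hi, gene.strand)


def cis_window(gene: GeneRecord, params: ScreenParams) -> GenomicInterval:
    """Symmetric cis window around the TSS, clipped at position 1."""
    return GenomicInterval(
        gene.locus.chrom,
        max(1, gene.tss - params.window_flank),
        gene.tss + params.window_flank,
        ".",
    )
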