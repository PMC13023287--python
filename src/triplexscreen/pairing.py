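"""Stage 1: cis-window pairing and SNP co-localization.

Each target gene is paired with every lncRNA whose locus overlaps the
gene's +/-50 kb cis window (any overlap, not containment), and significant
marker positions are intersected with lncRNA loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .model import (
    GenomicInterval,
    GeneRecord,
    LncRnaRecord,
    ScreenParams,
    SnpRecord,
    cis_window,
    interval_distance,
    interval_overlap,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenePair:
    """One candidate gene–lncRNA pairing inside a cis window."""

    gene_id: str
    lncrna_transcript_id: str
    distance: int
    window: GenomicInterval


@dataclass(frozen=True)
class SnpColocalization:
    """A marker falling inside a lncRNA locus."""

    snp_id: str
    lncrna_gene_id: str
    inside: bool = True


def select_canonical(lncrnas: list[LncRnaRecord]) -> list[LncRnaRecord]:
    """One transcript per lncRNA gene: the longest (ties: lowest transcript id)."""
    by_gene: dict[str, LncRnaRecord] = {}
    for rec in lncrnas:
        cur = by_gene.get(rec.gene_id)
        if cur is None or (
            (len(rec.transcript_seq), cur.transcript_id)
            > (len(cur.transcript_seq), rec.transcript_id)
        ):
            by_gene[rec.gene_id] = rec
    return [by_gene[g] for g in sorted(by_gene)]


def find_cis_lncrnas(
    genes: list[GeneRecord],
    lncrnas: list[LncRnaRecord],
    params: ScreenParams,
    *,
    canonical_only: bool = True,
) -> list[GenePair]:
    """All (gene, lncRNA) pairs whose locus overlaps the gene's cis window.

    Results are sorted by gene, then ascending TSS-to-locus distance, then
    transcript id.  A lncRNA may pair with several genes when windows
    overlap; all pairs are reported.
    """
    if not genes or not lncrnas:
        logger.info("empty annotation set: no candidate pairs")
        return []
    candidates = select_canonical(lncrnas) if canonical_only else lncrnas
    pairs = []
    for gene in genes:
        window = cis_window(gene, params)
        for lnc in candidates:
            if interval_overlap(window, lnc.locus):
                pairs.append(
                    GenePair(
                        gene_id=gene.gene_id,
                        lncrna_transcript_id=lnc.transcript_id,
                        distance=interval_distance(gene.tss, lnc.locus),
                        window=window,
                    )
                )
    pairs.sort(key=lambda p: (p.gene_id, p.distance, p.lncrna_transcript_id))
    return pairs


def snp_colocalize(
    snps: list[SnpRecord], lncrnas: list[LncRnaRecord]
) -> list[SnpColocalization]:
    """Markers whose position falls within a lncRNA locus (inclusive bounds)."""
    out = []
    for snp in snps:
        for lnc in lncrnas:
            if lnc.locus.chrom == snp.chrom and lnc.locus.contains(snp.pos):
                out.append(SnpColocalization(snp_id=snp.snp_id, lncrna_gene_id=lnc.gene_id))
    return out
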