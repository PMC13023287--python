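"""End-to-end orchestration of the screen over an annotated locus set."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from . import io as tsio
from .controls import run_screen_with_controls
from .cpg import CpGIsland, detect_cpg_islands, overlap_hits_islands
from .model import GeneRecord, LncRnaRecord, ScreenParams, SnpRecord, promoter_region
from .pairing import find_cis_lncrnas, snp_colocalize
from .prioritize import PairEvaluation, evaluate_pair, rank_pairs, render_reports
from .simulate import SimulatedLocusSet
from .structure import (
    EnergyModel,
    accessible_regions,
    overlap_hits_accessible,
    unpaired_profile,
)
from .triads import TriadTable
from .triplex import Tfo1Cluster, scan_triplexes, select_tfo1

logger = logging.getLogger(__name__)


@dataclass
class PairResult:
    """Everything computed for one candidate pair."""

    gene_id: str
    lncrna_transcript_id: str
    cluster: Tfo1Cluster
    evaluation: PairEvaluation


def run_screen(
    genes: list[GeneRecord],
    lncrnas: list[LncRnaRecord],
    snps: list[SnpRecord],
    genome: dict[str, str],
    control_promoter_seq: str,
    params: ScreenParams,
    *,
    table: TriadTable | None = None,
    energy_model: EnergyModel | None = None,
    ingested_islands: list[CpGIsland] | None = None,
    shuffle_mode: str = "mononucleotide",
    outdir: str | Path | None = None,
) -> tuple[list[PairResult], dict[str, Path]]:
    """Run stages 1–6 and (optionally) write the report tables.

    CpG islands are detected on each promoter with the Gardiner-Garden–
    Frommer rule unless an ingested island track is supplied.
    """
    table = table or TriadTable.default()
    energy_model = energy_model or EnergyModel()
    pairs = find_cis_lncrnas(genes, lncrnas, params)
    colocs = snp_colocalize(snps, lncrnas)
    genes_by_id = {g.gene_id: g for g in genes}
    lnc_by_tid = {l.transcript_id: l for l in lncrnas}
    coloc_lnc_genes = {c.lncrna_gene_id for c in colocs}

    profile_cache: dict[str, list] = {}
    results: list[PairResult] = []
    for pair in pairs:
        gene = genes_by_id[pair.gene_id]
        lnc = lnc_by_tid[pair.lncrna_transcript_id]
        region = promoter_region(gene, params)
        prom_seq = genome[region.chrom][region.start - 1 : region.end]

        hits = scan_triplexes(
            lnc.transcript_seq,
            prom_seq,
            params,
            table,
            chrom=region.chrom,
            origin=region.start,
        )
        cluster = select_tfo1(hits)
        counts = run_screen_with_controls(
            gene.gene_id,
            lnc.transcript_id,
            prom_seq,
            lnc.transcript_seq,
            control_promoter_seq,
            params,
            table,
            shuffle_mode=shuffle_mode,
        )

        if ingested_islands is not None:
            islands = [
                isl for isl in ingested_islands if isl.interval.chrom == region.chrom
            ]
        else:
            islands = detect_cpg_islands(
                prom_seq, chrom=region.chrom, origin=region.start
            )
        cpg_count, _ = overlap_hits_islands(list(cluster.member_hits), islands)

        if lnc.transcript_id not in profile_cache:
            profile = unpaired_profile(lnc.transcript_seq, params, energy_model)
            profile_cache[lnc.transcript_id] = accessible_regions(
                profile, params.punp_threshold
            )
        regions = profile_cache[lnc.transcript_id]
        acc_count, _ = overlap_hits_accessible(list(cluster.member_hits), regions)

        evaluation = evaluate_pair(
            gene.gene_id,
            lnc.label,
            counts,
            cpg_count,
            acc_count,
            snp_inside=lnc.gene_id in coloc_lnc_genes,
            params=params,
        )
        results.append(
            PairResult(
                gene_id=gene.gene_id,
                lncrna_transcript_id=lnc.transcript_id,
                cluster=cluster,
                evaluation=evaluation,
            )
        )

    paths: dict[str, Path] = {}
    if outdir is not None:
        outdir = Path(outdir)
        paths = render_reports(
            [r.evaluation for r in results], pairs, colocs, outdir, params
        )
        hits_dir = outdir / "hits"
        hits_dir.mkdir(parents=True, exist_ok=True)
        for r in results:
            stem = f"{r.gene_id}_{r.lncrna_transcript_id}"
            members = list(r.cluster.member_hits)
            tsio.write_hits_bed(hits_dir / f"{stem}.bed", members, stem)
            tsio.write_tsv(hits_dir / f"{stem}.tsv", tsio.hits_to_frame(members))
    return results, paths


def run_screen_on_dataset(
    dataset: SimulatedLocusSet,
    *,
    outdir: str | Path | None = None,
    shuffle_mode: str = "mononucleotide",
) -> tuple[list[PairResult], dict[str, Path]]:
    """Convenience wrapper running the full screen on a simulated locus set."""
    return run_screen(
        dataset.genes,
        dataset.lncrnas,
        dataset.snps,
        dataset.genome,
        dataset.control_promoter_seq,
        dataset.params,
        shuffle_mode=shuffle_mode,
        outdir=outdir,
    )
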