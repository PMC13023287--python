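"""Stage 6: hierarchical filtering into confidence tiers and report tables.

Three criteria are evaluated per pair, in order:

* **A — density & specificity** (primary): the observed TFO1 count strictly
  exceeds both shuffled nulls, is at least ``enrichment_min_fold`` times the
  biological control, and reaches the density floor ``min_target_hits``.
  The floor operationalises "high density of overlapping triplexes": on the
  published screen values it is exactly what separates the three robust
  pairs (22–35 overlapping triplexes) from the next candidate (17).
* **B — accessibility**: at least one hit overlaps a structurally
  accessible region of the transcript.
* **C — regulatory context**: at least one hit overlaps a CpG island.

A pair failing the specificity part of A is ``rejected``; a pair passing
all of A, B and C is ``high_confidence``; anything else is ``partial``.
SNP co-localization is annotated but never changes the tier.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .controls import ControlCounts, enrichment_ratio
from .model import ScreenParams
from .pairing import GenePair, SnpColocalization

TIERS = ("high_confidence", "partial", "rejected")
_TIER_ORDER = {t: i for i, t in enumerate(TIERS)}


@dataclass(frozen=True)
class PairEvaluation:
    """Full evaluation of one gene–lncRNA pair."""

    gene_id: str
    lncrna_id: str
    counts: ControlCounts
    cpg_overlap: int
    accessible_overlap: int
    enrichment: float
    snp_inside: bool
    tier: str
    failed_criteria: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if (self.tier == "high_confidence") != (not self.failed_criteria):
            raise ValueError("high_confidence iff no failed criteria")


def evaluate_pair(
    gene_id: str,
    lncrna_id: str,
    counts: ControlCounts,
    cpg_overlap: int,
    accessible_overlap: int,
    snp_inside: bool,
    params: ScreenParams,
) -> PairEvaluation:
    """Apply the three hierarchical criteria to one pair's numbers."""
    enrichment = enrichment_ratio(counts.target, counts.control)
    failed = []
    specific = (
        counts.target > counts.shuffled_lncrna
        and counts.target > counts.shuffled_target
        and enrichment >= params.enrichment_min_fold
    )
    dense = counts.target >= params.min_target_hits
    if not specific:
        failed.append("A:specificity")
    if not dense:
        failed.append("A:density")
    if accessible_overlap < 1:
        failed.append("B:accessibility")
    if cpg_overlap < 1:
        failed.append("C:cpg_context")
    if not failed:
        tier = "high_confidence"
    elif not specific:
        tier = "rejected"
    else:
        tier = "partial"
    return PairEvaluation(
        gene_id=gene_id,
        lncrna_id=lncrna_id,
        counts=counts,
        cpg_overlap=cpg_overlap,
        accessible_overlap=accessible_overlap,
        enrichment=enrichment,
        snp_inside=snp_inside,
        tier=tier,
        failed_criteria=tuple(failed),
    )


def rank_pairs(evaluations: list[PairEvaluation]) -> list[PairEvaluation]:
    """Deterministic total order: tier, target count desc, enrichment desc, id."""

    def key(ev: PairEvaluation):
        enr = ev.enrichment if math.isfinite(ev.enrichment) else float("1e18")
        return (
            _TIER_ORDER[ev.tier],
            -ev.counts.target,
            -enr,
            ev.gene_id,
            ev.lncrna_id,
        )

    return sorted(evaluations, key=key)


def _fmt_enrichment(value: float) -> str:
    return "inf" if math.isinf(value) else f"{value:.1f}"


def render_reports(
    evaluations: list[PairEvaluation],
    pairs: list[GenePair],
    colocalizations: list[SnpColocalization],
    outdir: str | Path,
    params: ScreenParams,
    *,
    extra_metadata: dict | None = None,
) -> dict[str, Path]:
    """Write the four stage tables, the master evaluation table and run metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ranked = rank_pairs(evaluations)

    t1 = pd.DataFrame(
        [
            {
                "gene": p.gene_id,
                "chrom": p.window.chrom,
                "lncrna_transcript_id": p.lncrna_transcript_id,
                "distance_bp": p.distance,
            }
            for p in pairs
        ],
        columns=["gene", "chrom", "lncrna_transcript_id", "distance_bp"],
    )
    t2 = pd.DataFrame(
        [
            {
                "gene": ev.gene_id,
                "lncrna": ev.lncrna_id,
                "target": ev.counts.target,
                "shuffled_lncrna": ev.counts.shuffled_lncrna,
                "shuffled_target": ev.counts.shuffled_target,
                "control": ev.counts.control,
                "enrichment": _fmt_enrichment(ev.enrichment),
            }
            for ev in ranked
        ],
        columns=[
            "gene",
            "lncrna",
            "target",
            "shuffled_lncrna",
            "shuffled_target",
            "control",
            "enrichment",
        ],
    )
    t3 = pd.DataFrame(
        [
            {
                "pair": f"{ev.gene_id}-{ev.lncrna_id}",
                "hits_overlapping_cpg_islands": ev.cpg_overlap,
            }
            for ev in ranked
        ],
        columns=["pair", "hits_overlapping_cpg_islands"],
    )
    t4 = pd.DataFrame(
        [
            {
                "lncrna": ev.lncrna_id,
                "hits_overlapping_accessible_regions": ev.accessible_overlap,
            }
            for ev in ranked
        ],
        columns=["lncrna", "hits_overlapping_accessible_regions"],
    )
    master = pd.DataFrame(
        [
            {
                "gene": ev.gene_id,
                "lncrna": ev.lncrna_id,
                "target": ev.counts.target,
                "shuffled_lncrna": ev.counts.shuffled_lncrna,
                "shuffled_target": ev.counts.shuffled_target,
                "control": ev.counts.control,
                "enrichment": _fmt_enrichment(ev.enrichment),
                "cpg_overlap": ev.cpg_overlap,
                "accessible_overlap": ev.accessible_overlap,
                "snp_inside": ev.snp_inside,
                "tier": ev.tier,
                "failed_criteria": ";".join(ev.failed_criteria),
            }
            for ev in ranked
        ],
        columns=[
            "gene",
            "lncrna",
            "target",
            "shuffled_lncrna",
            "shuffled_target",
            "control",
            "enrichment",
            "cpg_overlap",
            "accessible_overlap",
            "snp_inside",
            "tier",
            "failed_criteria",
        ],
    )
    coloc = pd.DataFrame(
        [
            {"snp_id": c.snp_id, "lncrna_gene_id": c.lncrna_gene_id, "inside": c.inside}
            for c in colocalizations
        ],
        columns=["snp_id", "lncrna_gene_id", "inside"],
    )

    paths = {}
    for name, df in (
        ("table1_pairs", t1),
        ("table2_controls", t2),
        ("table3_cpg", t3),
        ("table4_accessibility", t4),
        ("evaluations", master),
        ("snp_colocalizations", coloc),
    ):
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path

    metadata = {
        "tool": "triplexscreen",
        "version": __version__,
        "params": {k: v for k, v in vars(params).items()},
        "n_pairs": len(evaluations),
        "n_high_confidence": sum(ev.tier == "high_confidence" for ev in evaluations),
    }
    if extra_metadata:
        metadata.update(extra_metadata)
    meta_path = outdir / "run_metadata.json"
    meta_path.write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")
    paths["run_metadata"] = meta_path
    return paths
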