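"""Hierarchical tiering, ranking and report rendering."""

import json

import pandas as pd
import pytest

from triplexscreen.controls import ControlCounts
from triplexscreen.model import ScreenParams
from triplexscreen.prioritize import evaluate_pair, rank_pairs, render_reports
from triplexscreen.published import HIGH_CONFIDENCE_PAIRS, evaluate_published_pairs


def ev(counts, cpg, acc, params=None, snp=False):
    return evaluate_pair(
        "G", "L", ControlCounts(*counts), cpg, acc, snp, params or ScreenParams()
    )


class TestEvaluatePair:
    def test_strong_specific_pair_is_high_confidence(self):
        """The published PRSS21 pattern: 22 vs 1/2/5, 15 CpG, 22 accessible."""
        assert ev((22, 1, 2, 5), 15, 22).tier == "high_confidence"

    def test_null_dominated_pair_is_rejected(self):
        """Shuffled lncRNA above target (the published lnc85946 pattern)."""
        result = ev((3, 9, 1, 3), 0, 1)
        assert result.tier == "rejected"
        assert "A:specificity" in result.failed_criteria

    def test_specific_but_sparse_pair_is_partial(self):
        """Clear specificity but low density and no CpG context (lnc134182)."""
        result = ev((9, 2, 1, 2), 0, 9)
        assert result.tier == "partial"
        assert "A:density" in result.failed_criteria

    def test_missing_accessibility_blocks_high_confidence(self):
        result = ev((25, 1, 1, 2), 10, 0)
        assert result.tier == "partial"
        assert "B:accessibility" in result.failed_criteria

    def test_snp_annotation_does_not_change_tier(self):
        assert ev((22, 1, 2, 5), 15, 22, snp=True).tier == ev(
            (22, 1, 2, 5), 15, 22, snp=False
        ).tier

    def test_idempotent_pure_function(self):
        assert ev((9, 2, 1, 2), 0, 9) == ev((9, 2, 1, 2), 0, 9)

    def test_raising_enrichment_floor_never_promotes(self):
        order = {"rejected": 0, "partial": 1, "high_confidence": 2}
        for counts in [(22, 1, 2, 5), (35, 4, 2, 14), (6, 2, 2, 3), (3, 1, 1, 0)]:
            lax = ev(counts, 5, 5, ScreenParams(enrichment_min_fold=1.5))
            strict = ev(counts, 5, 5, ScreenParams(enrichment_min_fold=4.0))
            assert order[strict.tier] <= order[lax.tier]


class TestPublishedReproduction:
    def test_exactly_the_three_named_pairs_are_high_confidence(self):
        """The printed per-pair values reproduce the published robust trio."""
        evaluations = evaluate_published_pairs()
        high = {
            (e.gene_id, e.lncrna_id)
            for e in evaluations
            if e.tier == "high_confidence"
        }
        assert high == set(HIGH_CONFIDENCE_PAIRS)

    def test_null_dominated_published_pairs_are_rejected(self):
        tiers = {
            (e.gene_id, e.lncrna_id): e.tier for e in evaluate_published_pairs()
        }
        assert tiers[("ERCC1", "lnc85946")] == "rejected"
        assert tiers[("PRSS21", "lnc86008")] == "rejected"


class TestRankPairs:
    def test_single_pair(self):
        e = ev((22, 1, 2, 5), 15, 22)
        assert rank_pairs([e]) == [e]

    def test_high_confidence_pairs_rank_first(self):
        evaluations = evaluate_published_pairs()
        ranked = rank_pairs(evaluations)
        top = [(e.gene_id, e.lncrna_id) for e in ranked[:3]]
        assert set(top) == set(HIGH_CONFIDENCE_PAIRS)
        # within the top tier, target count decides
        assert [e.counts.target for e in ranked[:3]] == [35, 25, 22]

    def test_all_rejected_ordered_by_count(self):
        a = ev((3, 9, 1, 3), 0, 0)
        b = ev((2, 2, 1, 1), 0, 0)
        assert [e.counts.target for e in rank_pairs([b, a])] == [3, 2]


class TestRenderReports:
    def test_report_files_and_schema(self, tmp_path):
        evaluations = evaluate_published_pairs()
        paths = render_reports(evaluations, [], [], tmp_path, ScreenParams())
        t2 = pd.read_csv(paths["table2_controls"], sep="\t")
        assert list(t2.columns) == [
            "gene", "lncrna", "target", "shuffled_lncrna", "shuffled_target",
            "control", "enrichment",
        ]
        assert len(t2) == 11
        master = pd.read_csv(paths["evaluations"], sep="\t")
        assert len(master) == len(evaluations)
        meta = json.loads(paths["run_metadata"].read_text())
        assert meta["n_high_confidence"] == 3
        assert meta["params"]["min_triplex_len"] == 50

    def test_empty_evaluations_write_headers_only(self, tmp_path):
        paths = render_reports([], [], [], tmp_path, ScreenParams())
        t3 = pd.read_csv(paths["table3_cpg"], sep="\t")
        assert t3.empty and list(t3.columns) == ["pair", "hits_overlapping_cpg_islands"]
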