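"""Diagonal triplex scan and TFO1 density selection."""

import numpy as np
import pytest

from triplexscreen.model import GenomicInterval, ScreenParams
from triplexscreen.reference import brute_force_scan, max_interval_coverage
from triplexscreen.triplex import (
    TranscriptInterval,
    TriplexHit,
    scan_triplexes,
    select_tfo1,
)

from .conftest import random_seq


def hit_keys(hits):
    return [
        (h.tfo, (h.tts.start, h.tts.end), h.orientation, h.dna_strand, h.length,
         round(h.identity, 9), round(h.stability, 9))
        for h in hits
    ]


class TestScan:
    def test_homopolymer_main_diagonal_hit(self, params):
        """A poly-U third strand saturates a poly-A:T duplex tract."""
        hits = scan_triplexes("U" * 60, "A" * 60, params)
        full = [
            h for h in hits
            if h.length == 60 and h.orientation == "parallel" and h.dna_strand == "+"
        ]
        assert len(full) == 1
        assert full[0].identity == 100.0 and full[0].stability == 2.0
        # every emitted hit satisfies its own thresholds
        for h in hits:
            assert h.length >= params.min_triplex_len
            assert h.identity >= params.min_identity
            assert h.stability >= params.min_stability

    def test_unrelated_sequences_give_no_hits(self, params, rng):
        rna = random_seq(rng, 60)
        dna = random_seq(rng, 60, "ACGT")
        # random 60-mers essentially never reach 50 nt at 60% identity
        assert scan_triplexes(rna, dna, params) == brute_force_scan(rna, dna, params)

    def test_too_short_input_rejected(self, params):
        with pytest.raises(ValueError):
            scan_triplexes("U" * 10, "A" * 60, params)

    def test_matches_brute_force_on_random_pairs(self, params, rng):
        for _ in range(25):
            rna = random_seq(rng, int(rng.integers(50, 121)))
            dna = random_seq(rng, int(rng.integers(50, 121)), "ACGT")
            assert hit_keys(scan_triplexes(rna, dna, params)) == hit_keys(
                brute_force_scan(rna, dna, params)
            )

    def test_matches_brute_force_on_planted_pair(self, params):
        rna = "A" * 25 + "U" * 10 + "C" * 60 + "G" * 15 + "A" * 10
        dna = "T" * 20 + "G" * 70 + "A" * 30
        fast = scan_triplexes(rna, dna, params, chrom="c", origin=500)
        assert hit_keys(fast) == hit_keys(
            brute_force_scan(rna, dna, params, chrom="c", origin=500)
        )
        assert fast  # the planted C-run vs G-run tract is found

    def test_reverse_complement_covariance(self, params, rng):
        """Reverse-complementing the duplex relabels strands but keeps TTS coords."""
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(5):
            rna = "U" * 10 + "C" * 55 + random_seq(rng, 35)
            dna = random_seq(rng, 40, "ACGT") + "G" * 60 + random_seq(rng, 20, "ACGT")
            fwd = scan_triplexes(rna, dna, params)
            rev = scan_triplexes(rna, dna.translate(comp)[::-1], params)
            flip = {"+": "-", "-": "+"}
            fwd_set = {
                (h.tfo, (h.tts.start, h.tts.end), h.orientation, h.dna_strand)
                for h in fwd
            }
            rev_set = {
                (h.tfo, (len(dna) - h.tts.end + 1, len(dna) - h.tts.start + 1),
                 h.orientation, flip[h.dna_strand])
                for h in rev
            }
            assert fwd_set == rev_set

    def test_threshold_monotonicity(self, rng):
        """Raising lg, identity or stability never adds hits."""
        rna = "C" * 70 + random_seq(rng, 50)
        dna = random_seq(rng, 30, "ACGT") + "G" * 80 + random_seq(rng, 30, "ACGT")
        base = ScreenParams()
        n_base = len(scan_triplexes(rna, dna, base))
        for stricter in (
            ScreenParams(min_triplex_len=60),
            ScreenParams(min_identity=80.0),
            ScreenParams(min_stability=1.8),
        ):
            assert len(scan_triplexes(rna, dna, stricter)) <= n_base

    def test_ambiguous_bases_score_zero(self, params):
        clean = scan_triplexes("U" * 60, "A" * 60, params)
        with_n = scan_triplexes("U" * 60, "A" * 30 + "N" + "A" * 29, params)
        # the N interrupts the perfect diagonal: fewer/shorter hits, never more
        assert len(with_n) <= len(clean)


def make_hit(start, end, stability=2.0):
    length = end - start + 1
    return TriplexHit(
        tfo=TranscriptInterval(1, length),
        tts=GenomicInterval("c", start, end, "+"),
        orientation="parallel",
        dna_strand="+",
        length=length,
        identity=100.0,
        stability=stability,
    )


class TestSelectTfo1:
    def test_empty(self):
        cluster = select_tfo1([])
        assert cluster.hit_count == 0 and cluster.peak_interval is None

    def test_three_identical_hits(self):
        cluster = select_tfo1([make_hit(100, 160)] * 3)
        assert cluster.hit_count == 3

    def test_disjoint_hits_tie_breaks_leftmost(self):
        cluster = select_tfo1([make_hit(500, 560), make_hit(100, 160)])
        assert cluster.hit_count == 1
        assert cluster.peak_interval.start == 100

    def test_stability_breaks_depth_ties(self):
        cluster = select_tfo1([make_hit(100, 160, 1.2), make_hit(500, 560, 1.9)])
        assert cluster.peak_interval.start == 500

    def test_depth_matches_per_base_counting_oracle(self, rng):
        for _ in range(10):
            hits = [
                make_hit(int(s), int(s) + int(l))
                for s, l in zip(rng.integers(1, 500, 20), rng.integers(50, 120, 20))
            ]
            cluster = select_tfo1(hits)
            assert cluster.hit_count == max_interval_coverage(
                [(h.tts.start, h.tts.end) for h in hits]
            )


def test_hit_invariants_enforced():
    with pytest.raises(ValueError):
        TriplexHit(
            tfo=TranscriptInterval(1, 50),
            tts=GenomicInterval("c", 1, 60),
            orientation="parallel",
            dna_strand="+",
            length=50,
            identity=100.0,
            stability=2.0,
        )
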