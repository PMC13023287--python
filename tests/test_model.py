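"""Coordinate algebra: intervals, distances, promoters and cis windows."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triplexscreen.model import (
    ChromosomeMismatchError,
    GenomicInterval,
    ScreenParams,
    cis_window,
    interval_distance,
    interval_overlap,
    promoter_region,
)
from triplexscreen.published import LNC140240_LOCUS, PRSS21_CPG_ISLAND, PRSS21_TSS

from .conftest import make_gene

intervals = st.builds(
    lambda chrom, start, length: GenomicInterval(chrom, start, start + length),
    chrom=st.sampled_from(["1", "2"]),
    start=st.integers(1, 10_000),
    length=st.integers(0, 5_000),
)


class TestGenomicInterval:
    def test_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("1", 0, 10)
        with pytest.raises(ValueError):
            GenomicInterval("1", 10, 9)
        with pytest.raises(ValueError):
            GenomicInterval("1", 1, 10, "x")
        assert GenomicInterval("1", 5, 5).length == 1

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((10, 20), (20, 30), True),   # shared boundary base, inclusive coords
            ((10, 20), (21, 30), False),  # adjacent but disjoint
            ((10, 20), (12, 15), True),   # containment
        ],
    )
    def test_overlap_examples(self, a, b, expected):
        ia = GenomicInterval("1", *a)
        ib = GenomicInterval("1", *b)
        assert interval_overlap(ia, ib) is expected
        assert interval_overlap(ib, ia) is expected

    def test_overlap_requires_same_chromosome(self):
        assert not interval_overlap(
            GenomicInterval("1", 10, 20), GenomicInterval("2", 10, 20)
        )

    def test_promoter_contains_published_cpg_island(self):
        """The published CpG island lies inside the PRSS21 promoter region."""
        gene = make_gene("PRSS21", "13", PRSS21_TSS)
        promoter = promoter_region(gene, ScreenParams())
        assert promoter.start == 41_170_524 and promoter.end == 41_175_524
        assert interval_overlap(PRSS21_CPG_ISLAND, promoter)

    @given(a=intervals, b=intervals)
    @settings(max_examples=100, deadline=None)
    def test_overlap_symmetric_reflexive(self, a, b):
        assert interval_overlap(a, a)
        assert interval_overlap(a, b) == interval_overlap(b, a)


class TestIntervalDistance:
    def test_published_worked_example(self):
        """TSS-to-locus distance of the strongest published pair is 10,203 bp."""
        assert interval_distance(PRSS21_TSS, LNC140240_LOCUS) == 10_203

    def test_point_inside_is_zero(self):
        assert interval_distance(15, GenomicInterval("1", 10, 20)) == 0

    def test_point_just_past_end(self):
        assert interval_distance(21, GenomicInterval("1", 10, 20)) == 1

    def test_chromosome_mismatch_raises(self):
        with pytest.raises(ChromosomeMismatchError):
            interval_distance(5, GenomicInterval("2", 1, 10), chrom="1")

    @given(point=st.integers(1, 30_000), iv=intervals, shift=st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_zero_iff_inside_and_translation_invariant(self, point, iv, shift):
        d = interval_distance(point, iv)
        assert (d == 0) == iv.contains(point)
        assert interval_distance(point + shift, iv.shifted(shift)) == d


class TestPromoterAndWindow:
    def test_plus_strand_defaults(self):
        gene = make_gene("PRSS21", "13", PRSS21_TSS, "+")
        region = promoter_region(gene, ScreenParams())
        assert (region.start, region.end) == (41_170_524, 41_175_524)

    def test_minus_strand_clips_at_chromosome_start(self):
        gene = make_gene("G", "1", 1000, "-", length=900)
        region = promoter_region(gene, ScreenParams())
        assert (region.start, region.end) == (1, 4500)

    def test_degenerate_zero_extent(self):
        gene = make_gene("G", "1", 5000)
        params = ScreenParams(promoter_upstream=0, promoter_downstream=0)
        region = promoter_region(gene, params)
        assert (region.start, region.end) == (5000, 5000)

    def test_strand_flip_symmetry(self):
        """Minus-strand promoter with swapped extents equals the plus-strand one."""
        plus = promoter_region(
            make_gene("G", "1", 50_000, "+"),
            ScreenParams(promoter_upstream=3500, promoter_downstream=1500),
        )
        minus = promoter_region(
            make_gene("G", "1", 50_000, "-"),
            ScreenParams(promoter_upstream=1500, promoter_downstream=3500),
        )
        assert (plus.start, plus.end) == (minus.start, minus.end)

    @pytest.mark.parametrize(
        "tss, expected",
        [(100_000, (50_000, 150_000)), (10_000, (1, 60_000)),
         (PRSS21_TSS, (41_124_024, 41_224_024))],
    )
    def test_cis_window(self, tss, expected):
        window = cis_window(make_gene("G", "1", tss), ScreenParams())
        assert (window.start, window.end) == expected

    def test_cis_window_length_without_clipping(self):
        params = ScreenParams()
        window = cis_window(make_gene("G", "1", 1_000_000), params)
        assert window.length == 2 * params.window_flank + 1


class TestScreenParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_identity": 0},
            {"min_identity": 101},
            {"punp_threshold": 1.5},
            {"fold_span": 80, "fold_window": 70},
            {"min_triplex_len": 0},
            {"window_flank": -1},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScreenParams(**kwargs)
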