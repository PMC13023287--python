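"""Windowed partition-function accessibility (P_unp) and regions."""

import numpy as np
import pytest

from triplexscreen.model import GenomicInterval, ScreenParams
from triplexscreen.reference import enumerate_punp
from triplexscreen.structure import (
    AccessibilityProfile,
    EnergyModel,
    accessible_regions,
    overlap_hits_accessible,
    pair_probabilities,
    unpaired_profile,
)
from triplexscreen.triplex import TranscriptInterval, TriplexHit

from .conftest import random_seq


class TestPairProbabilities:
    def test_unpairable_sequence_gives_zero_matrix(self):
        assert not pair_probabilities("A" * 20).any()

    def test_simple_hairpin_pairs_terminal_bases(self):
        pm = pair_probabilities("GGGAAACCC")
        assert pm[0, 8] > 0.5
        assert np.allclose(pm, pm.T)
        assert (pm.sum(axis=1) <= 1 + 1e-12).all()

    def test_matches_enumeration_oracle(self, rng):
        model = EnergyModel()
        for _ in range(15):
            n = int(rng.integers(8, 26))
            seq = random_seq(rng, n)
            bp = model.boltzmann_matrix(seq)
            punp_dp = 1.0 - pair_probabilities(seq, model).sum(axis=1)
            assert np.abs(punp_dp - enumerate_punp(seq, bp)).max() < 1e-9

    def test_zero_energies_reduce_to_structure_counting(self, rng):
        """With all pair energies 0 every structure has weight 1."""
        model = EnergyModel(
            pair_energies={
                frozenset({"G", "C"}): 0.0,
                frozenset({"A", "U"}): 0.0,
                frozenset({"G", "U"}): 0.0,
            }
        )
        seq = random_seq(rng, 18)
        bp = model.boltzmann_matrix(seq)
        punp_dp = 1.0 - pair_probabilities(seq, model).sum(axis=1)
        assert np.abs(punp_dp - enumerate_punp(seq, bp)).max() < 1e-9

    def test_disallowed_pairs_rejected(self):
        with pytest.raises(ValueError):
            EnergyModel(pair_energies={frozenset({"A", "C"}): -1.0})


class TestProfile:
    def test_all_a_fully_accessible(self, params):
        profile = unpaired_profile("A" * 120, params)
        assert np.allclose(profile.punp, 1.0)

    def test_short_sequence_equals_single_window(self, params):
        seq = "GGGAAACCCAAAGGGAAACCC"
        profile = unpaired_profile(seq, params)
        single = 1.0 - pair_probabilities(seq, max_span=params.fold_span).sum(axis=1)
        assert np.allclose(profile.punp, single)

    def test_stem_is_less_accessible_than_loop(self, params):
        """8-bp GC stem with a 6-nt A loop: stem buried, loop exposed."""
        seq = "G" * 8 + "A" * 6 + "C" * 8
        profile = unpaired_profile(seq, params)
        stem = np.r_[profile.punp[:8], profile.punp[14:]]
        loop = profile.punp[8:14]
        assert stem.max() < 0.5
        assert loop.mean() > stem.mean()

    def test_values_bounded(self, params, rng):
        profile = unpaired_profile(random_seq(rng, 150), params)
        assert profile.punp.min() >= 0.0 and profile.punp.max() <= 1.0

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            AccessibilityProfile(np.array([0.1, 1.4]), 70, 70)


class TestRegions:
    def test_uniform_one_is_single_region(self):
        profile = AccessibilityProfile(np.ones(50), 70, 70)
        regions = accessible_regions(profile, 0.5)
        assert len(regions) == 1
        assert regions[0].interval == TranscriptInterval(1, 50)

    def test_uniform_zero_is_empty(self):
        assert accessible_regions(AccessibilityProfile(np.zeros(50), 70, 70), 0.5) == []

    def test_threshold_zero_spans_everything(self):
        profile = AccessibilityProfile(np.zeros(30), 70, 70)
        regions = accessible_regions(profile, 0.0)
        assert len(regions) == 1 and regions[0].interval.length == 30

    def test_regions_maximal_disjoint_sorted(self):
        punp = np.array([0.9, 0.9, 0.1, 0.6, 0.6, 0.6, 0.2, 0.8])
        regions = accessible_regions(AccessibilityProfile(punp, 70, 70), 0.5)
        assert [(r.interval.start, r.interval.end) for r in regions] == [
            (1, 2), (4, 6), (8, 8),
        ]
        assert regions[1].mean_punp == pytest.approx(0.6)


def test_overlap_hits_accessible_counts():
    def hit(tfo_start, tfo_end):
        return TriplexHit(
            tfo=TranscriptInterval(tfo_start, tfo_end),
            tts=GenomicInterval("c", 1, tfo_end - tfo_start + 1),
            orientation="parallel",
            dna_strand="+",
            length=tfo_end - tfo_start + 1,
            identity=100.0,
            stability=2.0,
        )

    punp = np.zeros(200)
    punp[99:120] = 1.0
    regions = accessible_regions(AccessibilityProfile(punp, 70, 70), 0.5)
    count, ann = overlap_hits_accessible([hit(1, 60), hit(80, 140)], regions)
    assert count == 1
    assert ann == [[], [0]]
    assert overlap_hits_accessible([hit(1, 60)], [])[0] == 0
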