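"""Synthetic locus generator: plants, truth records, determinism."""

import filecmp

import numpy as np
import pytest

from triplexscreen.model import ScreenParams, promoter_region
from triplexscreen.simulate import (
    SimConfig,
    expected_plant_hits,
    plant_tts,
    simulate_locus_set,
)
from triplexscreen.triplex import scan_triplexes

from .conftest import random_seq


class TestPlantTts:
    def test_perfect_plant_recovered_by_scan(self, params, rng):
        promoter = random_seq(rng, 400, "ACGT")
        new_seq, tfo = plant_tts(promoter, 150, 60, 100.0, "parallel", rng=rng)
        transcript = random_seq(rng, 100) + tfo + random_seq(rng, 100)
        hits = scan_triplexes(transcript, new_seq, params)
        full = [h for h in hits if h.identity == 100.0 and h.length == 60]
        assert any(h.tts.start == 151 and h.tts.end == 210 for h in full)

    def test_subthreshold_identity_plant_is_undetectable(self, params, rng):
        """A 50%-identity plant stays below the 60% scan threshold."""
        promoter = random_seq(rng, 400, "ACGT")
        new_seq, tfo = plant_tts(promoter, 150, 60, 50.0, "parallel", rng=rng)
        transcript = "A" * 100 + tfo + "A" * 100
        assert scan_triplexes(transcript, new_seq, params) == []

    def test_orientations_give_different_tfos(self, rng):
        promoter = "T" * 300
        _, par = plant_tts(promoter, 100, 60, 100.0, "parallel", rng=rng)
        _, anti = plant_tts(promoter, 100, 60, 100.0, "antiparallel", rng=rng)
        assert par != anti  # C-run vs G-run third strand

    def test_plant_must_fit(self, rng):
        with pytest.raises(ValueError):
            plant_tts("ACGT" * 10, 20, 60, 100.0, "parallel", rng=rng)

    def test_low_identity_warns(self, rng, caplog):
        plant_tts("A" * 200, 50, 60, 40.0, "parallel", rng=rng, min_identity=60.0)
        assert any("undetectable" in r.message for r in caplog.records)


class TestSimulateLocusSet:
    def test_truth_records_consistent(self):
        cfg = SimConfig(n_genes=3, n_planted=2, seed=11)
        ds = simulate_locus_set(cfg)
        assert len(ds.truths) == 3
        planted = [t for t in ds.truths if t.planted]
        assert len(planted) == 2
        for t, gene in zip(ds.truths, ds.genes):
            if not t.planted:
                assert t.intended_tier == "rejected"
                continue
            promoter = promoter_region(gene, ds.params)
            assert promoter.start <= t.tts_interval.start
            assert t.tts_interval.end <= promoter.end
            assert t.island_interval is not None

    def test_infeasible_config_raises_before_writing(self):
        params = ScreenParams(promoter_upstream=30, promoter_downstream=10)
        with pytest.raises(ValueError):
            simulate_locus_set(
                SimConfig(planted_tts_length=(100, 100), seed=0), params
            )

    def test_snp_placement_modes(self):
        inside = simulate_locus_set(SimConfig(n_genes=1, snp_plant="inside", seed=5))
        outside = simulate_locus_set(SimConfig(n_genes=1, snp_plant="outside", seed=5))
        locus = inside.lncrnas[0].locus
        assert locus.contains(inside.snps[0].pos)
        assert not outside.lncrnas[0].locus.contains(outside.snps[0].pos)
        none = simulate_locus_set(SimConfig(n_genes=1, snp_plant="none", seed=5))
        assert none.snps == []

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        cfg = SimConfig(n_genes=2, planted_tts_length=(60, 60), seed=77)
        simulate_locus_set(cfg, outdir=tmp_path / "a")
        simulate_locus_set(cfg, outdir=tmp_path / "b")
        names = [p.name for p in (tmp_path / "a").iterdir()]
        assert names
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False
        )
        assert not mismatch and not errors

    def test_buried_transcript_length_and_tfo_position(self):
        cfg = SimConfig(
            n_genes=1, accessibility_class="buried",
            planted_tts_length=(60, 60), seed=3,
        )
        ds = simulate_locus_set(cfg)
        t = ds.truths[0]
        seq = ds.lncrnas[0].transcript_seq
        assert len(seq) == cfg.transcript_length
        assert set(seq) == {"C", "G"}  # fully structured repeat transcript
        assert t.tfo_interval.length == 60

    def test_expected_plant_hits(self, params):
        assert expected_plant_hits(49, params) == 0
        assert expected_plant_hits(50, params) == 1
        assert expected_plant_hits(60, params) == 21
        # long tracts: extreme-shift hits no longer cover the central base
        assert expected_plant_hits(150, params) == 149
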