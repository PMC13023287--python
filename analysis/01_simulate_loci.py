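#!/usr/bin/env python
"""Generate the synthetic locus set used by the downstream analysis stages.

Four genes on separate chromosomes, one of them carrying a planted,
structurally exposed triplex target site with a CpG island around it and a
GWAS-style marker inside the paired lncRNA locus.  Writes FASTA/GFF3/VCF/
BED inputs plus the ground-truth table under results/simulated_loci/.
"""

from pathlib import Path

from triplexscreen.simulate import SimConfig, simulate_locus_set

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "simulated_loci"


def main(seed: int = 1) -> None:
    config = SimConfig(
        n_genes=4,
        n_planted=1,
        planted_tts_length=(60, 60),
        accessibility_class="exposed",
        island_plant=True,
        snp_plant="inside",
        seed=seed,
    )
    dataset = simulate_locus_set(config, outdir=OUTDIR)
    planted = [t for t in dataset.truths if t.planted]
    print(f"simulated {len(dataset.genes)} loci -> {OUTDIR}")
    for t in planted:
        print(
            f"  planted pair {t.pair_id}: TTS {t.tts_interval.start}-"
            f"{t.tts_interval.end}, intended tier {t.intended_tier}"
        )


if __name__ == "__main__":
    main()
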