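# Methods

## Scope and model

`triplexscreen` implements a staged screen for cis-acting lncRNA–gene
regulation via DNA:RNA triplexes.  The unit of positional logic is a
1-based inclusive genomic interval (Ensembl/GFF3 convention; BED input and
output are converted at the boundary).  The stages, their statistics and
their defaults are described below; all defaults live in
`triplexscreen.model.ScreenParams`.

### Cis pairing

A lncRNA is a candidate partner of a gene when its locus overlaps the
symmetric window `TSS ± window_flank` (default 50 kb — window sizes beyond
that are reported to inflate false positives in cis-target assignment).
Membership is *any overlap*, not containment: this is the most permissive
reading consistent with the published distance table, whose largest
distance (49,817 bp) sits just inside the flank.  The reported distance is
from the TSS point to the nearest locus edge (0 inside), which reproduces
the published PRSS21 example (10,203 bp) exactly.  When an annotation
carries several transcripts per lncRNA gene, only the canonical one is
paired; without a canonical tag the longest transcript is taken.  Promoters
are strand-aware (`−3500/+1500` around the TSS, clipped at position 1);
windows are symmetric and therefore strand-agnostic.  Genes without an
annotated strand are treated as forward, with a logged warning.

### Triad table and triplex scan

The scan is an ungapped diagonal search: for each duplex strand (either
strand may serve as the purine-rich strand) and each third-strand
orientation, every RNA-vs-DNA alignment diagonal is scored with a triad
weight table.  The default table assigns weight 2 to the canonical triads
(parallel/pyrimidine motif: U·A:T, C·G:C; antiparallel/purine motif:
A·A:T, G·G:C, U·A:T) and weight 1 to documented weak triads (parallel
G·G:C, G·T:A; antiparallel C·A:T); the table ships as an editable
key-value file because the upstream tool's exact stabilities are not
published.  A window qualifies as a hit when

* length ≥ `min_triplex_len` (50 nt),
* identity = % positions with positive weight ≥ `min_identity` (60 %),
* mean weight ≥ `min_stability` (1.0).

Overlapping qualifying windows on one diagonal describe the same contact
and are reduced to a single hit per overlap-component: the window with the
highest mean stability, ties broken by length then leftmost position.
"Longest qualifying window" was rejected as the representative because the
thresholds leave slack around a strong core — a perfect 60-mer tolerates
tens of random flanking positions before identity or stability break, so
the longest window systematically overshoots the underlying site, whereas
the stability-first rule recovers planted site boundaries exactly.  Scoring
margins are exact at the default thresholds (integer prefix sums; the
pruning step uses a small epsilon only as a conservative superset filter,
with the final checks in exact form).

The **TFO1** is the region of maximal coverage depth over the hits' TTS
intervals (sweep line over endpoints); the cluster is every hit covering
the peak, ties between equal-depth runs broken by higher mean member
stability then leftmost position.  Density is measured on target-DNA
coordinates.  Gap/indel handling and the upstream tool's remaining
parameters are deliberately not reproduced; bit parity with that binary is
a non-goal.

### Permutation and biological nulls

Each pair is re-screened with (i) the shuffled transcript, (ii) the
shuffled promoter, and (iii) an unrelated control promoter (the published
screen used the myostatin promoter from a different chromosome; the
simulator emits a dedicated control chromosome).  The default shuffle is a
seeded mononucleotide permutation — the simplest reading of
"randomized" — with an Altschul–Erickson dinucleotide shuffle available
because CpG density influences triplex tracts.  One shuffle per null
mirrors the single printed null counts; an `n_replicates` option reports
the rounded median.  Shuffle seeds derive deterministically from the run
seed and the pair identifiers (CRC32, < 2^31).  Fold enrichment is
`target/control`, with the conventions 0/0 → 1.0 (no signal) and
n/0 → +inf.

### CpG islands

The detector is the Gardiner-Garden–Frommer rule — 200-bp windows, step 1,
GC ≥ 50 %, obs/exp CpG = `N_CG·L/(N_C·N_G)` ≥ 0.6 — chosen to emulate a
genome browser's precomputed island track; Takai–Jones strictness
(500/55 %/0.65) is available through the same parameters.  Overlapping
qualifying windows are merged and the merged island re-scored (the
re-scored GC/obs-exp of a merged run can in principle dip below the window
thresholds; boundaries are what downstream overlap uses, and they equal the
brute-force window evaluation exactly).  Ingested BED islands bypass
validation and carry a provenance flag.  A hit overlaps an island with ≥ 1
shared base; no minimum-fraction rule.

### Accessibility

Per-base unpaired probabilities are computed RNAplfold-style: sliding
windows of `fold_window` = 70 nt, step 1; within each window a
McCaskill-type inside/outside dynamic programme over pseudoknot-free
structures with hairpin loops ≥ 3 nt and pair span ≤ `fold_span` = 70;
per-base values are averaged over all windows covering the base (the
upstream tool's aggregation is version-dependent; the arithmetic mean is
used).  The energy model is a simple additive base-pair model — GC −3,
AU −2, GU −1 (kcal/mol-like), kT 0.616, lone pairs allowed, no dangles or
loop entropies — *not* the Turner nearest-neighbour model.  The screen
consumes only the binary cut `P_unp ≥ punp_threshold` (0.5), so the design
goal is internal consistency: the windowed DP agrees with brute-force
Boltzmann enumeration of all structures to < 1e−9 per base on every tested
input, and the outside pass is organised through an auxiliary
parent-contribution table so the whole computation is O(n³) per window.
Accessible regions are maximal per-base runs at or above the threshold
(region means are reported but the threshold is applied per base); a hit is
"accessible" when its TFO interval overlaps ≥ 1 region.  Swapping in an
external folding engine is possible by replacing
`structure.pair_probabilities`; such engines are treated as cross-checks,
never as the implementation.

### Hierarchical tiers

Three criteria, evaluated in order and all recorded:

* **A — density & specificity** (primary): target count strictly above
  both shuffled nulls, enrichment ≥ `enrichment_min_fold` (2.0), and
  target count ≥ `min_target_hits` (20).
* **B — accessibility**: ≥ 1 hit in accessible transcript sequence.
* **C — regulatory context**: ≥ 1 hit overlapping a CpG island.

`high_confidence` requires all three; a pair failing the *specificity*
part of A is `rejected`; anything else is `partial`.  The density floor
operationalises "high density of overlapping triplexes" as the primary
criterion: on the published per-pair values it is exactly what separates
the three robust pairs (22–35 overlapping triplexes) from the next
candidate (17) — enrichment, accessibility and CpG context alone would
admit six pairs.  Twenty is the midpoint operating point between those two
groups.  The CpG criterion is kept at ≥ 1 hit because one retained
published pair has only 4 island hits, so any stricter bar would drop it.
SNP co-localization is annotated but never changes a tier.  Tier
assignment is a pure function of the numeric inputs; raising
`enrichment_min_fold` can only demote.

## Synthetic locus generator

The generator (`triplexscreen.simulate`) emulates the screen's real inputs:
per-gene chromosomes (default 240 kb, gene TSS centred), promoters carrying
planted triplex target sites of 51–150 bp (the size range observed for
real predicted sites), CpG-enriched islands (i.i.d. GC ≈ 70 %, obs/exp ≈ 1,
planted ±200 bp around the TTS), lncRNA loci 5–40 kb upstream, transcripts
with the triad-matched TFO embedded, markers inside or outside lncRNA loci,
and a control-promoter chromosome.  Everything is deterministic in
(config, seed) and byte-identical across runs.

Plant design required care, because the scan's triad channels make
low-complexity DNA intrinsically "sticky":

* Against an A:T column, three of four RNA bases score in the antiparallel
  motif; against a G:C column, C (weight 2) and G (weight 1) score in the
  parallel motif.  A long planted tract containing A or T columns therefore
  accumulates marginal 60 %-identity windows from *any* transcript,
  swamping the permutation contrast.  Both plant classes consequently use a
  **G-homopolymer TTS**: its minus strand is all C columns, which support
  no triad at all, leaving exactly two live channels that a suitable
  transcript composition keeps quiet.
* The transcript background is drawn A/U-rich and C/G-poor
  (A 0.45, C 0.10, G 0.05, U 0.40) so neither the parallel channel
  (C + G fraction) nor the antiparallel channel (G fraction) of the tract
  attracts random windows, even after shuffling redistributes the planted
  TFO's pyrimidines (the default transcript length, 700 nt, keeps the
  post-shuffle C fraction low for the largest plants).  The genomic
  background is GC-rich (0.60, promoter-proximal DNA is GC-rich in
  mammals), which also keeps A/T-rich patches — antiparallel-channel
  magnets for any transcript — vanishingly rare in scanned regions.
* The planted tract is bounded by `CCC` on both sides in the promoter:
  dead columns pin the site's boundaries, so the best recovered hit
  matches the planted interval exactly (Jaccard 1.0 in the validation
  studies).
* **Exposed** plants embed the canonical parallel TFO — a C-run, which has
  no Watson–Crick partner within itself and therefore stays
  single-stranded in the folding ensemble.
* **Buried** plants use a (C₅G₅)ₙ TFO — still 100 % identity against the
  G-run, mean stability 1.5 — and the *entire* buried-class transcript is
  that repeat.  A self-contained structured insert unavoidably exposes
  hairpin-loop or leftover-register bases somewhere, and qualifying windows
  can protrude past a planted site while the thresholds still hold, so any
  partially-random buried transcript eventually leaks an accessible hit.
  With the full repeat the fold is sequence-deterministic (max
  P_unp ≈ 0.29 under default energies) and every possible hit lies in
  paired sequence.  The trade-off is that the buried class's shuffled
  nulls are as repeat-rich as the original, so the permutation contrast is
  not a designed property of this class; its asserted properties are
  "no accessible hits" and "never high-confidence".

A perfect exposed plant of length L yields at least
`2·min(L − 50, (L−1)/2) + 1` overlapping hits covering the tract centre
(one per alignment shift of the homopolymer), so a 60-nt plant already
produces a TFO1 density of 21 — above the density floor — which is how the
generator's intended tiers are computed.  Identity-degraded plants place
zero-weight mismatches at seeded non-adjacent positions; a plant below the
identity threshold is undetectable by design and triggers a warning.

What the generator does **not** model: repeats and isochores, realistic
gene structure, linkage disequilibrium, transcription or expression, any
equine-genome mimicry.  Passing tests demonstrate the pipeline's internal
correctness and its behaviour under planted signal and clean nulls — not
performance on real genomes, where sequence composition is far less
benign (the stickiness analysis above is a reminder of how strongly
low-complexity DNA attracts triplex calls at these thresholds).

## Validation studies and problem sizes

The validation suite (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs:

* worked examples on the published coordinates and counts (distance
  10,203 bp; enrichment 22/5 = 4.4; exactly three high-confidence pairs
  among the eleven published ones);
* exact-agreement comparisons against naive reference implementations in
  `triplexscreen.reference` — 100 random RNA/DNA pairs ≤ 120 nt for the
  scan, 100 random sequences ≤ 25 nt for the partition function
  (enumeration over every pseudoknot-free structure), 50 random 1-kb
  sequences plus two degenerate constructs for the CpG detector;
* planted-signal studies at 100 seeded replicates each (60-nt plants,
  300-nt transcripts for speed; TFO1 dominance over all three nulls,
  planted-boundary Jaccard, exposed/buried accessibility discrimination);
* a full end-to-end determinism check (two runs, byte-identical reports).

Numerical notes: the scan uses exact integer margins; the partition
function works in linear (non-log) space, safe for 70-nt windows under the
default energies (Boltzmann factors ≤ 130 per pair, ≤ ~35 pairs per
window, well inside float64 range); ties anywhere (component selection,
TFO1 peaks, ranking) are broken deterministically, and pair-level results
are independent of evaluation order.

## Known limitations

* No gapped alignments in the scan; no pH dependence of C⁺·G:C; no
  thermodynamic triplex energetics.
* The folding model has no loop entropies or stacking; its P_unp values
  are internally consistent but not comparable in absolute terms to a
  nearest-neighbour engine's.
* The CpG detector approximates, but does not claim parity with, any
  particular genome browser's precomputed track.
* Multiple-testing control is out of scope (the screen, like the study it
  models, reports raw counts and a single fold-enrichment per pair).
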