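"""Published values of the equine fertility lncRNA screen (worked examples).

The package ships the printed per-pair numbers of the published screen of
GWAS fertility-candidate genes in Pura Raza Española mares — TFO1
overlapping-triplex counts with their shuffled/control nulls, CpG-island
and accessibility overlap counts, and TSS-to-locus distances — together
with the coordinates of its strongest pair (PRSS21 and the lncRNA
lnc140240 on ECA13).  These serve as inputs for the worked examples and
for reproducing the published confidence tiers; they are not produced by
this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .controls import ControlCounts
from .model import GenomicInterval, ScreenParams
from .prioritize import PairEvaluation, evaluate_pair

#: Coordinates of the strongest published pair (EquCab3.0, chromosome ECA13).
PRSS21_TSS = 41_174_024
PRSS21_GENE_LOCUS = GenomicInterval("13", 41_173_894, 41_211_128, "+")
LNC140240_LOCUS = GenomicInterval("13", 41_160_959, 41_163_821, ".")
PRSS21_CPG_ISLAND = GenomicInterval("13", 41_174_357, 41_175_187, ".")

#: The three pairs the published hierarchical filter retained.
HIGH_CONFIDENCE_PAIRS = (
    ("PRSS21", "lnc140240"),
    ("HTRA3", "lnc82066"),
    ("ERCC1", "lnc129946"),
)


def load_published_screen() -> pd.DataFrame:
    """Per-pair published screen values as a DataFrame (11 pairs)."""
    with resources.files("triplexscreen.data").joinpath("published_screen.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def evaluate_published_pairs(params: ScreenParams | None = None) -> list[PairEvaluation]:
    """Run the hierarchical filter on the published per-pair values."""
    params = params or ScreenParams()
    df = load_published_screen()
    out = []
    for row in df.itertuples(index=False):
        counts = ControlCounts(
            target=int(row.target),
            shuffled_lncrna=int(row.shuffled_lncrna),
            shuffled_target=int(row.shuffled_target),
            control=int(row.control),
        )
        out.append(
            evaluate_pair(
                gene_id=str(row.gene),
                lncrna_id=str(row.lncrna),
                counts=counts,
                cpg_overlap=int(row.cpg_hits),
                accessible_overlap=int(row.accessible_hits),
                snp_inside=bool(row.snp_inside),
                params=params,
            )
        )
    return out
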