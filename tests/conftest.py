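import numpy as np
import pytest

from triplexscreen.model import (
    GenomicInterval,
    GeneRecord,
    LncRnaRecord,
    ScreenParams,
)


@pytest.fixture(scope="session")
def params() -> ScreenParams:
    return ScreenParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_gene(
    gene_id="G1", chrom="1", tss=100_000, strand="+", length=20_000
) -> GeneRecord:
    lo, hi = (tss, tss + length) if strand == "+" else (tss - length, tss)
    return GeneRecord(
        gene_id=gene_id,
        symbol=gene_id,
        locus=GenomicInterval(chrom, max(1, lo), hi, strand),
        tss=tss,
    )


def make_lncrna(
    gene_id="L1", transcript_id="T1", chrom="1", start=90_000, end=92_000, seq=None
) -> LncRnaRecord:
    return LncRnaRecord(
        gene_id=gene_id,
        transcript_id=transcript_id,
        label=transcript_id.lower(),
        locus=GenomicInterval(chrom, start, end, "+"),
        transcript_seq=seq or ("ACGU" * 70),
    )


def random_seq(rng: np.random.Generator, n: int, alphabet="ACGU") -> str:
    return "".join(rng.choice(list(alphabet), size=n))
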