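"""Readers and writers for the formats the screen touches.

External conventions: FASTA for sequences, GFF3 (1-based inclusive) for
annotations, BED (0-based half-open, converted on read/write) for islands
and TTS tracks, VCF or 3-column TSV for marker positions, TSV for reports.
Internally everything is 1-based inclusive.  Sequences are case-folded to
upper on read; transcripts are normalised to the RNA alphabet, genomic
sequences to DNA.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cpg import CpGIsland
from .model import GenomicInterval, GeneRecord, LncRnaRecord, SnpRecord
from .triplex import TriplexHit

logger = logging.getLogger(__name__)


def read_fasta(path: str | Path, *, molecule: str | None = None) -> dict[str, str]:
    """Read FASTA into {id: sequence}; molecule 'dna'/'rna' normalises T/U."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if molecule == "dna":
            seq = seq.replace("U", "T")
        elif molecule == "rna":
            seq = seq.replace("T", "U")
        records[rec.id] = seq
    return records


def write_fasta(path: str | Path, records: dict[str, str], *, width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_gff3(
    path: str | Path,
    *,
    transcripts: dict[str, str] | None = None,
    tss_override: dict[str, int] | None = None,
    validate_lncrna_length: bool = True,
) -> tuple[list[GeneRecord], list[LncRnaRecord]]:
    """Parse gene and lnc_RNA features into screen records.

    Gene TSS defaults to the 5' end of the gene feature (strand-aware) and
    can be overridden per gene id via ``tss_override``.  lnc_RNA features
    need ``ID`` (transcript id) and ``Parent`` or ``geneID`` attributes;
    their sequences are looked up in ``transcripts`` by transcript id.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    tss_override = tss_override or {}
    genes: list[GeneRecord] = []
    lncrnas: list[LncRnaRecord] = []
    for feat in db.all_features():
        if feat.featuretype == "gene":
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            symbol = feat.attributes.get("Name", [gene_id])[0]
            strand = feat.strand if feat.strand in "+-" else "."
            locus = GenomicInterval(feat.seqid, feat.start, feat.end, strand)
            tss = tss_override.get(
                gene_id, feat.start if strand != "-" else feat.end
            )
            genes.append(GeneRecord(gene_id=gene_id, symbol=symbol, locus=locus, tss=tss))
        elif feat.featuretype == "lnc_RNA":
            transcript_id = feat.attributes.get("ID", [feat.id])[0]
            parent = feat.attributes.get("Parent", [transcript_id])[0]
            label = feat.attributes.get("Name", [transcript_id])[0]
            seq = (transcripts or {}).get(transcript_id, "")
            if not seq:
                raise ValueError(
                    f"no transcript sequence provided for lnc_RNA {transcript_id!r}"
                )
            strand = feat.strand if feat.strand in "+-" else "."
            lncrnas.append(
                LncRnaRecord(
                    gene_id=parent,
                    transcript_id=transcript_id,
                    label=label,
                    locus=GenomicInterval(feat.seqid, feat.start, feat.end, strand),
                    transcript_seq=seq,
                    validate_length=validate_lncrna_length,
                )
            )
    return genes, lncrnas


def write_gff3(
    path: str | Path, genes: list[GeneRecord], lncrnas: list[LncRnaRecord]
) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append(
            "\t".join(
                [
                    g.locus.chrom,
                    "triplexscreen",
                    "gene",
                    str(g.locus.start),
                    str(g.locus.end),
                    ".",
                    g.locus.strand,
                    ".",
                    f"ID={g.gene_id};Name={g.symbol}",
                ]
            )
        )
    for l in lncrnas:
        lines.append(
            "\t".join(
                [
                    l.locus.chrom,
                    "triplexscreen",
                    "lnc_RNA",
                    str(l.locus.start),
                    str(l.locus.end),
                    ".",
                    l.locus.strand if l.locus.strand in "+-" else ".",
                    ".",
                    f"ID={l.transcript_id};Parent={l.gene_id};Name={l.label}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed_intervals(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """BED4 records as 1-based inclusive intervals with names."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
        chrom, start0, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else f"region_{lineno}"
        out.append((GenomicInterval(chrom, start0 + 1, end, "."), name))
    return out


def read_bed_islands(path: str | Path) -> list[CpGIsland]:
    """Ingest a CpG-island BED track (provenance-flagged, no re-validation)."""
    return [
        CpGIsland(interval=iv, gc_percent=float("nan"), obs_exp_cpg=float("nan"),
                  from_detector=False)
        for iv, _ in read_bed_intervals(path)
    ]


def write_bed_intervals(
    path: str | Path, entries: list[tuple[GenomicInterval, str]]
) -> None:
    lines = [
        f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}" for iv, name in entries
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_hits_bed(path: str | Path, hits: list[TriplexHit], name: str) -> None:
    """BED6 TTS track; score = round(10 * stability)."""
    lines = []
    for h in hits:
        lines.append(
            "\t".join(
                [
                    h.tts.chrom,
                    str(h.tts.start - 1),
                    str(h.tts.end),
                    name,
                    str(round(10 * h.stability)),
                    h.dna_strand,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def hits_to_frame(hits: list[TriplexHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tts_chrom": h.tts.chrom,
                "tts_start": h.tts.start,
                "tts_end": h.tts.end,
                "tfo_start": h.tfo.start,
                "tfo_end": h.tfo.end,
                "orientation": h.orientation,
                "dna_strand": h.dna_strand,
                "length": h.length,
                "identity": round(h.identity, 2),
                "stability": round(h.stability, 3),
            }
            for h in hits
        ],
        columns=[
            "tts_chrom",
            "tts_start",
            "tts_end",
            "tfo_start",
            "tfo_end",
            "orientation",
            "dna_strand",
            "length",
            "identity",
            "stability",
        ],
    )


def read_vcf_positions(path: str | Path) -> list[SnpRecord]:
    """Marker ids and positions from a (plain-text) VCF."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch():
            alleles = None
            if rec.ref and rec.alts:
                alleles = (rec.ref, rec.alts[0])
            out.append(
                SnpRecord(
                    snp_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    chrom=rec.chrom,
                    pos=rec.pos,
                    alleles=alleles,
                )
            )
    return out


def write_vcf_positions(path: str | Path, snps: list[SnpRecord], contigs: dict[str, int]) -> None:
    lines = ["##fileformat=VCFv4.2"]
    for chrom, length in contigs.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for s in snps:
        ref, alt = s.alleles if s.alleles else ("A", "G")
        lines.append(f"{s.chrom}\t{s.pos}\t{s.snp_id}\t{ref}\t{alt}\t.\t.\t.")
    Path(path).write_text("\n".join(lines) + "\n")


def read_snp_tsv(path: str | Path) -> list[SnpRecord]:
    """3-column TSV (snp_id, chrom, pos) alternative to VCF."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        SnpRecord(snp_id=str(r.snp_id), chrom=str(r.chrom), pos=int(r.pos))
        for r in df.itertuples(index=False)
    ]


def write_tsv(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def load_run_config(path: str | Path) -> dict:
    """YAML run configuration: input paths, parameter overrides, toggles."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    return cfg
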