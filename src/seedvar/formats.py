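"""Readers/writers for FASTA, GFF3, VCF, BED and the tabular files, plus the
shared genomic coordinate model.

All in-memory coordinates are 0-based half-open.  GFF3 and VCF are 1-based
inclusive on disk; the conversion happens exactly once, here, at the I/O
boundary.  BED is already 0-based half-open and passes through unchanged.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Malformed record or file; message names the offending line/record."""


class ValidationError(ValueError):
    """Record parsed but violates a model invariant (bounds, alphabet...)."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

_ALPHABET = set("ACGTN")


@dataclass
class Genome:
    """Reference sequences keyed by chromosome id (uppercase A/C/G/T/N)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for chrom, seq in self.sequences.items():
            if set(seq) - _ALPHABET:
                bad = sorted(set(seq) - _ALPHABET)
                raise ValidationError(f"{chrom}: non-ACGTN characters {bad}")

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end), 0-based half-open."""
        if chrom not in self.sequences:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        if not (0 <= start <= end <= len(self.sequences[chrom])):
            raise ValidationError(
                f"[{start},{end}) out of bounds for {chrom} "
                f"(length {len(self.sequences[chrom])})"
            )
        return self.sequences[chrom][start:end]


@dataclass
class GeneModel:
    """Single-transcript gene model.

    ``exons`` are sorted, non-overlapping [start, end) intervals in genome
    coordinates; ``cds_segments`` are (start, end, phase) triples contained in
    exons.  ``tss`` is the transcription start: ``start`` on '+', ``end - 1``
    on '-'.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds_segments: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValidationError(f"{self.gene_id}: empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"{self.gene_id}: exons overlap/unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds_segments)

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Genomic [start, end) gaps between consecutive exons."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def cds_sequence(self, genome: Genome) -> str:
        """Spliced CDS in transcript orientation (starts at the initiator)."""
        parts = [genome.fetch(self.chrom, s, e) for s, e, _ in self.cds_segments]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class VariantCall:
    """One cultivar's call at one site: the unit the depth/fraction filters
    act on.  ``pos`` is 0-based (VCF POS - 1)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    cultivar: str
    depth: int
    alt_fraction: float

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError("position must be >= 0")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValidationError("ref/alt must be non-empty and differ")
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise ValidationError("alt_fraction outside [0,1]")


@dataclass
class QTLInterval:
    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"QTL {self.name}: start >= end")


@dataclass
class TissuePanel:
    """The ordered tissue columns with their seed/stage metadata."""

    labels: list[str]
    is_seed: dict[str, bool]
    stage: dict[str, str | None]  # 'S1'..'S7' for seed columns, else None

    def seed_labels(self) -> list[str]:
        return [t for t in self.labels if self.is_seed[t]]

    def validate(self) -> None:
        for t in self.labels:
            if t not in self.is_seed or t not in self.stage:
                raise ValidationError(f"tissue {t!r} lacks seed/stage metadata")


@dataclass
class ExpressionMatrix:
    """Genes x tissues FPKM matrix plus the tissue panel metadata."""

    values: pd.DataFrame  # index: gene_id, columns: tissue labels
    panel: TissuePanel

    def __post_init__(self) -> None:
        if list(self.values.columns) != self.panel.labels:
            raise ValidationError("matrix columns do not match tissue panel")
        if self.values.isna().any().any():
            raise ValidationError("expression matrix has missing cells")
        if (self.values.values < 0).any():
            raise ValidationError("negative FPKM")
        self.panel.validate()


@dataclass
class CoverageTrack:
    """Per-cultivar read depth: a flat default plus sparse exceptions.

    Stands in for genome-wide coverage when deciding whether a cultivar with
    no variant record can be trusted as homozygous reference at a site.
    """

    default_depth: int
    exceptions: dict[tuple[str, str, int], int] = field(default_factory=dict)

    def depth(self, cultivar: str, chrom: str, pos: int) -> int:
        return self.exceptions.get((cultivar, chrom, pos), self.default_depth)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> Genome:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise FormatError(f"{path}: no FASTA records")
    return Genome(seqs)


def write_fasta(genome: Genome, path: str | os.PathLike, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into GeneModel records.

    One transcript per gene is assumed (the canonical-transcript convention);
    a gene with several mRNAs raises.
    """
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="error", keep_order=True
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise FormatError(f"{path}: {exc}") from exc
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(g, featuretype="mRNA"))
        if len(mrnas) != 1:
            raise FormatError(
                f"{g.id}: expected exactly one mRNA, found {len(mrnas)}"
            )
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.children(mrnas[0], featuretype="exon")
        )
        cds = sorted(
            (f.start - 1, f.end, int(f.frame))
            for f in db.children(mrnas[0], featuretype="CDS")
        )
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start - 1,
                end=g.end,
                exons=exons,
                cds_segments=cds,
            )
        )
    return genes


def write_gff3(genes: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            def line(ftype: str, s: int, e: int, phase: str, attrs: str) -> str:
                return (
                    f"{g.chrom}\tseedvar\t{ftype}\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t{phase}\t{attrs}\n"
                )

            mrna_id = f"{g.gene_id}.t1"
            fh.write(line("gene", g.start, g.end, ".", f"ID={g.gene_id}"))
            fh.write(
                line("mRNA", g.start, g.end, ".",
                     f"ID={mrna_id};Parent={g.gene_id}")
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    line("exon", s, e, ".",
                         f"ID={mrna_id}.exon{i};Parent={mrna_id}")
                )
            for i, (s, e, phase) in enumerate(g.cds_segments, 1):
                fh.write(
                    line("CDS", s, e, str(phase),
                         f"ID={mrna_id}.cds{i};Parent={mrna_id}")
                )


# ---------------------------------------------------------------------------
# VCF (v4.2, INFO DP + AF, one alternate allele per record)
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike, cultivar: str) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(
                    f"{path}: {rec.chrom}:{rec.pos} is not biallelic; "
                    "multi-allelic records are not supported"
                )
            info = rec.info
            if "DP" not in info or "AF" not in info:
                raise FormatError(
                    f"{path}: {rec.chrom}:{rec.pos} lacks DP/AF INFO fields"
                )
            af = info["AF"]
            if isinstance(af, tuple):
                af = af[0]
            calls.append(
                VariantCall(
                    chrom=rec.chrom,
                    pos=rec.pos - 1,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    cultivar=cultivar,
                    depth=int(info["DP"]),
                    # undo float32 drift (0.9 must still satisfy >= 0.9)
                    alt_fraction=round(float(af), 6),
                )
            )
    return calls


def write_vcf(
    calls: list[VariantCall],
    path: str | os.PathLike,
    contig_lengths: dict[str, int],
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        )
        fh.write(
            '##INFO=<ID=AF,Number=A,Type=Float,'
            'Description="Alternate allele fraction">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\t.\t"
                f"DP={c.depth};AF={c.alt_fraction:g}\n"
            )


def write_diff_vcf(diffs, path, contig_lengths) -> None:
    """Write group-differentiating variants with CLASS and group-allele tags."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="Variant class">\n')
        fh.write('##INFO=<ID=SMALL_ALLELE,Number=1,Type=String,Description="Allele carried by the small-seeded group">\n')
        fh.write('##INFO=<ID=LARGE_ALLELE,Number=1,Type=String,Description="Allele carried by the large-seeded group">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for d in sorted(diffs, key=lambda d: (d.chrom, d.pos)):
            alts = sorted({a for a in (d.small_allele, d.large_allele) if a != d.ref})
            fh.write(
                f"{d.chrom}\t{d.pos + 1}\t.\t{d.ref}\t{','.join(alts)}\t.\t.\t"
                f"CLASS={d.variant_class};SMALL_ALLELE={d.small_allele};"
                f"LARGE_ALLELE={d.large_allele}\n"
            )


# ---------------------------------------------------------------------------
# BED (0-based half-open on disk and in memory)
# ---------------------------------------------------------------------------

def read_bed(path: str | os.PathLike) -> list[QTLInterval]:
    out: list[QTLInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer bounds") from exc
            name = fields[3] if len(fields) > 3 else f"interval{lineno}"
            out.append(QTLInterval(fields[0], start, end, name))
    return out


def write_bed(intervals: list[QTLInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda iv: (iv.chrom, iv.start)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


# ---------------------------------------------------------------------------
# expression / tissue metadata / DE / coverage tables
# ---------------------------------------------------------------------------

def read_expression(
    path: str | os.PathLike, tissue_meta_path: str | os.PathLike
) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(tissue_meta_path, sep="\t")
    panel = TissuePanel(
        labels=list(meta["tissue"]),
        is_seed={r.tissue: bool(r.is_seed) for r in meta.itertuples()},
        stage={
            r.tissue: (None if pd.isna(r.stage) or r.stage == "." else r.stage)
            for r in meta.itertuples()
        },
    )
    return ExpressionMatrix(values=values, panel=panel)


def write_expression(
    matrix: ExpressionMatrix,
    path: str | os.PathLike,
    tissue_meta_path: str | os.PathLike,
) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.4f")
    rows = [
        {
            "tissue": t,
            "is_seed": int(matrix.panel.is_seed[t]),
            "stage": matrix.panel.stage[t] or ".",
        }
        for t in matrix.panel.labels
    ]
    pd.DataFrame(rows).to_csv(tissue_meta_path, sep="\t", index=False)


def read_de_table(path: str | os.PathLike) -> pd.DataFrame:
    """Columns: gene_id, stage, log2fc (large vs small), q."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "stage", "log2fc", "q"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {required - set(df.columns)}")
    return df


def write_de_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_coverage(path: str | os.PathLike) -> CoverageTrack:
    """Sparse depth exceptions over a flat default.

    First line ``#default_depth=<int>``; then TSV columns
    cultivar, chrom, pos (1-based, matching VCF POS), depth.
    """
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#default_depth="):
            raise FormatError(f"{path}: missing #default_depth header")
        default_depth = int(header.split("=", 1)[1])
        body = fh.read()
    exceptions: dict[tuple[str, str, int], int] = {}
    if body.strip():
        df = pd.read_csv(io.StringIO(body), sep="\t")
        for r in df.itertuples():
            exceptions[(r.cultivar, r.chrom, int(r.pos) - 1)] = int(r.depth)
    return CoverageTrack(default_depth=default_depth, exceptions=exceptions)


def write_coverage(track: CoverageTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"#default_depth={track.default_depth}\n")
        fh.write("cultivar\tchrom\tpos\tdepth\n")
        for (cultivar, chrom, pos), depth in sorted(track.exceptions.items()):
            fh.write(f"{cultivar}\t{chrom}\t{pos + 1}\t{depth}\n")


def read_categories(path: str | os.PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene_id"], df["category"]))


def write_categories(categories: dict[str, str], path: str | os.PathLike) -> None:
    pd.DataFrame(
        sorted(categories.items()), columns=["gene_id", "category"]
    ).to_csv(path, sep="\t", index=False)
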