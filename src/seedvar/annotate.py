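"""Region and coding-consequence annotation of differentiating variants, and
the genome-wide summary statistics built on them (Ts/Tv spectrum, InDel
length spectrum, 100-kb window frequencies, highly polymorphic genes).

Consequence severity follows the precedence
``splice_site > start_loss > stop_gain > frameshift > non_synonymous >
synonymous``; the first three plus frameshift make up the *large-effect*
category.  stop_gain is reserved for frame-preserving changes: a change
whose net CDS length shift is not a multiple of three is a frameshift even
when the shifted reading frame happens to terminate early.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .formats import GeneModel, Genome, ValidationError
from .variant_core import COMPLEX, INDEL, MNP, SNP, DiffVariant

PROMOTER_BP = 2000
SPLICE_WINDOW_BP = 2
WINDOW_BP = 100_000

PROMOTER = "promoter"
EXON = "exon"
INTRON = "intron"
INTERGENIC = "intergenic"

SYNONYMOUS = "synonymous"
NON_SYNONYMOUS = "non_synonymous"
LARGE_EFFECT = "large_effect"
NON_CODING = "non_coding"

FRAMESHIFT = "frameshift"
START_LOSS = "start_loss"
STOP_GAIN = "stop_gain"
SPLICE_SITE = "splice_site"


class ContractError(ValueError):
    pass


@dataclass
class RegionLabel:
    region: str  # promoter | exon | intron | intergenic
    gene_id: str | None  # None iff intergenic


@dataclass
class Consequence:
    effect: str  # synonymous | non_synonymous | large_effect | non_coding
    subtype: str | None = None  # frameshift|start_loss|stop_gain|splice_site


@dataclass
class AnnotatedVariant:
    variant: DiffVariant
    region: str
    gene_id: str | None
    effect: str | None  # None for variants outside genes
    subtype: str | None


@dataclass
class WindowStat:
    chrom: str
    start: int
    end: int
    counts: dict[str, int]  # per variant class
    frequency: float  # variants per 100 kb, normalized by actual tile length

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class GeneVariantSummary:
    gene_id: str
    region_counts: dict[str, int]  # promoter/exon/intron hits on this gene
    effect_counts: dict[str, int]
    exonic_density_per_kb: float
    intronic_density_per_kb: float


# ---------------------------------------------------------------------------
# region assignment
# ---------------------------------------------------------------------------

class GeneIndex:
    """Interval indexes over exons, gene spans and strand-aware promoters."""

    def __init__(self, genes: list[GeneModel], promoter_bp: int = PROMOTER_BP):
        self.genes = {g.gene_id: g for g in genes}
        self.promoter_bp = promoter_bp
        self._exons: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._spans: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._promoters: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for g in genes:
            self._spans[g.chrom].addi(g.start, g.end, g.gene_id)
            for s, e in g.exons:
                self._exons[g.chrom].addi(s, e, g.gene_id)
            if g.strand == "+":
                ps, pe = max(0, g.start - promoter_bp), g.start
            else:
                ps, pe = g.end, g.end + promoter_bp
            if ps < pe:
                self._promoters[g.chrom].addi(ps, pe, g.gene_id)

    def _nearest_by_tss(self, gene_ids: set[str], pos: int) -> str:
        return min(
            sorted(gene_ids),
            key=lambda gid: (abs(self.genes[gid].tss - pos), gid),
        )

    def assign_region(self, v: DiffVariant) -> RegionLabel:
        """Label by the variant's reference span with precedence
        exon > intron > promoter > intergenic; gene ties broken by nearest
        TSS, then lexicographic gene id."""
        span = (v.pos, v.pos + len(v.ref))
        hits = {iv.data for iv in self._exons[v.chrom].overlap(*span)}
        if hits:
            return RegionLabel(EXON, self._nearest_by_tss(hits, v.pos))
        hits = {iv.data for iv in self._spans[v.chrom].overlap(*span)}
        if hits:
            return RegionLabel(INTRON, self._nearest_by_tss(hits, v.pos))
        hits = {iv.data for iv in self._promoters[v.chrom].overlap(*span)}
        if hits:
            return RegionLabel(PROMOTER, self._nearest_by_tss(hits, v.pos))
        return RegionLabel(INTERGENIC, None)


def assign_region(
    v: DiffVariant, genes: list[GeneModel], promoter_bp: int = PROMOTER_BP
) -> RegionLabel:
    return GeneIndex(genes, promoter_bp).assign_region(v)


# ---------------------------------------------------------------------------
# coding consequence
# ---------------------------------------------------------------------------

def _alt_cds_segments(
    gene: GeneModel, pos: int, ref_len: int, alt_len: int
) -> list[tuple[int, int]]:
    """CDS segment coordinates on the mutated chromosome.

    The mutated chromosome equals ``chrom[:pos] + alt + chrom[pos+ref_len:]``;
    positions at or before ``pos`` are unchanged, positions at or beyond
    ``pos + ref_len`` shift by ``alt_len - ref_len``, and a boundary falling
    strictly inside the replaced span is clipped to the end of the alt
    allele.
    """
    shift = alt_len - ref_len

    def remap(x: int) -> int:
        if x <= pos:
            return x
        if x >= pos + ref_len:
            return x + shift
        return pos + alt_len

    out = []
    for s, e, _ in gene.cds_segments:
        ns, ne = remap(s), remap(e)
        if ne > ns:
            out.append((ns, ne))
    return out


def _translate(cds: str) -> str:
    usable = len(cds) - len(cds) % 3
    return str(Seq(cds[:usable]).translate())


def call_consequence(
    v: DiffVariant,
    gene: GeneModel,
    genome: Genome,
    splice_window_bp: int = SPLICE_WINDOW_BP,
) -> Consequence:
    """Consequence of substituting the large-group allele into the gene.

    Splice disruption is checked first (reference span touching the terminal
    ``splice_window_bp`` bases of any intron).  Variants not overlapping the
    CDS (UTR exon or intron interior) are ``non_coding``.  Otherwise the
    mutated CDS is rebuilt in transcript orientation and compared with the
    reference CDS and its translation.
    """
    span = (v.pos, v.pos + len(v.ref))
    if not (gene.start < span[1] and span[0] < gene.end):
        raise ContractError(f"variant {v.chrom}:{v.pos + 1} outside {gene.gene_id}")
    if gene.cds_length % 3 != 0:
        raise ValidationError(f"{gene.gene_id}: CDS length not divisible by 3")

    for istart, iend in gene.introns():
        donor = (istart, min(istart + splice_window_bp, iend))
        acceptor = (max(iend - splice_window_bp, istart), iend)
        for ws, we in (donor, acceptor):
            if span[0] < we and ws < span[1]:
                return Consequence(LARGE_EFFECT, SPLICE_SITE)

    cds_overlap = any(
        span[0] < e and s < span[1] for s, e, _ in gene.cds_segments
    )
    if not cds_overlap:
        return Consequence(NON_CODING)

    alt = v.large_allele if v.large_allele != v.ref else v.small_allele
    chrom_seq = genome.sequences[v.chrom]
    mutated = chrom_seq[: v.pos] + alt + chrom_seq[v.pos + len(v.ref):]
    alt_segments = _alt_cds_segments(gene, v.pos, len(v.ref), len(alt))
    alt_cds = "".join(mutated[s:e] for s, e in alt_segments)
    if gene.strand == "-":
        alt_cds = str(Seq(alt_cds).reverse_complement())
    ref_cds = gene.cds_sequence(genome)

    if alt_cds[:3] != "ATG":
        return Consequence(LARGE_EFFECT, START_LOSS)
    if (len(alt_cds) - len(ref_cds)) % 3 != 0:
        return Consequence(LARGE_EFFECT, FRAMESHIFT)
    ref_prot = _translate(ref_cds)
    alt_prot = _translate(alt_cds)
    if "*" in alt_prot[:-1]:
        return Consequence(LARGE_EFFECT, STOP_GAIN)
    if alt_prot == ref_prot:
        return Consequence(SYNONYMOUS)
    return Consequence(NON_SYNONYMOUS)


def annotate_variants(
    diffs: list[DiffVariant],
    genes: list[GeneModel],
    genome: Genome,
    promoter_bp: int = PROMOTER_BP,
    splice_window_bp: int = SPLICE_WINDOW_BP,
) -> list[AnnotatedVariant]:
    index = GeneIndex(genes, promoter_bp)
    out = []
    for v in diffs:
        label = index.assign_region(v)
        effect = subtype = None
        if label.region in (EXON, INTRON):
            cons = call_consequence(
                v, index.genes[label.gene_id], genome, splice_window_bp
            )
            effect, subtype = cons.effect, cons.subtype
        out.append(
            AnnotatedVariant(v, label.region, label.gene_id, effect, subtype)
        )
    return out


# ---------------------------------------------------------------------------
# spectra and window statistics
# ---------------------------------------------------------------------------

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def ts_tv(snps: list[DiffVariant]) -> dict:
    """Transition/transversion counts over the differentiating substitution
    (small-group vs large-group allele) of SNP-class variants."""
    counts = {"transition": 0, "transversion": 0}
    pairs: dict[str, int] = defaultdict(int)
    for v in snps:
        if v.variant_class != SNP:
            raise ValidationError(f"{v.chrom}:{v.pos + 1} is not a SNP")
        a, b = v.small_allele, v.large_allele
        key = "/".join(sorted((a, b)))
        pairs[key] += 1
        both_purine = a in _PURINES and b in _PURINES
        both_pyrimidine = a in _PYRIMIDINES and b in _PYRIMIDINES
        counts["transition" if both_purine or both_pyrimidine else "transversion"] += 1
    counts["by_substitution"] = dict(pairs)
    return counts


def indel_spectrum(indels: list[DiffVariant]) -> dict:
    """Per-length insertion/deletion counts, oriented by the non-reference
    group allele relative to the reference."""
    ins: dict[int, int] = defaultdict(int)
    dels: dict[int, int] = defaultdict(int)
    for v in indels:
        if v.variant_class != INDEL:
            raise ValidationError(f"{v.chrom}:{v.pos + 1} is not an InDel")
        allele = v.large_allele if v.large_allele != v.ref else v.small_allele
        delta = len(allele) - len(v.ref)
        if delta == 0:
            raise ValidationError(f"{v.chrom}:{v.pos + 1}: zero length change")
        (ins if delta > 0 else dels)[abs(delta)] += 1
    return {"insertions": dict(ins), "deletions": dict(dels)}


def window_frequency(
    variants: list[DiffVariant],
    genome: Genome,
    window_bp: int = WINDOW_BP,
) -> list[WindowStat]:
    """Variant counts and per-100-kb frequency in non-overlapping tiles from
    position 0; the last partial tile is normalized by its actual length."""
    by_chrom: dict[str, list[DiffVariant]] = defaultdict(list)
    for v in variants:
        by_chrom[v.chrom].append(v)
    out: list[WindowStat] = []
    for chrom, length in genome.lengths.items():
        tiles = [
            (s, min(s + window_bp, length)) for s in range(0, length, window_bp)
        ]
        counts = [
            {cls: 0 for cls in (SNP, MNP, INDEL, COMPLEX)} for _ in tiles
        ]
        for v in by_chrom.get(chrom, []):
            counts[v.pos // window_bp][v.variant_class] += 1
        for (s, e), c in zip(tiles, counts):
            total = sum(c.values())
            out.append(
                WindowStat(chrom, s, e, c, frequency=total / (e - s) * window_bp)
            )
    return out


# ---------------------------------------------------------------------------
# highly polymorphic genes
# ---------------------------------------------------------------------------

def summarize_genes(
    annotated: list[AnnotatedVariant], genes: list[GeneModel]
) -> list[GeneVariantSummary]:
    """Per-gene region/effect counts and per-kb exonic/intronic densities."""
    by_gene: dict[str, list[AnnotatedVariant]] = defaultdict(list)
    for a in annotated:
        if a.gene_id is not None:
            by_gene[a.gene_id].append(a)
    out = []
    for g in genes:
        hits = by_gene.get(g.gene_id, [])
        region_counts: dict[str, int] = defaultdict(int)
        effect_counts: dict[str, int] = defaultdict(int)
        for a in hits:
            region_counts[a.region] += 1
            if a.effect is not None:
                effect_counts[a.effect] += 1
        exon_kb = g.exon_length / 1000
        intron_kb = sum(e - s for s, e in g.introns()) / 1000
        out.append(
            GeneVariantSummary(
                gene_id=g.gene_id,
                region_counts=dict(region_counts),
                effect_counts=dict(effect_counts),
                exonic_density_per_kb=(
                    region_counts[EXON] / exon_kb if exon_kb else 0.0
                ),
                intronic_density_per_kb=(
                    region_counts[INTRON] / intron_kb if intron_kb else 0.0
                ),
            )
        )
    return out


def polymorphic_gene_outliers(
    summaries: list[GeneVariantSummary], region: str
) -> tuple[set[str], float]:
    """Genes whose per-kb density in ``region`` ('exonic' or 'intronic') lies
    strictly above the third quartile of the density distribution over genes
    with at least one polymorphism there.  Q3 uses linear interpolation
    between order statistics.  Returns (flagged gene ids, Q3)."""
    if region not in ("exonic", "intronic"):
        raise ValidationError("region must be 'exonic' or 'intronic'")
    attr = f"{region}_density_per_kb"
    dens = {
        s.gene_id: getattr(s, attr) for s in summaries if getattr(s, attr) > 0
    }
    if len(dens) < 4:
        raise ValidationError(
            f"need >=4 genes with {region} polymorphisms, have {len(dens)}"
        )
    q3 = float(np.percentile(list(dens.values()), 75, method="linear"))
    return {g for g, d in dens.items() if d > q3}, q3
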