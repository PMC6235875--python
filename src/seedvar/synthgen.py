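"""Synthetic four-cultivar dataset generator with planted ground truth.

Emulates the inputs of a cultivar-group resequencing study: a reference
genome, multi-exon gene models stamped into it, per-cultivar variant calls
(two "small-seeded" and two "large-seeded" cultivars), a 29-tissue FPKM
matrix, a per-stage differential-expression table, QTL intervals and a
functional-category map.  Every downstream observable is planted: which
sites differentiate the groups (and which are spoiled by low depth, low
alternate fraction, within-group polymorphism or the 10-bp cluster rule),
each variant's region and coding consequence, which genes are seed-specific
(tau > 0.6), which pass the S3/S5 differential-expression gate, and which
end up as candidate genes inside QTLs.

Everything is driven by one numpy Generator; a fixed config (including the
seed) reproduces byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .formats import (
    CoverageTrack,
    ExpressionMatrix,
    GeneModel,
    Genome,
    QTLInterval,
    TissuePanel,
    ValidationError,
    VariantCall,
)
from .variant_core import COMPLEX, INDEL, MNP, SNP, classify_variant

SMALL_CULTIVARS = ("Himchana1", "Pusa362")
LARGE_CULTIVARS = ("JGK3", "PG0515")
CULTIVARS = SMALL_CULTIVARS + LARGE_CULTIVARS

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# expected outcome labels for planted sites
DIFFERENTIATING = "differentiating"
REMOVED_DENSITY = "removed_density"
LOW_DEPTH = "low_depth_alt"
LOW_DEPTH_REF = "low_depth_ref"
LOW_AF = "low_af"
SHARED = "shared"
WITHIN_GROUP = "within_group"


class GenerationError(RuntimeError):
    pass


class PlacementError(GenerationError):
    pass


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _codon_aa(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SynthConfig:
    """Study conditions for the synthetic dataset.

    The default scale (2 chromosomes x 2 Mb, 200 genes, ~5,000 planted
    group-differentiating variants split across the four classes in roughly
    the proportions seen in cultivar resequencing) keeps a full pipeline run
    within minutes while exercising every downstream rule.
    """

    seed: int = 42
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 200
    n_diff_snp: int = 4200
    n_diff_mnp: int = 110
    n_diff_indel: int = 370
    n_diff_complex: int = 280
    n_confound_variants: int = 300
    fraction_low_depth: float = 0.02
    n_density_clusters: int = 15
    n_seed_specific: int = 30
    n_candidate_genes: int = 12
    n_qtls: int = 6
    expression_noise_sd: float = 0.2

    def validate(self) -> None:
        counts = (
            self.n_chroms, self.n_genes, self.n_diff_snp, self.n_diff_mnp,
            self.n_diff_indel, self.n_diff_complex, self.n_confound_variants,
            self.n_density_clusters, self.n_seed_specific,
            self.n_candidate_genes, self.n_qtls,
        )
        if any(c < 0 for c in counts):
            raise ValidationError("all counts must be >= 0")
        if self.n_chroms <= 0 or self.chrom_length <= 0:
            raise ValidationError("need positive n_chroms and chrom_length")
        if self.chrom_length < 20_000:
            raise ValidationError(
                "chrom_length must be >= 10x the mean gene footprint (~2 kb)"
            )
        if not 0 <= self.fraction_low_depth <= 1:
            raise ValidationError("fraction_low_depth outside [0,1]")
        if self.n_candidate_genes > self.n_seed_specific:
            raise ValidationError("candidates must be a subset of seed-specific genes")

    @property
    def n_diff_total(self) -> int:
        return (
            self.n_diff_snp + self.n_diff_mnp
            + self.n_diff_indel + self.n_diff_complex
        )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SynthConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class PlantedSite:
    chrom: str
    pos: int  # 0-based
    ref: str
    small_allele: str
    large_allele: str
    variant_class: str
    region: str | None  # promoter/exon/intron/intergenic (None for confounders)
    gene_id: str | None
    effect: str | None  # synonymous/non_synonymous/large_effect/non_coding
    subtype: str | None
    expected: str  # DIFFERENTIATING / REMOVED_DENSITY / LOW_DEPTH / ...
    carrier: str | None = None  # 'small' | 'large' | 'all' | 'dual'


@dataclass
class GroundTruth:
    sites: list[PlantedSite]
    seed_specific_genes: dict[str, str]  # gene_id -> planted peak tissue
    pattern_by_gene: dict[str, str]
    de_genes_s3s5: list[str]  # higher in large at S3 and/or S5
    qtl_member_genes: dict[str, list[str]]  # qtl name -> contained genes
    candidate_genes: list[str]

    def expected_diff(self) -> list[PlantedSite]:
        return [s for s in self.sites if s.expected == DIFFERENTIATING]

    def expected_diff_keys(self) -> set[tuple[str, int]]:
        return {(s.chrom, s.pos) for s in self.expected_diff()}

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "cultivars": {"small": SMALL_CULTIVARS, "large": LARGE_CULTIVARS},
            "sites": [
                {**dataclasses.asdict(s), "pos": s.pos + 1}  # 1-based on disk
                for s in self.sites
            ],
            "seed_specific_genes": self.seed_specific_genes,
            "pattern_by_gene": self.pattern_by_gene,
            "de_genes_s3s5": self.de_genes_s3s5,
            "qtl_member_genes": self.qtl_member_genes,
            "candidate_genes": self.candidate_genes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        sites = [
            PlantedSite(**{**d, "pos": d["pos"] - 1}) for d in payload["sites"]
        ]
        return cls(
            sites=sites,
            seed_specific_genes=payload["seed_specific_genes"],
            pattern_by_gene=payload["pattern_by_gene"],
            de_genes_s3s5=payload["de_genes_s3s5"],
            qtl_member_genes=payload["qtl_member_genes"],
            candidate_genes=payload["candidate_genes"],
        )


# ---------------------------------------------------------------------------
# reference genome
# ---------------------------------------------------------------------------

def generate_reference(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> Genome:
    """Uniform-base random chromosomes Ca01..Ca<n> of the configured length."""
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    for i in range(cfg.n_chroms):
        arr = base_codes[rng.integers(0, 4, size=cfg.chrom_length)]
        seqs[f"Ca{i + 1:02d}"] = arr.tobytes().decode("ascii")
    return Genome(seqs)


# ---------------------------------------------------------------------------
# gene models (stamped into the genome so CDS/splice motifs are real)
# ---------------------------------------------------------------------------

_MIN_GAP = 4500  # between gene spans; keeps 2-kb promoters unambiguous
_EDGE_PAD = 3000


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random internal non-stop codons + one stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(_BASES[i] for i in rng.integers(0, 4, size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append(["TAA", "TAG", "TGA"][int(rng.integers(0, 3))])
    return "".join(codons)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _design_gene(
    rng: np.random.Generator, gene_id: str, chrom: str, start: int, strand: str
) -> tuple[GeneModel, str]:
    """Design a multi-exon gene; returns the model plus the genomic sequence
    to stamp at [start, start + len)."""
    n_codons = int(rng.integers(100, 250))
    cds = _random_cds(rng, n_codons)
    utr5 = _random_seq(rng, int(rng.integers(40, 120)))
    utr3 = _random_seq(rng, int(rng.integers(40, 120)))
    transcript = utr5 + cds + utr3
    n_exons = int(rng.integers(2, 6))
    # exon boundaries in transcript coordinates, keeping every exon >= 30 bp
    for _ in range(50):
        cuts = sorted(rng.integers(30, len(transcript) - 30, size=n_exons - 1))
        bounds = [0, *cuts, len(transcript)]
        if all(b - a >= 30 for a, b in zip(bounds, bounds[1:])):
            break
    else:
        bounds = [0, len(transcript)]
    tx_exons = list(zip(bounds, bounds[1:]))
    introns = [
        "GT" + _random_seq(rng, int(rng.integers(150, 400))) + "AG"
        for _ in range(len(tx_exons) - 1)
    ]
    # genomic piece in transcript orientation, with exon genomic offsets
    parts, gx_exons, offset = [], [], 0
    for i, (a, b) in enumerate(tx_exons):
        parts.append(transcript[a:b])
        gx_exons.append((offset, offset + (b - a), a, b))
        offset += b - a
        if i < len(introns):
            parts.append(introns[i])
            offset += len(introns[i])
    piece = "".join(parts)
    glen = len(piece)
    if strand == "-":
        piece = _revcomp(piece)

    def to_genome(lo: int, hi: int) -> tuple[int, int]:
        if strand == "+":
            return start + lo, start + hi
        return start + glen - hi, start + glen - lo

    exons = sorted(to_genome(lo, hi) for lo, hi, _, _ in gx_exons)
    cds_lo, cds_hi = len(utr5), len(utr5) + len(cds)
    cds_segments = []
    cum = 0  # CDS bases preceding the segment, in transcript order
    for lo, hi, a, b in gx_exons:
        seg_a, seg_b = max(a, cds_lo), min(b, cds_hi)
        if seg_a < seg_b:
            phase = (3 - cum % 3) % 3
            gs, ge = to_genome(lo + (seg_a - a), lo + (seg_b - a))
            cds_segments.append((gs, ge, phase))
            cum += seg_b - seg_a
    span = to_genome(0, glen)
    model = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=span[0],
        end=span[1],
        exons=exons,
        cds_segments=sorted(cds_segments),
    )
    return model, piece


def generate_gene_models(
    cfg: SynthConfig, genome: Genome, rng: np.random.Generator | None = None
) -> list[GeneModel]:
    """Place non-overlapping genes on alternating strands and stamp their
    designed sequences into the genome (mutates ``genome.sequences``)."""
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    chroms = list(genome.sequences)
    buffers = {c: bytearray(genome.sequences[c], "ascii") for c in chroms}
    per_chrom = [cfg.n_genes // len(chroms)] * len(chroms)
    for i in range(cfg.n_genes % len(chroms)):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    gid = 0
    for chrom, n_here in zip(chroms, per_chrom):
        cursor = _EDGE_PAD
        for _ in range(n_here):
            gid += 1
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            model, piece = _design_gene(
                rng, f"Ca.g{gid:04d}", chrom, cursor, strand
            )
            if model.end + _MIN_GAP + _EDGE_PAD > len(buffers[chrom]):
                raise PlacementError(
                    f"cannot place {cfg.n_genes} genes on "
                    f"{cfg.n_chroms} x {cfg.chrom_length} bp"
                )
            buffers[chrom][model.start:model.end] = piece.encode("ascii")
            genes.append(model)
            cursor = model.end + int(rng.integers(_MIN_GAP, _MIN_GAP + 3500))
    for chrom in chroms:
        genome.sequences[chrom] = buffers[chrom].decode("ascii")
    return genes


# ---------------------------------------------------------------------------
# variant planting
# ---------------------------------------------------------------------------

_CELL = 32  # occupancy granularity; >= 2 cells apart guarantees > 10 bp spacing


class _GeneRec:
    """Planting-time view of a gene: transcript/genome coordinate maps."""

    def __init__(self, model: GeneModel, genome: Genome):
        self.model = model
        seq = genome.sequences[model.chrom]
        tx: list[int] = []  # genome position of each transcript base
        exons = model.exons if model.strand == "+" else model.exons[::-1]
        for s, e in exons:
            rng_ = range(s, e) if model.strand == "+" else range(e - 1, s - 1, -1)
            tx.extend(rng_)
        self.tx_positions = tx
        cds: list[int] = []
        segs = (
            model.cds_segments
            if model.strand == "+"
            else model.cds_segments[::-1]
        )
        for s, e, _ in segs:
            rng_ = range(s, e) if model.strand == "+" else range(e - 1, s - 1, -1)
            cds.extend(rng_)
        self.cds_positions = cds
        self.utr5_len = self.tx_positions.index(self.cds_positions[0])
        if model.strand == "+":
            self.cds_seq = "".join(seq[p] for p in cds)
        else:
            self.cds_seq = "".join(seq[p].translate(_COMPLEMENT) for p in cds)

    def codon(self, c: int) -> str:
        return self.cds_seq[3 * c: 3 * c + 3]

    @property
    def n_codons(self) -> int:
        return len(self.cds_seq) // 3

    def contiguous(self, k: int, length: int) -> bool:
        """Are transcript CDS indices [k, k+length) adjacent in the genome?"""
        p = self.cds_positions[k: k + length]
        step = 1 if self.model.strand == "+" else -1
        return all(b - a == step for a, b in zip(p, p[1:]))


class _Planter:
    def __init__(self, cfg, genome, genes, rng, require_poly, forbid_poly):
        self.cfg = cfg
        self.genome = genome
        self.genes = genes
        self.rng = rng
        self.recs = {g.gene_id: _GeneRec(g, genome) for g in genes}
        self.require_poly = list(require_poly)
        self.forbid_poly = set(forbid_poly)
        self.occupied: dict[str, set[int]] = {c: set() for c in genome.sequences}
        self.sites: list[PlantedSite] = []
        self.coverage_exceptions: dict[tuple[str, str, int], int] = {}
        self.zones = self._intergenic_zones()

    # -- geometry helpers --------------------------------------------------

    def _intergenic_zones(self) -> dict[str, list[tuple[int, int]]]:
        pad = 2500
        zones: dict[str, list[tuple[int, int]]] = {}
        for chrom, length in self.genome.lengths.items():
            spans = sorted(
                (g.start, g.end) for g in self.genes if g.chrom == chrom
            )
            edges = [500] + [e + pad for _, e in spans]
            ends = [s - pad for s, _ in spans] + [length - 500]
            zones[chrom] = [
                (a, b) for a, b in zip(edges, ends) if b - a >= 100
            ]
        return zones

    def _claim(self, chrom: str, pos: int, ref_len: int) -> bool:
        cells = {
            (pos + d) // _CELL for d in range(-1, ref_len + 1)
        }
        probe = {c + d for c in cells for d in (-1, 0, 1)}
        if probe & self.occupied[chrom]:
            return False
        self.occupied[chrom] |= cells
        return True

    _TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

    def _alt_base(self, ref: str, exclude: str = "") -> str:
        """Substitute base with a transition-biased mutation model
        (P(transition) = 0.65, matching the transition excess typical of
        plant resequencing spectra)."""
        partner = self._TRANSITION.get(ref)
        transversions = [
            b for b in _BASES if b != ref and b != partner and b not in exclude
        ]
        if partner is not None and partner not in exclude:
            if not transversions or self.rng.random() < 0.65:
                return partner
        return transversions[int(self.rng.integers(0, len(transversions)))]

    def _indel_len(self, insertion: bool) -> int:
        # short lengths dominate; insertions up to 20 bp, deletions up to 10
        max_len = 20 if insertion else 10
        ls = np.arange(1, max_len + 1)
        w = 0.65 ** ls
        return int(self.rng.choice(ls, p=w / w.sum()))

    # -- allele builders (return pos, ref, alt or None) --------------------

    def _noncoding_alleles(self, chrom: str, pos: int, cls: str):
        seq = self.genome.sequences[chrom]
        if cls == SNP:
            ref = seq[pos]
            return pos, ref, self._alt_base(ref)
        if cls == MNP:
            n = int(self.rng.integers(2, 5))
            ref = seq[pos: pos + n]
            alt = "".join(self._alt_base(b) for b in ref)
            return pos, ref, alt
        if cls == INDEL:
            if self.rng.integers(0, 2) == 0:  # insertion
                ins = _random_seq(self.rng, self._indel_len(True))
                return pos, seq[pos], seq[pos] + ins
            dlen = self._indel_len(False)
            return pos, seq[pos: pos + 1 + dlen], seq[pos]
        # complex: substitution mixed with a length change
        for _ in range(30):
            lr = int(self.rng.integers(2, 5))
            la = int(self.rng.integers(2, 5))
            ref = seq[pos: pos + lr]
            alt = _random_seq(self.rng, la)
            try:
                if alt != ref and classify_variant(ref, alt) == COMPLEX:
                    return pos, ref, alt
            except ValidationError:
                continue
        return None

    def _tx_substitution(self, rec: _GeneRec, k: int, new_seq: str):
        """Genome-space (pos, ref, alt) replacing CDS transcript bases
        [k, k+len(new_seq)) with new_seq (transcript orientation)."""
        length = len(new_seq)
        gpos = rec.cds_positions[k: k + length]
        left = min(gpos)
        seq = self.genome.sequences[rec.model.chrom]
        ref = seq[left: left + length]
        alt = new_seq if rec.model.strand == "+" else _revcomp(new_seq)
        return left, ref, alt

    # -- planting primitives ----------------------------------------------

    def _emit(self, chrom, pos, ref, alt, cls, region, gene_id, effect,
              subtype, expected, carrier=None, small_alt=None):
        """Record a planted site.  ``carrier`` in {'small','large','all'} or
        None to draw at random; dual-allele sites pass ``small_alt``."""
        if carrier is None:
            carrier = "small" if self.rng.integers(0, 2) == 0 else "large"
        if small_alt is not None:
            carrier = "dual"
            small_allele, large_allele = small_alt, alt
        elif carrier == "all":
            small_allele = large_allele = alt
        elif carrier == "small":
            small_allele, large_allele = alt, ref
        else:
            small_allele, large_allele = ref, alt
        self.sites.append(
            PlantedSite(
                chrom=chrom, pos=int(pos), ref=ref,
                small_allele=small_allele, large_allele=large_allele,
                variant_class=cls, region=region, gene_id=gene_id,
                effect=effect, subtype=subtype, expected=expected,
                carrier=carrier,
            )
        )
        return self.sites[-1]

    def _plant_intergenic(self, cls, expected=DIFFERENTIATING, carrier=None,
                          dual=False):
        for _ in range(200):
            chrom = f"Ca{int(self.rng.integers(0, self.cfg.n_chroms)) + 1:02d}"
            zones = self.zones.get(chrom, [])
            if not zones:
                continue
            a, b = zones[int(self.rng.integers(0, len(zones)))]
            pos = int(self.rng.integers(a, b - 30))
            built = self._noncoding_alleles(chrom, pos, cls)
            if built is None:
                continue
            pos, ref, alt = built
            if not self._claim(chrom, pos, len(ref)):
                continue
            small_alt = None
            if dual:
                small_alt = self._alt_base(ref, exclude=alt)
            return self._emit(chrom, pos, ref, alt, cls, "intergenic", None,
                              None, None, expected, carrier, small_alt)
        raise GenerationError(f"no room for an intergenic {cls}")

    def _eligible_genes(self, evidence: bool) -> list[str]:
        ids = [g.gene_id for g in self.genes]
        if evidence:
            ids = [g for g in ids if g not in self.forbid_poly]
        if not ids:
            raise GenerationError("no eligible genes")
        return ids

    def _plant_promoter(self, cls, gene_id=None):
        genes = [gene_id] if gene_id else self._eligible_genes(True)
        for _ in range(200):
            gid = genes[int(self.rng.integers(0, len(genes)))]
            g = self.recs[gid].model
            if g.strand == "+":
                lo, hi = g.start - 1985, g.start - 30
            else:
                lo, hi = g.end + 30, g.end + 1985
            pos = int(self.rng.integers(lo, hi - 25))
            built = self._noncoding_alleles(g.chrom, pos, cls)
            if built is None:
                continue
            pos, ref, alt = built
            if not self._claim(g.chrom, pos, len(ref)):
                continue
            return self._emit(g.chrom, pos, ref, alt, cls, "promoter", gid,
                              None, None, DIFFERENTIATING)
        raise GenerationError(f"no room for a promoter {cls}")

    def _plant_intron(self, cls):
        genes = self._eligible_genes(False)
        for _ in range(300):
            gid = genes[int(self.rng.integers(0, len(genes)))]
            g = self.recs[gid].model
            introns = [iv for iv in g.introns() if iv[1] - iv[0] >= 80]
            if not introns:
                continue
            istart, iend = introns[int(self.rng.integers(0, len(introns)))]
            pos = int(self.rng.integers(istart + 12, iend - 40))
            built = self._noncoding_alleles(g.chrom, pos, cls)
            if built is None:
                continue
            pos, ref, alt = built
            if pos + len(ref) > iend - 10:
                continue
            if not self._claim(g.chrom, pos, len(ref)):
                continue
            return self._emit(g.chrom, pos, ref, alt, cls, "intron", gid,
                              "non_coding", None, DIFFERENTIATING)
        raise GenerationError(f"no room for an intronic {cls}")

    def _plant_splice(self, gene_id=None):
        genes = [gene_id] if gene_id else self._eligible_genes(True)
        for _ in range(300):
            gid = genes[int(self.rng.integers(0, len(genes)))]
            g = self.recs[gid].model
            introns = g.introns()
            if not introns:
                continue
            istart, iend = introns[int(self.rng.integers(0, len(introns)))]
            pos = [istart, istart + 1, iend - 2, iend - 1][
                int(self.rng.integers(0, 4))
            ]
            ref = self.genome.sequences[g.chrom][pos]
            if not self._claim(g.chrom, pos, 1):
                continue
            return self._emit(g.chrom, pos, ref, self._alt_base(ref), SNP,
                              "intron", gid, "large_effect", "splice_site",
                              DIFFERENTIATING)
        raise GenerationError("no room for a splice-site SNP")

    def _plant_utr_snp(self):
        genes = self._eligible_genes(False)
        for _ in range(300):
            gid = genes[int(self.rng.integers(0, len(genes)))]
            rec = self.recs[gid]
            if rec.utr5_len < 12:
                continue
            k = int(self.rng.integers(4, rec.utr5_len - 4))
            # stay clear of exon boundaries
            p = rec.tx_positions[k]
            step = 1 if rec.model.strand == "+" else -1
            if (rec.tx_positions[k - 1] != p - step
                    or rec.tx_positions[k + 1] != p + step):
                continue
            ref = self.genome.sequences[rec.model.chrom][p]
            if not self._claim(rec.model.chrom, p, 1):
                continue
            return self._emit(rec.model.chrom, p, ref, self._alt_base(ref),
                              SNP, "exon", gid, "non_coding", None,
                              DIFFERENTIATING)
        raise GenerationError("no room for a UTR SNP")

    def _plant_coding_snp(self, kind: str, gene_id=None):
        """kind in {synonymous, non_synonymous, stop_gain, start_loss}."""
        genes = [gene_id] if gene_id else self._eligible_genes(
            kind in ("non_synonymous", "stop_gain", "start_loss")
        )
        for _ in range(400):
            gid = genes[int(self.rng.integers(0, len(genes)))]
            rec = self.recs[gid]
            if kind == "start_loss":
                c = 0
            else:
                c = int(self.rng.integers(1, rec.n_codons - 1))
            codon = rec.codon(c)
            found = None
            for off in self.rng.permutation(3):
                for b in self.rng.permutation(list(_BASES)):
                    if b == codon[off]:
                        continue
                    new = codon[:off] + b + codon[off + 1:]
                    if kind == "synonymous":
                        ok = new not in _STOPS and _codon_aa(new) == _codon_aa(codon)
                    elif kind == "non_synonymous":
                        ok = new not in _STOPS and _codon_aa(new) != _codon_aa(codon)
                    elif kind == "stop_gain":
                        ok = new in _STOPS
                    else:  # start_loss: any change to the initiator
                        ok = True
                    if ok:
                        found = (3 * c + int(off), b)
                        break
                if found:
                    break
            if found is None:
                continue
            k, b = found
            pos, ref, alt = self._tx_substitution(rec, k, b)
            if not self._claim(rec.model.chrom, pos, len(ref)):
                continue
            effect = (
                "large_effect" if kind in ("stop_gain", "start_loss")
                else kind
            )
            subtype = kind if kind in ("stop_gain", "start_loss") else None
            return self._emit(rec.model.chrom, pos, ref, alt, SNP, "exon",
                              gid, effect, subtype, DIFFERENTIATING)
        raise GenerationError(f"could not plant a {kind} SNP")

    def _plant_coding_mnp(self, gene_id=None):
        """Two adjacent substituted bases in one interior codon -> missense."""
        genes = [gene_id] if gene_id else self._eligible_genes(True)
        for _ in range(400):
            gid = genes[int(self.rng.integers(0, len(genes)))]
            rec = self.recs[gid]
            c = int(self.rng.integers(1, rec.n_codons - 1))
            if not rec.contiguous(3 * c, 3):
                continue
            codon = rec.codon(c)
            found = None
            for b1 in self.rng.permutation(list(_BASES)):
                for b2 in self.rng.permutation(list(_BASES)):
                    if b1 == codon[0] or b2 == codon[1]:
                        continue
                    new = b1 + b2 + codon[2]
                    if new not in _STOPS and _codon_aa(new) != _codon_aa(codon):
                        found = b1 + b2
                        break
                if found:
                    break
            if found is None:
                continue
            pos, ref, alt = self._tx_substitution(rec, 3 * c, found)
            if not self._claim(rec.model.chrom, pos, len(ref)):
                continue
            return self._emit(rec.model.chrom, pos, ref, alt, MNP, "exon",
                              gid, "non_synonymous", None, DIFFERENTIATING)
        raise GenerationError("could not plant a coding MNP")

    def _plant_coding_indel(self, inframe: bool, gene_id=None):
        """Frameshift (1-2 bp) or in-frame whole-codon deletion inside a CDS
        segment, anchored VCF-style on the base to the left."""
        genes = [gene_id] if gene_id else self._eligible_genes(True)
        seq_of = self.genome.sequences
        for _ in range(400):
            gid = genes[int(self.rng.integers(0, len(genes)))]
            rec = self.recs[gid]
            g = rec.model
            if inframe:
                c = int(self.rng.integers(2, rec.n_codons - 2))
                k = 3 * c
                if not rec.contiguous(k - 1, 5):
                    continue
                gpos = rec.cds_positions[k: k + 3]
                left = min(gpos)
                pos = left - 1
                ref = seq_of[g.chrom][pos: pos + 4]
                alt = ref[0]
            else:
                segs = [s for s in g.cds_segments if s[1] - s[0] >= 20]
                if not segs:
                    continue
                s, e, _ = segs[int(self.rng.integers(0, len(segs)))]
                dlen = int(self.rng.integers(1, 3))
                pos = int(self.rng.integers(s + 3, e - dlen - 4))
                if self.rng.integers(0, 2) == 0:  # insertion of 1-2 bp
                    alt = seq_of[g.chrom][pos] + _random_seq(self.rng, dlen)
                    ref = seq_of[g.chrom][pos]
                else:
                    ref = seq_of[g.chrom][pos: pos + 1 + dlen]
                    alt = ref[0]
            if classify_variant(ref, alt) != INDEL:
                continue
            if not self._claim(g.chrom, pos, len(ref)):
                continue
            effect = "non_synonymous" if inframe else "large_effect"
            subtype = None if inframe else "frameshift"
            return self._emit(g.chrom, pos, ref, alt, INDEL, "exon", gid,
                              effect, subtype, DIFFERENTIATING)
        raise GenerationError("could not plant a coding InDel")

    def _plant_cluster(self):
        """Three differentiating SNPs within one 10-bp window; the density
        rule must remove all three."""
        for _ in range(300):
            chrom = f"Ca{int(self.rng.integers(0, self.cfg.n_chroms)) + 1:02d}"
            zones = self.zones.get(chrom, [])
            if not zones:
                continue
            a, b = zones[int(self.rng.integers(0, len(zones)))]
            base = int(self.rng.integers(a, b - 40))
            offsets = sorted(
                self.rng.choice(np.arange(1, 10), size=2, replace=False)
            )
            positions = [base, base + int(offsets[0]), base + int(offsets[1])]
            cells = {p // _CELL for p in positions}
            probe = {c + d for c in cells for d in (-1, 0, 1)}
            if probe & self.occupied[chrom]:
                continue
            self.occupied[chrom] |= cells
            carrier = "small" if self.rng.integers(0, 2) == 0 else "large"
            for p in positions:
                ref = self.genome.sequences[chrom][p]
                self._emit(chrom, p, ref, self._alt_base(ref), SNP,
                           "intergenic", None, None, None, REMOVED_DENSITY,
                           carrier)
            return
        raise GenerationError("no room for a density cluster")


# label allocation within each variant class (fractions of the class budget;
# the remainder goes to intergenic placements)
_ALLOCATION = {
    SNP: [
        ("promoter", 0.15), ("intron", 0.20), ("synonymous", 0.015),
        ("non_synonymous", 0.024), ("utr", 0.007), ("stop_gain", 0.003),
        ("start_loss", 0.0015), ("splice_site", 0.0035), ("dual", 0.0025),
    ],
    MNP: [("promoter", 0.18), ("intron", 0.22), ("non_synonymous", 0.14)],
    INDEL: [
        ("promoter", 0.15), ("intron", 0.20), ("frameshift", 0.07),
        ("inframe", 0.04),
    ],
    COMPLEX: [("promoter", 0.15), ("intron", 0.20)],
}


def _allocate(cls: str, n: int) -> list[tuple[str, int]]:
    out = [(label, int(round(frac * n))) for label, frac in _ALLOCATION[cls]]
    used = sum(c for _, c in out)
    out.append(("intergenic", max(0, n - used)))
    return out


def plant_variants(
    cfg: SynthConfig,
    genome: Genome,
    genes: list[GeneModel],
    rng: np.random.Generator | None = None,
    require_poly_genes: tuple[str, ...] | list[str] = (),
    forbid_poly_genes: tuple[str, ...] | list[str] = (),
) -> tuple[dict[str, list[VariantCall]], CoverageTrack, list[PlantedSite]]:
    """Plant group-differentiating variants and confounders; emit the four
    per-cultivar call sets plus the coverage sidecar.

    ``require_poly_genes`` each receive at least one promoter or
    non-synonymous or large-effect differentiating variant;
    ``forbid_poly_genes`` receive none of those evidence types.
    """
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    bad = set(require_poly_genes) & set(forbid_poly_genes)
    if bad:
        raise ValidationError(f"genes both required and forbidden: {sorted(bad)}")
    planter = _Planter(cfg, genome, genes, rng, require_poly_genes,
                       forbid_poly_genes)

    budgets = {cls: dict(_allocate(cls, n)) for cls, n in (
        (SNP, cfg.n_diff_snp), (MNP, cfg.n_diff_mnp),
        (INDEL, cfg.n_diff_indel), (COMPLEX, cfg.n_diff_complex),
    )}

    def spend(cls: str, label: str) -> None:
        budgets[cls][label] = max(0, budgets[cls].get(label, 0) - 1)

    # directed phase: guarantee evidence on the required genes
    for i, gid in enumerate(sorted(require_poly_genes)):
        planter._plant_promoter(SNP, gene_id=gid)
        spend(SNP, "promoter")
        if i % 4 == 1:
            planter._plant_coding_snp("non_synonymous", gene_id=gid)
            spend(SNP, "non_synonymous")
        elif i % 4 == 2:
            planter._plant_coding_indel(inframe=False, gene_id=gid)
            spend(INDEL, "frameshift")
        elif i % 4 == 3:
            planter._plant_coding_snp("stop_gain", gene_id=gid)
            spend(SNP, "stop_gain")

    # random phase
    planters = {
        "intergenic": lambda cls: planter._plant_intergenic(cls),
        "promoter": lambda cls: planter._plant_promoter(cls),
        "intron": lambda cls: planter._plant_intron(cls),
        "dual": lambda cls: planter._plant_intergenic(cls, dual=True),
        "utr": lambda cls: planter._plant_utr_snp(),
        "synonymous": lambda cls: planter._plant_coding_snp("synonymous"),
        "non_synonymous": lambda cls: (
            planter._plant_coding_snp("non_synonymous")
            if cls == SNP else planter._plant_coding_mnp()
        ),
        "stop_gain": lambda cls: planter._plant_coding_snp("stop_gain"),
        "start_loss": lambda cls: planter._plant_coding_snp("start_loss"),
        "splice_site": lambda cls: planter._plant_splice(),
        "frameshift": lambda cls: planter._plant_coding_indel(inframe=False),
        "inframe": lambda cls: planter._plant_coding_indel(inframe=True),
    }
    for cls in (SNP, MNP, INDEL, COMPLEX):
        for label, count in budgets[cls].items():
            for _ in range(count):
                planters[label](cls)

    # confounders
    n_conf = cfg.n_confound_variants
    n_shared = int(round(0.4 * n_conf))
    n_within = int(round(0.3 * n_conf))
    n_low_af = n_conf - n_shared - n_within
    for _ in range(n_shared):
        planter._plant_intergenic(SNP, expected=SHARED, carrier="all")
    for _ in range(n_within):
        planter._plant_intergenic(SNP, expected=WITHIN_GROUP)
    for _ in range(n_low_af):
        planter._plant_intergenic(SNP, expected=LOW_AF)
    n_low_depth = int(round(cfg.fraction_low_depth * cfg.n_diff_total))
    for i in range(n_low_depth):
        planter._plant_intergenic(
            SNP, expected=LOW_DEPTH if i % 2 == 0 else LOW_DEPTH_REF
        )
    for _ in range(cfg.n_density_clusters):
        planter._plant_cluster()

    calls, coverage = _build_calls(planter, rng)
    return calls, coverage, planter.sites


def _build_calls(
    planter: _Planter, rng: np.random.Generator
) -> tuple[dict[str, list[VariantCall]], CoverageTrack]:
    calls: dict[str, list[VariantCall]] = {cv: [] for cv in CULTIVARS}
    exceptions: dict[tuple[str, str, int], int] = {}

    def good_dp() -> int:
        return int(rng.integers(20, 61))

    def good_af() -> float:
        return round(float(rng.uniform(0.92, 1.0)), 3)

    def add(cv: str, s: PlantedSite, allele: str, dp: int, af: float) -> None:
        calls[cv].append(
            VariantCall(s.chrom, s.pos, s.ref, allele, cv, dp, af)
        )

    for s in planter.sites:
        group = (
            SMALL_CULTIVARS if s.carrier == "small"
            else LARGE_CULTIVARS if s.carrier == "large"
            else CULTIVARS
        )
        alt = s.small_allele if s.carrier == "small" else s.large_allele
        if s.carrier == "all":
            alt = s.large_allele
        spoiled = int(rng.integers(0, 2))  # which group member gets spoiled
        if s.expected in (DIFFERENTIATING, REMOVED_DENSITY, SHARED):
            if s.carrier == "dual":
                for cv in SMALL_CULTIVARS:
                    add(cv, s, s.small_allele, good_dp(), good_af())
                for cv in LARGE_CULTIVARS:
                    add(cv, s, s.large_allele, good_dp(), good_af())
            else:
                for cv in group:
                    add(cv, s, alt, good_dp(), good_af())
        elif s.expected == WITHIN_GROUP:
            add(group[spoiled], s, alt, good_dp(), good_af())
        elif s.expected == LOW_AF:
            for i, cv in enumerate(group):
                af = round(float(rng.uniform(0.6, 0.85)), 3) if i == spoiled \
                    else good_af()
                add(cv, s, alt, good_dp(), af)
        elif s.expected == LOW_DEPTH:
            for i, cv in enumerate(group):
                dp = int(rng.integers(4, 10)) if i == spoiled else good_dp()
                add(cv, s, alt, dp, good_af())
        elif s.expected == LOW_DEPTH_REF:
            for cv in group:
                add(cv, s, alt, good_dp(), good_af())
            other = LARGE_CULTIVARS if s.carrier == "small" else SMALL_CULTIVARS
            exceptions[(other[spoiled], s.chrom, s.pos)] = int(
                rng.integers(4, 10)
            )
        else:
            raise GenerationError(f"unhandled expected label {s.expected}")
    coverage = CoverageTrack(default_depth=40, exceptions=exceptions)
    planter.coverage_exceptions = exceptions
    return calls, coverage


# ---------------------------------------------------------------------------
# expression, DE table, QTLs
# ---------------------------------------------------------------------------

VEGETATIVE_TISSUES = (
    "Root", "Stem", "MatureLeaf", "YoungLeaf", "ShootApex", "FlowerBud",
    "Flower", "Petal", "Anther", "Pistil", "Pod", "Nodule", "Seedling",
    "GerminatingSeed", "SAM",
)
SEED_STAGES = tuple(f"S{i}" for i in range(1, 8))
SMALL_PREFIX, LARGE_PREFIX = "H1", "JGK3"


def default_panel() -> TissuePanel:
    """7 seed stages x 2 cultivars + 15 vegetative/floral tissues."""
    labels, is_seed, stage = [], {}, {}
    for prefix in (SMALL_PREFIX, LARGE_PREFIX):
        for s in SEED_STAGES:
            t = f"{prefix}_{s}"
            labels.append(t)
            is_seed[t], stage[t] = True, s
    for t in VEGETATIVE_TISSUES:
        labels.append(t)
        is_seed[t], stage[t] = False, None
    return TissuePanel(labels, is_seed, stage)


@dataclass
class GeneRoles:
    """Planted expression/DE roles; genes not listed are ubiquitous."""

    candidates: list[str]
    seedspec_no_poly: list[str]
    seedspec_poly_no_de: list[str]
    non_seed: list[str]
    not_expressed: list[str]
    de_extra: list[str]

    @property
    def seed_specific(self) -> list[str]:
        return self.candidates + self.seedspec_no_poly + self.seedspec_poly_no_de


def assign_roles(
    cfg: SynthConfig, genes: list[GeneModel], rng: np.random.Generator
) -> GeneRoles:
    ids = [g.gene_id for g in genes]
    order = list(rng.permutation(ids))
    n_cand = min(cfg.n_candidate_genes, len(order))
    rest_ss = min(cfg.n_seed_specific, len(order)) - n_cand
    n_no_poly = rest_ss // 2
    n_poly_no_de = rest_ss - n_no_poly

    def take(n: int) -> list[str]:
        out, order[:n] = order[:n], []
        return out

    candidates = take(n_cand)
    no_poly = take(n_no_poly)
    poly_no_de = take(n_poly_no_de)
    non_seed = take(min(20, len(order)))
    not_expressed = take(min(10, len(order)))
    de_extra = take(min(8, len(order)))
    return GeneRoles(candidates, no_poly, poly_no_de, non_seed,
                     not_expressed, de_extra)


def generate_expression(
    cfg: SynthConfig,
    genes: list[GeneModel],
    roles: GeneRoles,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, dict[str, str], dict[str, str], list[str]]:
    """FPKM matrix and DE table realizing the planted roles.

    Returns (matrix, de_table, peak_tissue_by_seed_specific_gene,
    pattern_by_gene, de_genes_s3s5).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 3)
    panel = default_panel()
    ids = [g.gene_id for g in genes]
    values = pd.DataFrame(0.0, index=ids, columns=panel.labels)
    sd = cfg.expression_noise_sd
    pattern: dict[str, str] = {}
    peaks: dict[str, str] = {}
    planted_sig: set[tuple[str, str]] = set()  # (gene, stage) with low q
    de_s3s5: list[str] = []

    def background(base: float) -> np.ndarray:
        vals = base * 2 ** rng.normal(0.0, sd, size=len(panel.labels))
        return np.clip(vals, 1.5, None)

    half = len(roles.seedspec_poly_no_de) // 2
    fc_fail = set(roles.seedspec_poly_no_de[:half])  # fold change below 2
    de_extra_s3s5 = set(roles.de_extra[: len(roles.de_extra) // 2])

    for gid in ids:
        if gid in roles.not_expressed:
            values.loc[gid] = rng.uniform(0.0, 0.4, size=len(panel.labels))
            pattern[gid] = "not_expressed"
        elif gid in roles.non_seed:
            row = background(float(2 ** rng.normal(3.0, 0.5)))
            for t in panel.labels:
                if panel.is_seed[t]:
                    row[panel.labels.index(t)] = float(rng.uniform(0.0, 0.5))
            values.loc[gid] = row
            pattern[gid] = "non_seed"
        elif gid in roles.seed_specific:
            row = rng.uniform(0.0, 1.2, size=len(panel.labels))
            if gid in roles.candidates or gid in fc_fail:
                stage = "S3" if rng.integers(0, 2) == 0 else "S5"
                ratio = 1.15 if gid in fc_fail else float(rng.uniform(4.0, 6.0))
            else:
                stage = SEED_STAGES[int(rng.integers(0, 7))]
                ratio = float(rng.uniform(0.85, 1.2))
            peak_val = float(rng.uniform(50.0, 90.0))
            peak_col = f"{LARGE_PREFIX}_{stage}"
            row[panel.labels.index(peak_col)] = peak_val
            row[panel.labels.index(f"{SMALL_PREFIX}_{stage}")] = peak_val / ratio
            values.loc[gid] = row
            pattern[gid] = "seed_specific"
            peaks[gid] = peak_col
            if gid in roles.candidates:
                planted_sig.add((gid, stage))
                de_s3s5.append(gid)
            elif gid in fc_fail:
                planted_sig.add((gid, stage))  # significant q, weak fold change
        else:
            base = float(2 ** rng.normal(3.0, 0.5))
            row = background(base)
            if gid in roles.de_extra:
                stage = ("S3" if rng.integers(0, 2) == 0 else "S5") \
                    if gid in de_extra_s3s5 else "S2"
                idx = panel.labels.index(f"{LARGE_PREFIX}_{stage}")
                row[idx] = base * float(rng.uniform(4.5, 6.0))
                planted_sig.add((gid, stage))
                if stage in ("S3", "S5"):
                    de_s3s5.append(gid)
            values.loc[gid] = row
            pattern[gid] = "ubiquitous"

    rows = []
    for gid in ids:
        for stage in SEED_STAGES:
            v_large = values.at[gid, f"{LARGE_PREFIX}_{stage}"]
            v_small = values.at[gid, f"{SMALL_PREFIX}_{stage}"]
            log2fc = float(np.log2((v_large + 1.0) / (v_small + 1.0)))
            q = float(rng.uniform(0.001, 0.02)) if (gid, stage) in planted_sig \
                else float(rng.uniform(0.1, 0.9))
            rows.append({"gene_id": gid, "stage": stage,
                         "log2fc": round(log2fc, 4), "q": round(q, 5)})
    de_table = pd.DataFrame(rows)
    matrix = ExpressionMatrix(values=values.round(4), panel=panel)
    return matrix, de_table, peaks, pattern, sorted(de_s3s5)


def generate_qtls(
    cfg: SynthConfig,
    genes: list[GeneModel],
    rng: np.random.Generator | None = None,
    prefer_genes: tuple[str, ...] | list[str] = (),
) -> tuple[list[QTLInterval], dict[str, list[str]]]:
    """QTL intervals each fully containing a short run of genes; one interval
    additionally half-overlaps its downstream neighbour (a planted negative
    for the containment rule)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 4)
    if cfg.n_qtls == 0:
        return [], {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        by_chrom.setdefault(g.chrom, []).append(g)
    prefer = [g for g in prefer_genes]
    qtls: list[QTLInterval] = []
    members: dict[str, list[str]] = {}
    gene_by_id = {g.gene_id: g for g in genes}
    for qi in range(cfg.n_qtls):
        if qi < min(2, len(prefer)):
            anchor = gene_by_id[prefer[qi]]
        else:
            anchor = genes[int(rng.integers(0, len(genes)))]
        row = by_chrom[anchor.chrom]
        idx = row.index(anchor)
        run = row[idx: idx + int(rng.integers(2, 5))]
        start = max(0, run[0].start - int(rng.integers(200, 1200)))
        name = f"qtl{qi + 1:02d}"
        if qi == cfg.n_qtls - 1 and run[-1] is not row[-1]:
            # half-overlap the next gene: it must NOT count as a member
            nxt = row[row.index(run[-1]) + 1]
            end = (nxt.start + nxt.end) // 2
        else:
            end = run[-1].end + int(rng.integers(200, 1200))
        qtls.append(QTLInterval(anchor.chrom, start, end, name))
        members[name] = [g.gene_id for g in run]
    return qtls, members


# ---------------------------------------------------------------------------
# dataset orchestration and on-disk layout
# ---------------------------------------------------------------------------

FILES = {
    "genome": "genome.fa",
    "gff": "genes.gff3",
    "vcf": "{cultivar}.vcf",
    "coverage": "coverage.tsv",
    "expression": "expression.tsv",
    "tissues": "tissues.tsv",
    "de": "de_table.tsv",
    "qtls": "qtls.bed",
    "categories": "categories.tsv",
    "truth": "truth.json",
}

_CANDIDATE_CATEGORIES = (
    "cell_cycle", "cell_growth", "endoreduplication", "transcription_factor",
)


@dataclass
class SynthDataset:
    cfg: SynthConfig
    genome: Genome
    genes: list[GeneModel]
    calls_by_cultivar: dict[str, list[VariantCall]]
    coverage: CoverageTrack
    expression: ExpressionMatrix
    de_table: pd.DataFrame
    qtls: list[QTLInterval]
    categories: dict[str, str]
    truth: GroundTruth


def generate_dataset(cfg: SynthConfig) -> SynthDataset:
    """Run the whole generator with one seeded RNG."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genome = generate_reference(cfg, rng)
    genes = generate_gene_models(cfg, genome, rng)
    roles = assign_roles(cfg, genes, rng)
    calls, coverage, sites = plant_variants(
        cfg, genome, genes, rng,
        require_poly_genes=roles.candidates,
        forbid_poly_genes=roles.seedspec_no_poly,
    )
    matrix, de_table, peaks, pattern, de_s3s5 = generate_expression(
        cfg, genes, roles, rng
    )
    qtls, members = generate_qtls(cfg, genes, rng, prefer_genes=roles.candidates)
    categories = {
        gid: _CANDIDATE_CATEGORIES[i % len(_CANDIDATE_CATEGORIES)]
        for i, gid in enumerate(sorted(roles.candidates))
    }
    for i, gid in enumerate(sorted(roles.seedspec_poly_no_de)):
        categories[gid] = "other"
    truth = GroundTruth(
        sites=sites,
        seed_specific_genes=peaks,
        pattern_by_gene=pattern,
        de_genes_s3s5=de_s3s5,
        qtl_member_genes=members,
        candidate_genes=sorted(roles.candidates),
    )
    return SynthDataset(cfg, genome, genes, calls, coverage, matrix,
                        de_table, qtls, categories, truth)


def write_dataset(ds: SynthDataset, outdir: str | os.PathLike) -> None:
    from . import formats

    os.makedirs(outdir, exist_ok=True)
    p = lambda key, **kw: os.path.join(outdir, FILES[key].format(**kw))
    formats.write_fasta(ds.genome, p("genome"))
    formats.write_gff3(ds.genes, p("gff"))
    for cv in CULTIVARS:
        formats.write_vcf(
            ds.calls_by_cultivar[cv], p("vcf", cultivar=cv), ds.genome.lengths
        )
    formats.write_coverage(ds.coverage, p("coverage"))
    formats.write_expression(ds.expression, p("expression"), p("tissues"))
    formats.write_de_table(ds.de_table, p("de"))
    formats.write_bed(ds.qtls, p("qtls"))
    formats.write_categories(ds.categories, p("categories"))
    ds.truth.to_json(p("truth"))
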