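"""Region assignment, consequence calling (vs a re-translation oracle) and
the summary statistics."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq

from seedvar.annotate import (
    GeneIndex,
    assign_region,
    call_consequence,
    indel_spectrum,
    polymorphic_gene_outliers,
    summarize_genes,
    ts_tv,
    window_frequency,
)
from seedvar.formats import GeneModel, Genome, ValidationError
from seedvar.variant_core import DiffVariant, classify_variant
from seedvar.synthgen import SynthConfig, generate_gene_models, generate_reference


# ---------------------------------------------------------------------------
# independent re-translation oracle
# ---------------------------------------------------------------------------

def oracle_consequence(v, gene, genome, splice_window_bp=2):
    """Brute-force oracle: edit the chromosome base-by-base, re-splice the
    CDS, translate both proteins in full and diff them."""
    span = set(range(v.pos, v.pos + len(v.ref)))
    splice = set()
    for s, e in gene.introns():
        splice |= set(range(s, min(s + splice_window_bp, e)))
        splice |= set(range(max(e - splice_window_bp, s), e))
    if span & splice:
        return ("large_effect", "splice_site")
    cds_pos = [p for s, e, _ in gene.cds_segments for p in range(s, e)]
    if not span & set(cds_pos):
        return ("non_coding", None)
    alt = v.large_allele if v.large_allele != v.ref else v.small_allele
    seq = genome.sequences[v.chrom]
    chars = list(seq)
    chars[v.pos] = alt
    for p in range(v.pos + 1, v.pos + len(v.ref)):
        chars[p] = ""

    def spliced(source):
        s = "".join(source[p] for p in cds_pos)
        return str(Seq(s).reverse_complement()) if gene.strand == "-" else s

    ref_cds, alt_cds = spliced(list(seq)), spliced(chars)

    def protein(cds):
        usable = len(cds) - len(cds) % 3
        return str(Seq(cds[:usable]).translate())

    if alt_cds[:3] != "ATG":
        return ("large_effect", "start_loss")
    if (len(alt_cds) - len(ref_cds)) % 3 != 0:
        return ("large_effect", "frameshift")
    ref_prot, alt_prot = protein(ref_cds), protein(alt_cds)
    if "*" in alt_prot[:-1]:
        return ("large_effect", "stop_gain")
    if alt_prot == ref_prot:
        return ("synonymous", None)
    return ("non_synonymous", None)


# ---------------------------------------------------------------------------
# a hand-built plus-strand gene with known codons
# ---------------------------------------------------------------------------
# exon1 [100,130): 12 bp 5'UTR + 6 codons ATG GAA TGG CTT AAG GGA
# intron [130,160): GT ... AG
# exon2 [160,200): 7 codons CCT ACT GAT TGC CAT GAC TAA + 19 bp 3'UTR

_SEQ = (
    "A" * 100
    + "TTTTTTTTTTTT"
    + "ATGGAATGGCTTAAGGGA"
    + "GT" + "C" * 26 + "AG"
    + "CCTACTGATTGCCATGACTAA"
    + "G" * 19
    + "A" * 100
)
_GENOME = Genome({"c": _SEQ})
_GENE = GeneModel(
    gene_id="g1",
    chrom="c",
    strand="+",
    start=100,
    end=200,
    exons=[(100, 130), (160, 200)],
    cds_segments=[(112, 130, 0), (160, 181, 0)],
)


def _variant(pos, ref, alt):
    return DiffVariant("c", pos, ref, ref, alt, classify_variant(ref, alt))


@pytest.mark.parametrize(
    "pos,ref_len,alt,effect,subtype",
    [
        (117, 1, "G", "synonymous", None),        # GAA -> GAG (Glu)
        (120, 1, "A", "large_effect", "stop_gain"),  # TGG -> TGA
        (165, 3, None, "large_effect", "frameshift"),  # 2-bp deletion
        (130, 1, "A", "large_effect", "splice_site"),  # GT donor
        (112, 1, "G", "large_effect", "start_loss"),   # ATG -> GTG
        (105, 1, "A", "non_coding", None),        # 5'UTR exon base
        (140, 1, "A", "non_coding", None),        # intron interior
        (122, 1, "G", "non_synonymous", None),    # CTT -> CGT (Leu -> Arg)
    ],
)
def test_consequence_examples(pos, ref_len, alt, effect, subtype):
    ref = _SEQ[pos: pos + ref_len]
    v = _variant(pos, ref, alt if alt is not None else ref[0])
    got = call_consequence(v, _GENE, _GENOME)
    assert (got.effect, got.subtype) == (effect, subtype)
    assert oracle_consequence(v, _GENE, _GENOME) == (effect, subtype)


def test_inframe_codon_deletion_is_non_synonymous():
    # remove the ACT codon at [163,166), anchored on the base before
    v = _variant(162, _SEQ[162:166], _SEQ[162])
    got = call_consequence(v, _GENE, _GENOME)
    assert (got.effect, got.subtype) == ("non_synonymous", None)
    assert oracle_consequence(v, _GENE, _GENOME) == ("non_synonymous", None)


def test_consequence_matches_oracle_on_random_gene_models():
    cfg = SynthConfig(seed=11, n_chroms=1, chrom_length=120_000, n_genes=12)
    rng = np.random.default_rng(11)
    genome = generate_reference(cfg, rng)
    genes = generate_gene_models(cfg, genome, rng)
    bases = "ACGT"
    checked = 0
    for i in range(400):
        gene = genes[int(rng.integers(0, len(genes)))]
        pos = int(rng.integers(gene.start, gene.end - 8))
        kind = rng.random()
        seq = genome.sequences[gene.chrom]
        if kind < 0.4:
            ref = seq[pos]
            alt = bases[int(rng.integers(0, 4))]
        elif kind < 0.6:
            n = int(rng.integers(2, 4))
            ref = seq[pos: pos + n]
            alt = "".join(
                b for c in ref
                for b in [bases[(bases.index(c) + 1 + int(rng.integers(0, 3))) % 4]]
            )
        elif kind < 0.8:
            n = int(rng.integers(1, 5))
            ref = seq[pos: pos + 1 + n]
            alt = ref[0]
        else:
            n = int(rng.integers(1, 5))
            ref = seq[pos]
            alt = ref + "".join(bases[j] for j in rng.integers(0, 4, size=n))
        if ref == alt:
            continue
        v = DiffVariant(gene.chrom, pos, ref, ref, alt,
                        classify_variant(ref, alt))
        got = call_consequence(v, gene, genome)
        assert (got.effect, got.subtype) == oracle_consequence(v, gene, genome)
        checked += 1
    assert checked > 300


# ---------------------------------------------------------------------------
# region assignment
# ---------------------------------------------------------------------------

def test_region_precedence_and_strand():
    minus = GeneModel("g2", "c", "-", 10_000, 12_000,
                      exons=[(10_000, 12_000)],
                      cds_segments=[(10_100, 11_900, 0)])
    genes = [_GENE, minus]
    # 1501 bp upstream of the + strand TSS (gene starts at 100... use g2)
    assert assign_region(_variant(12_499, "A", "G"), genes).region == "promoter"
    assert assign_region(_variant(12_499, "A", "G"), genes).gene_id == "g2"
    assert assign_region(_variant(50, "A", "G"), genes).region == "promoter"
    assert assign_region(_variant(11_000, "A", "G"), genes).region == "exon"
    assert assign_region(_variant(140, "A", "G"), genes).region == "intron"
    assert assign_region(_variant(60_000, "A", "G"), genes).region == "intergenic"
    # genic placement wins over another gene's promoter
    nested = GeneModel("g3", "c", "+", 12_100, 12_900,
                       exons=[(12_100, 12_900)],
                       cds_segments=[(12_200, 12_800, 0)])
    label = assign_region(_variant(12_499, "A", "G"), genes + [nested])
    assert (label.region, label.gene_id) == ("exon", "g3")


def test_region_partition_sums(small_dataset):
    index = GeneIndex(small_dataset.genes)
    diffs = [
        DiffVariant(s.chrom, s.pos, s.ref, s.small_allele, s.large_allele,
                    s.variant_class)
        for s in small_dataset.truth.expected_diff()
    ]
    counts = {"promoter": 0, "exon": 0, "intron": 0, "intergenic": 0}
    for v in diffs:
        counts[index.assign_region(v).region] += 1
    assert sum(counts.values()) == len(diffs)


# ---------------------------------------------------------------------------
# Ts/Tv, indel spectrum, windows, outliers
# ---------------------------------------------------------------------------

def test_ts_tv_counts():
    snps = [
        _variant(1, "A", "G"), _variant(2, "C", "T"), _variant(3, "A", "T"),
        _variant(4, "G", "C"),
    ]
    res = ts_tv(snps)
    assert res["transition"] == 2 and res["transversion"] == 2
    assert res["by_substitution"] == {"A/G": 1, "C/T": 1, "A/T": 1, "C/G": 1}
    with pytest.raises(ValidationError):
        ts_tv([_variant(5, "A", "AT")])


def test_indel_spectrum():
    indels = [
        _variant(1, "A", "ATG"),   # insertion length 2
        _variant(2, "ATTA", "A"),  # deletion length 3
        _variant(3, "A", "AC"),    # insertion length 1
    ]
    spec = indel_spectrum(indels)
    assert spec == {"insertions": {2: 1, 1: 1}, "deletions": {3: 1}}
    total = sum(spec["insertions"].values()) + sum(spec["deletions"].values())
    assert total == len(indels)
    with pytest.raises(ValidationError):
        indel_spectrum([_variant(4, "A", "G")])


def test_window_frequency_arithmetic():
    genome = Genome({"chr1": "A" * 1_000_000, "chr2": "A" * 250_000})
    rng = np.random.default_rng(3)
    positions = sorted(int(p) for p in rng.integers(0, 1_000_000, size=142))
    variants = [_variant(p, "A", "G") for p in positions]
    for v in variants:
        v.chrom = "chr1"
    stats = window_frequency(variants, genome)
    chr1 = [w for w in stats if w.chrom == "chr1"]
    assert sum(w.total for w in chr1) == 142
    assert sum(w.frequency for w in chr1) / len(chr1) == pytest.approx(14.2)
    chr2 = [w for w in stats if w.chrom == "chr2"]
    assert all(w.total == 0 for w in chr2)
    # partial tile normalized by its true length
    genome2 = Genome({"c": "A" * 150_000})
    v = _variant(120_000, "A", "G")
    v.chrom = "c"
    tail = window_frequency([v], genome2)[-1]
    assert (tail.start, tail.end, tail.total) == (100_000, 150_000, 1)
    assert tail.frequency == pytest.approx(2.0)


def quartile_oracle(values):
    srt = sorted(values)
    pos = 0.75 * (len(srt) - 1)
    lo = math.floor(pos)
    frac = pos - lo
    q3 = srt[lo] if lo + 1 == len(srt) else srt[lo] + frac * (srt[lo + 1] - srt[lo])
    return {i for i, v in enumerate(values) if v > q3}, q3


class _S:
    def __init__(self, gene_id, dens):
        self.gene_id = gene_id
        self.exonic_density_per_kb = dens
        self.intronic_density_per_kb = 0.0


def test_quartile_outliers_example():
    summaries = [_S(f"g{i}", d) for i, d in enumerate([1, 2, 3, 4, 100])]
    flagged, q3 = polymorphic_gene_outliers(summaries, "exonic")
    assert q3 == pytest.approx(4.0)
    assert flagged == {"g4"}
    same = [_S(f"g{i}", 5.0) for i in range(6)]
    assert polymorphic_gene_outliers(same, "exonic")[0] == set()
    with pytest.raises(ValidationError):
        polymorphic_gene_outliers([_S("a", 1), _S("b", 2), _S("c", 3)], "exonic")


def test_quartile_outliers_match_oracle():
    rng = np.random.default_rng(5)
    for _ in range(200):
        n = int(rng.integers(4, 40))
        dens = [float(x) for x in np.round(rng.gamma(2.0, 2.0, size=n) + 0.01, 4)]
        summaries = [_S(f"g{i}", d) for i, d in enumerate(dens)]
        flagged, q3 = polymorphic_gene_outliers(summaries, "exonic")
        want_idx, want_q3 = quartile_oracle(dens)
        assert q3 == pytest.approx(want_q3)
        assert flagged == {f"g{i}" for i in want_idx}
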