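"""QTL containment, candidate selection and platform concordance."""

import numpy as np
import pytest

from seedvar.annotate import AnnotatedVariant
from seedvar.candidates import (
    genotype_concordance,
    qtl_membership,
    select_candidates,
)
from seedvar.expression import DEResult, SpecificityResult
from seedvar.formats import GeneModel, QTLInterval, ValidationError
from seedvar.variant_core import DiffVariant


def _gene(gene_id, start, end, chrom="c"):
    return GeneModel(gene_id, chrom, "+", start, end,
                     exons=[(start, end)],
                     cds_segments=[(start, start + 3 * ((end - start) // 3), 0)])


def test_containment_rule():
    g = _gene("g", 100, 200)
    assert qtl_membership(g, [QTLInterval("c", 50, 300, "q1")]) == (True, ["q1"])
    assert qtl_membership(g, [QTLInterval("c", 150, 300, "q2")]) == (False, [])
    assert qtl_membership(g, [QTLInterval("x", 50, 300, "q3")]) == (False, [])
    # any-overlap mode relaxes the rule
    assert qtl_membership(
        g, [QTLInterval("c", 150, 300, "q2")], containment=False
    ) == (True, ["q2"])


def test_containment_matches_exhaustive_oracle():
    rng = np.random.default_rng(6)
    for _ in range(300):
        genes = [
            _gene(f"g{i}", s, s + int(rng.integers(50, 400)))
            for i, s in enumerate(rng.integers(0, 50_000, size=8))
        ]
        qtls = [
            QTLInterval("c", int(s), int(s) + int(rng.integers(100, 5000)),
                        f"q{i}")
            for i, s in enumerate(rng.integers(0, 50_000, size=5))
        ]
        for g in genes:
            member, names = qtl_membership(g, qtls)
            want = sorted(
                q.name for q in qtls
                if q.chrom == g.chrom and q.start <= g.start and g.end <= q.end
            )
            assert names == want and member == bool(want)


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------

def _spec(gene_id, pattern="seed_specific"):
    return SpecificityResult(gene_id, 0.9, "JGK3_S3", pattern)


def _annot(gene_id, region="promoter", effect=None, subtype=None):
    v = DiffVariant("c", 10, "A", "A", "G", "SNP")
    return AnnotatedVariant(v, region, gene_id, effect, subtype)


def _de(gene_id, log2fc=2.0, q=0.01, stage="S3"):
    return DEResult(gene_id, stage, log2fc, q)


@pytest.fixture()
def scenario():
    genes = [_gene(f"g{i}", 1000 * i + 100, 1000 * i + 400) for i in range(6)]
    spec = [
        _spec("g0"), _spec("g1"), _spec("g2"), _spec("g3"),
        _spec("g4", pattern="ubiquitous"),
    ]
    annotated = [
        _annot("g0"),                                    # promoter evidence
        _annot("g1", region="exon", effect="non_synonymous"),
        _annot("g2", region="exon", effect="large_effect", subtype="stop_gain"),
        _annot("g3", region="exon", effect="synonymous"),  # not evidence
        _annot("g4"),                                    # not seed-specific
    ]
    de = {
        "g0": [_de("g0")],
        "g1": [_de("g1", stage="S5")],
        "g2": [_de("g2", log2fc=0.5)],  # fails the fold-change gate
        "g3": [_de("g3")],
        "g4": [_de("g4")],
    }
    qtls = [QTLInterval("c", 0, 600, "q1")]
    return genes, spec, annotated, de, qtls


def test_select_candidates_triple_intersection(scenario):
    genes, spec, annotated, de, qtls = scenario
    cands, marginals = select_candidates(
        spec, annotated, de, genes, qtls, categories={"g0": "cell_cycle"}
    )
    ids = [c.gene_id for c in cands]
    assert ids == ["g0", "g1"]
    by_id = {c.gene_id: c for c in cands}
    assert by_id["g0"].has_promoter_poly and not by_id["g0"].has_nonsyn
    assert by_id["g1"].has_nonsyn
    assert by_id["g0"].qtl_member and by_id["g0"].qtl_names == ["q1"]
    assert not by_id["g1"].qtl_member
    assert by_id["g0"].category == "cell_cycle"
    assert by_id["g1"].category == "unassigned"
    assert marginals == {
        "promoter": {"g0"}, "non_synonymous": {"g1"}, "large_effect": set()
    }
    # naive recomputation of the defining intersection
    seed_specific = {r.gene_id for r in spec if r.pattern == "seed_specific"}
    evidence = {
        a.gene_id for a in annotated
        if a.region == "promoter" or a.effect in ("non_synonymous", "large_effect")
    }
    de_pass = {
        g for g, rs in de.items()
        if any(r.stage in ("S3", "S5") and r.log2fc >= 1 and r.q <= 0.05
               for r in rs)
    }
    assert set(ids) == seed_specific & evidence & de_pass


def test_relaxing_q_threshold_never_shrinks_candidates(scenario):
    genes, spec, annotated, de, qtls = scenario
    strict, _ = select_candidates(spec, annotated, de, genes, qtls, max_q=0.001)
    loose, _ = select_candidates(spec, annotated, de, genes, qtls, max_q=0.5)
    assert {c.gene_id for c in strict} <= {c.gene_id for c in loose}


def test_select_candidates_rejects_unknown_gene_ids(scenario):
    genes, spec, annotated, de, qtls = scenario
    with pytest.raises(ValidationError):
        select_candidates(
            spec + [_spec("ghost")], annotated + [_annot("ghost")],
            de, genes, qtls,
        )


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def _panel(n_sites, cultivars=("a", "b", "c", "d")):
    return {
        ("c", i): {cv: "A" for cv in cultivars} for i in range(n_sites)
    }


def test_concordance_exact_ratio():
    a = _panel(48)
    b = _panel(48)
    mismatched = 0
    for site in list(b)[:13]:
        b[site]["a"] = "G"
        mismatched += 1
    report = genotype_concordance(a, b)
    assert (report.n_sites, report.n_cultivars) == (48, 4)
    assert report.n_comparisons == 192
    assert report.n_matches == 192 - mismatched
    assert report.concordance == pytest.approx(179 / 192)


def test_concordance_identical_and_errors():
    a = _panel(3)
    assert genotype_concordance(a, a).concordance == 1.0
    with pytest.raises(ValidationError):
        genotype_concordance({}, {})
    b = _panel(4)
    with pytest.raises(ValidationError):
        genotype_concordance(a, b)
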