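"""Candidate-gene prioritization: intersect seed-specific genes carrying
polymorphism evidence (promoter, non-synonymous or large-effect) with the
differential-expression direction at seed stages S3/S5, then attach QTL
membership and functional categories.  Also computes genotype concordance
between two calling platforms for validation panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotate import (
    AnnotatedVariant,
    LARGE_EFFECT,
    NON_SYNONYMOUS,
    PROMOTER,
)
from .expression import (
    DEResult,
    SEED_SPECIFIC,
    SpecificityResult,
    s3s5_higher_in_large,
)
from .formats import GeneModel, QTLInterval, ValidationError

CATEGORIES = (
    "cell_cycle",
    "cell_growth",
    "endoreduplication",
    "transcription_factor",
    "other",
    "unassigned",
)


@dataclass
class CandidateGene:
    gene_id: str
    has_promoter_poly: bool
    has_nonsyn: bool
    has_large_effect: bool
    de_s3s5_higher_in_large: bool
    qtl_member: bool
    qtl_names: list[str] = field(default_factory=list)
    category: str = "unassigned"


@dataclass
class ConcordanceReport:
    n_sites: int
    n_cultivars: int
    n_comparisons: int
    n_matches: int

    @property
    def concordance(self) -> float:
        return self.n_matches / self.n_comparisons


def qtl_membership(
    gene: GeneModel,
    qtls: list[QTLInterval],
    containment: bool = True,
) -> tuple[bool, list[str]]:
    """Is the gene "located within" a QTL?

    Under the default containment rule the gene span must lie fully inside
    the QTL interval (0-based half-open on both sides); ``containment=False``
    relaxes this to any overlap.
    """
    names = []
    for q in qtls:
        if q.chrom != gene.chrom:
            continue
        if containment:
            hit = q.start <= gene.start and gene.end <= q.end
        else:
            hit = q.start < gene.end and gene.start < q.end
        if hit:
            names.append(q.name)
    return bool(names), sorted(names)


def evidence_flags(
    annotated: list[AnnotatedVariant],
) -> dict[str, dict[str, bool]]:
    """Per-gene polymorphism evidence from annotated variants."""
    flags: dict[str, dict[str, bool]] = {}
    for a in annotated:
        if a.gene_id is None:
            continue
        f = flags.setdefault(
            a.gene_id,
            {"has_promoter_poly": False, "has_nonsyn": False, "has_large_effect": False},
        )
        if a.region == PROMOTER:
            f["has_promoter_poly"] = True
        if a.effect == NON_SYNONYMOUS:
            f["has_nonsyn"] = True
        if a.effect == LARGE_EFFECT:
            f["has_large_effect"] = True
    return flags


def select_candidates(
    spec_results: list[SpecificityResult],
    annotated: list[AnnotatedVariant],
    de_by_gene: dict[str, list[DEResult]],
    genes: list[GeneModel],
    qtls: list[QTLInterval],
    categories: dict[str, str] | None = None,
    containment: bool = True,
    min_fold: float = 2.0,
    max_q: float = 0.05,
) -> tuple[list[CandidateGene], dict[str, set[str]]]:
    """Candidate genes plus the three marginal evidence lists.

    A candidate is a seed-specific gene with >=1 of the three polymorphism
    evidence types that passes the DE gate higher-in-large at S3 and/or S5.
    QTL membership and functional category are reported but not gating.
    Returns (candidates, {"promoter"/"non_synonymous"/"large_effect": gene
    sets restricted to seed-specific DE-passing genes}).
    """
    categories = categories or {}
    gene_models = {g.gene_id: g for g in genes}
    seed_specific = {r.gene_id for r in spec_results if r.pattern == SEED_SPECIFIC}
    flags = evidence_flags(annotated)
    unknown = {g for g in flags if g not in gene_models}
    if unknown:
        raise ValidationError(f"annotated variants name unknown genes {sorted(unknown)}")

    candidates: list[CandidateGene] = []
    marginals: dict[str, set[str]] = {
        "promoter": set(),
        "non_synonymous": set(),
        "large_effect": set(),
    }
    for gene_id in sorted(seed_specific):
        f = flags.get(gene_id)
        if f is None or not any(f.values()):
            continue
        de_pass = s3s5_higher_in_large(
            de_by_gene.get(gene_id, []), min_fold=min_fold, max_q=max_q
        )
        if not de_pass:
            continue
        if f["has_promoter_poly"]:
            marginals["promoter"].add(gene_id)
        if f["has_nonsyn"]:
            marginals["non_synonymous"].add(gene_id)
        if f["has_large_effect"]:
            marginals["large_effect"].add(gene_id)
        member, names = qtl_membership(
            gene_models[gene_id], qtls, containment=containment
        )
        candidates.append(
            CandidateGene(
                gene_id=gene_id,
                has_promoter_poly=f["has_promoter_poly"],
                has_nonsyn=f["has_nonsyn"],
                has_large_effect=f["has_large_effect"],
                de_s3s5_higher_in_large=True,
                qtl_member=member,
                qtl_names=names,
                category=categories.get(gene_id, "unassigned"),
            )
        )
    return candidates, marginals


def category_summary(candidates: list[CandidateGene]) -> dict[str, dict[str, int]]:
    """Counts per functional category x evidence type."""
    out: dict[str, dict[str, int]] = {}
    for c in candidates:
        row = out.setdefault(
            c.category,
            {"promoter": 0, "non_synonymous": 0, "large_effect": 0, "qtl": 0},
        )
        row["promoter"] += c.has_promoter_poly
        row["non_synonymous"] += c.has_nonsyn
        row["large_effect"] += c.has_large_effect
        row["qtl"] += c.qtl_member
    return out


def genotype_concordance(
    set_a: dict[tuple[str, int], dict[str, str]],
    set_b: dict[tuple[str, int], dict[str, str]],
) -> ConcordanceReport:
    """Exact base agreement over all site x cultivar cells of two platforms'
    genotype tables (e.g. resequencing vs mass-spectrometry validation)."""
    if set(set_a) != set(set_b):
        raise ValidationError("site keys differ between the two call sets")
    if not set_a:
        raise ValidationError("no sites to compare")
    cultivars: set[str] = set()
    n_matches = n_comparisons = 0
    for site, calls_a in set_a.items():
        calls_b = set_b[site]
        if set(calls_a) != set(calls_b):
            raise ValidationError(f"cultivar keys differ at {site}")
        cultivars.update(calls_a)
        for cv, base in calls_a.items():
            n_comparisons += 1
            n_matches += base == calls_b[cv]
    if n_comparisons == 0:
        raise ValidationError("zero comparisons")
    return ConcordanceReport(
        n_sites=len(set_a),
        n_cultivars=len(cultivars),
        n_comparisons=n_comparisons,
        n_matches=n_matches,
    )
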