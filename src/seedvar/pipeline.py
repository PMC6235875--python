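"""End-to-end pipeline over an on-disk dataset directory.

Stages mirror the study's funnel: per-cultivar calls -> depth/fraction
filters -> merged 10-bp density filter -> group-differentiating set ->
region/consequence annotation -> seed-specificity screen -> S3/S5 DE gate ->
QTL-aware candidate genes.  Counts at every stage are collected in
``PipelineResult.funnel``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

from . import annotate as ann
from . import candidates as cand
from . import expression as expr
from . import formats
from . import variant_core as vc
from .synthgen import CULTIVARS, FILES, LARGE_CULTIVARS, SMALL_CULTIVARS


@dataclass
class PipelineResult:
    diffs: list[vc.DiffVariant]
    annotated: list[ann.AnnotatedVariant]
    window_stats: list[ann.WindowStat]
    gene_summaries: list[ann.GeneVariantSummary]
    spec_results: list[expr.SpecificityResult]
    candidate_genes: list[cand.CandidateGene]
    marginals: dict[str, set[str]]
    funnel: dict[str, int] = field(default_factory=dict)

    def diff_keys(self) -> set[tuple[str, int]]:
        return {(d.chrom, d.pos) for d in self.diffs}

    def class_counts(self) -> dict[str, int]:
        out = {c: 0 for c in vc.VARIANT_CLASSES}
        for d in self.diffs:
            out[d.variant_class] += 1
        return out


def run_pipeline(
    dirpath: str | os.PathLike,
    small: tuple[str, ...] = SMALL_CULTIVARS,
    large: tuple[str, ...] = LARGE_CULTIVARS,
    min_depth: int = vc.MIN_DEPTH,
    min_alt_fraction: float = vc.MIN_ALT_FRACTION,
    promoter_bp: int = ann.PROMOTER_BP,
    splice_window_bp: int = ann.SPLICE_WINDOW_BP,
    tau_threshold: float = expr.TAU_THRESHOLD,
    min_fold: float = expr.MIN_FOLD,
    max_q: float = expr.MAX_Q,
    qtl_containment: bool = True,
) -> PipelineResult:
    p = lambda key, **kw: os.path.join(dirpath, FILES[key].format(**kw))
    genome = formats.read_fasta(p("genome"))
    genes = formats.read_gff3(p("gff"))
    cultivars = (*small, *large)
    calls = {
        cv: formats.read_vcf(p("vcf", cultivar=cv), cv) for cv in cultivars
    }
    coverage = formats.read_coverage(p("coverage"))
    matrix = formats.read_expression(p("expression"), p("tissues"))
    de_table = formats.read_de_table(p("de"))
    qtls = formats.read_bed(p("qtls"))
    categories = (
        formats.read_categories(p("categories"))
        if os.path.exists(p("categories"))
        else {}
    )

    funnel: dict[str, int] = {}
    funnel["raw_calls"] = sum(len(v) for v in calls.values())
    passing = {
        cv: vc.filter_calls(v, min_depth, min_alt_fraction)
        for cv, v in calls.items()
    }
    funnel["calls_passing_filters"] = sum(len(v) for v in passing.values())

    sites = vc.collate_sites(calls, coverage)
    funnel["merged_sites"] = len(sites)
    sites = vc.apply_density_filter(
        sites, min_depth=min_depth, min_alt_fraction=min_alt_fraction
    )
    funnel["sites_after_density_filter"] = len(sites)

    diffs = vc.group_differential(sites, small, large, min_depth, min_alt_fraction)
    funnel["group_differentiating"] = len(diffs)

    annotated = ann.annotate_variants(
        diffs, genes, genome, promoter_bp, splice_window_bp
    )
    window_stats = ann.window_frequency(diffs, genome)
    gene_summaries = ann.summarize_genes(annotated, genes)

    spec_results = expr.screen_specificity(matrix, tau_threshold=tau_threshold)
    funnel["seed_specific_genes"] = sum(
        r.pattern == expr.SEED_SPECIFIC for r in spec_results
    )
    de_by_gene = expr.de_results_from_table(de_table)

    candidate_genes, marginals = cand.select_candidates(
        spec_results, annotated, de_by_gene, genes, qtls, categories,
        containment=qtl_containment, min_fold=min_fold, max_q=max_q,
    )
    funnel["candidate_genes"] = len(candidate_genes)
    return PipelineResult(
        diffs=diffs,
        annotated=annotated,
        window_stats=window_stats,
        gene_summaries=gene_summaries,
        spec_results=spec_results,
        candidate_genes=candidate_genes,
        marginals=marginals,
        funnel=funnel,
    )


def annotated_table(annotated: list[ann.AnnotatedVariant]) -> pd.DataFrame:
    """Flat per-variant table (1-based positions, VCF-style)."""
    rows = []
    for a in annotated:
        v = a.variant
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos + 1,
                "ref": v.ref,
                "small_allele": v.small_allele,
                "large_allele": v.large_allele,
                "class": v.variant_class,
                "region": a.region,
                "gene_id": a.gene_id or ".",
                "effect": a.effect or ".",
                "subtype": a.subtype or ".",
            }
        )
    return pd.DataFrame(rows)


def candidate_table(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for c in result.candidate_genes:
        rows.append(
            {
                "gene_id": c.gene_id,
                "has_promoter_poly": int(c.has_promoter_poly),
                "has_nonsyn": int(c.has_nonsyn),
                "has_large_effect": int(c.has_large_effect),
                "de_s3s5_higher_in_large": int(c.de_s3s5_higher_in_large),
                "qtl_member": int(c.qtl_member),
                "qtl_names": ",".join(c.qtl_names) or ".",
                "category": c.category,
            }
        )
    return pd.DataFrame(rows)
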