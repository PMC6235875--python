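"""Prioritize candidate seed-size genes and demonstrate platform concordance.

A candidate is a seed-specific gene carrying polymorphism evidence
(promoter variant, non-synonymous or large-effect change) that shows higher
expression in the large-seeded cultivar at S3 and/or S5.  QTL containment
and functional category are attached as supporting evidence.  A 48-SNP x
4-cultivar validation panel with 13 discordant bases illustrates the
concordance report (179/192 = 93.2% agreement).
"""

import argparse
from pathlib import Path

import pandas as pd

from seedvar.candidates import category_summary, genotype_concordance
from seedvar.pipeline import candidate_table, run_pipeline
from seedvar.synthgen import CULTIVARS, FILES, GroundTruth


def concordance_demo():
    """48 sites x 4 cultivars, 13 planted discordant bases."""
    reseq = {("Ca01", i): {cv: "A" for cv in CULTIVARS} for i in range(48)}
    massarray = {site: dict(calls) for site, calls in reseq.items()}
    for i in range(13):
        massarray[("Ca01", i)][CULTIVARS[i % 4]] = "G"
    return genotype_concordance(reseq, massarray)


def main() -> None:
    root = Path(__file__).resolve().parents[1] / "results"
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=root / "dataset")
    ap.add_argument("--out", type=Path, default=root)
    args = ap.parse_args()

    result = run_pipeline(args.data_dir)
    table = candidate_table(result)
    table.to_csv(args.out / "candidates.tsv", sep="\t", index=False)

    print("discovery funnel:", result.funnel)
    print(f"candidates: {len(result.candidate_genes)} "
          f"(promoter: {len(result.marginals['promoter'])}, "
          f"non-synonymous: {len(result.marginals['non_synonymous'])}, "
          f"large-effect: {len(result.marginals['large_effect'])})")
    summary = category_summary(result.candidate_genes)
    pd.DataFrame(summary).T.to_csv(args.out / "category_summary.tsv", sep="\t")
    print("evidence by category:", summary)

    truth = GroundTruth.from_json(args.data_dir / FILES["truth"])
    got = {c.gene_id for c in result.candidate_genes}
    print(f"planted candidate recovery: "
          f"{'exact' if got == set(truth.candidate_genes) else 'MISMATCH'}")

    report = concordance_demo()
    print(f"validation concordance demo: {report.n_matches}/"
          f"{report.n_comparisons} bases ({report.concordance:.1%})")
    print(f"wrote candidates.tsv and category_summary.tsv under {args.out}")


if __name__ == "__main__":
    main()
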