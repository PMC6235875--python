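"""Annotate the differentiating variants and summarize the landscape.

Assigns each variant a genomic region (promoter = 2 kb upstream of the TSS,
exon, intron, intergenic) and a coding consequence (synonymous,
non-synonymous, large-effect with its subtype), then computes the Ts/Tv
spectrum, the InDel length spectrum, per-100-kb window frequencies and the
highly polymorphic genes (per-kb density above Q3).
"""

import argparse
from collections import Counter
from pathlib import Path

import pandas as pd
import pysam

from seedvar import annotate as ann
from seedvar import formats
from seedvar.pipeline import annotated_table
from seedvar.synthgen import FILES
from seedvar.variant_core import DiffVariant


def read_diff_vcf(path):
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            out.append(DiffVariant(
                chrom=rec.chrom, pos=rec.pos - 1, ref=rec.ref,
                small_allele=rec.info["SMALL_ALLELE"],
                large_allele=rec.info["LARGE_ALLELE"],
                variant_class=rec.info["CLASS"],
            ))
    return out


def main() -> None:
    root = Path(__file__).resolve().parents[1] / "results"
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=root / "dataset")
    ap.add_argument("--diff-vcf", type=Path, default=root / "diff.vcf")
    ap.add_argument("--out", type=Path, default=root)
    args = ap.parse_args()

    genome = formats.read_fasta(args.data_dir / FILES["genome"])
    genes = formats.read_gff3(args.data_dir / FILES["gff"])
    diffs = read_diff_vcf(args.diff_vcf)

    annotated = ann.annotate_variants(diffs, genes, genome)
    annotated_table(annotated).to_csv(args.out / "annotated.tsv", sep="\t",
                                      index=False)

    regions = Counter(a.region for a in annotated)
    effects = Counter(a.effect for a in annotated if a.effect)
    print("regions:", dict(regions))
    print("coding consequences:", dict(effects))

    snps = [d for d in diffs if d.variant_class == "SNP"]
    tt = ann.ts_tv(snps)
    total = tt["transition"] + tt["transversion"]
    print(f"Ts/Tv: {tt['transition']}/{tt['transversion']} "
          f"({100 * tt['transition'] / total:.1f}% transitions)")

    indels = [d for d in diffs if d.variant_class == "InDel"]
    spec = ann.indel_spectrum(indels)
    ins, dels = spec["insertions"], spec["deletions"]
    print(f"InDels: {sum(ins.values())} insertions "
          f"(1-{max(ins)} bp), {sum(dels.values())} deletions (1-{max(dels)} bp)")

    windows = ann.window_frequency(diffs, genome)
    pd.DataFrame(
        [
            {"chrom": w.chrom, "start": w.start, "end": w.end,
             **w.counts, "frequency_per_100kb": round(w.frequency, 3)}
            for w in windows
        ]
    ).to_csv(args.out / "window_frequency.tsv", sep="\t", index=False)

    summaries = ann.summarize_genes(annotated, genes)
    rows = []
    for region in ("exonic", "intronic"):
        flagged, q3 = ann.polymorphic_gene_outliers(summaries, region)
        print(f"highly polymorphic genes ({region}): {len(flagged)} "
              f"above Q3={q3:.3f}/kb")
        rows += [{"region": region, "gene_id": g, "q3_per_kb": round(q3, 4)}
                 for g in sorted(flagged)]
    pd.DataFrame(rows).to_csv(args.out / "polymorphic_gene_outliers.tsv",
                              sep="\t", index=False)
    print(f"wrote annotated.tsv, window_frequency.tsv, "
          f"polymorphic_gene_outliers.tsv under {args.out}")


if __name__ == "__main__":
    main()
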