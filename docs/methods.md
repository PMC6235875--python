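# Methods

This note documents the models, rules and numerical choices behind seedvar:
what each stage computes, which parameters matter, what the synthetic data
does and does not emulate, and where the design was genuinely open.

## Coordinate model and file boundaries

All in-memory coordinates are 0-based half-open. GFF3 and VCF are 1-based
inclusive on disk; conversion happens exactly once, in `seedvar.formats`,
and nowhere else. BED is 0-based half-open on both sides of the boundary.
VCF records must be biallelic; MNP and complex variants are single records
with multi-base REF/ALT (the atomic-record convention of haplotype-aware
callers) and are never decomposed into constituent SNPs. AF values parsed
from VCF are rounded to six decimals so that a printed `0.9` still satisfies
the `>= 0.9` threshold after float32 round-tripping.

## Variant classes and site filters

`classify_variant` trims the common prefix/suffix of an allele pair (keeping
one base per side) and then classes it: both length 1 → SNP; equal lengths
≥ 2 → MNP (at least the two flanking positions differ); one allele a
prefix/suffix extension of the other → InDel; mixed substitution and length
change → complex. Anchored VCF spellings (`A→ATG`) and padded substitutions
(`CA→CG`) therefore classify the same as their minimal forms.

Calls are confident at depth ≥ 10 and alternate fraction ≥ 0.9 (both
inclusive). The 0.9 fraction effectively excludes heterozygotes, which is
the intended behaviour for a selfing crop: genotypes are modelled as
homozygous single-allele calls per cultivar throughout.

The density filter removes every variant lying in **any** 10-bp window
containing ≥ 3 variant start positions — equivalently, any member of a
position triple with span ≤ 9. It runs per chromosome on the merged site
set (all cultivars, all classes jointly, restricted to sites with at least
one threshold-passing call) *before* the group comparison. Running it on
the merged set rather than per cultivar VCF is a deliberate fixed choice;
the alternative would let a cluster present in only one cultivar survive.

## Group-differentiating sites

A site is emitted when (i) all four cultivars have a confident allele,
(ii) the two small-seeded cultivars agree, (iii) the two large-seeded
cultivars agree, and (iv) the group alleles differ. Three details:

- A cultivar with a record that *fails* the thresholds is a no-call, not a
  reference call — a failed call is ambiguous evidence.
- A cultivar with no record is confidently reference only where a coverage
  track shows depth ≥ 10. The track is a sparse sidecar (flat default depth
  plus per-site exceptions); a genome-wide per-base vector would add nothing
  at this scale.
- Two different non-reference alleles across the groups still differentiate
  them; neither group needs to match the reference. The variant class (and,
  downstream, the consequence) is computed on the large-group allele when it
  is non-reference, otherwise on the small-group allele.

`pairwise_differential` is the same operation restricted to one cultivar per
side; the group set is provably a subset of every small-vs-large pairwise
set, and the test suite checks this by enumeration.

## Region assignment

Precedence: exon > intron > promoter > intergenic, applied to the variant's
reference span. The promoter is the 2 kb immediately upstream of the TSS
(transcript start, not CDS start), strand-aware. When a span touches several
genes, ties break by nearest TSS and then lexicographic gene id. The
precedence means a variant inside one gene that also sits in another gene's
promoter is labelled genic — the categories partition the variant set.

## Coding consequences

For a variant overlapping a gene, splice disruption is tested first: the
reference span intersecting the terminal 2 bp of any intron (the canonical
GT/AG dinucleotides) is `large_effect/splice_site`. The 2-bp window is a
parameter (`splice_window_bp`); the classical donor/acceptor width is the
default. Variants not overlapping the CDS (UTR exon or intron interior) are
`non_coding`.

Otherwise the mutated CDS is rebuilt: the chromosome is spliced
(`seq[:pos] + alt + seq[pos+len(ref):]`), CDS segment boundaries are remapped
(positions past the edit shift by the length difference; a boundary inside
the replaced span clips to the end of the alternate allele), and the segments
are concatenated in transcript orientation (reverse complement on minus
strand). Classification then follows the severity chain

    splice_site > start_loss > stop_gain > frameshift
    > non_synonymous > synonymous

with these definitions: any change leaving the rebuilt CDS without an
initial ATG is `start_loss`; a net CDS length change not divisible by 3 is
`frameshift`; a frame-preserving change whose translation contains a stop
before the final codon is `stop_gain`; otherwise the full reference and
alternate proteins are compared — identical means `synonymous`, different
means `non_synonymous`. In-frame InDels land in `non_synonymous` (the
three-way CDS classification has no separate in-frame class). Restricting
`stop_gain` to frame-preserving changes keeps the chain well-defined: a
1-bp deletion whose shifted frame happens to hit an early stop is a
frameshift, not a stop gain.

The test suite verifies this implementation against an independent oracle
that edits the chromosome base-by-base, re-splices, translates both proteins
in full and diffs them — 100% agreement over ≥ 1,000 random variants of all
four classes on random gene models of both strands.

## Summary statistics

- **Ts/Tv** is computed on the differentiating substitution — the
  small-group vs large-group allele pair — so it is defined even when both
  alleles are non-reference. A↔G and C↔T are transitions.
- **InDel spectrum**: length = |len(alt) − len(ref)| of the non-reference
  group allele; alt longer ⇒ insertion.
- **Window frequencies** use non-overlapping 100-kb tiles from position 0;
  the final partial tile is normalized by its true length. Tile counts sum
  to chromosome totals by construction and by test.
- **Highly polymorphic genes**: per-kb densities over exonic (or intronic)
  gene space, among genes with ≥ 1 polymorphism there; flagged strictly
  above Q3. Q3 uses linear interpolation between order statistics (the
  common default); the boxplot convention in the source material names no
  method, so the choice is explicit and oracle-tested. Fewer than four genes
  is an error rather than a silent quartile.

## Tissue specificity and the DE gate

τ is the max-normalized complement mean over N tissues, computed on
log2(FPKM + 1) by default (`log_transform=False` switches to raw values,
under which τ is exactly scale-invariant). τ = 0 for a uniform profile,
1 for single-tissue expression; moving expression mass onto the peak never
decreases it. All-zero profiles carry no τ and classify as `not_expressed`
(cutoff 1 FPKM). A gene is `seed_specific` when its peak column is a seed
stage **and** τ > 0.6 (strict); expressed nowhere in seed but somewhere else
is `non_seed`; everything else is `ubiquitous`. The 14 seed columns from the
two cultivars enter the index as separate tissues (no pre-averaging) — the
cited index literature does not restate its exact floor/averaging choices,
so both the transform and the threshold are explicit parameters.

The DE gate takes per-stage (gene, log2fc, q) rows as input — q-values come
from the upstream DE caller or the generator, never re-derived here. Pass =
|log2fc| ≥ 1 and q ≤ 0.05, both inclusive; the candidate screen additionally
requires `higher_in = large` at S3 and/or S5. When only replicate FPKMs
exist, `de_from_replicates` provides a clearly-labelled synthetic stand-in
(Welch t per gene, Benjamini–Hochberg across genes, fold change of means
with pseudocount 1) used in tests only.

## Candidates, QTLs, concordance

Candidate = seed-specific ∧ (promoter OR non-synonymous OR large-effect
evidence) ∧ DE-pass higher-in-large at S3/S5. QTL membership and functional
category (from a user-supplied gene→category table) are reported, not
gating. "Located within" a QTL means full containment of the gene span in
the interval, tested in half-open coordinates; any-overlap is available
behind `containment=False` since interval tools default to overlap. The
marginal promoter / non-synonymous / large-effect lists are emitted
separately because one gene can carry several evidence types.

Genotype concordance counts exact base matches over all site × cultivar
cells of two platforms' tables and reports the raw fraction; for the classic
48-site × 4-cultivar panel with 179 matches this is 179/192 = 93.2%, and the
report surfaces both counts rather than a rounded percentage.

## The synthetic study

`SynthConfig` defaults define the study conditions: 2 chromosomes × 2 Mb,
200 genes, 4,960 planted differentiating variants (4,200 SNP / 110 MNP /
370 InDel / 280 complex — roughly the class proportions of cultivar
resequencing), 300 confounders, ~99 low-depth spoilers (2% of the planted
set), 15 three-SNP density clusters, 30 seed-specific genes of which 12 are
candidates, 6 QTLs. One seeded numpy Generator drives everything; a fixed
config reproduces byte-identical files.

What it emulates, concretely:

- Genes are designed in transcript space (5′UTR, ATG + non-stop codons +
  stop, GT..AG introns ≥ 150 bp, multi-exon, both strands) and stamped into
  the uniform-base genome, so every consequence label is re-derivable from
  the emitted FASTA+GFF3 alone. Gene spans keep ≥ 4.5 kb clear of each
  other, making 2-kb promoter labels unambiguous.
- Planted variants keep ≥ 2 cells of a 32-bp occupancy grid apart, so no
  accidental 10-bp cluster forms; intentional clusters (span ≤ 9) are the
  only density-filter casualties. SNP alternates follow a transition-biased
  substitution model (P(transition) = 0.65), giving a realistic Ts excess;
  insertion lengths run 1–20 bp and deletions 1–10 bp with geometrically
  decaying weights.
- Confounders plant each failure mode the filters must catch: alleles shared
  by all four cultivars, within-group polymorphism, one spoiled alternate
  fraction (0.6–0.85), one spoiled depth (4–9), and low-coverage reference
  cultivars recorded in the coverage sidecar.
- Expression profiles realize the four patterns; planted DE genes carry a
  ≥ 4-fold cultivar ratio at S3/S5 with q ∈ [0.001, 0.02], while every
  non-planted (gene, stage) pair draws q ∈ [0.1, 0.9], so the gate's decision
  set is deterministic by construction. Negative controls include
  seed-specific genes with no qualifying polymorphism, and polymorphic
  seed-specific genes that fail DE on fold change or on q.
- QTL intervals fully contain short gene runs (pads shorter than the
  intergenic gaps keep neighbours out); one interval half-overlaps its
  downstream neighbour as a planted negative for the containment rule.

What it does **not** emulate: read-level data (no FASTQ/BAM, no alignment or
base-quality error model), linkage disequilibrium or demography, codon
usage, heterozygosity, alternative splicing (one transcript per gene),
overlapping genes, or realistic chromosome counts and sizes. Passing the
planted-recovery suite therefore shows the *rules* are implemented exactly
as specified, not that the pipeline is robust to alignment artefacts or
messy real-world call sets.

## Problem sizes and determinism

The default end-to-end study (generate, write, read back, full funnel) runs
in a few seconds on one CPU; oracle suites use 1,000 random cases for the
density filter, consequence caller and QTL containment and 500 for the
quartile rule, all seeded. Property tests run hypothesis in derandomized
mode. `scripts/acceptance.py --seed N` threads the given seed through the
study and derives sub-seeds (N + small offsets) for the oracle RNGs.

## Known limitations

- Variants whose reference span crosses a CDS boundary without touching a
  splice window (possible only for multi-base variants entering from a UTR)
  are classified via the boundary-clipping remap described above; the oracle
  agrees on all randomly generated cases, but pathological spellings (e.g.
  a deletion spanning an entire intron) are out of scope.
- Sites where cultivar records disagree on the REF spelling raise instead of
  re-harmonizing alleles; the generator never emits such records, and real
  multi-caller inputs would need upstream normalization.
- The concordance operation compares single bases per cell, matching the
  mass-spectrometry validation design; it does not handle indel validation.
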