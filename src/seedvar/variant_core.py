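"""Variant classification, site filters and the group-differentiating set.

The central object is the *group-differentiating variant*: a site where both
small-seeded cultivars carry one allele, both large-seeded cultivars carry
another, and the two alleles differ — with every cultivar's call confident
(depth >= 10; alternate-allele fraction >= 0.9 for non-reference calls, or
coverage >= 10 for reference calls).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .formats import CoverageTrack, Genome, ValidationError, VariantCall

MIN_DEPTH = 10
MIN_ALT_FRACTION = 0.9
DENSITY_WINDOW_BP = 10
DENSITY_MAX_IN_WINDOW = 2

SNP = "SNP"
MNP = "MNP"
INDEL = "InDel"
COMPLEX = "complex"
VARIANT_CLASSES = (SNP, MNP, INDEL, COMPLEX)


def classify_variant(ref: str, alt: str) -> str:
    """Classify a ref/alt allele pair as SNP, MNP, InDel or complex.

    SNP: one substituted base.  MNP: >=2 consecutive substituted bases, same
    allele lengths.  InDel: pure length change.  Complex: substitution and
    length change mixed in one record.  Shared prefix/suffix bases (VCF
    anchor padding) are trimmed before classification.
    """
    if not ref or not alt:
        raise ValidationError("empty allele")
    if ref == alt:
        raise ValidationError("identical ref and alt alleles")
    # trim common suffix then prefix, keeping >=1 base on each side
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
    if len(ref) == len(alt):
        return SNP if len(ref) == 1 else MNP
    shorter, longer = sorted((ref, alt), key=len)
    if longer.startswith(shorter) or longer.endswith(shorter):
        return INDEL
    return COMPLEX


def filter_calls(
    calls: Iterable[VariantCall],
    min_depth: int = MIN_DEPTH,
    min_alt_fraction: float = MIN_ALT_FRACTION,
) -> list[VariantCall]:
    """Retain calls with depth >= min_depth and alt_fraction >= min_alt_fraction."""
    if min_depth <= 0:
        raise ValidationError("min_depth must be positive")
    if not 0.0 <= min_alt_fraction <= 1.0:
        raise ValidationError("min_alt_fraction outside [0,1]")
    return [
        c
        for c in calls
        if c.depth >= min_depth and c.alt_fraction >= min_alt_fraction
    ]


def density_filter(
    positions: Sequence[int],
    window_bp: int = DENSITY_WINDOW_BP,
    max_in_window: int = DENSITY_MAX_IN_WINDOW,
) -> list[int]:
    """Drop every variant lying in any window of ``window_bp`` consecutive
    bases that contains more than ``max_in_window`` variant start positions.

    ``positions`` are the sorted variant start positions of one chromosome.
    With the defaults this removes a variant iff it belongs to a triple whose
    position span is <= 9 — the cluster rule used to purge alignment
    artefacts around indels.
    """
    positions = list(positions)
    if positions != sorted(positions):
        raise ValidationError("positions must be sorted")
    k = max_in_window  # a window is "bad" once it holds k+1 variants
    removed = [False] * len(positions)
    for i in range(len(positions) - k):
        if positions[i + k] - positions[i] <= window_bp - 1:
            for j in range(i, i + k + 1):
                removed[j] = True
    return [p for p, r in zip(positions, removed) if not r]


# ---------------------------------------------------------------------------
# site collation and group comparison
# ---------------------------------------------------------------------------

REF_CALL = "reference"
NO_CALL = "no-call"


@dataclass
class SiteGenotypes:
    """Per-cultivar observations at one site.

    ``calls`` maps cultivar -> VariantCall for cultivars with a VCF record;
    the remaining cultivars are implicitly reference (trusted only where the
    coverage track shows sufficient depth).
    """

    chrom: str
    pos: int
    ref: str
    calls: dict[str, VariantCall]
    ref_depth: dict[str, int]  # coverage for cultivars without a record

    def allele(
        self,
        cultivar: str,
        min_depth: int = MIN_DEPTH,
        min_alt_fraction: float = MIN_ALT_FRACTION,
    ) -> str | None:
        """Confident allele for a cultivar, or None (no-call).

        A cultivar with a record is confident iff depth and fraction pass; a
        cultivar without one is confidently reference iff coverage passes.
        A record that fails the thresholds is ambiguous evidence — it yields
        no-call rather than falling back to reference.
        """
        if cultivar in self.calls:
            c = self.calls[cultivar]
            if c.depth >= min_depth and c.alt_fraction >= min_alt_fraction:
                return c.alt
            return None
        if cultivar in self.ref_depth and self.ref_depth[cultivar] >= min_depth:
            return self.ref
        return None


@dataclass
class DiffVariant:
    """A site whose allele cleanly separates the two cultivar groups."""

    chrom: str
    pos: int
    ref: str
    small_allele: str
    large_allele: str
    variant_class: str

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def collate_sites(
    calls_by_cultivar: dict[str, list[VariantCall]],
    coverage: CoverageTrack,
) -> list[SiteGenotypes]:
    """Merge per-cultivar call lists into per-site records.

    Records at a shared position must agree on REF (synthgen guarantees it;
    discordant representations raise rather than being re-harmonized).
    """
    by_site: dict[tuple[str, int], dict[str, VariantCall]] = defaultdict(dict)
    for cultivar, calls in calls_by_cultivar.items():
        for c in calls:
            if c.cultivar != cultivar:
                raise ValidationError(
                    f"call labelled {c.cultivar!r} under cultivar {cultivar!r}"
                )
            by_site[(c.chrom, c.pos)][cultivar] = c
    sites: list[SiteGenotypes] = []
    for (chrom, pos), calls in sorted(by_site.items()):
        refs = {c.ref for c in calls.values()}
        if len(refs) != 1:
            raise ValidationError(
                f"{chrom}:{pos + 1}: cultivar records disagree on REF {sorted(refs)}"
            )
        ref = refs.pop()
        ref_depth = {
            cv: coverage.depth(cv, chrom, pos)
            for cv in calls_by_cultivar
            if cv not in calls
        }
        sites.append(SiteGenotypes(chrom, pos, ref, calls, ref_depth))
    return sites


def _diff_class(ref: str, small: str, large: str) -> str:
    # class of the differentiating change, relative to the reference where
    # one group is reference, otherwise on the large-group allele
    alt = large if large != ref else small
    return classify_variant(ref, alt)


def group_differential(
    sites: Iterable[SiteGenotypes],
    small: Sequence[str],
    large: Sequence[str],
    min_depth: int = MIN_DEPTH,
    min_alt_fraction: float = MIN_ALT_FRACTION,
) -> list[DiffVariant]:
    """Sites where the small pair and the large pair carry distinct alleles.

    All four cultivars must be confidently called (see SiteGenotypes.allele);
    within-group disagreement or any no-call drops the site.  Two different
    non-reference alleles across the groups still differentiate them.
    """
    small, large = list(small), list(large)
    if set(small) & set(large):
        raise ValidationError("a cultivar cannot be in both groups")
    out: list[DiffVariant] = []
    for site in sites:
        known = set(site.calls) | set(site.ref_depth)
        unknown = (set(small) | set(large)) - known
        if unknown:
            raise ValidationError(
                f"{site.chrom}:{site.pos + 1}: no record or coverage for "
                f"cultivars {sorted(unknown)}"
            )
        alleles = {
            cv: site.allele(cv, min_depth, min_alt_fraction)
            for cv in (*small, *large)
        }
        if any(a is None for a in alleles.values()):
            continue
        small_alleles = {alleles[cv] for cv in small}
        large_alleles = {alleles[cv] for cv in large}
        if len(small_alleles) != 1 or len(large_alleles) != 1:
            continue
        (small_allele,) = small_alleles
        (large_allele,) = large_alleles
        if small_allele == large_allele:
            continue
        out.append(
            DiffVariant(
                chrom=site.chrom,
                pos=site.pos,
                ref=site.ref,
                small_allele=small_allele,
                large_allele=large_allele,
                variant_class=_diff_class(site.ref, small_allele, large_allele),
            )
        )
    return out


def pairwise_differential(
    sites: Iterable[SiteGenotypes],
    cultivar_a: str,
    cultivar_b: str,
    min_depth: int = MIN_DEPTH,
    min_alt_fraction: float = MIN_ALT_FRACTION,
) -> list[DiffVariant]:
    """group_differential restricted to one cultivar per side."""
    if cultivar_a == cultivar_b:
        raise ValidationError("pairwise comparison needs two distinct cultivars")
    return group_differential(
        sites, [cultivar_a], [cultivar_b], min_depth, min_alt_fraction
    )


def apply_density_filter(
    sites: list[SiteGenotypes],
    window_bp: int = DENSITY_WINDOW_BP,
    max_in_window: int = DENSITY_MAX_IN_WINDOW,
    min_depth: int = MIN_DEPTH,
    min_alt_fraction: float = MIN_ALT_FRACTION,
) -> list[SiteGenotypes]:
    """Density-filter the merged site set per chromosome.

    Positions entering the filter are the start positions of sites carrying
    at least one threshold-passing call in any cultivar (all variant classes
    jointly), mirroring a post-calling cluster purge on the merged call set.
    """
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for s in sites:
        if any(
            c.depth >= min_depth and c.alt_fraction >= min_alt_fraction
            for c in s.calls.values()
        ):
            by_chrom[s.chrom].append(s.pos)
    keep: set[tuple[str, int]] = set()
    for chrom, positions in by_chrom.items():
        for p in density_filter(sorted(positions), window_bp, max_in_window):
            keep.add((chrom, p))
    return [s for s in sites if (s.chrom, s.pos) in keep]
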