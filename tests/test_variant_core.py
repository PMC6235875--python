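"""Variant classing, site filters and the group-differential operation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedvar.formats import CoverageTrack, ValidationError, VariantCall
from seedvar.variant_core import (
    COMPLEX,
    INDEL,
    MNP,
    SNP,
    SiteGenotypes,
    classify_variant,
    collate_sites,
    density_filter,
    filter_calls,
    group_differential,
    pairwise_differential,
)


def density_oracle(positions, window_bp=10, max_in_window=2):
    """Exhaustive scan of every possible window alignment."""
    positions = sorted(positions)
    if not positions:
        return []
    removed = set()
    for w in range(positions[0] - window_bp, positions[-1] + 1):
        inside = [p for p in positions if w <= p < w + window_bp]
        if len(inside) > max_in_window:
            removed.update(inside)
    return [p for p in positions if p not in removed]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ref,alt,expected",
    [
        ("A", "G", SNP),
        ("AT", "GC", MNP),
        ("ATG", "GCA", MNP),
        ("A", "ATG", INDEL),
        ("ATTA", "A", INDEL),
        ("TGA", "A", INDEL),  # suffix-anchored deletion
        ("ATG", "GC", COMPLEX),
        ("CA", "CG", SNP),  # padded substitution trims to a SNP
        ("ACT", "AGT", SNP),
    ],
)
def test_classify_variant(ref, alt, expected):
    assert classify_variant(ref, alt) == expected


def test_classify_rejects_identical_or_empty():
    with pytest.raises(ValidationError):
        classify_variant("A", "A")
    with pytest.raises(ValidationError):
        classify_variant("", "A")


# ---------------------------------------------------------------------------
# depth / fraction filter
# ---------------------------------------------------------------------------

def _call(depth, af):
    return VariantCall("c", 10, "A", "G", "cv", depth, af)


def test_filter_calls_thresholds():
    kept = filter_calls([_call(12, 0.95), _call(9, 1.0), _call(10, 0.89)])
    assert [(c.depth, c.alt_fraction) for c in kept] == [(12, 0.95)]
    assert filter_calls([]) == []
    # order preserved
    calls = [_call(20, 0.95), _call(11, 0.92), _call(50, 0.99)]
    assert filter_calls(calls) == calls


# ---------------------------------------------------------------------------
# density filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "positions,retained",
    [
        ([100, 105, 109], []),  # span 9 -> one 10-bp window holds all three
        ([100, 105, 120], [100, 105, 120]),
        ([100, 109, 110], [100, 109, 110]),  # no triple within span <= 9
        ([], []),
        ([1, 2, 3, 50], [50]),
        ([1, 2, 10, 11, 30], [30]),  # {2,10,11} and {1,2,10} both span <= 9
    ],
)
def test_density_filter_examples(positions, retained):
    assert density_filter(positions) == retained
    assert density_oracle(positions) == retained


def test_density_filter_requires_sorted_input():
    with pytest.raises(ValidationError):
        density_filter([10, 5])


@settings(derandomize=True, max_examples=200)
@given(
    st.lists(st.integers(min_value=0, max_value=120), min_size=0, max_size=25),
    st.integers(min_value=2, max_value=25),
)
def test_density_filter_matches_exhaustive_scan(positions, window_bp):
    positions = sorted(set(positions))
    assert density_filter(positions, window_bp=window_bp) == density_oracle(
        positions, window_bp=window_bp
    )


# ---------------------------------------------------------------------------
# group differential
# ---------------------------------------------------------------------------

SMALL = ("s1", "s2")
LARGE = ("l1", "l2")


def _site(alleles, depths=None, afs=None, ref="A", ref_depth=40, pos=100):
    """alleles: cultivar -> alt allele (omit for reference cultivars)."""
    depths = depths or {}
    afs = afs or {}
    calls = {
        cv: VariantCall("c", pos, ref, alt, cv,
                        depths.get(cv, 30), afs.get(cv, 0.95))
        for cv, alt in alleles.items()
    }
    refs = {
        cv: ref_depth for cv in (*SMALL, *LARGE) if cv not in alleles
    }
    return SiteGenotypes("c", pos, ref, calls, refs)


def test_basic_differentiating_site():
    (d,) = group_differential([_site({"l1": "G", "l2": "G"})], SMALL, LARGE)
    assert (d.small_allele, d.large_allele, d.variant_class) == ("A", "G", SNP)


def test_within_group_polymorphism_not_emitted():
    assert group_differential(
        [_site({"s1": "G", "l1": "G", "l2": "G"})], SMALL, LARGE
    ) == []


def test_low_depth_reference_blocks_site():
    site = _site({"l1": "G", "l2": "G"}, ref_depth=7)
    assert group_differential([site], SMALL, LARGE) == []


def test_low_depth_alt_call_blocks_site():
    site = _site({"l1": "G", "l2": "G"}, depths={"l2": 7})
    assert group_differential([site], SMALL, LARGE) == []


def test_low_alt_fraction_blocks_site():
    site = _site({"l1": "G", "l2": "G"}, afs={"l1": 0.7})
    assert group_differential([site], SMALL, LARGE) == []


def test_two_nonreference_alleles_differentiate():
    (d,) = group_differential(
        [_site({"s1": "T", "s2": "T", "l1": "G", "l2": "G"})], SMALL, LARGE
    )
    assert (d.small_allele, d.large_allele) == ("T", "G")
    assert d.variant_class == SNP  # classed on the large-group allele


def test_shared_alt_not_emitted():
    site = _site({cv: "G" for cv in (*SMALL, *LARGE)})
    assert group_differential([site], SMALL, LARGE) == []


def test_group_label_swap_symmetry():
    rng = np.random.default_rng(0)
    bases = ["A", "C", "G", "T"]
    sites = []
    for i in range(200):
        alleles = {
            cv: bases[rng.integers(0, 4)]
            for cv in (*SMALL, *LARGE)
            if rng.random() < 0.8
        }
        alleles = {cv: a for cv, a in alleles.items() if a != "A"}
        sites.append(_site(alleles, pos=100 * i))
    fwd = group_differential(sites, SMALL, LARGE)
    rev = group_differential(sites, LARGE, SMALL)
    assert {(d.chrom, d.pos) for d in fwd} == {(d.chrom, d.pos) for d in rev}
    fwd_alleles = {(d.chrom, d.pos): (d.small_allele, d.large_allele) for d in fwd}
    for d in rev:
        assert fwd_alleles[(d.chrom, d.pos)] == (d.large_allele, d.small_allele)


def test_group_subset_of_pairwise():
    rng = np.random.default_rng(1)
    bases = ["A", "C", "G", "T"]
    sites = []
    for i in range(300):
        alleles = {
            cv: bases[rng.integers(0, 4)]
            for cv in (*SMALL, *LARGE)
            if rng.random() < 0.9
        }
        alleles = {cv: a for cv, a in alleles.items() if a != "A"}
        sites.append(_site(alleles, pos=100 * i))
    group = {(d.chrom, d.pos) for d in group_differential(sites, SMALL, LARGE)}
    for s in SMALL:
        for l in LARGE:
            pair = {
                (d.chrom, d.pos) for d in pairwise_differential(sites, s, l)
            }
            assert group <= pair


def test_pairwise_rejects_same_cultivar():
    with pytest.raises(ValidationError):
        pairwise_differential([], "s1", "s1")


def test_group_rejects_overlapping_groups():
    with pytest.raises(ValidationError):
        group_differential([], ("a", "b"), ("b", "c"))


def test_collate_sites_rejects_ref_disagreement():
    a = VariantCall("c", 5, "A", "G", "s1", 30, 0.95)
    b = VariantCall("c", 5, "AT", "A", "l1", 30, 0.95)
    with pytest.raises(ValidationError, match="REF"):
        collate_sites({"s1": [a], "l1": [b]}, CoverageTrack(40))


def test_collate_sites_uses_coverage_for_absent_cultivars():
    a = VariantCall("c", 5, "A", "G", "l1", 30, 0.95)
    track = CoverageTrack(40, {("s1", "c", 5): 6})
    (site,) = collate_sites({"s1": [], "l1": [a]}, track)
    assert site.ref_depth == {"s1": 6}
    assert site.allele("s1") is None  # not trusted as reference at depth 6
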