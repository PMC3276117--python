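"""Enumeration of diplotypes consistent with unphased states."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from phasecnv.sites import (
    Diplotype,
    Haplotype,
    InconsistentStatesError,
    SiteSpec,
    SiteType,
    collapse_diplotype,
    enumerate_icn_diplotypes,
    enumerate_snp_diplotypes,
    enumerate_snvc_diplotypes,
    enumerate_unphased_states,
    expand_multisite,
    parse_diplotype,
    parse_haplotype,
    parse_state,
    state_to_str,
)


def names(diplotypes):
    return sorted(str(d) for d in diplotypes)


# ---------------------------------------------------------------- brute force
def brute_icn(total, site):
    out = set()
    if total > site.max_total_copies:
        return out
    for a in range(total + 1):
        b = total - a
        if a <= site.max_allele_copies and b <= site.max_allele_copies:
            out.add(Diplotype(Haplotype((a,)), Haplotype((b,))))
    return out


def brute_snvc(units, site):
    """All ordered assignments of each copy unit to one of two haplotypes,
    deduplicated as unordered pairs."""
    units = list(units)
    out = set()
    if len(units) > site.max_total_copies:
        return out
    for mask in itertools.product((0, 1), repeat=len(units)):
        left = site.sort_units(u for u, side in zip(units, mask) if side == 0)
        right = site.sort_units(u for u, side in zip(units, mask) if side == 1)
        if len(left) <= site.max_allele_copies and len(right) <= site.max_allele_copies:
            out.add(Diplotype(Haplotype((left,)), Haplotype((right,))))
    return out


def brute_multisite(per_site_sets):
    """Ordered haplotype pairs per site, all combinations, global dedup."""
    ordered_per_site = [
        [(d.first.alleles[0], d.second.alleles[0]) for d in s]
        + [(d.second.alleles[0], d.first.alleles[0]) for d in s]
        for s in per_site_sets
    ]
    out = set()
    for combo in itertools.product(*ordered_per_site):
        h1 = Haplotype(tuple(pair[0] for pair in combo))
        h2 = Haplotype(tuple(pair[1] for pair in combo))
        out.add(Diplotype(h1, h2))
    return out


# ------------------------------------------------------------------ ICN sites
def test_icn_total_three_decomposes_two_ways():
    site = SiteSpec("s", SiteType.ICN, (), max_total_copies=6, max_allele_copies=3)
    assert names(enumerate_icn_diplotypes(3, site)) == ["0/3", "1/2"]


def test_icn_total_zero_is_unique(icn_site):
    assert names(enumerate_icn_diplotypes(0, icn_site)) == ["0/0"]


def test_icn_allele_cap_prunes_decompositions(icn_site):
    # total 4 with per-haplotype cap 2 leaves only the balanced split
    assert enumerate_icn_diplotypes(4, icn_site) == brute_icn(4, icn_site) != set()
    assert names(enumerate_icn_diplotypes(4, icn_site)) == ["2/2"]


def test_icn_negative_total_rejected(icn_site):
    with pytest.raises(ValueError):
        enumerate_icn_diplotypes(-1, icn_site)


@given(total=st.integers(0, 12))
def test_icn_count_is_floor_half_plus_one_without_caps(total):
    site = SiteSpec("s", SiteType.ICN, (), max_total_copies=100, max_allele_copies=100)
    assert len(enumerate_icn_diplotypes(total, site)) == total // 2 + 1


@given(total=st.integers(0, 8), allele_cap=st.integers(0, 4), total_cap=st.integers(0, 8))
def test_icn_matches_brute_force(total, allele_cap, total_cap):
    site = SiteSpec("s", SiteType.ICN, (), max_total_copies=total_cap, max_allele_copies=allele_cap)
    assert enumerate_icn_diplotypes(total, site) == brute_icn(total, site)


# ----------------------------------------------------------------- SNVC sites
def test_snvc_aag_has_three_bipartitions():
    site = SiteSpec("s", SiteType.SNVC, ("A", "G"), max_total_copies=4, max_allele_copies=3)
    got = names(enumerate_snvc_diplotypes(("A", "A", "G"), site))
    assert got == ["-/A,A,G", "A,A/G", "A/A,G"]


def test_snvc_deletion_only_splits_into_deletions(snvc_site):
    assert names(enumerate_snvc_diplotypes((), snvc_site)) == ["-/-"]


def test_snvc_two_distinct_units(snvc_site):
    assert names(enumerate_snvc_diplotypes(("A", "B"), snvc_site)) == ["-/A,B", "A/B"]


def test_snvc_symbol_outside_alphabet_rejected(snvc_site):
    with pytest.raises(ValueError):
        enumerate_snvc_diplotypes(("A", "Z"), snvc_site)


@given(
    counts=st.tuples(st.integers(0, 4), st.integers(0, 4)).filter(lambda c: sum(c) <= 4),
    allele_cap=st.integers(0, 4),
)
def test_snvc_matches_brute_force_bipartitions(counts, allele_cap):
    site = SiteSpec("s", SiteType.SNVC, ("A", "B"), max_total_copies=4, max_allele_copies=allele_cap)
    units = ("A",) * counts[0] + ("B",) * counts[1]
    assert enumerate_snvc_diplotypes(units, site) == brute_snvc(units, site)


# ------------------------------------------------------------------ SNP sites
def test_snp_heterozygote_and_homozygote(snp_site):
    assert names(enumerate_snp_diplotypes(("a", "t"), snp_site)) == ["a/t"]
    assert names(enumerate_snp_diplotypes(("a", "a"), snp_site)) == ["a/a"]


def test_snp_pair_is_unordered():
    site = SiteSpec("s", SiteType.SNP, ("c", "g"), 2, 1)
    assert names(enumerate_snp_diplotypes(("g", "c"), site)) == ["c/g"]


# ------------------------------------------------------------------ multisite
def test_multisite_icn_snp_example(snp_site):
    icn = SiteSpec("s", SiteType.ICN, (), max_total_copies=6, max_allele_copies=3)
    per_site = [enumerate_icn_diplotypes(3, icn), enumerate_snp_diplotypes(("a", "t"), snp_site)]
    got = names(expand_multisite(per_site))
    assert got == ["0_a/3_t", "0_t/3_a", "1_a/2_t", "1_t/2_a"]


def test_multisite_homozygous_sites_have_no_phase_ambiguity(icn_site, snp_site):
    per_site = [
        enumerate_icn_diplotypes(2, SiteSpec("s", SiteType.ICN, (), 4, 1)),
        enumerate_snp_diplotypes(("a", "a"), snp_site),
    ]
    assert names(expand_multisite(per_site)) == ["1_a/1_a"]


def test_multisite_third_homozygous_site_does_not_multiply(snp_site):
    icn = SiteSpec("s", SiteType.ICN, (), max_total_copies=6, max_allele_copies=3)
    snp2 = SiteSpec("s2", SiteType.SNP, ("c", "g"), 2, 1)
    per_site = [
        enumerate_icn_diplotypes(3, icn),
        enumerate_snp_diplotypes(("a", "t"), snp_site),
        enumerate_snp_diplotypes(("c", "c"), snp2),
    ]
    result = expand_multisite(per_site)
    assert len(result) == 4
    assert result == brute_multisite(per_site)


def test_multisite_empty_site_set_signals_inconsistency(icn_site):
    with pytest.raises(InconsistentStatesError):
        expand_multisite([enumerate_icn_diplotypes(1, icn_site), set()])


@given(
    totals=st.lists(st.integers(0, 4), min_size=1, max_size=3),
    snvc_size=st.integers(0, 3),
)
def test_multisite_matches_brute_force(totals, snvc_size):
    snvc = SiteSpec("snvc", SiteType.SNVC, ("A", "B"), 4, 2)
    sites = [SiteSpec(f"i{k}", SiteType.ICN, (), 4, 2) for k in range(len(totals))]
    per_site = [enumerate_icn_diplotypes(t, s) for t, s in zip(totals, sites)]
    per_site.append(enumerate_snvc_diplotypes(("A",) * snvc_size, snvc))
    if any(not s for s in per_site):
        return
    assert expand_multisite(per_site) == brute_multisite(per_site)


@given(total=st.integers(0, 4), counts=st.tuples(st.integers(0, 2), st.integers(0, 2)))
def test_round_trip_collapse_reproduces_states(total, counts):
    icn = SiteSpec("icn", SiteType.ICN, (), 4, 2)
    snvc = SiteSpec("snvc", SiteType.SNVC, ("A", "B"), 4, 2)
    units = ("A",) * counts[0] + ("B",) * counts[1]
    per_site = [
        enumerate_icn_diplotypes(total, icn),
        enumerate_snvc_diplotypes(units, snvc),
    ]
    if any(not s for s in per_site):
        return
    for d in expand_multisite(per_site):
        assert collapse_diplotype(d, [icn, snvc]) == (total, units)


# -------------------------------------------------------------- serialization
def test_diplotype_is_unordered_and_canonical(icn_site, snp_site):
    h1 = parse_haplotype("1_a", [icn_site, snp_site])
    h2 = parse_haplotype("0_t", [icn_site, snp_site])
    assert Diplotype(h1, h2) == Diplotype(h2, h1)
    assert str(Diplotype(h1, h2)) == "0_t/1_a"


def test_haplotype_equality_is_canonical_string_equality(snvc_site):
    assert Haplotype((("A", "B"),)) == parse_haplotype("A,B", [snvc_site])
    assert str(Haplotype(((),))) == "-"


def test_parse_round_trips(icn_site, snvc_site, snp_site):
    sites = [icn_site, snvc_site, snp_site]
    for text in ["0_A,B_a/2_-_t", "1_A_a/1_A_a"]:
        assert str(parse_diplotype(text, sites)) == text


def test_state_round_trips(icn_site, snvc_site, snp_site):
    for site in (icn_site, snvc_site, snp_site):
        for state in enumerate_unphased_states(site):
            assert parse_state(state_to_str(state, site), site) == state


def test_enumerate_unphased_states_counts(icn_site, snvc_site, snp_site):
    assert enumerate_unphased_states(icn_site) == [0, 1, 2, 3, 4]
    # multisets of {A,B} of size 0..4: 1+2+3+4+5
    assert len(enumerate_unphased_states(snvc_site)) == 15
    assert len(enumerate_unphased_states(snp_site)) == 3
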