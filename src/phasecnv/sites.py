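"""Haplotype, diplotype and unphased-state representations for CNV loci.

A copy-number-variable locus is modelled as an ordered list of abstract
sites, each of one of three kinds:

* ``ICN`` (integer copy number) — a haplotype carries an integer number of
  copies of the CNV segment at the site.
* ``SNVC`` (single-nucleotide variation in a CNV) — a haplotype carries an
  unordered multiset of copy units, each labelled by its base at the variant
  position; the empty multiset is a deletion, written ``-``.
* ``SNP`` — a haplotype carries exactly one base.

High-throughput platforms do not observe haplotypes.  They observe only an
unphased per-site summary over the two haplotypes of an individual: the
total copy number at an ICN site, the pooled base multiset at an SNVC site,
or the unordered two-base genotype at a SNP site.  This module defines the
canonical text forms of these objects and enumerates every diplotype
(unordered haplotype pair) consistent with observed unphased states, per
site and jointly across sites.

Serialization conventions
-------------------------
``-`` renders a deletion, ``,`` separates copy units within a haplotype
allele, ``_`` separates sites within a haplotype, and ``/`` separates the
two haplotypes of a diplotype.  Copy units are kept sorted in alphabet
order and the two haplotypes of a diplotype are kept sorted
lexicographically, so equal objects always render identically.
"""

from __future__ import annotations

import enum
import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple, Union

__all__ = [
    "SiteType",
    "SiteSpec",
    "Allele",
    "State",
    "Haplotype",
    "Diplotype",
    "InconsistentStatesError",
    "allele_to_str",
    "parse_allele",
    "state_to_str",
    "parse_state",
    "enumerate_unphased_states",
    "enumerate_icn_diplotypes",
    "enumerate_snvc_diplotypes",
    "enumerate_snp_diplotypes",
    "expand_multisite",
    "diplotype_site_state",
    "collapse_diplotype",
    "parse_haplotype",
    "parse_diplotype",
]


class SiteType(str, enum.Enum):
    """Kind of variation measured at a site."""

    ICN = "ICN"
    SNVC = "SNVC"
    SNP = "SNP"


#: Per-site allele carried by one haplotype.  An ``int`` is an allelic copy
#: count (ICN site), a tuple of base symbols is a sorted multiset of copy
#: units (SNVC site; the empty tuple is a deletion), and a ``str`` is a
#: single base (SNP site).
Allele = Union[int, Tuple[str, ...], str]

#: Unphased per-site state observed over a diplotype.  An ``int`` is a total
#: copy number (ICN), a tuple of base symbols is the pooled base multiset
#: (SNVC) or the unordered two-base genotype (SNP).
State = Union[int, Tuple[str, ...]]


class InconsistentStatesError(ValueError):
    """Raised when no diplotype is consistent with the observed states."""


@dataclass(frozen=True)
class SiteSpec:
    """Description of one site.

    Parameters
    ----------
    site_id
        Opaque identifier, unique within a locus.
    site_type
        One of :class:`SiteType`.
    alphabet
        Ordered base symbols; required for SNVC and SNP sites, empty for
        ICN sites.  Symbols must be single characters so that pooled
        genotypes can be rendered without separators (e.g. ``AAG``).
    max_total_copies
        Cap on the summed copy number over a diplotype.
    max_allele_copies
        Cap on the copy number carried by a single haplotype.
    """

    site_id: str
    site_type: SiteType
    alphabet: Tuple[str, ...] = ()
    max_total_copies: int = 4
    max_allele_copies: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "site_type", SiteType(self.site_type))
        object.__setattr__(self, "alphabet", tuple(self.alphabet))
        if self.site_type in (SiteType.SNVC, SiteType.SNP) and not self.alphabet:
            raise ValueError(f"site {self.site_id!r}: {self.site_type.value} sites need an alphabet")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError(f"site {self.site_id!r}: duplicate alphabet symbols")
        for sym in self.alphabet:
            if len(sym) != 1 or sym in "_,/-":
                raise ValueError(f"site {self.site_id!r}: bad alphabet symbol {sym!r}")
        if self.max_total_copies < 0 or self.max_allele_copies < 0:
            raise ValueError(f"site {self.site_id!r}: copy caps must be non-negative")

    def sort_units(self, units: Iterable[str]) -> Tuple[str, ...]:
        """Return *units* as a tuple sorted in alphabet order."""
        order = {sym: i for i, sym in enumerate(self.alphabet)}
        try:
            return tuple(sorted(units, key=order.__getitem__))
        except KeyError as exc:
            raise ValueError(f"site {self.site_id!r}: symbol {exc.args[0]!r} not in alphabet") from None


def allele_to_str(allele: Allele) -> str:
    """Canonical text form of a per-site haplotype allele."""
    if isinstance(allele, bool):
        raise TypeError("allele may not be a bool")
    if isinstance(allele, int):
        return str(allele)
    if isinstance(allele, str):
        return allele
    return "-" if not allele else ",".join(allele)


def parse_allele(text: str, site: SiteSpec) -> Allele:
    """Parse the canonical text form of an allele at *site*."""
    if site.site_type is SiteType.ICN:
        count = int(text)
        if count < 0:
            raise ValueError(f"site {site.site_id!r}: negative copy count {count}")
        return count
    if site.site_type is SiteType.SNP:
        if text not in site.alphabet:
            raise ValueError(f"site {site.site_id!r}: base {text!r} not in alphabet")
        return text
    if text == "-":
        return ()
    return site.sort_units(text.split(","))


@dataclass(frozen=True)
class Haplotype:
    """A vector of per-site alleles in a fixed site order.

    Two haplotypes are equal iff their canonical strings are equal; alleles
    are expected to be canonical (SNVC multisets sorted) on construction,
    which the enumeration and parsing helpers in this module guarantee.
    """

    alleles: Tuple[Allele, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(self.alleles))

    def __str__(self) -> str:
        return "_".join(allele_to_str(a) for a in self.alleles)

    def __lt__(self, other: "Haplotype") -> bool:
        return str(self) < str(other)

    def __len__(self) -> int:
        return len(self.alleles)


@dataclass(frozen=True)
class Diplotype:
    """An unordered pair of haplotypes.

    The pair is stored sorted lexicographically by canonical string, so
    ``Diplotype(h1, h2) == Diplotype(h2, h1)`` and the rendered form
    ``h1/h2`` is canonical.
    """

    first: Haplotype
    second: Haplotype

    def __post_init__(self) -> None:
        if str(self.second) < str(self.first):
            first, second = self.second, self.first
            object.__setattr__(self, "first", first)
            object.__setattr__(self, "second", second)

    @property
    def pair(self) -> Tuple[Haplotype, Haplotype]:
        return (self.first, self.second)

    @property
    def is_homozygous(self) -> bool:
        return self.first == self.second

    def __str__(self) -> str:
        return f"{self.first}/{self.second}"

    def __lt__(self, other: "Diplotype") -> bool:
        return str(self) < str(other)


def state_to_str(state: State, site: SiteSpec) -> str:
    """Canonical text form of an unphased state at *site*."""
    if site.site_type is SiteType.ICN:
        return str(state)
    return "-" if not state else "".join(state)


def parse_state(text: str, site: SiteSpec) -> State:
    """Parse the canonical text form of an unphased state at *site*."""
    if site.site_type is SiteType.ICN:
        total = int(text)
        if total < 0:
            raise ValueError(f"site {site.site_id!r}: negative total copy number {total}")
        return total
    if site.site_type is SiteType.SNP:
        if len(text) != 2:
            raise ValueError(f"site {site.site_id!r}: SNP genotype must have two bases, got {text!r}")
        return site.sort_units(text)
    if text == "-":
        return ()
    return site.sort_units(text)


def enumerate_unphased_states(site: SiteSpec) -> list:
    """All unphased states allowed by the caps of *site*, in canonical order.

    ICN sites yield every total copy number up to ``max_total_copies``;
    SNVC sites yield every base multiset of size up to ``max_total_copies``;
    SNP sites yield every unordered two-base genotype.
    """
    if site.site_type is SiteType.ICN:
        return list(range(site.max_total_copies + 1))
    if site.site_type is SiteType.SNP:
        return [tuple(g) for g in itertools.combinations_with_replacement(site.alphabet, 2)]
    states: list = []
    for size in range(site.max_total_copies + 1):
        states.extend(tuple(m) for m in itertools.combinations_with_replacement(site.alphabet, size))
    return states


def _one_site(site_allele_a: Allele, site_allele_b: Allele) -> Diplotype:
    return Diplotype(Haplotype((site_allele_a,)), Haplotype((site_allele_b,)))


def enumerate_icn_diplotypes(total_copies: int, site: SiteSpec) -> set:
    """One-site diplotypes consistent with a total copy number.

    Returns every unordered pair of allelic copy counts ``(a, b)`` with
    ``a + b == total_copies`` and both counts within ``max_allele_copies``.
    A total of 3 yields ``[0/3]`` and ``[1/2]`` (caps permitting).  The set
    is empty when the caps admit no decomposition.
    """
    if total_copies < 0:
        raise ValueError(f"negative total copy number {total_copies}")
    out: set = set()
    if total_copies > site.max_total_copies:
        return out
    for a in range(total_copies // 2 + 1):
        b = total_copies - a
        if a <= site.max_allele_copies and b <= site.max_allele_copies:
            out.add(_one_site(a, b))
    return out


def enumerate_snvc_diplotypes(state: Tuple[str, ...], site: SiteSpec) -> set:
    """One-site diplotypes consistent with a pooled base multiset.

    Returns every unordered bipartition of the multiset into two haplotype
    multisets whose sizes respect ``max_allele_copies``; copy-unit order
    within a haplotype is not distinguished.  ``AAG`` yields ``[-/A,A,G]``,
    ``[A,A/G]`` and ``[A/A,G]`` (caps permitting).
    """
    units = site.sort_units(state)
    out: set = set()
    if len(units) > site.max_total_copies:
        return out
    counts = Counter(units)
    symbols = [s for s in site.alphabet if counts[s]]
    for take in itertools.product(*(range(counts[s] + 1) for s in symbols)):
        part_a = site.sort_units(
            itertools.chain.from_iterable([s] * k for s, k in zip(symbols, take))
        )
        part_b_counts = counts - Counter(part_a)
        part_b = site.sort_units(part_b_counts.elements())
        if len(part_a) <= site.max_allele_copies and len(part_b) <= site.max_allele_copies:
            out.add(_one_site(part_a, part_b))
    return out


def enumerate_snp_diplotypes(state: Tuple[str, str], site: SiteSpec) -> set:
    """The single one-site diplotype consistent with an unordered genotype."""
    if len(state) != 2:
        raise ValueError(f"SNP genotype must have two bases, got {state!r}")
    a, b = site.sort_units(state)
    return {_one_site(a, b)}


def enumerate_site_diplotypes(state: State, site: SiteSpec) -> set:
    """Dispatch on ``site.site_type`` to the matching enumeration."""
    if site.site_type is SiteType.ICN:
        return enumerate_icn_diplotypes(state, site)
    if site.site_type is SiteType.SNVC:
        return enumerate_snvc_diplotypes(state, site)
    return enumerate_snp_diplotypes(state, site)


def expand_multisite(per_site_sets: Sequence[Iterable[Diplotype]]) -> set:
    """Combine one-site diplotypes into multi-site diplotypes.

    For every choice of one one-site diplotype per site and every assignment
    of its two one-site haplotypes to the two chromosome slots, the
    multi-site pair is formed; results are deduplicated as unordered pairs.
    With one-site sets ``{[0/3], [1/2]}`` and ``{[a/t]}`` this yields
    ``[0_a/3_t]``, ``[0_t/3_a]``, ``[1_a/2_t]`` and ``[1_t/2_a]``.

    Raises
    ------
    InconsistentStatesError
        If any per-site set is empty (the individual has no consistent
        diplotype).
    """
    site_lists = [sorted(s) for s in per_site_sets]
    if not site_lists:
        raise ValueError("at least one site is required")
    for i, lst in enumerate(site_lists):
        if not lst:
            raise InconsistentStatesError(f"no consistent one-site diplotype at site index {i}")
    out: set = set()
    for combo in itertools.product(*site_lists):
        # Orientation only matters at heterozygous sites.
        het = [i for i, d in enumerate(combo) if not d.is_homozygous]
        for bits in itertools.product((0, 1), repeat=len(het)):
            orient = [0] * len(combo)
            for i, b in zip(het, bits):
                orient[i] = b
            left = tuple(d.pair[o].alleles[0] for d, o in zip(combo, orient))
            right = tuple(d.pair[1 - o].alleles[0] for d, o in zip(combo, orient))
            out.add(Diplotype(Haplotype(left), Haplotype(right)))
    return out


def diplotype_site_state(diplotype: Diplotype, site_index: int, site: SiteSpec) -> State:
    """Collapse one site of a diplotype to its unphased state."""
    a = diplotype.first.alleles[site_index]
    b = diplotype.second.alleles[site_index]
    if site.site_type is SiteType.ICN:
        return a + b
    if site.site_type is SiteType.SNP:
        return site.sort_units((a, b))
    return site.sort_units(a + b)


def collapse_diplotype(diplotype: Diplotype, sites: Sequence[SiteSpec]) -> Tuple[State, ...]:
    """Collapse a multi-site diplotype to its per-site unphased states."""
    if len(diplotype.first) != len(sites):
        raise ValueError("diplotype and site list have different lengths")
    return tuple(diplotype_site_state(diplotype, i, s) for i, s in enumerate(sites))


def parse_haplotype(text: str, sites: Sequence[SiteSpec]) -> Haplotype:
    """Parse a canonical haplotype string such as ``1_a`` or ``A,A_B``."""
    parts = text.split("_")
    if len(parts) != len(sites):
        raise ValueError(f"haplotype {text!r} has {len(parts)} sites, expected {len(sites)}")
    return Haplotype(tuple(parse_allele(p, s) for p, s in zip(parts, sites)))


def parse_diplotype(text: str, sites: Sequence[SiteSpec]) -> Diplotype:
    """Parse a canonical diplotype string such as ``0_a/3_t``."""
    parts = text.split("/")
    if len(parts) != 2:
        raise ValueError(f"diplotype {text!r} must contain exactly one '/'")
    return Diplotype(parse_haplotype(parts[0], sites), parse_haplotype(parts[1], sites))
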