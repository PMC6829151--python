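"""Mutation-spectrum classification.

Single base substitutions are collapsed over strands into six classes
(AT>GC, GC>AT, AT>CG, AT>TA, GC>TA, GC>CG), of which the first two are
transitions; indels are described by their signed size (+ insertion,
- deletion) with a small/large partition at 100 bp; and structural
variants (SVs) are typed from their breakpoints.  Breakpoint events
that cluster in one genomic region — the footprint of several
double-strand breaks from a single particle traversal — are merged
into one complex SV call, and every call, simple or complex, counts as
a single SV.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "SBS_CATEGORIES",
    "SBSClass",
    "IndelClass",
    "IndelSpectrum",
    "SVEvent",
    "SVCall",
    "classify_sbs",
    "tstv_ratio",
    "classify_indel",
    "bin_indel_spectrum",
    "cluster_sv_events",
    "SMALL_INDEL_MAX",
]

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: Strand-collapsed substitution classes; the first two are transitions.
SBS_CATEGORIES = ("AT>GC", "GC>AT", "AT>CG", "AT>TA", "GC>TA", "GC>CG")
_TRANSITION_CATEGORIES = frozenset({"AT>GC", "GC>AT"})

#: Indels of |size| below this many bases are "small"; at or above, SV territory.
SMALL_INDEL_MAX = 100

SV_TYPES = (
    "large_deletion",
    "large_insertion",
    "duplication",
    "inversion",
    "translocation_junction",
)


@dataclass(frozen=True)
class SBSClass:
    category: str
    is_transition: bool

    def __post_init__(self) -> None:
        if self.category not in SBS_CATEGORIES:
            raise ValueError(f"unknown SBS category {self.category!r}")
        if self.is_transition != (self.category in _TRANSITION_CATEGORIES):
            raise ValueError("transition flag inconsistent with category")


def classify_sbs(ref_base: str, alt_base: str) -> SBSClass:
    """Strand-collapsed class of a single base substitution.

    G>A and C>T both map to GC>AT, etc.  Transitions keep the purine/
    pyrimidine character (AT>GC, GC>AT); the other four classes are
    transversions.
    """
    ref, alt = ref_base.upper(), alt_base.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"not a single-base substitution: {ref_base!r}>{alt_base!r}")
    if ref == alt:
        raise ValueError("ref and alt bases are identical")
    # orient so that the reference base is A or G
    if ref in "CT":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    category = f"{ref}{_COMPLEMENT[ref]}>{alt}{_COMPLEMENT[alt]}"
    return SBSClass(category, category in _TRANSITION_CATEGORIES)


def tstv_ratio(substitutions: Iterable[SBSClass]) -> float:
    """Transition/transversion ratio of a set of substitutions."""
    ts = tv = 0
    for s in substitutions:
        if s.is_transition:
            ts += 1
        else:
            tv += 1
    if tv == 0:
        raise ValueError("Ts/Tv undefined with zero transversions")
    return ts / tv


@dataclass(frozen=True)
class IndelClass:
    """Signed indel size: positive for insertions, negative for deletions."""

    signed_size: int
    is_small: bool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.signed_size == 0:
            raise ValueError("indel size cannot be zero")
        small = abs(self.signed_size) < SMALL_INDEL_MAX
        if self.is_small is None:
            object.__setattr__(self, "is_small", small)
        elif self.is_small != small:
            raise ValueError("is_small inconsistent with |signed_size|")


def classify_indel(ref_allele: str, alt_allele: str) -> IndelClass:
    """Signed size of a VCF-anchored indel: len(alt) - len(ref)."""
    if len(ref_allele) == len(alt_allele):
        raise ValueError("equal-length alleles are not an indel")
    return IndelClass(len(alt_allele) - len(ref_allele))


@dataclass(frozen=True)
class IndelSpectrum:
    """Per-size indel histogram with the +1..-4 bp aggregate band."""

    counts: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def plus1_minus4_fraction(self) -> float:
        """Fraction of indels in the common +1 bp to -4 bp band."""
        if self.total == 0:
            return float("nan")
        band = sum(n for size, n in self.counts.items() if -4 <= size <= 1)
        return band / self.total

    def proportions(self) -> dict[int, float]:
        t = self.total
        return {size: n / t for size, n in sorted(self.counts.items())}


def bin_indel_spectrum(indels: Iterable[IndelClass]) -> IndelSpectrum:
    """Exact per-size histogram of small indels.

    Large indels (|size| >= 100 bp) belong in the SV accounting and
    are rejected here.
    """
    counts: Counter[int] = Counter()
    for ind in indels:
        if not ind.is_small:
            raise ValueError(
                f"indel of size {ind.signed_size} is not small; route to SV accounting"
            )
        counts[ind.signed_size] += 1
    return IndelSpectrum(dict(counts))


@dataclass(frozen=True)
class SVEvent:
    """One breakpoint-level structural-variant event.

    Deletions, insertions, duplications and inversions carry two
    breakpoints on a single chromosome; a translocation junction spans
    two chromosomes.  A reciprocal translocation is represented by its
    two junction records.
    """

    event_type: str
    breakpoints: tuple[tuple[str, int], ...]
    size: int | None = None

    def __post_init__(self) -> None:
        if self.event_type not in SV_TYPES:
            raise ValueError(f"unknown SV event type {self.event_type!r}")
        chroms = {c for c, _ in self.breakpoints}
        if self.event_type == "translocation_junction":
            if len(self.breakpoints) != 2 or len(chroms) != 2:
                raise ValueError("translocation junction must span two chromosomes")
        else:
            if len(self.breakpoints) != 2 or len(chroms) != 1:
                raise ValueError(
                    f"{self.event_type} must have two breakpoints on one chromosome"
                )


@dataclass(frozen=True)
class SVCall:
    """A counted structural variant: one or more clustered events.

    However many double-strand-break-derived sub-events a call
    comprises, it is counted as one SV (``counted_as`` is always 1).
    """

    line_id: str
    events: tuple[SVEvent, ...]
    sv_class: str

    counted_as: int = 1

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("an SV call needs at least one event")
        if self.counted_as != 1:
            raise ValueError("every SV call is counted exactly once")

    @property
    def is_complex(self) -> bool:
        return self.sv_class == "complex"


def _call_class(events: Sequence[SVEvent]) -> str:
    types = [e.event_type for e in events]
    if all(t == "translocation_junction" for t in types):
        # the two junction records of one reciprocal exchange (or a lone
        # junction whose partner went unconfirmed) form one translocation
        return "reciprocal_translocation"
    if len(events) == 1:
        return types[0]
    return "complex"


def cluster_sv_events(
    events: Iterable[SVEvent],
    line_id: str = "",
    proximity_window: int = 1_000_000,
) -> list[SVCall]:
    """Merge breakpoint events into counted SV calls.

    Two events are linked when any pair of their breakpoints lies on
    the same chromosome within ``proximity_window`` bases — clustered
    breakpoints are taken to descend from double-strand breaks of one
    particle traversal.  Linked groups of two or more non-translocation
    events become one ``complex`` call; the two junction records of a
    reciprocal translocation merge into one ``reciprocal_translocation``
    call; everything else keeps its simple type.  The total SV count of
    a line is simply ``len(cluster_sv_events(...))``.
    """
    events = list(events)
    n = len(events)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            linked = any(
                ci == cj and abs(pi - pj) <= proximity_window
                for ci, pi in events[i].breakpoints
                for cj, pj in events[j].breakpoints
            )
            if linked:
                union(i, j)

    groups: dict[int, list[SVEvent]] = {}
    for i, ev in enumerate(events):
        groups.setdefault(find(i), []).append(ev)

    calls = [
        SVCall(line_id=line_id, events=tuple(grp), sv_class=_call_class(grp))
        for _, grp in sorted(groups.items())
    ]
    return calls
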