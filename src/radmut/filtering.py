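"""Candidate-mutation extraction and VAF-based zygosity calling.

Induced mutations in selfed mutant lines are expected to be unique to a
single line, well covered, and supported by a substantial fraction of
reads.  The filter applies, in a fixed order, a read-depth window, a
read-support fraction, a cross-line uniqueness test (anything seen in
two or more lines is treated as shared background between the cultivar
and the reference assembly), and finally a variant-allele-frequency
(VAF) confidence gate below which calls are overwhelmingly sequencing
artifacts.  Passing calls are assigned a zygosity from their VAF.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CandidateVariant",
    "FilterThresholds",
    "FilteredVariant",
    "TruthEvaluation",
    "DuplicateVariantError",
    "compute_vaf",
    "apply_candidate_filters",
    "call_zygosity",
    "evaluate_against_truth",
    "DISPOSITIONS",
]

#: Dispositions in the order the criteria are applied.
DISPOSITIONS = ("pass", "fail_depth", "fail_support", "fail_shared", "fail_low_vaf")


class DuplicateVariantError(ValueError):
    """Raised when the same (line, locus, alt) record appears twice."""


@dataclass(frozen=True)
class CandidateVariant:
    """One putative mutation call in one mutant line, with read evidence.

    Coordinates are 1-based and alleles use the anchored VCF
    representation (indels share a leading anchor base).
    """

    line_id: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    depth: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError(
                f"alt_count {self.alt_count} outside [0, depth={self.depth}]"
            )

    @property
    def variant_kind(self) -> str:
        """'SBS', 'insertion' or 'deletion', from allele lengths."""
        if len(self.alt_allele) > len(self.ref_allele):
            return "insertion"
        if len(self.alt_allele) < len(self.ref_allele):
            return "deletion"
        return "SBS"

    @property
    def key(self) -> tuple:
        """Cross-line identity key: exact locus and allele match."""
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds of the candidate-extraction criteria.

    The depth window is exclusive on both sides ("more than five and
    less than 100" reads): eligible depth is 6..99.  Support of at
    least ``min_support_fraction`` of reads is required, and passing
    calls additionally need VAF >= ``min_confident_vaf`` (below 40%
    VAF the large majority of calls fail independent Sanger
    validation).  VAF strictly above ``min_homozygous_vaf_exclusive``
    is called homozygous, the closed band [min_confident_vaf,
    min_homozygous_vaf_exclusive] heterozygous.
    """

    min_depth_exclusive: int = 5
    max_depth_exclusive: int = 100
    min_support_fraction: float = 0.30
    min_confident_vaf: float = 0.40
    min_homozygous_vaf_exclusive: float = 0.75

    def __post_init__(self) -> None:
        if not (
            0
            < self.min_support_fraction
            <= self.min_confident_vaf
            <= self.min_homozygous_vaf_exclusive
            < 1
        ):
            raise ValueError(
                "require 0 < support <= confident VAF <= homozygous VAF < 1"
            )
        if self.min_depth_exclusive >= self.max_depth_exclusive:
            raise ValueError("depth window is empty")


@dataclass(frozen=True)
class FilteredVariant:
    """A candidate with its filter disposition and, if passing, zygosity."""

    variant: CandidateVariant
    disposition: str
    vaf: float
    zygosity: str = "not_applicable"

    def __post_init__(self) -> None:
        if self.disposition not in DISPOSITIONS:
            raise ValueError(f"unknown disposition {self.disposition!r}")
        if (self.disposition == "pass") != (self.zygosity != "not_applicable"):
            raise ValueError("zygosity is assigned iff the variant passes")


def compute_vaf(v: CandidateVariant) -> float:
    """Variant allele frequency: fraction of reads supporting the alt allele."""
    if v.depth <= 0:
        raise ValueError("VAF undefined at zero depth")
    return v.alt_count / v.depth


def call_zygosity(vaf: float, thresholds: FilterThresholds | None = None) -> str:
    """Call zygosity from VAF for a confidently detected mutation.

    VAF strictly above the homozygous threshold (default 0.75) is
    homozygous; VAF in the closed band down to the confidence
    threshold (default 0.40) is heterozygous.
    """
    thresholds = thresholds or FilterThresholds()
    if vaf < thresholds.min_confident_vaf:
        raise ValueError(
            f"VAF {vaf:.3f} below confidence threshold "
            f"{thresholds.min_confident_vaf}; zygosity is not called"
        )
    if vaf > thresholds.min_homozygous_vaf_exclusive:
        return "homozygous"
    return "heterozygous"


def apply_candidate_filters(
    records: Iterable[CandidateVariant],
    thresholds: FilterThresholds | None = None,
) -> list[FilteredVariant]:
    """Apply the candidate-extraction criteria across all lines.

    Criteria are checked in a fixed order — depth window, read-support
    fraction, cross-line uniqueness, VAF confidence — and the
    disposition records the first criterion failed, so every input
    record appears exactly once in the output with one deterministic
    reason.  The uniqueness criterion requires the full multi-line
    collection: a variant with an exact (chromosome, position, ref,
    alt) match in two or more lines is shared background, and all its
    records fail.
    """
    thresholds = thresholds or FilterThresholds()
    records = list(records)

    seen: set[tuple] = set()
    lines_by_key: dict[tuple, set[str]] = defaultdict(set)
    for v in records:
        dup_key = (v.line_id, v.chromosome, v.position, v.alt_allele)
        if dup_key in seen:
            raise DuplicateVariantError(
                f"duplicate record for line {v.line_id} at "
                f"{v.chromosome}:{v.position} {v.ref_allele}>{v.alt_allele}"
            )
        seen.add(dup_key)
        lines_by_key[v.key].add(v.line_id)

    out: list[FilteredVariant] = []
    for v in records:
        if not (thresholds.min_depth_exclusive < v.depth < thresholds.max_depth_exclusive):
            # VAF undefined at depth 0; report it as 0 for failed-depth records
            vaf = v.alt_count / v.depth if v.depth > 0 else 0.0
            out.append(FilteredVariant(v, "fail_depth", vaf))
            continue
        vaf = compute_vaf(v)
        if vaf < thresholds.min_support_fraction:
            out.append(FilteredVariant(v, "fail_support", vaf))
        elif len(lines_by_key[v.key]) > 1:
            out.append(FilteredVariant(v, "fail_shared", vaf))
        elif vaf < thresholds.min_confident_vaf:
            out.append(FilteredVariant(v, "fail_low_vaf", vaf))
        else:
            out.append(FilteredVariant(v, "pass", vaf, call_zygosity(vaf, thresholds)))
    return out


@dataclass
class TruthEvaluation:
    """Confusion summary of filter dispositions against simulator truth.

    ``table`` has one row per record origin ('true', 'background',
    'artifact') and one column per disposition; cell counts sum to the
    number of evaluated records.
    """

    table: pd.DataFrame

    @property
    def n_records(self) -> int:
        return int(self.table.to_numpy().sum())

    def kept(self, origin: str) -> int:
        return int(self.table.loc[origin, "pass"]) if origin in self.table.index else 0

    def rejected(self, origin: str) -> int:
        if origin not in self.table.index:
            return 0
        fails = [c for c in self.table.columns if c != "pass"]
        return int(self.table.loc[origin, fails].sum())

    @property
    def recall(self) -> float:
        """Fraction of emitted true mutations that pass the filter."""
        n_true = self.kept("true") + self.rejected("true")
        return self.kept("true") / n_true if n_true else float("nan")

    @property
    def precision(self) -> float:
        """Fraction of passing records that are true mutations."""
        n_pass = int(self.table["pass"].sum())
        return self.kept("true") / n_pass if n_pass else float("nan")


def evaluate_against_truth(
    filtered: Sequence[FilteredVariant],
    truth_table: pd.DataFrame,
) -> TruthEvaluation:
    """Tally filter dispositions by record origin using the simulator truth table.

    ``truth_table`` must pair every filtered record (keyed by line_id,
    chromosome, position, ref_allele, alt_allele) with an ``origin``
    column; a record without a truth entry is an error.
    """
    origin_by_key: dict[tuple, str] = {}
    for row in truth_table.itertuples(index=False):
        key = (row.line_id, row.chromosome, int(row.position), row.ref_allele, row.alt_allele)
        origin_by_key[key] = row.origin

    counts: Counter[tuple[str, str]] = Counter()
    for fv in filtered:
        v = fv.variant
        key = (v.line_id, v.chromosome, v.position, v.ref_allele, v.alt_allele)
        if key not in origin_by_key:
            raise ValueError(f"record {key} has no truth-table entry")
        counts[(origin_by_key[key], fv.disposition)] += 1

    origins = sorted({o for o, _ in counts})
    table = pd.DataFrame(
        [[counts.get((o, d), 0) for d in DISPOSITIONS] for o in origins],
        index=pd.Index(origins, name="origin"),
        columns=list(DISPOSITIONS),
    )
    return TruthEvaluation(table)
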