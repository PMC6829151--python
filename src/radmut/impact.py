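"""Minimal gene-effect annotation.

Implements only the impact rules relevant to radiation-mutagenesis
tallies: any mutation inside a transcript (5'UTR through 3'UTR)
"affects" the gene; nonsense, splice-site loss, frameshift and
SV-driven gene truncation are high impact; missense and inframe indels
are moderate.  Everything else within a transcript is low/other and
intergenic variants have no impact.  No attempt is made at general
effect prediction (no regulatory features, no transcript selection, no
HGVS).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .filtering import CandidateVariant
from .spectra import SVCall, SVEvent

__all__ = [
    "GeneModel",
    "EffectCall",
    "IMPACT_BY_EFFECT",
    "annotate_variant",
    "annotate_sv_call",
    "genes_affected_per_line",
]

#: Impact tier of each effect class.  High and moderate follow the
#: named rules; synonymous/UTR/intron/whole-gene duplication are scored
#: low_or_other; intergenic variants have no impact.
IMPACT_BY_EFFECT = {
    "nonsense": "high",
    "splice_site_loss": "high",
    "frameshift": "high",
    "gene_truncation": "high",
    "missense": "moderate",
    "inframe_indel": "moderate",
    "synonymous": "low_or_other",
    "utr": "low_or_other",
    "intron": "low_or_other",
    "whole_gene_duplication": "low_or_other",
    "intergenic": "none",
}

_SEVERITY_RANK = {"none": 0, "low_or_other": 1, "moderate": 2, "high": 3}


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript protein-coding gene model.

    All intervals are 1-based, fully closed, and given in genome
    coordinates in ascending order regardless of strand.  ``cds``
    intervals must lie within exons and their total length must be a
    multiple of 3.
    """

    gene_id: str
    chromosome: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not self.exons:
            raise ValueError("a gene model needs at least one exon")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if not (s1 <= e1 < s2 <= e2):
                raise ValueError("exons must be ordered and non-overlapping")
        if self.exons[0][0] < self.tx_start or self.exons[-1][1] > self.tx_end:
            raise ValueError("exons outside the transcript span")
        if sum(e - s + 1 for s, e in self.cds) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    def contains(self, position: int) -> bool:
        return self.tx_start <= position <= self.tx_end

    def splice_sites(self) -> tuple[tuple[int, int], ...]:
        """The canonical 2-base donor/acceptor windows of each intron."""
        sites = []
        for s, e in self.introns:
            sites.append((s, s + 1))
            sites.append((e - 1, e))
        return tuple(sites)

    def cds_sequence(self, reference: Mapping[str, str]) -> str:
        """Spliced CDS in coding orientation."""
        seq = "".join(reference[self.chromosome][s - 1 : e] for s, e in self.cds)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def cds_index(self, position: int) -> int | None:
        """0-based position within the coding sequence, or None if non-CDS."""
        offset = 0
        for s, e in self.cds:
            if s <= position <= e:
                idx = offset + (position - s)
                break
            offset += e - s + 1
        else:
            return None
        if self.strand == "-":
            total = sum(e - s + 1 for s, e in self.cds)
            idx = total - 1 - idx
        return idx


@dataclass(frozen=True)
class EffectCall:
    """Predicted effect of one variant on one gene."""

    gene_id: str | None
    effect: str
    impact_level: str
    line_id: str = ""
    origin: str = "small"  # 'small' (SBS/indel) or 'sv'

    def __post_init__(self) -> None:
        if self.effect not in IMPACT_BY_EFFECT:
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.impact_level != IMPACT_BY_EFFECT[self.effect]:
            raise ValueError(
                f"impact {self.impact_level!r} inconsistent with effect {self.effect!r}"
            )


def _effect(gene_id, effect, line_id, origin="small") -> EffectCall:
    return EffectCall(gene_id, effect, IMPACT_BY_EFFECT[effect], line_id, origin)


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def _sbs_effect(gene: GeneModel, position: int, alt: str, reference: Mapping[str, str]) -> str:
    idx = gene.cds_index(position)
    if idx is None:
        return "intron" if any(s <= position <= e for s, e in gene.introns) else "utr"
    cds = gene.cds_sequence(reference)
    alt_base = alt if gene.strand == "+" else str(Seq(alt).reverse_complement())
    mutated = cds[:idx] + alt_base + cds[idx + 1 :]
    codon_i = idx // 3
    ref_aa = str(Seq(cds[codon_i * 3 : codon_i * 3 + 3]).translate())
    alt_aa = str(Seq(mutated[codon_i * 3 : codon_i * 3 + 3]).translate())
    if alt_aa == ref_aa:
        return "synonymous"
    if alt_aa == "*":
        return "nonsense"
    # start-codon loss is scored like a missense change (moderate)
    return "missense"


def annotate_variant(
    variant: CandidateVariant,
    genes: Sequence[GeneModel],
    reference: Mapping[str, str],
) -> list[EffectCall]:
    """Effect calls of a small mutation (SBS or indel) on every overlapped gene.

    An SBS in CDS is translated strand-aware into nonsense, missense or
    synonymous; a CDS indel is a frameshift unless its size is a
    multiple of 3 (inframe); a hit on a canonical 2-base splice
    dinucleotide is splice-site loss; within a transcript but outside
    the CDS it is UTR or intron; and outside all transcripts the call
    is intergenic with no impact.
    """
    if variant.chromosome not in reference:
        raise ValueError(f"variant on unknown chromosome {variant.chromosome!r}")
    span_end = variant.position + max(len(variant.ref_allele) - 1, 0)
    calls: list[EffectCall] = []
    for gene in genes:
        if gene.chromosome != variant.chromosome:
            continue
        if not _overlaps(variant.position, span_end, gene.tx_start, gene.tx_end):
            continue
        if any(_overlaps(variant.position, span_end, s, e) for s, e in gene.splice_sites()):
            calls.append(_effect(gene.gene_id, "splice_site_loss", variant.line_id))
            continue
        if variant.variant_kind == "SBS":
            eff = _sbs_effect(gene, variant.position, variant.alt_allele, reference)
            calls.append(_effect(gene.gene_id, eff, variant.line_id))
        else:
            size = len(variant.alt_allele) - len(variant.ref_allele)
            # the anchor base itself is unchanged; the edit applies after it
            edit_start = variant.position + 1
            in_cds = any(
                _overlaps(edit_start, max(edit_start, span_end), s, e)
                for s, e in gene.cds
            )
            if in_cds:
                eff = "inframe_indel" if size % 3 == 0 else "frameshift"
            elif any(
                _overlaps(edit_start, max(edit_start, span_end), s, e)
                for s, e in gene.introns
            ):
                eff = "intron"
            else:
                eff = "utr"
            calls.append(_effect(gene.gene_id, eff, variant.line_id))
    if not calls:
        calls.append(_effect(None, "intergenic", variant.line_id))
    return calls


def annotate_sv_call(call: SVCall, genes: Sequence[GeneModel]) -> list[EffectCall]:
    """Effect calls of a structural variant on the genes it touches.

    A gene disrupted at a breakpoint, or overlapped by a deleted
    interval, is truncated (high impact); a gene copied whole inside a
    duplication is affected but not truncated (low/other).  One call is
    emitted per (gene, SV call).
    """
    truncated: set[str] = set()
    duplicated: set[str] = set()
    for ev in call.events:
        for gene in genes:
            bps_inside = [
                p for c, p in ev.breakpoints if c == gene.chromosome and gene.contains(p)
            ]
            if ev.event_type in ("large_deletion",):
                (c1, p1), (c2, p2) = ev.breakpoints
                lo, hi = min(p1, p2), max(p1, p2)
                if c1 == gene.chromosome and _overlaps(lo, hi, gene.tx_start, gene.tx_end):
                    truncated.add(gene.gene_id)
            elif ev.event_type == "duplication":
                (c1, p1), (c2, p2) = ev.breakpoints
                lo, hi = min(p1, p2), max(p1, p2)
                if c1 != gene.chromosome:
                    continue
                if bps_inside:
                    truncated.add(gene.gene_id)
                elif lo <= gene.tx_start and gene.tx_end <= hi:
                    duplicated.add(gene.gene_id)
            elif bps_inside:
                # inversion, large insertion or translocation junction
                # breaking inside the gene body disrupts it
                truncated.add(gene.gene_id)
    calls = [_effect(g, "gene_truncation", call.line_id, "sv") for g in sorted(truncated)]
    calls += [
        _effect(g, "whole_gene_duplication", call.line_id, "sv")
        for g in sorted(duplicated - truncated)
    ]
    if not calls:
        calls.append(_effect(None, "intergenic", call.line_id, "sv"))
    return calls


def genes_affected_per_line(effect_calls: Iterable[EffectCall]) -> pd.DataFrame:
    """Per-line affected-gene tallies, split by small-mutation vs SV origin.

    A gene counts once per line however many variants hit it; for the
    high/moderate tallies the most severe impact on the gene wins.
    Columns: affected / high / moderate, each total and per origin.
    """
    best: dict[tuple[str, str, str], int] = {}
    lines: set[str] = set()
    for call in effect_calls:
        lines.add(call.line_id)
        if call.gene_id is None or call.impact_level == "none":
            continue
        for origin in (call.origin, "any"):
            key = (call.line_id, origin, call.gene_id)
            rank = _SEVERITY_RANK[call.impact_level]
            best[key] = max(best.get(key, 0), rank)

    rows = []
    for line in sorted(lines):
        row = {"line_id": line}
        for origin, suffix in (("any", "total"), ("small", "small"), ("sv", "sv")):
            ranks = [r for (l, o, _), r in best.items() if l == line and o == origin]
            row[f"affected_{suffix}"] = len(ranks)
            row[f"high_{suffix}"] = sum(r == 3 for r in ranks)
            row[f"moderate_{suffix}"] = sum(r == 2 for r in ranks)
        rows.append(row)
    return pd.DataFrame(rows).set_index("line_id") if rows else pd.DataFrame(
        columns=[
            "affected_total", "high_total", "moderate_total",
            "affected_small", "high_small", "moderate_small",
            "affected_sv", "high_sv", "moderate_sv",
        ]
    )
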