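"""Readers, writers, run configuration and the pipeline driver.

Interchange formats: FASTA for the reference, GFF3 for gene models,
VCF (per-sample DP and AD) for small-mutation candidates, a simple
breakpoint TSV for SV events, and TSV/JSON for tabular outputs.
Coordinates are 1-based, fully closed throughout.

The SV breakpoint TSV dialect has columns::

    line_id  event_type  chrom1  pos1  chrom2  pos2  size

with ``size`` empty for translocation junctions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam
import yaml

from .compare import (
    ComparisonReport,
    build_comparison_report,
    chi_square_vs_expected,
    summarize_group,
)
from .filtering import (
    CandidateVariant,
    FilteredVariant,
    FilterThresholds,
    apply_candidate_filters,
)
from .impact import GeneModel, annotate_sv_call, annotate_variant, genes_affected_per_line
from .rates import (
    CallableProfile,
    SelfingModel,
    estimate_generation_totals,
    expected_homozygous_fraction,
)
from .spectra import SVEvent, classify_indel, cluster_sv_events

logger = logging.getLogger("radmut")

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_sv_tsv",
    "write_sv_tsv",
    "read_callable_tsv",
    "write_callable_tsv",
    "GroupConfig",
    "RunConfig",
    "load_config",
    "run_pipeline",
    "classified_counts",
]


class VcfFieldError(ValueError):
    """A VCF record lacks the depth fields (DP/AD) the pipeline needs."""


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path, line_id: str | None = None) -> list[CandidateVariant]:
    """Read candidate variants from a VCF with per-sample DP and AD.

    Multi-allelic records are split into one candidate per alt allele,
    each keeping the site depth.  ``line_id`` defaults to the sample
    name (or the file stem for sample-less VCFs).
    """
    path = Path(path)
    out: list[CandidateVariant] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        inferred = line_id or (samples[0] if samples else path.stem)
        for i, rec in enumerate(vf.fetch() if vf.index else vf):
            try:
                if samples:
                    fmt = rec.samples[samples[0]]
                    ad = fmt.get("AD")
                    dp = fmt.get("DP")
                else:
                    ad = rec.info.get("AD")
                    dp = rec.info.get("DP")
                if ad is None and dp is None:
                    raise VcfFieldError(
                        f"{path}: record {i + 1} at {rec.chrom}:{rec.pos} "
                        "has neither DP nor AD"
                    )
                alts = rec.alts or ()
                depth = int(dp) if dp is not None else int(sum(a or 0 for a in ad))
                for ai, alt in enumerate(alts):
                    alt_count = (
                        int(ad[ai + 1]) if ad is not None and len(ad) > ai + 1
                        else depth
                    )
                    out.append(
                        CandidateVariant(
                            line_id=inferred, chromosome=rec.chrom, position=rec.pos,
                            ref_allele=rec.ref, alt_allele=alt,
                            depth=depth, alt_count=alt_count,
                        )
                    )
            except VcfFieldError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise ValueError(f"{path}: malformed record {i + 1}: {exc}") from exc
    return out


def write_vcf(
    path: str | Path,
    variants: Sequence[CandidateVariant | FilteredVariant],
    line_id: str | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write candidates (optionally with dispositions) as a one-sample VCF.

    Disposition and zygosity of :class:`FilteredVariant` inputs are
    written as the DISP and ZYG INFO tags.
    """
    pairs = [
        (v.variant, v) if isinstance(v, FilteredVariant) else (v, None)
        for v in variants
    ]
    if line_id is None:
        line_id = pairs[0][0].line_id if pairs else "sample"

    header = pysam.VariantHeader()
    contigs: dict[str, int] = dict(contig_lengths or {})
    for cv, _ in pairs:
        need = cv.position + len(cv.ref_allele) + 1000
        contigs[cv.chromosome] = max(contigs.get(cv.chromosome, 0), need)
    for name in sorted(contigs):
        header.contigs.add(name, length=contigs[name])
    header.formats.add("DP", 1, "Integer", "Read depth at the site")
    header.formats.add("AD", "R", "Integer", "Allelic read depths (ref, alt)")
    header.info.add("DISP", 1, "String", "Filter disposition")
    header.info.add("ZYG", 1, "String", "Called zygosity")
    header.add_sample(line_id)

    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for cv, fv in sorted(pairs, key=lambda p: (p[0].chromosome, p[0].position)):
            rec = vf.new_record(
                contig=cv.chromosome, start=cv.position - 1,
                alleles=(cv.ref_allele, cv.alt_allele),
            )
            rec.samples[line_id]["DP"] = cv.depth
            rec.samples[line_id]["AD"] = (cv.depth - cv.alt_count, cv.alt_count)
            if fv is not None:
                rec.info["DISP"] = fv.disposition
                rec.info["ZYG"] = fv.zygosity
            vf.write(rec)


# ---------------------------------------------------------------------------
# FASTA / GFF3


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS, computed phases)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chromosome}\tradmut\tgene\t{g.tx_start}\t{g.tx_end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chromosome}\tradmut\tmRNA\t{g.tx_start}\t{g.tx_end}\t.\t"
                f"{g.strand}\t.\tID={tid};Parent={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chromosome}\tradmut\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={tid}\n"
                )
            coding = list(g.cds) if g.strand == "+" else list(g.cds)[::-1]
            phase = 0
            for s, e in coding:
                fh.write(
                    f"{g.chromosome}\tradmut\tCDS\t{s}\t{e}\t.\t{g.strand}\t"
                    f"{phase}\tParent={tid}\n"
                )
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
        fh.flush()


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read single-transcript gene models from a GFF3 file."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        exons = sorted(
            (f.start, f.end) for f in db.children(g, featuretype="exon")
        )
        cds = sorted((f.start, f.end) for f in db.children(g, featuretype="CDS"))
        genes.append(
            GeneModel(
                gene_id=g.id, chromosome=g.seqid, strand=g.strand,
                tx_start=g.start, tx_end=g.end,
                exons=tuple(exons), cds=tuple(cds),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# TSV dialects


def write_sv_tsv(events_by_line: Mapping[str, Sequence[SVEvent]], path: str | Path) -> None:
    rows = []
    for line_id, events in events_by_line.items():
        for ev in events:
            (c1, p1), (c2, p2) = ev.breakpoints
            rows.append(
                dict(line_id=line_id, event_type=ev.event_type,
                     chrom1=c1, pos1=p1, chrom2=c2, pos2=p2,
                     size="" if ev.size is None else ev.size)
            )
    pd.DataFrame(
        rows, columns=["line_id", "event_type", "chrom1", "pos1", "chrom2", "pos2", "size"]
    ).to_csv(path, sep="\t", index=False)


def read_sv_tsv(path: str | Path) -> dict[str, list[SVEvent]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})
    out: dict[str, list[SVEvent]] = {}
    for row in df.itertuples(index=False):
        size = None if pd.isna(row.size) or row.size == "" else int(row.size)
        ev = SVEvent(
            row.event_type,
            ((row.chrom1, int(row.pos1)), (row.chrom2, int(row.pos2))),
            size=size,
        )
        out.setdefault(row.line_id, []).append(ev)
    return out


def write_callable_tsv(profiles: Iterable[CallableProfile], path: str | Path) -> None:
    pd.DataFrame(
        [(p.line_id, p.callable_length, p.min_depth) for p in profiles],
        columns=["line_id", "callable_length", "min_depth"],
    ).to_csv(path, sep="\t", index=False)


def read_callable_tsv(path: str | Path) -> list[CallableProfile]:
    df = pd.read_csv(path, sep="\t")
    return [
        CallableProfile(r.line_id, float(r.callable_length), int(getattr(r, "min_depth", 5)))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# run configuration and pipeline driver


@dataclass
class GroupConfig:
    label: str
    dose: float
    vcfs: list[str]
    sv_tsv: str | None = None
    callable_tsv: str | None = None


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    groups: list[GroupConfig]
    outdir: str = "radmut_out"
    seed: int = 0
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    induced_generation: int = 1
    observed_generation: int = 5
    target_generations: tuple[int, ...] = (1, 2, 3)
    homozygosity_mode: str = "mendelian"  # or "fixed"
    fixed_hom_fraction: float = 0.85
    callable_length: float | None = None  # used when no callable TSVs are given
    reference_fasta: str | None = None
    gff3: str | None = None

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        if self.homozygosity_mode not in ("mendelian", "fixed"):
            raise ValueError("homozygosity_mode must be 'mendelian' or 'fixed'")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    groups = [GroupConfig(**g) for g in raw.pop("groups")]
    thresholds = FilterThresholds(**raw.pop("thresholds", {}))
    if "target_generations" in raw:
        raw["target_generations"] = tuple(raw["target_generations"])
    return RunConfig(groups=groups, thresholds=thresholds, **raw)


def classified_counts(
    passed: Sequence[FilteredVariant],
    sv_calls_by_line: Mapping[str, int] | None = None,
    line_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-line SBS/DEL/INS/SV count table from pass-filtered variants."""
    sv_calls_by_line = dict(sv_calls_by_line or {})
    lines = set(line_ids or []) | set(sv_calls_by_line)
    counts: dict[str, dict[str, int]] = {}
    for fv in passed:
        if fv.disposition != "pass":
            continue
        v = fv.variant
        lines.add(v.line_id)
        row = counts.setdefault(v.line_id, {"SBS": 0, "DEL": 0, "INS": 0, "SV": 0})
        if v.variant_kind == "SBS":
            row["SBS"] += 1
        else:
            size = classify_indel(v.ref_allele, v.alt_allele).signed_size
            row["DEL" if size < 0 else "INS"] += 1
    for line_id in lines:
        counts.setdefault(line_id, {"SBS": 0, "DEL": 0, "INS": 0, "SV": 0})
        counts[line_id]["SV"] = int(sv_calls_by_line.get(line_id, 0))
    df = pd.DataFrame.from_dict(counts, orient="index").sort_index()
    df.index.name = "line_id"
    df["Total"] = df[["SBS", "DEL", "INS", "SV"]].sum(axis=1)
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Execute filter -> classify -> rates -> impact -> compare.

    Returns the report bundle as a dict and writes TSV/JSON outputs
    under ``config.outdir``.  The cross-line uniqueness filter runs on
    the pooled records of all groups, as background variants are
    shared across the whole panel.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    all_records: list[CandidateVariant] = []
    lines_by_group: dict[str, list[str]] = {}
    sv_events_by_line: dict[str, list[SVEvent]] = {}
    callable_by_group: dict[str, float] = {}
    for g in config.groups:
        if not g.vcfs:
            raise ValueError(f"group {g.label!r} has no input VCFs")
        ids: list[str] = []
        for vcf in g.vcfs:
            recs = read_vcf(vcf)
            if recs:
                ids.append(recs[0].line_id)
            all_records.extend(recs)
        lines_by_group[g.label] = ids
        if g.sv_tsv:
            sv_events_by_line.update(read_sv_tsv(g.sv_tsv))
        if g.callable_tsv:
            profiles = read_callable_tsv(g.callable_tsv)
            callable_by_group[g.label] = float(
                pd.Series([p.callable_length for p in profiles]).mean()
            )
        elif config.callable_length:
            callable_by_group[g.label] = float(config.callable_length)
        else:
            raise ValueError(
                f"group {g.label!r} needs a callable TSV or a global callable_length"
            )
    logger.info("read %d candidate records", len(all_records))

    filtered = apply_candidate_filters(all_records, config.thresholds)
    passed = [fv for fv in filtered if fv.disposition == "pass"]
    logger.info("filter: %d in, %d pass", len(filtered), len(passed))

    sv_counts = {
        line: len(cluster_sv_events(evs, line_id=line))
        for line, evs in sv_events_by_line.items()
    }

    summaries = []
    for g in config.groups:
        ids = lines_by_group[g.label]
        group_pass = [fv for fv in passed if fv.variant.line_id in ids]
        counts = classified_counts(
            group_pass, {l: sv_counts.get(l, 0) for l in ids}, line_ids=ids
        )
        counts.to_csv(outdir / f"counts_{g.label}.tsv", sep="\t")
        summaries.append(summarize_group(g.label, counts))

    mean_callable = float(pd.Series(callable_by_group).mean())
    report = build_comparison_report(
        summaries, mean_callable, {g.label: g.dose for g in config.groups}
    )
    report.table.to_csv(outdir / "comparison_table.tsv", sep="\t")

    # zygosity and per-generation back-estimation
    model = SelfingModel(config.induced_generation)
    if config.homozygosity_mode == "fixed":
        expected_hom = config.fixed_hom_fraction
        override = config.fixed_hom_fraction
    else:
        expected_hom = expected_homozygous_fraction(model, config.observed_generation)
        override = None
    zygosity: dict[str, dict] = {}
    for g in config.groups:
        ids = set(lines_by_group[g.label])
        zyg = [fv.zygosity for fv in passed if fv.variant.line_id in ids]
        n_hom, n_tot = sum(z == "homozygous" for z in zyg), len(zyg)
        mean_hom_per_line = n_hom / max(len(ids), 1)
        estimates = {
            k: estimate_generation_totals(
                mean_hom_per_line, config.observed_generation, k, model,
                expected_hom_fraction_override=override,
            )
            for k in config.target_generations
        }
        entry: dict = {
            "n_homozygous": n_hom,
            "n_detected": n_tot,
            "observed_fraction": n_hom / n_tot if n_tot else float("nan"),
            "expected_fraction": expected_hom,
            "generation_estimates": {
                k: {"expected_detected": e.expected_detected,
                    "rate_1e8": round(e.rate(callable_by_group[g.label]) * 1e8, 1)}
                for k, e in estimates.items()
            },
        }
        if n_tot:
            entry["chi_square"] = chi_square_vs_expected(
                n_hom, n_tot, expected_hom
            ).p_value
        zygosity[g.label] = entry

    # gene-impact tallies, when annotation inputs are configured
    impact_table = None
    if config.reference_fasta and config.gff3:
        reference = read_fasta(config.reference_fasta)
        genes = read_gff3(config.gff3)
        calls = []
        for fv in passed:
            calls.extend(annotate_variant(fv.variant, genes, reference))
        for line, evs in sv_events_by_line.items():
            for call in cluster_sv_events(evs, line_id=line):
                calls.extend(annotate_sv_call(call, genes))
        impact_table = genes_affected_per_line(calls)
        impact_table.to_csv(outdir / "genes_affected.tsv", sep="\t")

    bundle = {
        "n_records": len(all_records),
        "n_pass": len(passed),
        "dispositions": pd.Series(
            [fv.disposition for fv in filtered]
        ).value_counts().to_dict(),
        "comparison": report.to_json_dict(),
        "zygosity": zygosity,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=float)
    if impact_table is not None:
        bundle["genes_affected"] = impact_table
    bundle["report"] = report
    return bundle
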