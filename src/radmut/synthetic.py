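"""Synthetic study generator: genome, induced mutations, selfing, bulk reads.

Emulates a two-group radiation-mutagenesis design in a selfing diploid:
dry seeds irradiated with gamma rays (low LET) or carbon ions (high
LET), mutant lines selfed from M1 to M5, and each line sequenced as a
bulk of >20 M6 seedlings at ~30x so that read counts reflect the
zygosity of the M5 parent.  The generator produces a toy reference
genome with gene models, radiation-specific true mutations (single
base substitutions, small indels, structural variants), their
Mendelian transmission through selfing, and variant-record-level read
evidence — the same record types the analysis pipeline consumes — plus
a truth table for evaluation.  No read sequences are simulated.

Per-line mutation counts are Poisson around group means; the default
group spectra use the mean counts, substitution-class make-up, indel
size distribution and SV type mix characteristic of ~250 Gy gamma and
~30 Gy carbon-ion irradiation of rice seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filtering import CandidateVariant
from .impact import GeneModel
from .spectra import SBS_CATEGORIES, SVEvent

__all__ = [
    "SyntheticGenomeSpec",
    "RadiationSpectrum",
    "TruthMutation",
    "BulkSamplingSpec",
    "Reference",
    "generate_reference",
    "induce_mutations",
    "transmit_selfing",
    "simulate_bulk_reads",
    "simulate_group",
    "SimulatedGroup",
    "gamma_spectrum",
    "carbon_ion_spectrum",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Dimensions of the toy reference genome and its gene complement."""

    n_chromosomes: int = 2
    chromosome_length: int = 400_000
    gc_fraction: float = 0.44
    n_genes: int = 60
    gene_length: int = 3_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.chromosome_length, self.gene_length) <= 0:
            raise ValueError("all sizes must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes cannot be negative")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.chromosome_length < 10 * self.gene_length:
            raise ValueError("chromosome_length must be >= 10 x gene_length")
        if self.gene_length < 600:
            raise ValueError("gene_length must be >= 600 to fit UTRs, intron and CDS")


@dataclass(frozen=True)
class RadiationSpectrum:
    """Expected per-line mutation yield and class make-up of one radiation.

    Means are per line; ``sbs_category_probs`` follows the order of
    :data:`radmut.spectra.SBS_CATEGORIES`; ``indel_size_probs`` maps
    signed sizes (bases, + insertion / - deletion) to probabilities;
    ``sv_type_probs`` distributes SVs over simple types plus
    ``complex`` (a clustered multi-DSB event carrying
    ``complex_event_range`` sub-events).
    """

    label: str
    dose: float
    mean_sbs: float
    mean_del: float
    mean_ins: float
    mean_sv: float
    sbs_category_probs: tuple[float, ...]
    indel_size_probs: dict[int, float]
    sv_type_probs: dict[str, float]
    complex_event_range: tuple[int, int] = (2, 3)

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if min(self.mean_sbs, self.mean_del, self.mean_ins, self.mean_sv) < 0:
            raise ValueError("means must be non-negative")
        if len(self.sbs_category_probs) != len(SBS_CATEGORIES):
            raise ValueError("need one probability per SBS category")
        for name, probs in (
            ("sbs_category_probs", self.sbs_category_probs),
            ("indel_size_probs", tuple(self.indel_size_probs.values())),
            ("sv_type_probs", tuple(self.sv_type_probs.values())),
        ):
            if probs and abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(p < 0 for p in probs):
                raise ValueError(f"{name} must be non-negative")
        if any(s == 0 for s in self.indel_size_probs):
            raise ValueError("indel sizes are signed and non-zero")
        lo, hi = self.complex_event_range
        if not 2 <= lo <= hi:
            raise ValueError("complex SVs carry at least two sub-events")


@dataclass
class TruthMutation:
    """Simulator-side ground truth for one induced mutation in one line."""

    line_id: str
    chromosome: str
    position: int
    mutation_class: str  # SBS | small_del | small_ins | SV
    ref_allele: str
    alt_allele: str
    induced_generation: int = 1
    genotype_by_generation: dict[int, str] = field(default_factory=dict)
    sv_type: str | None = None
    sv_events: tuple[SVEvent, ...] = ()


@dataclass(frozen=True)
class BulkSamplingSpec:
    """Bulk M6 sampling and sequencing-noise parameters."""

    n_seedlings: int = 24
    mean_depth: float = 30.0
    error_rate: float = 0.002
    n_background_variants: int = 50
    n_false_positives: int = 5

    def __post_init__(self) -> None:
        if self.n_seedlings < 1:
            raise ValueError("need at least one seedling in the bulk")
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")
        if not 0 <= self.error_rate < 0.05:
            raise ValueError("error rate must be in [0, 0.05)")
        if min(self.n_background_variants, self.n_false_positives) < 0:
            raise ValueError("counts cannot be negative")


@dataclass(frozen=True)
class Reference:
    """Toy reference: chromosome sequences plus gene models."""

    sequences: dict[str, str]
    genes: tuple[GeneModel, ...]

    @property
    def chromosome_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


# ---------------------------------------------------------------------------
# default spectra

# Substitution classes in SBS_CATEGORIES order (AT>GC, GC>AT, AT>CG,
# AT>TA, GC>TA, GC>CG).  GC>AT transitions dominate both radiations and
# the overall Ts/Tv sits near 1.6 (Ts fraction ~0.615).
_GAMMA_SBS_PROBS = (0.185, 0.430, 0.080, 0.130, 0.130, 0.045)
_CION_SBS_PROBS = (0.148, 0.467, 0.070, 0.125, 0.130, 0.060)

# Signed indel sizes; deletions outnumber insertions ~3:1 and the
# +1..-4 band holds ~70% (gamma) / ~60% (C-ion) of small indels.
_GAMMA_INDEL_PROBS = {
    1: 0.17, 2: 0.04, 3: 0.025, 6: 0.015,
    -1: 0.28, -2: 0.13, -3: 0.07, -4: 0.05, -5: 0.05, -6: 0.04,
    -8: 0.035, -10: 0.03, -15: 0.025, -20: 0.02, -30: 0.01,
    -50: 0.007, -80: 0.003,
}
_CION_INDEL_PROBS = {
    1: 0.15, 2: 0.06, 3: 0.04, 6: 0.03,
    -1: 0.24, -2: 0.11, -3: 0.06, -4: 0.05, -5: 0.04, -6: 0.045,
    -8: 0.04, -10: 0.035, -15: 0.03, -20: 0.025, -30: 0.02,
    -50: 0.015, -80: 0.01,
}

# Gamma SVs are rare and, when seen, large insertions or reciprocal
# translocations; carbon ions additionally produce deletions,
# duplications, inversions and clustered multi-DSB (complex) events.
_GAMMA_SV_PROBS = {"large_insertion": 0.5, "reciprocal_translocation": 0.5}
_CION_SV_PROBS = {
    "large_deletion": 0.35,
    "large_insertion": 0.10,
    "duplication": 0.10,
    "inversion": 0.15,
    "reciprocal_translocation": 0.15,
    "complex": 0.15,
}


def gamma_spectrum() -> RadiationSpectrum:
    """Default gamma-ray group: 250 Gy, many small mutations, few SVs."""
    return RadiationSpectrum(
        label="gamma", dose=250.0,
        mean_sbs=57.0, mean_del=17.7, mean_ins=5.9, mean_sv=0.6,
        sbs_category_probs=_GAMMA_SBS_PROBS,
        indel_size_probs=dict(_GAMMA_INDEL_PROBS),
        sv_type_probs=dict(_GAMMA_SV_PROBS),
    )


def carbon_ion_spectrum() -> RadiationSpectrum:
    """Default carbon-ion group: 30 Gy, fewer small mutations, more SVs."""
    return RadiationSpectrum(
        label="C-ion", dose=30.0,
        mean_sbs=43.7, mean_del=13.6, mean_ins=5.3, mean_sv=2.0,
        sbs_category_probs=_CION_SBS_PROBS,
        indel_size_probs=dict(_CION_INDEL_PROBS),
        sv_type_probs=dict(_CION_SV_PROBS),
    )


# ---------------------------------------------------------------------------
# reference genome


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + non-stop codons + TAA, total (n_codons+2)*3 bases."""
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(_BASES, size=3))
        if codon not in _STOPS and codon != "ATG":
            codons.append(codon)
    return "ATG" + "".join(codons) + "TAA"


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _build_gene(
    rng: np.random.Generator, gene_id: str, chrom: str, offset: int,
    length: int, strand: str, gc: float,
) -> tuple[str, GeneModel]:
    """Forward-built gene piece written at 1-based genome offset."""
    utr = length // 10
    intron_len = max(length // 6, 20)
    cds_total = length - 2 * utr - intron_len
    cds_total -= cds_total % 3
    inner_codons = cds_total // 3 - 2
    if inner_codons < 1:
        raise ValueError("gene_length too small for a coding gene")

    cds_seq = _random_cds(rng, inner_codons)
    e1 = cds_total // 2  # intron may split a codon; frame is carried across
    intron = "GT" + "".join(_random_seq(rng, intron_len - 4, gc)) + "AG"
    utr5 = "".join(_random_seq(rng, utr, gc))
    utr3_len = length - (utr + cds_total + intron_len)
    utr3 = "".join(_random_seq(rng, utr3_len, gc))
    piece = utr5 + cds_seq[:e1] + intron + cds_seq[e1:] + utr3
    n = len(piece)

    exons = [(1, utr + e1), (utr + e1 + intron_len + 1, n)]
    cds = [(utr + 1, utr + e1), (utr + e1 + intron_len + 1, utr + e1 + intron_len + (cds_total - e1))]
    if strand == "-":
        piece = _revcomp(piece)
        exons = sorted((n + 1 - e, n + 1 - s) for s, e in exons)
        cds = sorted((n + 1 - e, n + 1 - s) for s, e in cds)

    shift = offset - 1
    model = GeneModel(
        gene_id=gene_id,
        chromosome=chrom,
        strand=strand,
        tx_start=offset,
        tx_end=offset + n - 1,
        exons=tuple((s + shift, e + shift) for s, e in exons),
        cds=tuple((s + shift, e + shift) for s, e in cds),
    )
    return piece, model


def generate_reference(spec: SyntheticGenomeSpec) -> Reference:
    """Deterministically generate the toy genome and its gene models.

    Genes are packed non-overlapping with a one-gene-length gap, on
    alternating strands, each with a 5'UTR, two CDS exons separated by
    a canonical GT..AG intron, and a 3'UTR.  Raises a sizing error if
    ``n_genes`` cannot be packed.
    """
    rng = np.random.default_rng(spec.seed)
    gap = spec.gene_length
    per_chrom = max((spec.chromosome_length - gap) // (spec.gene_length + gap), 0)
    if spec.n_genes > per_chrom * spec.n_chromosomes:
        raise ValueError(
            f"cannot pack {spec.n_genes} genes of {spec.gene_length} bp into "
            f"{spec.n_chromosomes} x {spec.chromosome_length} bp "
            f"(capacity {per_chrom * spec.n_chromosomes})"
        )

    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    gene_no = 0
    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        seq = _random_seq(rng, spec.chromosome_length, spec.gc_fraction)
        n_here = min(per_chrom, spec.n_genes - gene_no)
        for gi in range(max(n_here, 0)):
            offset = gap + gi * (spec.gene_length + gap) + 1
            strand = "+" if gene_no % 2 == 0 else "-"
            piece, model = _build_gene(
                rng, f"gene{gene_no + 1:04d}", chrom, offset,
                spec.gene_length, strand, spec.gc_fraction,
            )
            seq[offset - 1 : offset - 1 + len(piece)] = list(piece)
            genes.append(model)
            gene_no += 1
        sequences[chrom] = "".join(seq)
    return Reference(sequences=sequences, genes=tuple(genes))


# ---------------------------------------------------------------------------
# mutation induction


def _pick_sbs(
    rng: np.random.Generator, reference: Reference, spectrum: RadiationSpectrum,
    used: set[tuple[str, int]],
) -> tuple[str, int, str, str]:
    chroms = list(reference.sequences)
    cat = SBS_CATEGORIES[rng.choice(len(SBS_CATEGORIES), p=np.asarray(spectrum.sbs_category_probs))]
    src, dst = cat.split(">")
    for _ in range(10_000):
        chrom = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(1, len(reference.sequences[chrom]) + 1))
        base = reference.sequences[chrom][pos - 1]
        if base in src and (chrom, pos) not in used:
            used.add((chrom, pos))
            alt = dst[0] if base == src[0] else _COMPLEMENT[dst[0]]
            return chrom, pos, base, alt
    raise RuntimeError("could not place an SBS; genome too small or saturated")


def _pick_indel(
    rng: np.random.Generator, reference: Reference, spectrum: RadiationSpectrum,
    used: set[tuple[str, int]], want_insertion: bool,
) -> tuple[str, int, str, str, int]:
    sizes = sorted(s for s in spectrum.indel_size_probs if (s > 0) == want_insertion)
    if not sizes:
        raise ValueError("spectrum has no indel sizes of the requested sign")
    probs = np.array([spectrum.indel_size_probs[s] for s in sizes])
    probs = probs / probs.sum()
    chroms = list(reference.sequences)
    for _ in range(10_000):
        size = int(rng.choice(sizes, p=probs))
        chrom = chroms[rng.integers(len(chroms))]
        seq = reference.sequences[chrom]
        pos = int(rng.integers(1, len(seq) - abs(size)))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        anchor = seq[pos - 1]
        if size > 0:
            inserted = "".join(rng.choice(_BASES, size=size))
            return chrom, pos, anchor, anchor + inserted, size
        return chrom, pos, seq[pos - 1 : pos - size], anchor, size
    raise RuntimeError("could not place an indel")


def _simple_sv_event(
    rng: np.random.Generator, reference: Reference, sv_type: str,
    chrom: str | None = None, anchor: int | None = None, window: int = 50_000,
) -> SVEvent:
    chroms = list(reference.sequences)
    if chrom is None:
        chrom = chroms[rng.integers(len(chroms))]
    clen = len(reference.sequences[chrom])
    size = int(rng.integers(100, min(20_000, clen // 4)))
    if anchor is None:
        p1 = int(rng.integers(1, clen - size))
    else:
        p1 = int(min(max(1, anchor + rng.integers(0, window)), clen - size - 1))
    return SVEvent(sv_type, ((chrom, p1), (chrom, p1 + size)), size=size)


def _make_sv(
    rng: np.random.Generator, reference: Reference, spectrum: RadiationSpectrum,
) -> tuple[str, tuple[SVEvent, ...]]:
    types = sorted(spectrum.sv_type_probs)
    probs = np.array([spectrum.sv_type_probs[t] for t in types])
    sv_type = str(rng.choice(types, p=probs))
    chroms = list(reference.sequences)

    if sv_type == "reciprocal_translocation" and len(chroms) >= 2:
        c1, c2 = [chroms[i] for i in rng.choice(len(chroms), size=2, replace=False)]
        p1 = int(rng.integers(1, len(reference.sequences[c1])))
        p2 = int(rng.integers(1, len(reference.sequences[c2])))
        ev = (
            SVEvent("translocation_junction", ((c1, p1), (c2, p2))),
            SVEvent("translocation_junction", ((c2, p2 + 1), (c1, p1 + 1))),
        )
        return sv_type, ev
    if sv_type == "complex":
        lo, hi = spectrum.complex_event_range
        k = int(rng.integers(lo, hi + 1))
        chrom = chroms[rng.integers(len(chroms))]
        clen = len(reference.sequences[chrom])
        anchor = int(rng.integers(1, max(clen - 100_000, clen // 2)))
        subtypes = rng.choice(["large_deletion", "duplication", "inversion"], size=k)
        events = tuple(
            _simple_sv_event(rng, reference, str(t), chrom=chrom, anchor=anchor)
            for t in subtypes
        )
        return sv_type, events
    if sv_type == "reciprocal_translocation":
        sv_type = "inversion"  # single-chromosome genomes cannot translocate
    return sv_type, (_simple_sv_event(rng, reference, sv_type),)


def induce_mutations(
    reference: Reference,
    spectrum: RadiationSpectrum,
    n_lines: int,
    seed: int | np.random.Generator = 0,
    line_prefix: str | None = None,
    induced_generation: int = 1,
) -> list[list[TruthMutation]]:
    """Draw per-line true mutations, all heterozygous at induction.

    Counts of each class are Poisson around the spectrum means; SBS
    ref/alt pairs follow ``sbs_category_probs`` respecting the
    reference base; complex SVs carry >= 2 sub-events at clustered
    breakpoints.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prefix = line_prefix or spectrum.label
    lines: list[list[TruthMutation]] = []
    for li in range(n_lines):
        line_id = f"{prefix}_{li + 1:03d}"
        used: set[tuple[str, int]] = set()
        muts: list[TruthMutation] = []

        def add(chrom, pos, mclass, ref, alt, sv_type=None, sv_events=()):
            muts.append(
                TruthMutation(
                    line_id=line_id, chromosome=chrom, position=pos,
                    mutation_class=mclass, ref_allele=ref, alt_allele=alt,
                    induced_generation=induced_generation,
                    genotype_by_generation={induced_generation: "heterozygous"},
                    sv_type=sv_type, sv_events=tuple(sv_events),
                )
            )

        for _ in range(rng.poisson(spectrum.mean_sbs)):
            chrom, pos, ref, alt = _pick_sbs(rng, reference, spectrum, used)
            add(chrom, pos, "SBS", ref, alt)
        for _ in range(rng.poisson(spectrum.mean_del)):
            chrom, pos, ref, alt, _size = _pick_indel(rng, reference, spectrum, used, False)
            add(chrom, pos, "small_del", ref, alt)
        for _ in range(rng.poisson(spectrum.mean_ins)):
            chrom, pos, ref, alt, _size = _pick_indel(rng, reference, spectrum, used, True)
            add(chrom, pos, "small_ins", ref, alt)
        for _ in range(rng.poisson(spectrum.mean_sv)):
            sv_type, events = _make_sv(rng, reference, spectrum)
            chrom, pos = events[0].breakpoints[0]
            add(chrom, pos, "SV", "N", f"<{sv_type.upper()}>", sv_type, events)
        lines.append(muts)
    return lines


# ---------------------------------------------------------------------------
# selfing and bulk sequencing


def transmit_selfing(
    lines: list[list[TruthMutation]],
    n_generations: int,
    seed: int | np.random.Generator = 0,
) -> list[list[TruthMutation]]:
    """Fill genotype trajectories by per-generation Mendelian draws.

    Each selfing round a heterozygous mutation is lost with probability
    1/4, stays heterozygous with 1/2 and fixes homozygous with 1/4;
    lost and homozygous are absorbing.  Trajectories are filled in
    place and the input is returned.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for muts in lines:
        for m in muts:
            if m.induced_generation > n_generations:
                raise ValueError("induced generation beyond the simulated range")
            state = "heterozygous"
            m.genotype_by_generation[m.induced_generation] = state
            for k in range(m.induced_generation + 1, n_generations + 1):
                if state == "heterozygous":
                    u = rng.random()
                    state = "lost" if u < 0.25 else ("heterozygous" if u < 0.75 else "homozygous")
                m.genotype_by_generation[k] = state
    return lines


def _bulk_allele_frequency(
    rng: np.random.Generator, state: str, n_seedlings: int
) -> float:
    """Mutant-allele frequency in a bulk of selfed offspring.

    A homozygous parent transmits the allele at frequency 1; a
    heterozygous parent's selfed seedlings are wt/het/hom at 1/4, 1/2,
    1/4, leaving the expected bulk allele frequency at 1/2.
    """
    if state == "homozygous":
        return 1.0
    n_wt, n_het, n_hom = rng.multinomial(n_seedlings, [0.25, 0.5, 0.25])
    return (0.5 * n_het + n_hom) / n_seedlings


def simulate_bulk_reads(
    lines: list[list[TruthMutation]],
    observed_generation: int,
    bulk: BulkSamplingSpec,
    reference: Reference,
    seed: int | np.random.Generator = 0,
) -> tuple[list[CandidateVariant], pd.DataFrame]:
    """Emit per-line candidate-variant records with read evidence.

    Small mutations carried at ``observed_generation`` produce one
    record each: depth ~ Poisson(mean_depth), alt reads ~
    Binomial(depth, f(1-e) + (1-f)e) with f the bulk allele frequency
    and e the symmetric per-base error rate.  Shared background
    variants (cultivar-vs-reference differences) are emitted
    homozygous and identically in every line; ``n_false_positives``
    low-VAF (<40%) artifact records are added per line.  Mendelian-lost
    mutations and SVs yield no record (SVs travel as breakpoint
    events).  Returns the records plus a truth table pairing each
    emitted record with its origin ('true', 'background', 'artifact').
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = list(reference.sequences)
    records: list[CandidateVariant] = []
    truth_rows: list[dict] = []

    def draw_depth() -> int:
        return max(int(rng.poisson(bulk.mean_depth)), 1)

    def emit(line_id, chrom, pos, ref, alt, depth, alt_count, origin, mclass, zyg):
        records.append(
            CandidateVariant(line_id, chrom, pos, ref, alt, depth, alt_count)
        )
        truth_rows.append(
            dict(
                line_id=line_id, chromosome=chrom, position=pos,
                ref_allele=ref, alt_allele=alt, origin=origin,
                mutation_class=mclass, zygosity=zyg,
            )
        )

    # shared background variants, identical across all lines, placed away
    # from every induced mutation so record keys stay unique per line
    bg_sites: list[tuple[str, int, str, str]] = []
    used_bg: set[tuple[str, int]] = {
        (m.chromosome, m.position) for muts in lines for m in muts
    }
    while len(bg_sites) < bulk.n_background_variants:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, len(reference.sequences[chrom]) + 1))
        if (chrom, pos) in used_bg:
            continue
        used_bg.add((chrom, pos))
        ref = reference.sequences[chrom][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        bg_sites.append((chrom, pos, ref, alt))

    for muts in lines:
        line_id = muts[0].line_id if muts else None
        occupied = {(m.chromosome, m.position) for m in muts}
        occupied |= used_bg
        for m in muts:
            if m.mutation_class == "SV":
                continue
            state = m.genotype_by_generation.get(observed_generation)
            if state is None:
                raise ValueError(
                    f"genotype at M{observed_generation} not resolved; run transmit_selfing"
                )
            if state == "lost":
                continue
            f = _bulk_allele_frequency(rng, state, bulk.n_seedlings)
            depth = draw_depth()
            p = f * (1 - bulk.error_rate) + (1 - f) * bulk.error_rate
            alt_count = int(rng.binomial(depth, p))
            if alt_count == 0:
                continue  # below the detection floor; never called
            emit(
                m.line_id, m.chromosome, m.position, m.ref_allele, m.alt_allele,
                depth, alt_count, "true", m.mutation_class, state,
            )
        if line_id is None:
            continue
        for chrom, pos, ref, alt in bg_sites:
            depth = draw_depth()
            p = 1.0 - bulk.error_rate
            alt_count = max(int(rng.binomial(depth, p)), 1)
            emit(line_id, chrom, pos, ref, alt, depth, alt_count,
                 "background", "SBS", "homozygous")
        n_fp = 0
        while n_fp < bulk.n_false_positives:
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(1, len(reference.sequences[chrom]) + 1))
            if (chrom, pos) in occupied:
                continue
            occupied.add((chrom, pos))
            ref = reference.sequences[chrom][pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            depth = max(draw_depth(), 6)
            alt_count = int(rng.binomial(depth, rng.uniform(0.05, 0.30)))
            ceiling = int(np.ceil(0.40 * depth)) - 1  # artifacts sit below 40% VAF
            alt_count = min(max(alt_count, 1), max(ceiling, 1))
            emit(line_id, chrom, pos, ref, alt, depth, alt_count,
                 "artifact", "SBS", "")
            n_fp += 1

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "line_id", "chromosome", "position", "ref_allele", "alt_allele",
            "origin", "mutation_class", "zygosity",
        ],
    )
    return records, truth


# ---------------------------------------------------------------------------
# one-call study simulation


@dataclass
class SimulatedGroup:
    """Everything the pipeline needs for one radiation group."""

    spectrum: RadiationSpectrum
    reference: Reference
    truth_lines: list[list[TruthMutation]]
    records: list[CandidateVariant]
    truth_table: pd.DataFrame
    callable_lengths: dict[str, float]

    @property
    def line_ids(self) -> list[str]:
        return sorted({m.line_id for muts in self.truth_lines for m in muts})


def simulate_group(
    spectrum: RadiationSpectrum,
    reference: Reference,
    n_lines: int = 7,
    n_generations: int = 5,
    bulk: BulkSamplingSpec | None = None,
    seed: int | np.random.Generator = 0,
    callable_fraction_range: tuple[float, float] = (0.92, 0.96),
) -> SimulatedGroup:
    """Simulate one radiation group end to end at the study's design points.

    Seven lines, selfing M1->M5, bulk M6 sequencing at ~30x.  Per-line
    callable lengths are drawn as a fraction of the genome (most of the
    genome reaches >= 5x at ~30x mean depth).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bulk = bulk or BulkSamplingSpec()
    truth = induce_mutations(reference, spectrum, n_lines, rng)
    truth = transmit_selfing(truth, n_generations, rng)
    records, truth_table = simulate_bulk_reads(truth, n_generations, bulk, reference, rng)
    genome_len = sum(reference.chromosome_lengths.values())
    lo, hi = callable_fraction_range
    callable_lengths = {
        (muts[0].line_id if muts else f"{spectrum.label}_{i + 1:03d}"):
            float(rng.uniform(lo, hi)) * genome_len
        for i, muts in enumerate(truth)
    }
    return SimulatedGroup(
        spectrum=spectrum, reference=reference, truth_lines=truth,
        records=records, truth_table=truth_table,
        callable_lengths=callable_lengths,
    )
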