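"""Mutation rates, Mendelian selfing model, and per-generation back-estimation.

A mutation induced in a heterozygous M1 plant segregates under
self-pollination: each generation an unfixed (heterozygous) mutation is
lost with probability 1/4, stays heterozygous with probability 1/2 and
fixes homozygous with probability 1/4.  Lost and homozygous are
absorbing, so at generation k (counting from induction at generation
m) the carrier probabilities are

    p_het(k) = (1/2)^(k-m),     p_hom(k) = p_lost(k) = (1 - p_het(k)) / 2.

Because sequencing a bulk of selfed offspring reports the zygosity of
their common parent, the homozygous fraction among *detectable*
mutations at M5 is p_hom / (p_hom + p_het) = 15/17 ~ 88.2%.  Field
reports sometimes use a fixed expected homozygosity of 85% instead;
both conventions are supported (see
:func:`estimate_generation_totals`).

The per-base-pair mutation rate divides the mean mutation count per
line by the mean callable genome length (bases at >= 5x depth), and
mutagenic effectiveness divides that rate by the absorbed dose in Gy.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CallableProfile",
    "SelfingModel",
    "GenerationEstimate",
    "RateReport",
    "mutation_rate",
    "genotype_distribution",
    "expected_homozygous_fraction",
    "estimate_generation_totals",
    "mutagenic_effectiveness",
]


@dataclass(frozen=True)
class CallableProfile:
    """Per-line callable genome: bases covered at >= min_depth reads."""

    line_id: str
    callable_length: float
    min_depth: int = 5

    def __post_init__(self) -> None:
        if self.callable_length <= 0:
            raise ValueError("callable length must be positive")


@dataclass(frozen=True)
class SelfingModel:
    """Generation-indexed genotype probabilities for a selfed mutation.

    ``induced_generation`` is the M-index at which the mutation arose
    heterozygous (default M1).
    """

    induced_generation: int = 1

    def __post_init__(self) -> None:
        if self.induced_generation < 1:
            raise ValueError("induced generation must be >= 1 (M1 is the first)")


def genotype_distribution(model: SelfingModel, k: int) -> tuple[float, float, float]:
    """(p_lost, p_het, p_hom) at generation M_k, closed form."""
    d = k - model.induced_generation
    if d < 0:
        raise ValueError(
            f"generation M{k} precedes induction at M{model.induced_generation}"
        )
    p_het = 0.5**d
    p_hom = p_lost = (1.0 - p_het) / 2.0
    return (p_lost, p_het, p_hom)


def expected_homozygous_fraction(model: SelfingModel, k: int) -> float:
    """Expected homozygous fraction among detectable (carrier) mutations at M_k."""
    if k <= model.induced_generation:
        raise ValueError("homozygosity is only defined after at least one selfing")
    p_lost, p_het, p_hom = genotype_distribution(model, k)
    return p_hom / (p_hom + p_het)


@dataclass(frozen=True)
class GenerationEstimate:
    """Back-estimated mutation load at a target generation."""

    target_generation: int
    induced_total: float  # estimated mutations present in the M1 plant
    expected_detected: float  # carriers (het+hom) expected at the target generation

    def rate(self, callable_length: float) -> float:
        """Per-bp mutation rate implied at the target generation."""
        if callable_length <= 0:
            raise ValueError("callable length must be positive")
        return self.expected_detected / callable_length


def estimate_generation_totals(
    observed_homozygous: float,
    observed_generation: int,
    target_generation: int,
    model: SelfingModel | None = None,
    expected_hom_fraction_override: float | None = None,
) -> GenerationEstimate:
    """Back-estimate the mutation load of an earlier generation.

    From the observed homozygous count at ``observed_generation``, the
    number of mutations induced at M1 is N = observed_homozygous /
    p_hom(k_obs); the expected *detectable* count at the target
    generation is N * (1 - p_lost(k_t)).  With
    ``expected_hom_fraction_override`` (e.g. a fixed 0.85), p_hom(k_obs)
    is replaced by override * (1 - p_lost(k_obs)) so that the override
    plays the role of the homozygous fraction among carriers.
    """
    model = model or SelfingModel()
    if observed_homozygous < 0:
        raise ValueError("observed homozygous count cannot be negative")
    if target_generation > observed_generation:
        raise ValueError("target generation must not be later than the observed one")

    p_lost_obs, _, p_hom_obs = genotype_distribution(model, observed_generation)
    if expected_hom_fraction_override is not None:
        p_hom_obs = expected_hom_fraction_override * (1.0 - p_lost_obs)
    if p_hom_obs == 0:
        raise ValueError("no homozygous mutations are expected at the observed generation")

    induced_total = observed_homozygous / p_hom_obs
    p_lost_t, _, _ = genotype_distribution(model, target_generation)
    return GenerationEstimate(
        target_generation=target_generation,
        induced_total=induced_total,
        expected_detected=induced_total * (1.0 - p_lost_t),
    )


def mutation_rate(mean_count: float, mean_callable: float) -> float:
    """Per-bp mutation rate: mean mutations per line / mean callable length."""
    if mean_callable <= 0:
        raise ValueError("mean callable length must be positive")
    return mean_count / mean_callable


def mutagenic_effectiveness(rate: float, dose: float) -> float:
    """Mutation rate per unit absorbed dose (per bp per Gy)."""
    if dose <= 0:
        raise ValueError("dose must be positive")
    return rate / dose


@dataclass(frozen=True)
class RateReport:
    """Rates and effectiveness of one radiation group.

    ``rate`` is per bp; formatting helpers report it in the
    conventional 1e-8/bp (rates) and 1e-9/bp/Gy (effectiveness) units,
    rounded to one decimal.
    """

    label: str
    mean_mutations: float
    mean_callable: float
    dose: float
    generation_estimates: tuple[GenerationEstimate, ...] = ()

    @property
    def rate(self) -> float:
        return mutation_rate(self.mean_mutations, self.mean_callable)

    @property
    def effectiveness(self) -> float:
        return mutagenic_effectiveness(self.rate, self.dose)

    @property
    def rate_1e8(self) -> float:
        return round(self.rate * 1e8, 1)

    @property
    def effectiveness_1e9(self) -> float:
        return round(self.effectiveness * 1e9, 1)
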