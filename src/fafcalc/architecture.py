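"""Disease genetic architecture and the maximum credible population allele frequency.

A variant can only cause a penetrant Mendelian disease if it is rarer in the
general population than the disease itself, discounted for how much of the
disease any single allele can explain and inflated for incomplete penetrance.
This module turns those architecture parameters (prevalence, inheritance mode,
allelic/genetic heterogeneity, penetrance) into a per-chromosome allele
frequency ceiling — the *maximum credible population AF* — and supports the
inverse exploration: given an observed frequency, what is the largest
penetrance under which a causal role remains credible?

Model
-----
Dominant:  max AF = prevalence × ½ × max_allelic_contribution / penetrance

The ½ converts a per-individual prevalence to a per-chromosome frequency
(heterozygous carriers; homozygotes are negligible at these frequencies).

Recessive: max AF = sqrt(prevalence × max_genetic_contribution / penetrance)
                    × max_allelic_contribution

Under Hardy–Weinberg random mating with free compound heterozygosity among a
gene's pathogenic alleles, the summed pathogenic allele frequency for the gene
is the square root of the attributable prevalence; a single variant then takes
at most ``max_allelic_contribution`` of that pool.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Union


class ParameterDomainError(ValueError):
    """An architecture parameter is outside its valid domain."""


class Inheritance(str, enum.Enum):
    DOMINANT = "dominant"
    RECESSIVE = "recessive"


def parse_fraction(value: Union[str, float, int]) -> float:
    """Parse a prevalence-style value: a decimal (``0.002``) or a fraction
    string (``"1/500"``).

    >>> parse_fraction("1/500")
    0.002
    """
    if isinstance(value, (int, float)):
        return float(value)
    text = value.strip()
    if "/" in text:
        return float(Fraction(text))
    return float(text)


def _check_unit_interval(name: str, value: float, *, closed_top: bool = True) -> None:
    top_ok = value <= 1 if closed_top else value < 1
    if not (value > 0 and top_ok and math.isfinite(value)):
        bound = "(0,1]" if closed_top else "(0,1)"
        raise ParameterDomainError(f"{name} must be in {bound}, got {value!r}")


@dataclass(frozen=True)
class DiseaseArchitecture:
    """Genetic-architecture parameters defining a disease's frequency ceiling.

    Parameters
    ----------
    prevalence
        Fraction of the population affected, in (0, 1). Accepts "1/500" via
        :func:`parse_fraction` upstream.
    inheritance
        ``dominant`` or ``recessive``.
    max_allelic_contribution
        Maximum proportion of cases (dominant) or of the gene's pathogenic
        alleles (recessive) attributable to a single variant, in (0, 1].
    penetrance
        Probability that a genotype-positive individual is affected, in (0, 1].
    max_genetic_contribution
        Proportion of all cases attributable to the gene under evaluation;
        required for recessive inheritance, fixed at 1 for dominant.
    """

    prevalence: float
    inheritance: Inheritance
    max_allelic_contribution: float
    penetrance: float = 1.0
    max_genetic_contribution: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "inheritance", Inheritance(self.inheritance))
        _check_unit_interval("prevalence", self.prevalence, closed_top=False)
        _check_unit_interval("max_allelic_contribution", self.max_allelic_contribution)
        _check_unit_interval("penetrance", self.penetrance)
        if self.inheritance is Inheritance.RECESSIVE:
            if self.max_genetic_contribution is None:
                raise ParameterDomainError(
                    "max_genetic_contribution is required for recessive inheritance"
                )
            _check_unit_interval("max_genetic_contribution", self.max_genetic_contribution)
        elif self.max_genetic_contribution is None:
            object.__setattr__(self, "max_genetic_contribution", 1.0)


@dataclass(frozen=True)
class DiseaseThreshold:
    """A maximum credible population AF together with its provenance."""

    max_credible_af: float
    architecture: DiseaseArchitecture

    def __post_init__(self) -> None:
        if not (0 < self.max_credible_af <= 1):
            raise ParameterDomainError(
                f"max_credible_af must be in (0,1], got {self.max_credible_af!r}"
            )


def max_credible_af(arch: DiseaseArchitecture) -> DiseaseThreshold:
    """Maximum credible population allele frequency for a pathogenic allele.

    Pure function of the architecture; capped at 1.0 so that extreme
    exploratory inputs remain usable. Computation is in double precision with
    no rounding (round only for display).

    >>> arch = DiseaseArchitecture(1 / 500, "dominant", 0.02, penetrance=0.5)
    >>> max_credible_af(arch).max_credible_af
    4e-05
    """
    if arch.inheritance is Inheritance.DOMINANT:
        af = arch.prevalence * 0.5 * arch.max_allelic_contribution / arch.penetrance
    else:
        gene_af = math.sqrt(
            arch.prevalence * arch.max_genetic_contribution / arch.penetrance
        )
        af = gene_af * arch.max_allelic_contribution
    return DiseaseThreshold(min(af, 1.0), arch)


def implied_min_penetrance(
    prevalence: float, max_allelic_contribution: float, observed_af: float
) -> float:
    """Largest penetrance compatible with causality at an observed frequency.

    Inverts the dominant model: a variant observed at ``observed_af`` can only
    cause the disease if its penetrance is at most
    ``prevalence × ½ × max_allelic_contribution / observed_af`` (capped at 1).
    Dominant model only.
    """
    for name, value in [
        ("prevalence", prevalence),
        ("max_allelic_contribution", max_allelic_contribution),
    ]:
        _check_unit_interval(name, value)
    if observed_af < 0 or observed_af > 1:
        raise ParameterDomainError(f"observed_af must be in [0,1], got {observed_af!r}")
    if observed_af == 0:
        raise ParameterDomainError(
            "observed_af is 0: any penetrance is compatible (undefined)"
        )
    return min(prevalence * 0.5 * max_allelic_contribution / observed_af, 1.0)
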