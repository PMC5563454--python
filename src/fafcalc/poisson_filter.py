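"""Poisson bounds linking population allele frequencies to sample allele counts.

Two directions:

* ``max_tolerated_ac`` — given a ceiling on the true population AF, the largest
  allele count one would expect to see in a reference sample of AN chromosomes
  at a one-sided confidence level (default 95%): the Poisson quantile at mean
  AF × AN. A variant observed more often than this is too common for the
  frequency ceiling to hold.

* ``filtering_af`` — the inverse, computed per variant: the highest AF ceiling
  (on a 1e-6 grid, "units of millionths") at which the observed count would
  already exceed the tolerated count. A variant is then filtered for a disease
  whenever its filtering AF is at or above the disease's maximum credible AF.

``popmax_filtering_af`` aggregates across reference populations by taking the
highest per-population filtering AF, so a variant common in any one major
continental population is filtered regardless of its frequency elsewhere.

The inversion is done in closed form (inverse regularised upper incomplete
gamma) and snapped to the grid; results are bit-identical to the defining
millionth-by-millionth scan, which the test suite checks exhaustively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

from scipy.special import gammainccinv
from scipy.stats import poisson

#: Canonical major continental populations, in tie-break order.
CANONICAL_POPULATIONS: Tuple[str, ...] = ("AFR", "AMR", "EAS", "NFE", "SAS")

DEFAULT_CONFIDENCE = 0.95
DEFAULT_GRANULARITY = 1e-6


class ParameterDomainError(ValueError):
    pass


class CountConsistencyError(ValueError):
    """Allele count exceeds allele number."""


@dataclass(frozen=True)
class PopulationCounts:
    """Observed allele count/number for one population at one site.

    ``ac`` alternate alleles observed out of ``an`` genotyped chromosomes.
    Homozygote counts play no role in the filtering computation.
    """

    population: str
    ac: int
    an: int

    def __post_init__(self) -> None:
        if self.ac < 0 or self.an < 0:
            raise ParameterDomainError(
                f"negative counts for {self.population}: ac={self.ac}, an={self.an}"
            )
        if self.ac > self.an:
            raise CountConsistencyError(
                f"ac {self.ac} > an {self.an} for population {self.population}"
            )


@dataclass(frozen=True)
class FilteringResult:
    """Per-population filtering AFs and their popmax aggregate."""

    per_population: Dict[str, float]
    popmax_af: float
    popmax_population: Optional[str]
    confidence: float = DEFAULT_CONFIDENCE


def _validate_confidence(confidence: float) -> None:
    if not (0 < confidence < 1):
        raise ParameterDomainError(f"confidence must be in (0,1), got {confidence!r}")


def max_tolerated_ac(
    max_credible_af: float, an: int, confidence: float = DEFAULT_CONFIDENCE
) -> int:
    """Largest allele count consistent with a true AF ≤ ``max_credible_af``.

    Returns the smallest integer k whose Poisson CDF at mean
    ``max_credible_af × an`` is at least ``confidence`` — the AC at the upper
    bound of the one-tailed confidence interval.

    >>> max_tolerated_ac(1e-4, 100_000)
    15
    """
    _validate_confidence(confidence)
    if not (0 <= max_credible_af <= 1):
        raise ParameterDomainError(f"max_credible_af out of [0,1]: {max_credible_af!r}")
    if an < 0:
        raise ParameterDomainError(f"an must be non-negative, got {an!r}")
    lam = max_credible_af * an
    if lam == 0:
        return 0
    return int(poisson.ppf(confidence, lam))


def filtering_af(
    ac: int,
    an: int,
    confidence: float = DEFAULT_CONFIDENCE,
    granularity: float = DEFAULT_GRANULARITY,
) -> float:
    """Per-variant filtering allele frequency.

    The largest multiple of ``granularity``, f, such that
    ``max_tolerated_ac(f, an, confidence) < ac`` — i.e. the highest disease
    threshold at which this variant's observed count is already too common.
    Singletons and unobserved variants (ac ≤ 1) get 0: one observation carries
    too little frequency information to filter on.

    Closed-form inversion: max_tolerated_ac(f) ≤ ac−1 iff the Poisson CDF at
    ac−1 with mean f·an is ≥ confidence, and CDF(ac−1; λ) = Q(ac, λ) (the
    regularised upper incomplete gamma), decreasing in λ. The boundary λ* is
    ``gammainccinv(ac, confidence)``; f is λ*/an floored to the grid, with a
    one-step check so the result matches the grid-scan definition exactly.
    """
    _validate_confidence(confidence)
    if ac < 0 or an < 0:
        raise ParameterDomainError(f"negative input: ac={ac}, an={an}")
    if ac > an:
        raise CountConsistencyError(f"ac {ac} > an {an}")
    if not (0 < granularity < 1):
        raise ParameterDomainError(f"granularity must be in (0,1), got {granularity!r}")
    if ac <= 1:
        return 0.0
    lam_star = float(gammainccinv(ac, confidence))
    steps = int(math.floor(lam_star / an / granularity))
    # Guard the floating-point boundary: the returned grid point must satisfy
    # the strict definition, and the next one must fail it.
    while steps > 0 and max_tolerated_ac(steps * granularity, an, confidence) >= ac:
        steps -= 1
    while max_tolerated_ac((steps + 1) * granularity, an, confidence) < ac:
        steps += 1
    return steps * granularity


def popmax_filtering_af(
    counts: Iterable[PopulationCounts],
    confidence: float = DEFAULT_CONFIDENCE,
    granularity: float = DEFAULT_GRANULARITY,
    populations: Sequence[str] = CANONICAL_POPULATIONS,
    min_an: int = 0,
) -> FilteringResult:
    """Highest per-population filtering AF across major continental populations.

    Populations with an = 0 (or below ``min_an``) are excluded rather than
    treated as frequency 0; labels outside ``populations`` are ignored.
    Ties broken by the fixed ordering of ``populations``.
    """
    counts = list(counts)
    if not counts:
        raise ParameterDomainError("at least one population required")
    order = {pop: i for i, pop in enumerate(populations)}
    per_population: Dict[str, float] = {}
    for pc in sorted(
        (c for c in counts if c.population in order), key=lambda c: order[c.population]
    ):
        if pc.an == 0 or pc.an < min_an:
            continue
        per_population[pc.population] = filtering_af(
            pc.ac, pc.an, confidence, granularity
        )
    if not per_population:
        return FilteringResult({}, 0.0, None, confidence)
    popmax_pop = max(
        per_population, key=lambda p: (per_population[p], -order[p])
    )
    return FilteringResult(
        per_population, per_population[popmax_pop], popmax_pop, confidence
    )
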