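"""Cohort statistics feeding the architecture model.

Case-series carrier proportions with binomial confidence intervals (Wald by
default, matching how large published case series report their commonest
variant), from which the maximum allelic contribution is estimated as the
upper bound of the most frequent variant's proportion; case/control burden
odds ratios stratified by reference allele-frequency bin; and a simple
penetrance estimate from case and population allele frequencies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

from scipy.stats import beta, norm

DEFAULT_AF_BREAKPOINTS: Tuple[float, ...] = (4e-5, 1e-4, 5e-4, 1e-3)


class InputError(ValueError):
    pass


class UndefinedOddsRatioError(ZeroDivisionError):
    """Both denominator cells prevent a finite, defined odds ratio."""


@dataclass(frozen=True)
class CaseSeries:
    """Carrier count of one variant in a disease cohort.

    The denominator is recorded as given in the source (alleles for recessive
    series, individuals for dominant ones); no conversion is applied.
    """

    variant_label: str
    carriers: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise InputError(f"total must be positive, got {self.total}")
        if not (0 <= self.carriers <= self.total):
            raise InputError(
                f"carriers must be in [0, total], got {self.carriers}/{self.total}"
            )

    @property
    def proportion(self) -> float:
        return self.carriers / self.total


@dataclass(frozen=True)
class ContingencyTable:
    """Case/control carrier counts for a burden comparison."""

    cases_with: int
    cases_without: int
    controls_with: int
    controls_without: int

    def __post_init__(self) -> None:
        cells = (self.cases_with, self.cases_without, self.controls_with, self.controls_without)
        if any(c < 0 for c in cells):
            raise InputError(f"negative cell in contingency table: {cells}")


@dataclass(frozen=True)
class AfBinning:
    """Right-closed, left-open allele-frequency bins plus an overflow bin.

    ``breakpoints`` (b1 < b2 < ... < bk) define bins (0, b1], (b1, b2], ...,
    (bk, 1]; a variant absent from the reference (af 0) falls in the lowest
    bin.
    """

    breakpoints: Tuple[float, ...] = DEFAULT_AF_BREAKPOINTS

    def __post_init__(self) -> None:
        bps = tuple(self.breakpoints)
        object.__setattr__(self, "breakpoints", bps)
        if not bps or any(not (0 < b < 1) for b in bps) or list(bps) != sorted(set(bps)):
            raise InputError(
                f"breakpoints must be strictly increasing and in (0,1): {bps}"
            )

    def labels(self) -> List[str]:
        edges = (0.0,) + self.breakpoints
        labs = [f"({lo:g}, {hi:g}]" for lo, hi in zip(edges, edges[1:])]
        labs.append(f"(> {self.breakpoints[-1]:g})")
        return labs

    def assign(self, af: float) -> str:
        if not (0 <= af <= 1):
            raise InputError(f"af out of [0,1]: {af}")
        for label, hi in zip(self.labels(), self.breakpoints):
            if af <= hi:
                return label
        return self.labels()[-1]


def proportion_ci(
    carriers: int,
    total: int,
    confidence: float = 0.95,
    method: str = "wald",
) -> Tuple[float, float]:
    """Binomial confidence interval for a carrier proportion.

    Wald (normal approximation, the default): p ± z·sqrt(p(1−p)/total),
    clamped to [0,1]. ``method="clopper-pearson"`` gives the exact interval
    for users who prefer it.

    >>> lo, hi = proportion_ci(104, 6179)
    >>> round(lo * 100, 1), round(hi * 100, 1)
    (1.4, 2.0)
    """
    if total <= 0:
        raise InputError(f"total must be positive, got {total}")
    if not (0 <= carriers <= total):
        raise InputError(f"carriers out of range: {carriers}/{total}")
    p = carriers / total
    if method == "wald":
        z = norm.ppf(0.5 + confidence / 2)
        half = z * math.sqrt(p * (1 - p) / total)
        return max(p - half, 0.0), min(p + half, 1.0)
    if method == "clopper-pearson":
        alpha = 1 - confidence
        lo = 0.0 if carriers == 0 else float(beta.ppf(alpha / 2, carriers, total - carriers + 1))
        hi = 1.0 if carriers == total else float(beta.ppf(1 - alpha / 2, carriers + 1, total - carriers))
        return lo, hi
    raise InputError(f"unknown CI method: {method!r}")


def _round_up_sig(value: float, sig_figures: int) -> float:
    if value <= 0:
        return value
    exponent = math.floor(math.log10(value))
    scale = 10.0 ** (exponent - sig_figures + 1)
    return math.ceil(value / scale - 1e-12) * scale


def max_allelic_contribution(
    series: Iterable[CaseSeries],
    confidence: float = 0.95,
    round_up_to_sig_figures: int | None = None,
    method: str = "wald",
) -> float:
    """Estimate the maximum allelic contribution from case series.

    Takes the upper confidence bound of the proportion of the most frequent
    variant in the collection; optionally rounded *up* to a number of
    significant figures (as done when extrapolating an estimate from one
    disorder to a less-characterised one, e.g. 9.2% → 0.1).
    """
    series = list(series)
    if not series:
        raise InputError("at least one case series required")
    top = max(series, key=lambda s: s.proportion)
    upper = proportion_ci(top.carriers, top.total, confidence, method)[1]
    if round_up_to_sig_figures is not None:
        upper = min(_round_up_sig(upper, round_up_to_sig_figures), 1.0)
    return upper


def burden_odds_ratio(table: ContingencyTable) -> float:
    """Case/control odds ratio for carrying a variant.

    OR = (cases with / cases without) / (controls with / controls without).
    Returns ``inf`` when no control carries a variant but some case does.
    """
    if table.cases_without == 0 or table.controls_without == 0:
        raise UndefinedOddsRatioError(
            "odds ratio undefined: a 'without' cell is zero"
        )
    if table.controls_with == 0:
        if table.cases_with == 0:
            return 0.0
        warnings.warn("no control carriers: odds ratio is infinite", stacklevel=2)
        return math.inf
    return (table.cases_with / table.cases_without) / (
        table.controls_with / table.controls_without
    )


def odds_ratio_ci(
    table: ContingencyTable, confidence: float = 0.95
) -> Tuple[float, float, float, bool]:
    """Odds ratio with log-normal CI.

    Haldane–Anscombe 0.5 correction is applied (and flagged in the returned
    boolean) only when exactly one cell is zero; with the correction the CI is
    computed on the corrected table while the point estimate stays exact where
    defined.
    """
    cells = [table.cases_with, table.cases_without, table.controls_with, table.controls_without]
    n_zero = sum(c == 0 for c in cells)
    corrected = n_zero == 1
    a, b, c, d = ((x + 0.5) for x in cells) if corrected else cells
    if min(b, d) == 0:
        raise UndefinedOddsRatioError("odds ratio undefined: a 'without' cell is zero")
    if c == 0:
        raise UndefinedOddsRatioError("CI undefined: no control carriers")
    log_or = math.log((a / b) / (c / d))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(0.5 + confidence / 2)
    point = burden_odds_ratio(table) if not corrected else math.exp(log_or)
    return point, math.exp(log_or - z * se), math.exp(log_or + z * se), corrected


def bin_by_af(
    variants: Iterable[Tuple[str, float]], binning: AfBinning | None = None
) -> Dict[str, List[str]]:
    """Partition variant ids into allele-frequency bins.

    Every id lands in exactly one bin; frequencies above the last breakpoint
    go to the overflow bin and af = 0 (absent from the reference) to the
    lowest.
    """
    binning = binning or AfBinning()
    out: Dict[str, List[str]] = {label: [] for label in binning.labels()}
    for variant_id, af in variants:
        out[binning.assign(af)].append(variant_id)
    return out


def estimate_penetrance(
    prevalence: float, case_af: float, population_af: float
) -> Tuple[float, bool]:
    """Penetrance estimate from case and population allele frequencies.

    penetrance ≈ prevalence × case_af / population_af, capped at 1. A capped
    estimate (flagged in the returned boolean) signals an inconsistent
    architecture — the variant is rarer in the population than its case
    enrichment and the assumed prevalence allow — which is itself informative.
    """
    if prevalence <= 0 or case_af <= 0:
        raise InputError("prevalence and case_af must be positive")
    if population_af <= 0:
        raise InputError("population_af must be positive (0 is undefined)")
    raw = prevalence * case_af / population_af
    return min(raw, 1.0), raw > 1.0
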