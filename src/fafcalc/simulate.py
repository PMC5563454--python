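"""Synthetic multi-population reference panels for end-to-end testing.

Emulates, at desk scale, the structure of a large exome-aggregation reference
sample: a site-frequency spectrum heavy on rare variants (discretised 1/x
density), per-population divergence (logit-normal perturbation of the global
frequency), binomial sampling of allele counts given each population's allele
number, and a spiked point mass of "pathogenic-like" sites absent from the
panel (true AF 0). Also provides a small filtering-efficiency experiment:
held-out carrier samples drawn from the same spectrum are filtered against
the panel's popmax filtering AFs across a ladder of disease thresholds.

Everything is driven by a single integer seed; a fixed seed gives
byte-identical VCF output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .poisson_filter import (
    CANONICAL_POPULATIONS,
    DEFAULT_CONFIDENCE,
    PopulationCounts,
)
from .vcf_io import VariantRecord, annotate_filtering_af, write_vcf


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic reference panel.

    Defaults are desk scale: five populations of 20,000 chromosomes each,
    1,000 sites, a 1/x frequency spectrum truncated to [1e-6, 0.5], moderate
    population divergence (logit-normal sd 0.5), and a 2% point mass of
    pathogenic-like sites with true AF 0.
    """

    n_populations: int = 5
    an_per_population: Tuple[int, ...] = ()
    n_sites: int = 1000
    af_min: float = 1e-6
    af_max: float = 0.5
    divergence: float = 0.5
    pathogenic_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.an_per_population:
            object.__setattr__(
                self, "an_per_population", (20_000,) * self.n_populations
            )
        if len(self.an_per_population) != self.n_populations:
            raise ConfigError("an_per_population length must equal n_populations")
        if self.n_populations < 1 or self.n_sites < 1:
            raise ConfigError("n_populations and n_sites must be positive")
        if all(an == 0 for an in self.an_per_population):
            raise ConfigError("at least one population needs AN > 0")
        if not (0 < self.af_min < self.af_max <= 1):
            raise ConfigError("need 0 < af_min < af_max <= 1")
        if not (0 <= self.pathogenic_fraction < 1):
            raise ConfigError("pathogenic_fraction must be in [0,1)")

    @property
    def populations(self) -> Tuple[str, ...]:
        base = CANONICAL_POPULATIONS
        if self.n_populations <= len(base):
            return base[: self.n_populations]
        extra = tuple(f"POP{i}" for i in range(len(base), self.n_populations))
        return base + extra


def _draw_global_afs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Global AF per site: inverse-CDF sample of a 1/x density on [af_min, af_max],
    with a pathogenic-like point mass at AF 0."""
    u = rng.random(config.n_sites)
    afs = config.af_min * (config.af_max / config.af_min) ** u
    pathogenic = rng.random(config.n_sites) < config.pathogenic_fraction
    afs[pathogenic] = 0.0
    return afs


def _perturb_per_population(
    afs: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Logit-normal divergence: per-population AF matrix (sites × populations)."""
    logit = np.log(afs / (1 - afs), out=np.full_like(afs, -np.inf), where=afs > 0)
    shift = rng.normal(0.0, config.divergence, size=(afs.size, config.n_populations))
    pert = logit[:, None] + shift
    with np.errstate(over="ignore"):
        pop_afs = 1.0 / (1.0 + np.exp(-pert))
    pop_afs[afs == 0] = 0.0
    return pop_afs


def simulate_reference_panel(
    config: SimulationConfig,
) -> Tuple[List[VariantRecord], pd.DataFrame]:
    """Draw a synthetic reference panel.

    Returns decomposed variant records (per-population AC ~ Binomial(AN,
    population AF)) and a truth table with the true global and per-population
    AFs per site. Reproducible under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    afs = _draw_global_afs(config, rng)
    pop_afs = _perturb_per_population(afs, config, rng)
    acs = rng.binomial(
        np.asarray(config.an_per_population)[None, :], pop_afs
    )
    pops = config.populations
    records = []
    truth_rows = []
    for i in range(config.n_sites):
        pos = i + 1
        counts = tuple(
            PopulationCounts(pop, int(acs[i, j]), int(config.an_per_population[j]))
            for j, pop in enumerate(pops)
            if config.an_per_population[j] > 0
        )
        records.append(VariantRecord("1", pos, "A", "T", counts))
        row = {"variant_id": f"1-{pos}-A-T", "true_af": afs[i],
               "pathogenic_like": bool(afs[i] == 0.0)}
        for j, pop in enumerate(pops):
            row[f"true_af_{pop}"] = pop_afs[i, j]
        truth_rows.append(row)
    return records, pd.DataFrame(truth_rows)


def write_panel(
    config: SimulationConfig,
    vcf_path: Union[str, Path],
    truth_path: Union[str, Path, None] = None,
    confidence: float = DEFAULT_CONFIDENCE,
) -> Tuple[List[VariantRecord], pd.DataFrame]:
    """Simulate, annotate with filtering AFs, and write VCF (+ optional truth TSV)."""
    records, truth = simulate_reference_panel(config)
    annotated = annotate_filtering_af(
        records, confidence=confidence, populations=config.populations
    )
    write_vcf(annotated, vcf_path, confidence=confidence, populations=config.populations)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False, float_format="%.8g")
    return annotated, truth


def filtering_efficiency_experiment(
    config: SimulationConfig,
    cutoffs: Sequence[float],
    n_samples: int = 100,
    confidence: float = DEFAULT_CONFIDENCE,
) -> pd.DataFrame:
    """Mean number of candidate variants retained per simulated sample, by cutoff.

    Held-out diploid individuals are drawn from the same per-population
    frequency spectrum as the panel; each individual's carried variants are
    filtered against the panel's popmax filtering AFs at each maximum credible
    AF cutoff. Tighter cutoffs can only retain fewer variants. Pathogenic-like
    sites (absent from the panel) are carried by forcing one heterozygous
    genotype, so their retention measures the filter's false-negative
    behaviour on variants with no frequency evidence.
    """
    cutoffs = list(cutoffs)
    if not cutoffs or any(c <= 0 for c in cutoffs) or cutoffs != sorted(cutoffs):
        raise ConfigError("cutoffs must be positive and sorted ascending")
    records, truth = simulate_reference_panel(config)
    annotated = annotate_filtering_af(
        records, confidence=confidence, populations=config.populations
    )
    fafs = np.array([r.filtering.popmax_af for r in annotated])
    pop_af_cols = [f"true_af_{pop}" for pop in config.populations]
    pop_afs = truth[pop_af_cols].to_numpy()
    pathogenic = truth["pathogenic_like"].to_numpy()

    rng = np.random.default_rng(config.seed + 1)
    home_pops = rng.integers(0, config.n_populations, size=n_samples)
    rows = []
    for s in range(n_samples):
        p = pop_afs[:, home_pops[s]]
        carried = rng.random(p.size) > (1 - p) ** 2  # ≥1 alt allele, diploid
        carried |= pathogenic  # spiked variants present in every sample
        for cutoff in cutoffs:
            retained = carried & (fafs < cutoff)
            rows.append({
                "sample": s,
                "cutoff": cutoff,
                "carried": int(carried.sum()),
                "retained": int(retained.sum()),
                "pathogenic_retained": int((carried & pathogenic & (fafs < cutoff)).sum()),
                "pathogenic_carried": int(pathogenic.sum()),
            })
    per_sample = pd.DataFrame(rows)
    summary = (
        per_sample.groupby("cutoff", sort=True)
        .agg(
            mean_retained=("retained", "mean"),
            mean_carried=("carried", "mean"),
            pathogenic_retention=("pathogenic_retained", "sum"),
            pathogenic_total=("pathogenic_carried", "sum"),
        )
        .reset_index()
    )
    summary["pathogenic_retention"] = (
        summary["pathogenic_retention"] / summary["pathogenic_total"]
    )
    return summary.drop(columns="pathogenic_total")
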