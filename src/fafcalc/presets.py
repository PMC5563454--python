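"""Packaged exemplar disease architectures.

Ships a small versioned YAML resource of genetic-architecture parameter sets
for exemplar inherited conditions (mostly cardiac), each with the maximum
tolerated allele count expected at the reference sample size of 121,412
chromosomes, so the end-to-end pipeline can be regression-tested without any
external download.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Dict, Optional, Tuple

import yaml

from .architecture import DiseaseArchitecture, parse_fraction
from .cohort import CaseSeries


class UnknownDiseaseError(KeyError):
    pass


@dataclass(frozen=True)
class DiseasePreset:
    name: str
    description: str
    architecture: DiseaseArchitecture
    expected_max_ac: int
    reference_an: int
    case_series: Optional[CaseSeries] = None


@lru_cache(maxsize=1)
def _load_raw() -> dict:
    text = resources.files("fafcalc.data").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def available_diseases() -> Tuple[str, ...]:
    return tuple(_load_raw()["diseases"])


def disease_preset(name: str) -> DiseasePreset:
    """Look up a packaged disease architecture by name (case-insensitive).

    >>> disease_preset("Marfan").expected_max_ac
    2
    """
    raw = _load_raw()
    matches = {k.lower(): k for k in raw["diseases"]}
    key = matches.get(name.lower())
    if key is None:
        raise UnknownDiseaseError(
            f"unknown disease {name!r}; available: {', '.join(raw['diseases'])}"
        )
    entry = raw["diseases"][key]
    arch = DiseaseArchitecture(
        prevalence=parse_fraction(entry["prevalence"]),
        inheritance=entry["inheritance"],
        max_allelic_contribution=float(entry["max_allelic_contribution"]),
        penetrance=float(entry.get("penetrance", 1.0)),
        max_genetic_contribution=(
            float(entry["max_genetic_contribution"])
            if "max_genetic_contribution" in entry
            else None
        ),
    )
    cs = entry.get("case_series")
    series = (
        CaseSeries(cs["variant"], int(cs["carriers"]), int(cs["total"])) if cs else None
    )
    return DiseasePreset(
        name=key,
        description=entry.get("description", ""),
        architecture=arch,
        expected_max_ac=int(entry["expected_max_ac"]),
        reference_an=int(raw["reference_an"]),
        case_series=series,
    )


def all_presets() -> Dict[str, DiseasePreset]:
    return {name: disease_preset(name) for name in available_diseases()}
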