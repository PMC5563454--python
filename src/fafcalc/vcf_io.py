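"""VCF input/output: per-population AC/AN in, filtering-AF annotations out.

Reads variant sites carrying per-population allele counts in INFO fields
(``AC_AFR``/``AN_AFR`` ... by default), decomposes multi-allelic lines into one
record per alternate allele, annotates each record with per-population and
popmax filtering allele frequencies, and applies a disease-specific filter
decision. Output is standard VCF (plain or bgzipped) with the annotations
declared in the header, or a flat table.

Variant identity is the textual (chrom, pos, ref, alt) key; no normalisation
or liftover is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd
import pysam

from .architecture import DiseaseThreshold
from .poisson_filter import (
    CANONICAL_POPULATIONS,
    DEFAULT_CONFIDENCE,
    FilteringResult,
    PopulationCounts,
    popmax_filtering_af,
)

logger = logging.getLogger(__name__)

#: Default INFO keys per population: (AC key, AN key).
DEFAULT_FIELD_MAP: Dict[str, Tuple[str, str]] = {
    pop: (f"AC_{pop}", f"AN_{pop}") for pop in CANONICAL_POPULATIONS
}


class VcfParseError(ValueError):
    pass


class UnannotatedRecordError(ValueError):
    pass


@dataclass(frozen=True)
class VariantRecord:
    """One (site, alt allele) with its per-population counts."""

    chrom: str
    pos: int
    ref: str
    alt: str
    counts: Tuple[PopulationCounts, ...] = ()
    filtering: Optional[FilteringResult] = None

    def __post_init__(self) -> None:
        if self.pos < 1 or not self.ref or not self.alt:
            raise VcfParseError(
                f"invalid record {self.chrom}:{self.pos} {self.ref}>{self.alt}"
            )

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of comparing a variant's popmax filtering AF to a disease threshold."""

    variant: Tuple[str, int, str, str]
    decision: str  # "filtered" | "retained"
    threshold_used: float
    popmax_af: float


def _as_tuple(value, n_alts: int):
    """Normalise an allele-indexed INFO value to a tuple of length n_alts."""
    if value is None:
        return (None,) * n_alts
    if isinstance(value, (tuple, list)):
        return tuple(value)
    return (value,) * n_alts


def read_population_counts(
    vcf_path: Union[str, Path],
    field_map: Optional[Dict[str, Tuple[str, str]]] = None,
) -> List[VariantRecord]:
    """Read per-population AC/AN from a VCF into decomposed variant records.

    ``field_map`` maps population label → (AC INFO key, AN INFO key); the
    default expects ``AC_AFR``/``AN_AFR`` etc. for the five major continental
    populations. Allele-indexed (Number=A) AC values are aligned to the
    corresponding alt; populations with missing AN are omitted from a record;
    records whose AC exceeds AN are skipped with a logged warning.
    """
    field_map = field_map or DEFAULT_FIELD_MAP
    records: List[VariantRecord] = []
    try:
        vcf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot open VCF {vcf_path}: {exc}") from exc
    with vcf:
        for rec in vcf:
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                counts: List[PopulationCounts] = []
                consistent = True
                for pop, (ac_key, an_key) in field_map.items():
                    an = rec.info.get(an_key)
                    if an is None:
                        continue
                    ac_values = _as_tuple(rec.info.get(ac_key, 0), len(alts))
                    ac = ac_values[i] if i < len(ac_values) else 0
                    ac = int(ac or 0)
                    an = int(an)
                    if ac > an:
                        logger.warning(
                            "skipping %s:%s %s>%s: AC_%s=%d exceeds AN=%d",
                            rec.chrom, rec.pos, rec.ref, alt, pop, ac, an,
                        )
                        consistent = False
                        break
                    counts.append(PopulationCounts(pop, ac, an))
                if not consistent:
                    continue
                if not counts:
                    logger.warning(
                        "no mapped population counts at %s:%s %s>%s",
                        rec.chrom, rec.pos, rec.ref, alt,
                    )
                records.append(
                    VariantRecord(rec.chrom, rec.pos, rec.ref, alt, tuple(counts))
                )
    return records


def annotate_filtering_af(
    records: Iterable[VariantRecord],
    confidence: float = DEFAULT_CONFIDENCE,
    populations: Sequence[str] = CANONICAL_POPULATIONS,
) -> List[VariantRecord]:
    """Attach per-population and popmax filtering AFs to each record."""
    annotated = []
    for rec in records:
        if rec.counts:
            result = popmax_filtering_af(
                rec.counts, confidence=confidence, populations=populations
            )
        else:
            logger.warning("record %s has no counts; FAF not computed", rec.variant_id)
            result = None
        annotated.append(replace(rec, filtering=result))
    return annotated


def _build_header(
    records: Sequence[VariantRecord],
    confidence: float,
    populations: Sequence[str],
) -> pysam.VariantHeader:
    pct = round(confidence * 100)
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(r.chrom for r in records):
        header.add_line(f"##contig=<ID={chrom}>")
    for pop in populations:
        header.add_line(
            f'##INFO=<ID=AC_{pop},Number=A,Type=Integer,'
            f'Description="Alternate allele count ({pop})">'
        )
        header.add_line(
            f'##INFO=<ID=AN_{pop},Number=1,Type=Integer,'
            f'Description="Genotyped allele number ({pop})">'
        )
        header.add_line(
            f'##INFO=<ID=FAF{pct}_{pop},Number=A,Type=Float,'
            f'Description="Filtering allele frequency ({pop}, one-sided {pct}% bound)">'
        )
    header.add_line(
        f'##INFO=<ID=FAF{pct}_popmax,Number=A,Type=Float,'
        f'Description="Highest per-population filtering allele frequency">'
    )
    header.add_line(
        f'##INFO=<ID=FAF{pct}_popmax_pop,Number=A,Type=String,'
        f'Description="Population attaining the popmax filtering allele frequency">'
    )
    return header


def write_vcf(
    records: Sequence[VariantRecord],
    out_path: Union[str, Path],
    confidence: float = DEFAULT_CONFIDENCE,
    populations: Sequence[str] = CANONICAL_POPULATIONS,
) -> None:
    """Write annotated records as VCF, one line per (site, alt allele).

    Counts are emitted as ``AC_<POP>``/``AN_<POP>`` and filtering AFs as
    ``FAF<pct>_<POP>``/``FAF<pct>_popmax``/``FAF<pct>_popmax_pop``; filtering
    AF values are multiples of the 1e-6 grid and round-trip at 6 decimal
    digits. ``.gz`` suffix selects bgzip output.
    """
    pct = round(confidence * 100)
    header = _build_header(records, confidence, populations)
    out_path = str(out_path)
    mode = "wz" if out_path.endswith(".gz") else "w"
    try:
        out = pysam.VariantFile(out_path, mode, header=header)
    except OSError as exc:
        raise VcfParseError(f"cannot write VCF {out_path}: {exc}") from exc
    with out:
        for rec in records:
            vr = out.new_record(
                contig=rec.chrom, start=rec.pos - 1, stop=rec.pos - 1 + len(rec.ref),
                alleles=(rec.ref, rec.alt),
            )
            for pc in rec.counts:
                vr.info[f"AC_{pc.population}"] = (pc.ac,)
                vr.info[f"AN_{pc.population}"] = pc.an
            if rec.filtering is not None:
                for pop, faf in rec.filtering.per_population.items():
                    vr.info[f"FAF{pct}_{pop}"] = (round(faf, 6),)
                vr.info[f"FAF{pct}_popmax"] = (round(rec.filtering.popmax_af, 6),)
                if rec.filtering.popmax_population is not None:
                    vr.info[f"FAF{pct}_popmax_pop"] = (rec.filtering.popmax_population,)
            out.write(vr)


def read_annotated_vcf(
    vcf_path: Union[str, Path],
    confidence: float = DEFAULT_CONFIDENCE,
    populations: Sequence[str] = CANONICAL_POPULATIONS,
) -> List[VariantRecord]:
    """Read a VCF previously written by :func:`write_vcf`, restoring FAFs."""
    pct = round(confidence * 100)
    records = read_population_counts(
        vcf_path, {pop: (f"AC_{pop}", f"AN_{pop}") for pop in populations}
    )
    out: List[VariantRecord] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        raw = list(vcf)
    # records are one per alt in file order, matching the decomposition above
    idx = 0
    for rec in raw:
        for i, _alt in enumerate(rec.alts or ()):
            per_pop = {}
            for pop in populations:
                value = rec.info.get(f"FAF{pct}_{pop}")
                if value is not None:
                    per_pop[pop] = float(_as_tuple(value, len(rec.alts))[i])
            popmax = rec.info.get(f"FAF{pct}_popmax")
            if popmax is None and not per_pop:
                out.append(records[idx])
            else:
                popmax_pop = rec.info.get(f"FAF{pct}_popmax_pop")
                if isinstance(popmax_pop, tuple):
                    popmax_pop = popmax_pop[i] if i < len(popmax_pop) else popmax_pop[0]
                result = FilteringResult(
                    per_pop,
                    float(_as_tuple(popmax, len(rec.alts))[i]) if popmax is not None else 0.0,
                    popmax_pop,
                    confidence,
                )
                out.append(replace(records[idx], filtering=result))
            idx += 1
    return out


def apply_disease_filter(
    records: Iterable[VariantRecord], threshold: Union[DiseaseThreshold, float]
) -> List[FilterDecision]:
    """Filter decision per record: filtered ⇔ popmax filtering AF ≥ threshold.

    A variant whose filtering AF reaches the disease's maximum credible AF is
    too common to be causal and is filtered; anything below remains a
    candidate. ``threshold`` is a :class:`DiseaseThreshold` or a bare maximum
    credible AF.
    """
    threshold_af = (
        threshold.max_credible_af
        if isinstance(threshold, DiseaseThreshold)
        else float(threshold)
    )
    decisions = []
    n_filtered = 0
    for rec in records:
        if rec.filtering is None:
            raise UnannotatedRecordError(
                f"record {rec.variant_id} has no filtering annotation"
            )
        filtered = rec.filtering.popmax_af >= threshold_af
        n_filtered += filtered
        decisions.append(
            FilterDecision(
                rec.key,
                "filtered" if filtered else "retained",
                threshold_af,
                rec.filtering.popmax_af,
            )
        )
    logger.info(
        "filtered %d / %d records at max credible AF %.3g",
        n_filtered, len(decisions), threshold_af,
    )
    return decisions


def records_to_frame(
    records: Sequence[VariantRecord],
    populations: Sequence[str] = CANONICAL_POPULATIONS,
) -> pd.DataFrame:
    """Flat table mirroring the VCF annotations (one row per record)."""
    rows = []
    for rec in records:
        row: Dict[str, object] = {
            "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": rec.alt,
        }
        by_pop = {pc.population: pc for pc in rec.counts}
        for pop in populations:
            pc = by_pop.get(pop)
            row[f"ac_{pop}"] = pc.ac if pc else None
            row[f"an_{pop}"] = pc.an if pc else None
            row[f"faf_{pop}"] = (
                rec.filtering.per_population.get(pop) if rec.filtering else None
            )
        row["faf_popmax"] = rec.filtering.popmax_af if rec.filtering else None
        row["faf_popmax_pop"] = (
            rec.filtering.popmax_population if rec.filtering else None
        )
        rows.append(row)
    return pd.DataFrame(rows)
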