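"""Shared fixtures and independent oracles.

The oracles implement the defining computations directly — iterative Poisson
mass summation and an exhaustive millionth-grid scan — without touching the
package's closed-form code paths, so they can referee it.
"""

from __future__ import annotations

import math
import textwrap
from pathlib import Path

import numpy as np
import pytest
from scipy.stats import poisson as scipy_poisson


def poisson_cdf_by_summation(k: int, lam: float) -> float:
    """P(X ≤ k) for X ~ Poisson(lam), by direct iterative PMF summation."""
    if k < 0:
        return 0.0
    pmf = math.exp(-lam)
    total = pmf
    for i in range(1, k + 1):
        pmf *= lam / i
        total += pmf
    return total


def max_tolerated_ac_by_summation(af: float, an: int, confidence: float = 0.95) -> int:
    """Smallest k with summed Poisson CDF ≥ confidence at mean af × an."""
    lam = af * an
    k = 0
    pmf = math.exp(-lam)
    total = pmf
    while total < confidence:
        k += 1
        pmf *= lam / k
        total += pmf
    return k


def filtering_af_by_grid_scan(
    ac: int, an: int, confidence: float = 0.95, granularity: float = 1e-6,
    max_lambda: float = 60.0,
) -> float:
    """Exhaustive scan over grid multiples: the largest f whose tolerated AC
    is below the observed AC. Uses the vectorised Poisson CDF over the whole
    grid, not the package's inversion."""
    if ac <= 1:
        return 0.0
    n_steps = int(max_lambda / an / granularity) + 2
    f = granularity * np.arange(1, n_steps)
    ok = scipy_poisson.cdf(ac - 1, f * an) >= confidence
    if not ok.any():
        return 0.0
    last = np.nonzero(ok)[0].max()
    assert ok[: last + 1].all(), "scan region not contiguous; raise max_lambda"
    return float(f[last])


@pytest.fixture
def write_vcf_text(tmp_path: Path):
    """Write a minimal five-population VCF from (chrom, pos, ref, alts, info) rows."""

    def _write(rows, filename: str = "input.vcf", populations=("AFR", "AMR", "EAS", "NFE", "SAS")):
        header = ["##fileformat=VCFv4.2"]
        contigs = dict.fromkeys(r[0] for r in rows)
        header += [f"##contig=<ID={c}>" for c in contigs]
        for pop in populations:
            header.append(
                f'##INFO=<ID=AC_{pop},Number=A,Type=Integer,Description="AC {pop}">'
            )
            header.append(
                f'##INFO=<ID=AN_{pop},Number=1,Type=Integer,Description="AN {pop}">'
            )
        header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
        lines = list(header)
        for chrom, pos, ref, alts, info in rows:
            lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alts}\t.\t.\t{info or '.'}")
        path = tmp_path / filename
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
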