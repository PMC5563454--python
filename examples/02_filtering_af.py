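"""Per-variant filtering allele frequency with popmax aggregation.

The filtering AF inverts the tolerated-count bound: it is the highest disease
threshold at which a variant's observed allele count would already be too
common. A variant is filtered for a disease when its filtering AF is at or
above the disease's maximum credible AF. Across populations we take the
highest per-population value (popmax), so being common anywhere disqualifies.
"""

from fafcalc import PopulationCounts, filtering_af, popmax_filtering_af

# Single population: 2 copies among 10,000 chromosomes.
faf = filtering_af(ac=2, an=10_000)
print(f"AC 2 / AN 10,000 -> filtering AF {faf:.1e}")
print("-> filter this variant for any disease whose max credible AF <= that value\n")

# Singletons carry no filterable frequency evidence.
print(f"AC 1 / AN 121,412 -> filtering AF {filtering_af(1, 121_412)}")

# Popmax across the five major continental populations.
counts = [
    PopulationCounts("AFR", 0, 8_000),
    PopulationCounts("AMR", 1, 6_000),
    PopulationCounts("EAS", 0, 7_000),
    PopulationCounts("NFE", 12, 50_000),
    PopulationCounts("SAS", 2, 15_000),
]
result = popmax_filtering_af(counts)
print("\nper-population filtering AFs:")
for pop, value in result.per_population.items():
    print(f"  {pop}: {value:.1e}")
print(f"popmax: {result.popmax_af:.1e} (attained in {result.popmax_population})")
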