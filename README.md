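# fafcalc

Frequency-based filtering of candidate Mendelian disease variants.

Rarity in a large reference sample (ExAC/gnomAD-scale aggregation of exomes)
is a necessary condition for a variant to cause a penetrant Mendelian
disorder, but commonly used cutoffs (0.1% dominant, 1% recessive) are far too
lenient for most diseases, and naïve frequency comparison ignores sampling
noise in observed allele counts. `fafcalc` implements a statistically explicit
alternative for clinical and research variant analysts:

1. **Maximum credible population AF.** From the disease's genetic
   architecture — prevalence *P*, maximum allelic contribution *α* (largest
   share of cases one variant can explain), maximum genetic contribution *γ*
   (largest share of cases one gene can explain, recessive), penetrance *f* —
   the highest true population allele frequency compatible with causality:

   - dominant:  `AF_max = P · ½ · α / f`
   - recessive: `AF_max = sqrt(P · γ / f) · α`

2. **Maximum tolerated allele count.** Observed counts fluctuate. For a
   sample of AN chromosomes, the count at the upper bound of the one-tailed
   95% CI of a Poisson distribution with mean `AF_max · AN` — the smallest k
   with `CDF_Pois(k; AF_max·AN) ≥ 0.95`. A variant seen more often is too
   common at that ceiling (5% one-sided error rate).

3. **Filtering allele frequency.** The inverse, precomputable per variant:
   the largest frequency on a 10⁻⁶ grid whose tolerated count is still below
   the observed AC. Computed per population and aggregated as **popmax** (the
   highest across AFR/AMR/EAS/NFE/SAS). Decision rule:
   *filter the variant iff its popmax filtering AF ≥ the disease's maximum
   credible AF.* Singletons are never filtered — one observation carries
   almost no frequency information.

Supporting cohort statistics estimate the architecture inputs (binomial CIs
for case-series carrier proportions, burden odds ratios by AF bin, penetrance
from case vs population frequencies), and a VCF layer reads per-population
AC/AN INFO fields, writes `FAF95_*` annotations, and applies disease presets.
A seeded simulator generates multi-population reference panels so the whole
pipeline is testable offline.

## Worked example

The classic dominant case is hypertrophic cardiomyopathy (HCM): prevalence
1/500, commonest causal variant (*MYBPC3*:c.1504C>T) explaining at most 2% of
cases, penetrance 0.5.

```python
from fafcalc import DiseaseArchitecture, max_credible_af, max_tolerated_ac

hcm = DiseaseArchitecture(1/500, "dominant", 0.02, penetrance=0.5)
threshold = max_credible_af(hcm)          # 4.0e-05
max_tolerated_ac(threshold.max_credible_af, 121_412)   # 9
```

Running `python examples/01_disease_thresholds.py` prints:

```
HCM maximum credible population AF: 4.0e-05
Maximum tolerated AC in 121,412 chromosomes: 9
-> any variant seen more than this many times is too common to cause HCM
```

So a candidate HCM variant seen 10+ times among 121,412 reference
chromosomes is not a credible cause, while *MYBPC3*:c.1504C>T itself (3
copies) survives. The same script tabulates all ten packaged disease presets,
from Marfan syndrome (max AC 2) to the recessive primary ciliary dyskinesia
(max AC 322 — recessive ceilings are orders of magnitude higher because
carriers are unaffected).

From the shell:

```bash
fafcalc max-af --inheritance dominant --prevalence 1/500 \
        --allelic-contribution 0.02 --penetrance 0.5   # 4e-05
fafcalc max-ac --af 4e-5 --an 121412                   # 9
fafcalc filtering-af --ac 2 --an 10000                 # 3.5e-05
fafcalc annotate --vcf panel.vcf --out annotated.vcf
fafcalc filter --vcf annotated.vcf --disease HCM
```

The other examples cover per-variant filtering AFs with popmax
(`02_filtering_af.py`), end-to-end VCF annotation and filtering on a
simulated panel (`03_annotate_and_filter_vcf.py`), and cohort statistics
(`04_cohort_statistics.py`).

See `docs/methods.md` for the model's assumptions, numerical conventions and
limitations.

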