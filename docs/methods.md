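# Methods

## The model

A variant causing a penetrant Mendelian disease cannot be more frequent in an
unselected population than the disease it causes, scaled by how much of the
disease it can explain. With prevalence *P*, maximum allelic contribution *α*,
maximum genetic contribution *γ* and penetrance *f*:

- **Dominant:** `AF_max = P · ½ · α / f`. The ½ converts per-individual
  prevalence to per-chromosome frequency, assuming affected carriers are
  heterozygous; no correction is made for homozygous carriers, negligible at
  the frequencies of interest (≲10⁻³).
- **Recessive:** `AF_max = sqrt(P · γ / f) · α`. Under Hardy–Weinberg random
  mating with free compound heterozygosity among a gene's pathogenic alleles,
  the gene's summed pathogenic allele frequency q satisfies `q² = P·γ/f`, so
  `q = sqrt(P·γ/f)`; one variant takes at most a fraction α of that pool.
  This is the interpretation of α that reproduces the published recessive
  worked example (primary ciliary dyskinesia, tolerated count 322 at
  121,412 chromosomes); placing α inside the square root does not.

Results are capped at 1.0 rather than raising, so exploratory extreme inputs
stay usable. All computation is double precision; rounding (2 significant
figures in the tables) is display-only.

The inverse exploration `implied_min_penetrance(P, α, AF_obs) = P·½·α/AF_obs`
(capped at 1) answers: how penetrant could a variant at this observed
frequency still be? It is exactly the algebraic inversion of the dominant
formula and round-trips with it.

X-linked and mitochondrial inheritance, de novo mutation, founder effects and
balancing selection are out of scope: the model assumes a panmictic population
at equilibrium and a disease architecture stable across populations.

## Sampling model and the two bounds

True population frequency is unobservable; a reference sample of AN
chromosomes yields a count AC. For rare variants AC is modelled as
Poisson with mean `AF · AN` (the binomial's low-frequency limit; at
AF ≤ 10⁻³ the difference is far below the 10⁻⁶ grid).

**Maximum tolerated AC** is the Poisson quantile: the smallest integer k with
`CDF(k; AF_max·AN) ≥ c`, one-sided confidence c = 0.95 by default
(configurable; 0.99 gives a stricter evidence standard). A true-AF-at-ceiling
variant therefore exceeds the bound in at most 5% of samples — the
framework's stated error rate, verified by Monte-Carlo in the tests.

**Filtering AF** inverts the bound per variant: the largest multiple of the
grid g = 10⁻⁶ ("units of millionths", configurable) such that
`max_tolerated_ac(f, AN) < AC` (strict inequality). Implementation: the
condition is `CDF_Pois(AC−1; f·AN) ≥ c`, and `CDF_Pois(k; λ) = Q(k+1, λ)`
(regularised upper incomplete gamma), monotone decreasing in λ; the boundary
is `λ* = gammainccinv(AC, c)` and f is `λ*/AN` floored to the grid. Two local
guard steps make the result immune to floating-point edge effects at grid
boundaries; the test suite proves bit-identity with the defining exhaustive
grid scan for AC ∈ 0..50 and AN ∈ {1,000; 10,000; 121,412}, and the bracket
property `max_tolerated_ac(f) ≤ AC−1 < AC ≤ max_tolerated_ac(f+g)` for larger
counts.

Variants with AC ≤ 1 are assigned filtering AF 0 and are therefore never
filtered: a single observation says almost nothing about true frequency.
Because the Poisson bound widens (relative to its mean) in small samples, the
filtering AF for a fixed AC *decreases* as AN grows — small or poorly
genotyped populations are automatically treated conservatively.

**Popmax.** Filtering AF is computed per major continental population (AFR,
AMR, EAS, NFE, SAS) and the maximum is taken, with ties broken by that fixed
ordering. Populations with AN = 0 (or below a configurable `min_an`, default
0) are excluded rather than treated as frequency 0. Bottlenecked or residual
groupings (e.g. FIN, OTH) are excluded from popmax by default — founder
effects can make a truly pathogenic allele locally common — but any label can
be whitelisted via the `populations` argument / `--populations` flag.

**Decision rule.** Filter ⇔ popmax filtering AF ≥ maximum credible AF. The
boundary case is filtered (≥, matching the published rule); the strict
inequality lives inside the filtering-AF definition.

## Cohort statistics

- **Case-series CIs** are Wald by default — `p ± z·sqrt(p(1−p)/n)`, clamped
  to [0,1] — because that is the interval style of the published case-series
  rows this package regresses against; Clopper–Pearson is selectable
  (`method="clopper-pearson"`) for users who prefer exact coverage. Both are
  cross-checked against statsmodels in the tests.
- **Maximum allelic contribution** is the Wald upper bound of the most
  frequent variant's case proportion, optionally rounded *up* to a given
  number of significant figures (the convention when extrapolating from a
  well-characterised disorder to a similar one, e.g. 9.2% → 0.1).
- **Burden odds ratios** use the cross-product form
  `(a/b)/(c/d)`; CIs are log-OR normal. A Haldane–Anscombe 0.5 correction is
  applied, and flagged, only when exactly one cell is zero. No control
  carriers with case carriers gives +inf with a warning; zero "without" cells
  raise rather than silently producing a number.
- **AF bins** are right-closed, left-open `(a, b]` with default breakpoints
  4×10⁻⁵, 10⁻⁴, 5×10⁻⁴, 10⁻³, an overflow bin above the last breakpoint, and
  reference-absent variants (AF 0) in the lowest bin. The boundary convention
  is a package choice (the source convention is unstated); it is pinned by a
  unit test.
- **Penetrance from frequencies:** `f ≈ P · AF_case / AF_pop`, capped at 1
  with a flag. The cap firing means the assumed prevalence, case enrichment
  and population frequency are mutually inconsistent — itself a useful
  signal. Both AFs must be on the same scale (per-chromosome), so no ½
  appears. This is a reconstruction of a calculator feature whose formula is
  published elsewhere; treat absolute values as indicative.
- Case-series denominators are stored as given (individuals or alleles, per
  source) and never converted.

## VCF layer

Multi-allelic sites are decomposed to one record per alternate allele before
any computation; AN is shared across alts of a site per VCF semantics.
Identity is the textual (chrom, pos, ref, alt) key; no normalisation or
liftover. Input INFO keys default to `AC_<POP>`/`AN_<POP>` and are fully
remappable (`field_map`) to match any dialect. Output adds
`FAF95_<POP>`, `FAF95_popmax`, `FAF95_popmax_pop` (Number=A, Float/String)
declared in the header; FAF values are grid multiples and round-trip at the
10⁻⁶ precision they are written with. Records with AC > AN are skipped with a
logged warning rather than aborting a batch; records missing all mapped keys
pass through flagged, unannotated.

## Synthetic panels

The simulator exists to exercise the pipeline end to end, not to mimic any
real reference cohort. Defaults (the study conditions for all seeded tests):
5 populations × 20,000 chromosomes, 1,000 sites, global AF drawn from a 1/x
density truncated to [10⁻⁶, 0.5] (neutral-like, rare-heavy), per-population
divergence by a logit-normal perturbation with sd 0.5 (enough to make popmax
non-trivial), and a 2% point mass of "pathogenic-like" sites with true AF 0.
Counts are Binomial(AN, population AF). One integer seed determines the VCF
byte-for-byte.

What it does *not* model: linkage, demography/coalescent structure, the real
site-frequency spectrum of a sequenced cohort, genotype-quality-dependent AN
variation, or sequencing error. Passing tests on these panels therefore
demonstrate the *logic* of the filter (calibration of counts, monotonicity in
the cutoff, guaranteed retention of reference-absent variants, ≤5% false
filtering at the ceiling), not performance on real exomes; the published
per-exome reduction figures depend on a real reference cohort and are not
reproduced here.

The filtering-efficiency experiment draws held-out diploid individuals from
the same spectrum (carrier iff ≥1 alt allele), filters each against the
panel's popmax filtering AFs over a cutoff ladder, and reports mean retained
variants per sample plus the retention rate of the spiked pathogenic-like
sites (always 1.0, since absent variants have filtering AF 0).

## Problem sizes and runtime

All threshold computations are closed-form and run in microseconds. Test
suite sizes: the exhaustive inversion check covers AC 0..50 × three sample
sizes on the full 10⁻⁶ grid (vectorised, seconds); the quantile/PMF-summation
cross-check covers λ ∈ [0, 400] in steps of 0.5; Monte-Carlo error-rate
checks use 10⁵ Poisson draws; synthetic panels in tests use 80–3,000 sites.
The whole suite runs in well under a minute on one CPU.

## Known limitations

- Architecture parameters are only as good as the case series behind them;
  for poorly characterised diseases the presets' extrapolation conventions
  (upper CI bound, round-up) are deliberately lenient.
- The Poisson bound is per-variant and uncorrected for multiple testing
  across a panel; at 95% one-sided confidence, ~1 in 20 truly-at-ceiling
  variants will still be (correctly) retained, and occasional pathogenic
  variants near the boundary can exceed it by chance — the 0.99 confidence
  option exists for exactly that check.
- A reference cohort enriched for the disease of interest violates the
  prevalence premise; the ceiling should then be computed from the in-cohort
  prevalence.
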