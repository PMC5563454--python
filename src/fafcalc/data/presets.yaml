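# Exemplar disease genetic architectures, version 1.
#
# Dominant cardiac conditions with large published case series carry the
# Wald upper bound of their commonest variant's case proportion as the
# maximum allelic contribution; the less-characterised disorders carry
# extrapolated or database-derived estimates. Penetrance 0.5 throughout,
# the minimum reported across these disorders. expected_max_ac is the
# maximum tolerated allele count at AN = 121,412 chromosomes (one-sided
# 95% bound), kept for regression testing.
version: 1
reference_an: 121412
diseases:
  HCM:
    description: Hypertrophic cardiomyopathy (commonest variant MYBPC3:c.1504C>T, 104/6,179 cases)
    inheritance: dominant
    prevalence: 1/500
    max_allelic_contribution: 0.020
    penetrance: 0.5
    case_series: {variant: "MYBPC3:c.1504C>T", carriers: 104, total: 6179}
    expected_max_ac: 9
  DCM:
    description: Dilated cardiomyopathy (TNNT2:c.629_631delAGA, 18/1,254 cases)
    inheritance: dominant
    prevalence: 1/250
    max_allelic_contribution: 0.021
    penetrance: 0.5
    case_series: {variant: "TNNT2:c.629_631delAGA", carriers: 18, total: 1254}
    expected_max_ac: 16
  ARVC:
    description: Arrhythmogenic right ventricular cardiomyopathy (PKP2:c.2146-1G>C, 24/361 cases)
    inheritance: dominant
    prevalence: 1/1000
    max_allelic_contribution: 0.092
    penetrance: 0.5
    case_series: {variant: "PKP2:c.2146-1G>C", carriers: 24, total: 361}
    expected_max_ac: 17
  LQTS:
    description: Long QT syndrome (KCNQ1:c.797T>C, 30/2,500 cases)
    inheritance: dominant
    prevalence: 1/2000
    max_allelic_contribution: 0.016
    penetrance: 0.5
    case_series: {variant: "KCNQ1:c.797T>C", carriers: 30, total: 2500}
    expected_max_ac: 3
  Brugada:
    description: Brugada syndrome (SCN5A:c.5350G>A, 14/2,111 cases)
    inheritance: dominant
    prevalence: 1/1000
    max_allelic_contribution: 0.010
    penetrance: 0.5
    case_series: {variant: "SCN5A:c.5350G>A", carriers: 14, total: 2111}
    expected_max_ac: 3
  Marfan:
    description: Marfan syndrome (UMD-FBN1 database, commonest variant 30/3,006 records)
    inheritance: dominant
    prevalence: 1/3000
    max_allelic_contribution: 0.015
    penetrance: 0.5
    expected_max_ac: 2
  Noonan:
    description: Noonan syndrome (allelic contribution extrapolated from cardiac conditions)
    inheritance: dominant
    prevalence: 1/1000
    max_allelic_contribution: 0.10
    penetrance: 0.5
    expected_max_ac: 18
  CPVT:
    description: Catecholaminergic polymorphic ventricular tachycardia
    inheritance: dominant
    prevalence: 1/10000
    max_allelic_contribution: 0.10
    penetrance: 0.5
    expected_max_ac: 3
  Ehlers-Danlos:
    description: Classic Ehlers-Danlos syndrome (up to 40% of cases from COL5A1; minimal allelic heterogeneity assumed)
    inheritance: dominant
    prevalence: 1/20000
    max_allelic_contribution: 0.40
    penetrance: 0.5
    expected_max_ac: 5
  PCD:
    description: Primary ciliary dyskinesia, recessive (DNAI1 ~9% of cases; IVS1+2_3insT ~57% of DNAI1 alleles, 17/358 case alleles)
    inheritance: recessive
    prevalence: 1/10000
    max_genetic_contribution: 0.09
    max_allelic_contribution: 0.57
    penetrance: 0.5
    case_series: {variant: "DNAI1:IVS1+2_3insT", carriers: 17, total: 358}
    expected_max_ac: 322
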