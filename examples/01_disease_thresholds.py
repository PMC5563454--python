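"""From a disease's genetic architecture to its allele-count ceiling.

Builds the hypertrophic cardiomyopathy architecture (prevalence 1 in 500,
commonest variant explaining at most 2% of cases, penetrance 0.5), derives the
maximum credible population allele frequency, and converts it to the maximum
tolerated allele count in a reference sample of 121,412 chromosomes. Then does
the same for every packaged disease preset.
"""

from fafcalc import (
    DiseaseArchitecture,
    available_diseases,
    disease_preset,
    max_credible_af,
    max_tolerated_ac,
)

AN = 121_412

hcm = DiseaseArchitecture(
    prevalence=1 / 500,
    inheritance="dominant",
    max_allelic_contribution=0.02,
    penetrance=0.5,
)
threshold = max_credible_af(hcm)
tolerated = max_tolerated_ac(threshold.max_credible_af, AN)

print(f"HCM maximum credible population AF: {threshold.max_credible_af:.1e}")
print(f"Maximum tolerated AC in {AN:,} chromosomes: {tolerated}")
print("-> any variant seen more than this many times is too common to cause HCM\n")

print(f"{'disease':<14}{'inheritance':<11}{'max credible AF':>16}{'max AC':>8}")
for name in available_diseases():
    preset = disease_preset(name)
    af = max_credible_af(preset.architecture).max_credible_af
    ac = max_tolerated_ac(af, preset.reference_an)
    print(f"{name:<14}{preset.architecture.inheritance.value:<11}{af:>16.2e}{ac:>8}")
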