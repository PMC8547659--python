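# Sodium -> systolic blood pressure dose-response coefficients.
#
# Linear meta-regression form: the SBP reduction (mm Hg) achieved by a
# 100 mmol/d (2.3 g/d) sodium reduction in an age-sex stratum is
#
#   k = main + age_interaction * (age_mid - reference_age)
#            + hypertension_interaction * hypertension_prevalence
#
# Values are in the range of the multivariable-adjusted meta-regression of
# 103 sodium-reduction randomized trials (Mozaffarian et al. 2014): larger
# effects at older ages and in hypertensive populations. Standard errors
# feed the Monte Carlo draws; all coefficients are data, not code.
main_effect_mmhg_per_100mmol: 3.74
main_effect_se: 0.35
age_interaction_mmhg_per_year: 0.105
age_interaction_se: 0.03
hypertension_interaction_mmhg: 1.87
hypertension_interaction_se: 0.55
reference_age_years: 50.0
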