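cause_id,age_lo,age_hi,rr,ci_low,ci_high
ischemic_heart_disease,25,44,1.72,1.56,1.90
ischemic_heart_disease,45,54,1.56,1.43,1.70
ischemic_heart_disease,55,64,1.44,1.33,1.56
ischemic_heart_disease,65,74,1.32,1.23,1.42
ischemic_heart_disease,75,84,1.22,1.14,1.31
ischemic_heart_disease,85,200,1.12,1.05,1.20
ischemic_stroke,25,44,1.85,1.62,2.11
ischemic_stroke,45,54,1.66,1.48,1.86
ischemic_stroke,55,64,1.50,1.36,1.65
ischemic_stroke,65,74,1.36,1.25,1.48
ischemic_stroke,75,84,1.24,1.15,1.34
ischemic_stroke,85,200,1.14,1.06,1.23
hemorrhagic_stroke,25,44,2.00,1.70,2.35
hemorrhagic_stroke,45,54,1.77,1.54,2.03
hemorrhagic_stroke,55,64,1.57,1.40,1.76
hemorrhagic_stroke,65,74,1.41,1.27,1.56
hemorrhagic_stroke,75,84,1.27,1.16,1.39
hemorrhagic_stroke,85,200,1.16,1.07,1.26
aortic_aneurysm,25,44,1.45,1.25,1.68
aortic_aneurysm,45,54,1.38,1.22,1.56
aortic_aneurysm,55,64,1.31,1.18,1.45
aortic_aneurysm,65,74,1.24,1.13,1.36
aortic_aneurysm,75,84,1.17,1.08,1.27
aortic_aneurysm,85,200,1.10,1.02,1.19
endocarditis,25,44,1.30,1.10,1.54
endocarditis,45,54,1.26,1.08,1.47
endocarditis,55,64,1.21,1.06,1.38
endocarditis,65,74,1.17,1.04,1.32
endocarditis,75,84,1.12,1.02,1.23
endocarditis,85,200,1.08,1.00,1.17
hypertensive_heart_disease,25,44,1.95,1.60,2.38
hypertensive_heart_disease,45,54,1.76,1.48,2.09
hypertensive_heart_disease,55,64,1.58,1.36,1.84
hypertensive_heart_disease,65,74,1.42,1.25,1.61
hypertensive_heart_disease,75,84,1.28,1.15,1.42
hypertensive_heart_disease,85,200,1.16,1.06,1.27
rheumatic_heart_disease,25,44,1.35,1.12,1.63
rheumatic_heart_disease,45,54,1.30,1.10,1.54
rheumatic_heart_disease,55,64,1.25,1.08,1.45
rheumatic_heart_disease,65,74,1.19,1.05,1.35
rheumatic_heart_disease,75,84,1.14,1.03,1.26
rheumatic_heart_disease,85,200,1.09,1.01,1.18
other_cvd,25,44,1.50,1.30,1.73
other_cvd,45,54,1.42,1.26,1.60
other_cvd,55,64,1.34,1.21,1.48
other_cvd,65,74,1.26,1.15,1.38
other_cvd,75,84,1.19,1.10,1.29
other_cvd,85,200,1.12,1.04,1.21
ckd,25,44,1.42,1.22,1.65
ckd,45,54,1.37,1.20,1.56
ckd,55,64,1.32,1.18,1.48
ckd,65,74,1.27,1.15,1.40
ckd,75,84,1.22,1.11,1.34
ckd,85,200,1.17,1.07,1.28
stomach_cancer,25,44,1.18,1.05,1.33
stomach_cancer,45,54,1.18,1.05,1.33
stomach_cancer,55,64,1.18,1.05,1.33
stomach_cancer,65,74,1.18,1.05,1.33
stomach_cancer,75,84,1.18,1.05,1.33
stomach_cancer,85,200,1.18,1.05,1.33
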