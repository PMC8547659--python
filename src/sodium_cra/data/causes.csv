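cause_id,label,group,pathway,include_in_mortality,include_in_morbidity
ischemic_heart_disease,Ischemic heart disease,cvd,bp_mediated,1,1
ischemic_stroke,Ischemic stroke,cvd,bp_mediated,1,1
hemorrhagic_stroke,Hemorrhagic stroke,cvd,bp_mediated,1,1
aortic_aneurysm,Aortic aneurysm,cvd,bp_mediated,1,1
endocarditis,Endocarditis,cvd,bp_mediated,1,0
hypertensive_heart_disease,Hypertensive heart disease,cvd,bp_mediated,1,1
rheumatic_heart_disease,Rheumatic heart disease,cvd,bp_mediated,1,0
other_cvd,Other cardiovascular diseases,cvd,bp_mediated,1,1
ckd,Chronic kidney disease,ckd,bp_mediated,1,1
stomach_cancer,Stomach cancer,cancer,direct,1,1
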