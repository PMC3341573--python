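# target: uncomplicated urinary tract infection
# provenance: literature-reported positive/negative likelihood ratios of symptoms and signs for predicting uncomplicated urinary tract infection in women
finding_id,label,lr_pos,lr_neg,sensitivity,specificity,dependence_group,modality,note
dysuria,Dysuria,1.5,0.5,,,,history,
frequency,Frequency,1.8,0.6,,,,history,
hematuria,Hematuria,2,0.9,,,,history,
fever,Fever,1.6,0.9,,,,history,
flank_pain,Flank pain,1.1,0.9,,,,history,
lower_abdominal_pain,Lower abdominal pain,1.1,0.9,,,,history,
vaginal_discharge,Vaginal discharge,0.3,3.1,,,vaginal,history,
vaginal_irritation,Vaginal irritation,0.2,2.7,,,vaginal,history,
back_pain,Back pain,1.6,0.8,,,,history,
self_diagnosis,Self-diagnosis,4,0.1,,,,history,
vaginal_discharge_exam,Vaginal discharge on physical examination,0.7,1.1,,,,exam,
cva_tenderness,Costovertebral angle tenderness,1.7,0.9,,,,exam,
dipstick_urinalysis,Dipstick urinalysis,4.2,0.3,,,,laboratory,footnoted in the source accuracy table
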