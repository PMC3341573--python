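# target: organic
# provenance: category-oriented likelihood ratios of patient characteristics, symptoms and laboratory results for the organic-disease category in non-acute abdominal pain (derived from a primary-care diagnostic study)
# note: the source table's garbled ESR unit label is transcribed with a corrected label and the original values
finding_id,label,lr_pos,lr_neg,sensitivity,specificity,dependence_group,modality,note
male_sex,Male sex,1.41,0.78,,,,history,
age_gt_30,Age > 30 years,1.12,0.64,,,,history,
age_gt_60,Age > 60 years,1.47,0.9,,,,history,
age_30_to_60,30 < Age < 60 years,1.08,0.88,,,,history,
blood_in_stool,History of blood in stool,1.5,0.89,,,,history,
pain_affecting_sleep,Pain affecting sleep,1.3,0.77,,,,history,
no_pain_relief_defecation,No pain relief after defecation,1.1,0.72,,,,history,
no_specific_character,No specific character to pain,1.5,0.93,,,,history,
weight_loss,Weight loss > 1 kg in 4 weeks,1.29,0.89,,,,history,
wbc_gt_10000,White blood cell count > 10000 per mm3,2.28,0.9,,,,laboratory,
esr_gt_20,Erythrocyte sedimentation rate > 20 mm per hour,2,0.92,,,,laboratory,
low_hemoglobin,Low hemoglobin level,1.78,0.87,,,,laboratory,
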