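# provenance: final diagnoses (percent of patients) in a primary-care cohort with non-acute abdominal pain, grouped into non-organic and organic categories; neoplastic diagnoses additionally tagged organic/neoplasm
disease_id,label,prevalence_pct,category_path
abdominal_symptoms_no_dx,Abdominal symptoms (no diagnosis),63.1,non-organic
stomach_function_gastritis,Disorders of stomach function/gastritis,7.6,non-organic
irritable_bowel_syndrome,Irritable bowel syndrome,14.8,non-organic
infectious_diarrhea,"Infectious diarrhea, dysentery",0.4,organic
other_presumed_infections,Other presumed infections,1.1,organic
malig_neoplasm_stomach,Malignant neoplasm stomach,0.2,organic/neoplasm
malig_neoplasm_colon_rectum,"Malignant neoplasm colon, rectum",0.4,organic/neoplasm
malig_neoplasm_pancreas,Malignant neoplasm pancreas,0.2,organic/neoplasm
malig_neoplasm_other_sites,Malignant neoplasm other and unspecified sites,0.2,organic/neoplasm
benign_neoplasms_digestive,Benign neoplasms (digestive tract),0.9,organic/neoplasm
disease_of_oesophagus,Disease of oesophagus,0.4,organic
duodenal_ulcer,Duodenal ulcer,1.7,organic
other_peptic_ulcers,Other peptic ulcers,1.0,organic
appendicitis,Appendicitis,0.1,organic
inguinal_hernia,Inguinal hernia,0.1,organic
hiatus_hernia,Hiatus (diaphragm) hernia,0.3,organic
other_abdominal_hernia,Other abdominal hernia,0.1,organic
diverticular_diseases,Diverticular diseases of intestines,1.4,organic
chronic_enteritis_uc,Chronic enteritis/ulcerative colitis,1.3,organic
anal_fissure_abscess,Anal fissure/perianal abscess,0.4,organic
cholecystitis_cholelithiasis,Cholecystitis/cholelithiasis,0.3,organic
other_disease_digestive,Other disease digestive system,0.1,organic
haemorrhoids,Haemorrhoids,0.6,organic
malig_neoplasm_lung,Malignant neoplasm trachea/bronchus/lung,0.2,organic/neoplasm
pyelonephritis_acute,"Pyelonephritis/pyelitis, acute",0.1,organic
cystitis_urinary_infection,Cystitis/other urinary infection,0.2,organic
malig_neoplasm_kidney,Malignant neoplasm kidney,0.1,organic/neoplasm
urinary_calculus,Urinary calculus,0.4,organic
other_disease_urinary,Other disease of urinary system,0.2,organic
malig_neoplasm_cervix,Malignant neoplasm cervix,0.1,organic/neoplasm
malig_neoplasm_female_genital,Other malignant neoplasm (female genital system),0.1,organic/neoplasm
fibroid_myoma,Fibroid/myoma (uterus/cervix),0.9,organic/neoplasm
other_diseases_female_genital,Other diseases female genital tract,0.6,organic
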