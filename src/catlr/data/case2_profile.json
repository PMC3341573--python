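{
  "attributes": {
    "onset": "non-acute"
  },
  "findings": {
    "male_sex": "absent",
    "blood_in_stool": "absent",
    "pain_affecting_sleep": "absent",
    "no_pain_relief_defecation": "absent",
    "no_specific_character": "absent",
    "weight_loss": "absent",
    "wbc_gt_10000": "absent",
    "esr_gt_20": "absent",
    "low_hemoglobin": "absent"
  }
}
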