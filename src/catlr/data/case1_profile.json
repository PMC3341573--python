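{
  "attributes": {},
  "findings": {
    "dysuria": "present",
    "frequency": "present",
    "vaginal_discharge": "absent",
    "vaginal_irritation": "absent",
    "self_diagnosis": "present"
  }
}
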