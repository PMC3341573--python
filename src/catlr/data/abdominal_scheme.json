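{
  "id": "onset",
  "type": "router",
  "question": "Is the abdominal pain acute or non-acute in onset?",
  "field": "onset",
  "children": {
    "acute": {
      "type": "action",
      "action": "work up acute abdominal pain"
    },
    "non-acute": {
      "id": "organic_history",
      "type": "reviser",
      "question": "Do history findings favour an organic cause?",
      "category": "organic",
      "prior": {"source": "diseases"},
      "table": "abdominal_findings",
      "modality": "history",
      "threshold": 0.10,
      "children": {
        "above": {
          "type": "action",
          "action": "pursue organic work-up"
        },
        "below": {
          "id": "organic_labs",
          "type": "reviser",
          "question": "Do laboratory findings favour an organic cause?",
          "category": "organic",
          "prior": {"source": "carried"},
          "table": "abdominal_findings",
          "modality": "laboratory",
          "threshold": 0.10,
          "children": {
            "above": {
              "type": "action",
              "action": "pursue organic work-up"
            },
            "below": {
              "id": "neoplasm",
              "type": "reviser",
              "question": "Is a neoplasm still a concern?",
              "category": "organic/neoplasm",
              "prior": {"source": "fixed", "probability": 0.04},
              "table": "abdominal_findings",
              "modality": null,
              "threshold": 0.10,
              "children": {
                "above": {
                  "type": "action",
                  "action": "refer to specialist"
                },
                "below": {
                  "type": "action",
                  "action": "symptomatic treatment & follow-up"
                }
              }
            }
          }
        }
      }
    }
  }
}
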