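{
  "type": "object",
  "required": ["beta", "n_samples", "aps", "counts"],
  "properties": {
    "beta": {"type": "number"},
    "n_samples": {"type": "integer"},
    "counts": {
      "type": "object",
      "properties": {},
      "additionalProperties": {"type": "integer"}
    },
    "aps": {
      "type": "object",
      "properties": {},
      "additionalProperties": {
        "type": "object",
        "required": ["cutoffs", "histograms", "per_length"],
        "properties": {
          "cutoffs": {
            "type": "object",
            "required": [
              "ap_id", "similarity_cutoff", "location_cutoff",
              "ap_sub_length", "beta", "precision", "recall", "f_beta"
            ],
            "properties": {
              "ap_id": {"type": "string"},
              "similarity_cutoff": {"type": "number"},
              "location_cutoff": {"type": "integer"},
              "ap_sub_length": {"type": "integer"},
              "beta": {"type": "number"},
              "precision": {"type": "number"},
              "recall": {"type": "number"},
              "f_beta": {"type": "number"}
            }
          },
          "histograms": {
            "type": "object",
            "required": ["true", "random"],
            "properties": {},
            "additionalProperties": {
              "type": "object",
              "required": ["similarity", "end_distance", "n"],
              "properties": {
                "n": {"type": "integer"},
                "similarity": {
                  "type": "object",
                  "required": ["edges", "counts"],
                  "properties": {
                    "edges": {"type": "array", "items": {"type": "number"}},
                    "counts": {"type": "array", "items": {"type": "integer"}}
                  }
                },
                "end_distance": {
                  "type": "object",
                  "required": ["edges", "counts"],
                  "properties": {
                    "edges": {"type": "array", "items": {"type": "number"}},
                    "counts": {"type": "array", "items": {"type": "integer"}}
                  }
                }
              }
            }
          },
          "per_length": {
            "type": "array",
            "items": {
              "type": "object",
              "required": [
                "ap_sub_length", "similarity_cutoff", "location_cutoff",
                "precision", "recall", "f_beta", "n_true", "n_random"
              ],
              "properties": {
                "ap_sub_length": {"type": "integer"},
                "similarity_cutoff": {"type": "number"},
                "location_cutoff": {"type": "integer"},
                "precision": {"type": "number"},
                "recall": {"type": "number"},
                "f_beta": {"type": "number"},
                "n_true": {"type": "integer"},
                "n_random": {"type": "integer"}
              }
            }
          }
        }
      }
    }
  }
}
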