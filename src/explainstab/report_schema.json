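{
  "type": "object",
  "required_properties": {
    "alpha": {"type": "number"},
    "stages": {
      "type": "object",
      "required_properties": {
        "cohort": {
          "type": "object",
          "required_properties": {
            "n_subjects": {"type": "number"},
            "n_features": {"type": "number"},
            "n_sites": {"type": "number"}
          }
        }
      }
    }
  }
}
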