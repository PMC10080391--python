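{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "hlamm pipeline configuration",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "seed": {
      "type": "integer",
      "default": 0,
      "description": "Master seed; per-stage seeds are derived from it deterministically."
    },
    "population": {
      "type": "string",
      "default": "EUR",
      "description": "Population label selecting rows of the haplotype frequency table."
    },
    "simulate": {
      "type": "object",
      "description": "Overrides for SimulationConfig fields (see hlamm.synthetic.SimulationConfig).",
      "additionalProperties": true
    },
    "scoring": {
      "type": "object",
      "description": "Overrides for ScoringConfig fields (see hlamm.scoring.ScoringConfig).",
      "additionalProperties": true
    },
    "outcomes": {
      "type": "object",
      "description": "Overrides for OutcomeConfig fields (see hlamm.outcomes.OutcomeConfig).",
      "additionalProperties": true
    },
    "survival": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "covariates": {
          "type": "array",
          "items": {"type": "string"},
          "default": ["baseline_egfr", "recipient_age", "donor_age", "graft_number"]
        },
        "eval_times": {
          "type": "array",
          "items": {"type": "number"},
          "default": [1.0, 2.0, 3.0, 4.0],
          "description": "Years at which time-dependent AUC is evaluated."
        },
        "horizon": {"type": "number", "default": 4.0, "description": "Calibration horizon, years."},
        "n_boot": {"type": "integer", "default": 200, "description": "Bootstrap refits for calibration bands."},
        "calibration_groups": {"type": "integer", "default": 5}
      }
    }
  }
}
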