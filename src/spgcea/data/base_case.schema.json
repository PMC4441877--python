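{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "spgcea model configuration",
  "description": "Shape of the YAML configuration consumed by spgcea.load_params. Shipped as documentation; the loader performs the equivalent checks natively and additionally rejects unknown keys with their dotted path.",
  "type": "object",
  "required": ["horizon_years", "clinical", "costs", "utility", "discount"],
  "additionalProperties": false,
  "properties": {
    "horizon_years": {"type": "number", "exclusiveMinimum": 0},
    "clinical": {
      "type": "object",
      "additionalProperties": false,
      "required": ["baseline_attacks_per_day", "pain_relief_prob", "initial_freq_reduction", "annual_decline_fraction"],
      "properties": {
        "baseline_attacks_per_day": {"type": "number", "exclusiveMinimum": 0},
        "pain_relief_prob": {"type": "number", "minimum": 0, "maximum": 1},
        "initial_freq_reduction": {"type": "number", "minimum": 0, "maximum": 1},
        "annual_decline_fraction": {"type": "number", "minimum": 0, "maximum": 1}
      }
    },
    "costs": {
      "type": "object",
      "additionalProperties": false,
      "required": ["med_cost_per_attack", "implant_drg", "device_cost", "imaging_cost", "titration_visits_cost", "revision_drg", "revision_prob", "revision_device_paid_by_payer", "antibiotics_cost", "infection_prob", "explant_cost", "explant_prob"],
      "properties": {
        "med_cost_per_attack": {"type": "number", "minimum": 0},
        "implant_drg": {"type": "number", "minimum": 0},
        "device_cost": {"type": "number", "minimum": 0},
        "imaging_cost": {"type": "number", "minimum": 0},
        "titration_visits_cost": {"type": "number", "minimum": 0},
        "revision_drg": {"type": "number", "minimum": 0},
        "revision_prob": {"type": "number", "minimum": 0, "maximum": 1},
        "revision_device_paid_by_payer": {"type": "boolean"},
        "antibiotics_cost": {"type": "number", "minimum": 0},
        "infection_prob": {"type": "number", "minimum": 0, "maximum": 1},
        "explant_cost": {"type": "number", "minimum": 0},
        "explant_prob": {"type": "number", "minimum": 0, "maximum": 1}
      }
    },
    "utility": {
      "type": "object",
      "additionalProperties": false,
      "required": ["baseline_utility", "spg_utility_points", "annual_qaly_gain"],
      "properties": {
        "baseline_utility": {"type": "number", "minimum": -0.594, "maximum": 1},
        "spg_utility_points": {
          "type": "array",
          "minItems": 1,
          "items": {
            "type": "array",
            "prefixItems": [
              {"type": "number", "minimum": 0},
              {"type": "number", "minimum": -0.594, "maximum": 1}
            ],
            "minItems": 2,
            "maxItems": 2
          }
        },
        "annual_qaly_gain": {"type": "array", "minItems": 1, "items": {"type": "number"}},
        "extrapolation_rule": {"enum": ["year2-average", "hold-last"]}
      }
    },
    "discount": {
      "type": "object",
      "additionalProperties": false,
      "required": ["annual_rate"],
      "properties": {
        "annual_rate": {"type": "number", "minimum": 0},
        "cycle_length_days": {"type": "number", "exclusiveMinimum": 0},
        "timing": {"enum": ["start", "midpoint", "end", "continuous"]},
        "stim_med_timing": {"enum": ["start", "midpoint", "end", "continuous"]}
      }
    }
  }
}
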