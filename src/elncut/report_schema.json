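{
  "type": "object",
  "required": [
    "version", "config", "cohort_summaries", "continuous_models",
    "occult_table_path", "series_paths", "break_points",
    "selected_cutpoint", "cutpoint_spread", "derivation_fit", "validation_fit"
  ],
  "properties": {
    "version": {"type": "string"},
    "config": {
      "type": "object",
      "required": ["mode", "m_total", "sparsity_floor", "bandwidth"],
      "properties": {
        "mode": {"type": "string"},
        "seed": {"type": ["integer", "null"]},
        "m_total": {"type": "integer"},
        "sparsity_floor": {"type": "integer"},
        "bandwidth": {"type": "number"},
        "threshold_override": {"type": ["integer", "null"]}
      }
    },
    "cohort_summaries": {
      "type": "object",
      "required": ["derivation"],
      "properties": {
        "derivation": {
          "type": "object",
          "required": ["n_patients", "deaths", "censored_fraction",
                       "median_followup_years", "eln_median", "eln_iqr",
                       "n_stage_proportions"]
        }
      }
    },
    "continuous_models": {
      "type": "object",
      "required": [
        "stage_migration_or", "os_hr_node_negative", "os_hr_node_positive",
        "positive_vs_examined"
      ]
    },
    "occult_table_path": {"type": "string"},
    "series_paths": {"type": "object"},
    "break_points": {"type": "object"},
    "selected_cutpoint": {"type": "integer"},
    "cutpoint_spread": {"type": "array", "items": {"type": "number"}},
    "derivation_fit": {
      "type": "object",
      "required": ["threshold", "hr", "ci_low", "ci_high", "p_value",
                   "n_above", "n_below", "events_above", "events_below",
                   "endpoint", "subset"],
      "properties": {
        "threshold": {"type": "integer"},
        "hr": {"type": "number"},
        "ci_low": {"type": "number"},
        "ci_high": {"type": "number"},
        "p_value": {"type": "number"},
        "n_above": {"type": "integer"},
        "n_below": {"type": "integer"},
        "events_above": {"type": "integer"},
        "events_below": {"type": "integer"},
        "endpoint": {"type": "string"},
        "subset": {"type": "string"}
      }
    },
    "validation_fit": {"type": ["object", "null"]}
  }
}
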