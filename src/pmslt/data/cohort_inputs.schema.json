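{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "cohort_inputs.csv",
  "description": "One row per sex x 5-year age band (male/female, 0-4 .. 100-104; 42 rows). Rates suffixed per_100k are per 100,000 persons and are converted to per-person on load; case-fatality rates (cfr) are per prevalent case-year; disability rates (dr) are YLD per prevalent case, i.e. disability weights, also stored per 100k. SBP columns are blank below age 15.",
  "type": "object",
  "properties": {
    "sex": {"enum": ["male", "female"]},
    "age_group": {"type": "string", "pattern": "^\\d+-\\d+$"},
    "n": {"type": "number", "minimum": 0, "description": "population count in the base year"},
    "cold_prevalence_pct": {"type": "number", "minimum": 0, "maximum": 100},
    "mortality_per_100k": {"type": "number", "minimum": 0},
    "yld_prop": {"type": "number", "minimum": 0, "maximum": 1,
                 "description": "all-cause morbidity as proportion of a life year lost"},
    "sbp_mean": {"type": ["number", "null"]},
    "sbp_sd": {"type": ["number", "null"], "exclusiveMinimum": 0},
    "ihd_ir_per_100k": {"type": "number", "minimum": 0},
    "ihd_cfr": {"type": "number", "minimum": 0},
    "ihd_dr_per_100k": {"type": "number", "minimum": 0},
    "isch_stroke_ir_per_100k": {"type": "number", "minimum": 0},
    "isch_stroke_cfr": {"type": "number", "minimum": 0},
    "isch_stroke_dr_per_100k": {"type": "number", "minimum": 0},
    "hem_stroke_ir_per_100k": {"type": "number", "minimum": 0},
    "hem_stroke_cfr": {"type": "number", "minimum": 0},
    "hem_stroke_dr_per_100k": {"type": "number", "minimum": 0}
  },
  "required": ["sex", "age_group", "n", "cold_prevalence_pct",
               "mortality_per_100k", "yld_prop"]
}
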