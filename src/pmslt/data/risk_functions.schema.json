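{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "risk_functions.csv",
  "description": "Relative risks of disease incidence per 10 mmHg systolic blood pressure under a log-linear exposure-response (slope per mmHg = ln(rr_per_10mmhg)/10). Each disease must cover a contiguous run of 5-year age bands ending at 100-104; bands below the youngest entry contribute no impact fraction unless the loader's inherit flag is set. rr_lo/rr_hi are optional 95% CI bounds used by the uncertainty analysis.",
  "type": "object",
  "properties": {
    "disease": {"enum": ["ihd", "isch_stroke", "hem_stroke"]},
    "age_group": {"type": "string", "pattern": "^\\d+-\\d+$"},
    "rr_per_10mmhg": {"type": "number", "exclusiveMinimum": 0},
    "rr_lo": {"type": "number", "exclusiveMinimum": 0},
    "rr_hi": {"type": "number", "exclusiveMinimum": 0}
  },
  "required": ["disease", "age_group", "rr_per_10mmhg"]
}
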