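{
  "name": "FRAM",
  "provenance": "published",
  "intercept": null,
  "terms": [
    {"name": "ifg", "source_field": "fpg", "encoding": "band", "params": {"low": 6.1, "high": 7.0}},
    {"name": "sbp_elevated", "source_field": "sbp", "encoding": "ge", "params": {"cutpoint": 130.0}},
    {"name": "triglyceride_elevated", "source_field": "triglyceride", "encoding": "ge", "params": {"cutpoint": 1.7}},
    {"name": "hdl_low", "source_field": "hdl", "encoding": "lt_by_sex", "params": {"male_cut": 1.0, "female_cut": 1.3}},
    {"name": "bmi_overweight", "source_field": "bmi", "encoding": "band", "params": {"low": 25.0, "high": 30.0}},
    {"name": "bmi_obese", "source_field": "bmi", "encoding": "ge", "params": {"cutpoint": 30.0}},
    {"name": "family_history", "source_field": "family_history_t2dm", "encoding": "indicator", "params": {}}
  ],
  "beta": [1.98, 0.50, 0.58, 0.94, 0.30, 0.92, 0.57]
}
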