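{
  "name": "SAHS",
  "provenance": "published",
  "intercept": null,
  "terms": [
    {"name": "age", "source_field": "age", "encoding": "linear", "params": {}},
    {"name": "gender", "source_field": "sex", "encoding": "female", "params": {}},
    {"name": "ethnicity", "source_field": "ethnicity", "encoding": "non_chinese", "params": {}},
    {"name": "fpg", "source_field": "fpg", "encoding": "linear", "params": {"factor": 18.0182}},
    {"name": "sbp", "source_field": "sbp", "encoding": "linear", "params": {}},
    {"name": "hdl", "source_field": "hdl", "encoding": "linear", "params": {"factor": 38.67}},
    {"name": "bmi", "source_field": "bmi", "encoding": "linear", "params": {}},
    {"name": "family_history", "source_field": "family_history_t2dm", "encoding": "indicator", "params": {}}
  ],
  "beta": [0.028, 0.661, 0.412, 0.079, 0.018, -0.039, 0.070, 0.481]
}
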