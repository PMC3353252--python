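{
  "name": "ARIC",
  "provenance": "published",
  "intercept": null,
  "terms": [
    {"name": "age", "source_field": "age", "encoding": "linear", "params": {}},
    {"name": "ethnicity", "source_field": "ethnicity", "encoding": "non_chinese", "params": {}},
    {"name": "fpg", "source_field": "fpg", "encoding": "linear", "params": {"factor": 18.0182}},
    {"name": "sbp", "source_field": "sbp", "encoding": "linear", "params": {}},
    {"name": "triglyceride", "source_field": "triglyceride", "encoding": "linear", "params": {"factor": 88.57}},
    {"name": "hdl", "source_field": "hdl", "encoding": "linear", "params": {"factor": 38.67}},
    {"name": "waist", "source_field": "waist", "encoding": "linear", "params": {}},
    {"name": "height", "source_field": "height", "encoding": "linear", "params": {}},
    {"name": "family_history", "source_field": "family_history_t2dm", "encoding": "indicator", "params": {}}
  ],
  "beta": [0.0173, 0.4433, 0.0880, 0.0111, 0.0027, -0.0122, 0.0273, -0.0326, 0.4981]
}
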