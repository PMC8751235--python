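{
  "prior_source": "possibility",
  "link_source": "possibility",
  "ie_link": 0.9,
  "top_link": 1.0,
  "leak": 0.0,
  "or_mode": "noisy-or",
  "evidence": {"TE": true},
  "roc_convention": "signed",
  "path_score": "min-edge",
  "pareto_threshold": 0.2,
  "pareto_exclude": ["RM", "OC", "OP"],
  "highlight_paths": [
    ["X3", "M2", "M9", "RM", "TE"],
    ["X1", "M1", "OC", "TE"],
    ["X4", "M7", "OP", "TE"]
  ]
}
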