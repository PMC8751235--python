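{
  "events": [
    {"id": "TE", "kind": "top", "label": "Suffocation accident during ship repair"},
    {"id": "RM", "kind": "intermediate", "label": "Inadequate human-resource management"},
    {"id": "OC", "kind": "intermediate", "label": "Poor organizational climate"},
    {"id": "OP", "kind": "intermediate", "label": "Flawed organizational process"},
    {"id": "M1", "kind": "intermediate", "label": "Risk-seeking with weak security awareness"},
    {"id": "M2", "kind": "intermediate", "label": "Poor competence"},
    {"id": "M3", "kind": "intermediate", "label": "Lack of working experience"},
    {"id": "M4", "kind": "intermediate", "label": "Lax daily safety management and inspection"},
    {"id": "M5", "kind": "intermediate", "label": "Failure to implement the safety management system and operating procedures"},
    {"id": "M6", "kind": "intermediate", "label": "Unreasonable ship-repair planning"},
    {"id": "M7", "kind": "intermediate", "label": "Inadequate guidelines for emergency rescue"},
    {"id": "M8", "kind": "intermediate", "label": "Inadequate on-site control"},
    {"id": "M9", "kind": "intermediate", "label": "Inadequate safety briefing and training"},
    {"id": "M10", "kind": "intermediate", "label": "Lack of team communication and cooperation"},
    {"id": "X1", "kind": "basic", "label": "Underestimation of hazardous situations"},
    {"id": "X2", "kind": "basic", "label": "Delay in emergency response"},
    {"id": "X3", "kind": "basic", "label": "Operating errors"},
    {"id": "X4", "kind": "basic", "label": "Emergency-response failure"},
    {"id": "X5", "kind": "basic", "label": "Improper use of personal protective equipment"},
    {"id": "X6", "kind": "basic", "label": "Poor risk perception prior to work"},
    {"id": "X7", "kind": "basic", "label": "Rescue attempted without a plan"},
    {"id": "X8", "kind": "basic", "label": "Entering a confined space without assessing the air"},
    {"id": "X9", "kind": "basic", "label": "Failure to observe the entry permit"},
    {"id": "X10", "kind": "basic", "label": "Poor teamwork: separate operation without monitoring"},
    {"id": "X11", "kind": "basic", "label": "Distracting behaviour during work"},
    {"id": "X12", "kind": "basic", "label": "Long duration of work in a confined space"},
    {"id": "X13", "kind": "basic", "label": "Dangerous situation not reported in time"},
    {"id": "X14", "kind": "basic", "label": "Multiple hazard sources"},
    {"id": "X15", "kind": "basic", "label": "Limitations of the operating environment"},
    {"id": "X16", "kind": "basic", "label": "Poor ventilation system"},
    {"id": "X17", "kind": "basic", "label": "Defective device"},
    {"id": "X18", "kind": "basic", "label": "Improper pipeline interconnection"},
    {"id": "X19", "kind": "basic", "label": "Failure of safety equipment"}
  ],
  "gates": [
    {"event": "TE", "type": "or", "inputs": ["RM", "OC", "OP"]},
    {"event": "RM", "type": "or", "inputs": ["M9", "M10"]},
    {"event": "OC", "type": "or", "inputs": ["M1", "M3"]},
    {"event": "OP", "type": "and", "inputs": ["M4", "M6", "M7", "M8"]},
    {"event": "M1", "type": "or", "inputs": ["X1", "X5", "X11"]},
    {"event": "M2", "type": "and", "inputs": ["X3", "X4"]},
    {"event": "M3", "type": "or", "inputs": ["X2", "X12"]},
    {"event": "M4", "type": "or", "inputs": ["X6", "X10"]},
    {"event": "M5", "type": "or", "inputs": ["X8", "X9"]},
    {"event": "M6", "type": "and", "inputs": ["X14", "X15"]},
    {"event": "M7", "type": "or", "inputs": ["X4", "X7", "X13"]},
    {"event": "M8", "type": "or", "inputs": ["X16", "X17", "X18", "X19"]},
    {"event": "M9", "type": "or", "inputs": ["M2", "M5"]},
    {"event": "M10", "type": "and", "inputs": ["X7", "X13"]}
  ]
}
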