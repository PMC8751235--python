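{
  "unsafe_acts": [
    {"factor": "UA1", "symbol": "X1", "category": "Errors", "label": "Underestimation of hazardous situations"},
    {"factor": "UA2", "symbol": "X2", "category": "Errors", "label": "Delay in emergency response"},
    {"factor": "UA3", "symbol": "X3", "category": "Errors", "label": "Operating errors"},
    {"factor": "UA4", "symbol": "X4", "category": "Errors", "label": "Emergency-response failure"},
    {"factor": "UA5", "symbol": "X5", "category": "Violations", "label": "Improper use of personal protective equipment"},
    {"factor": "UA6", "symbol": "X6", "category": "Violations", "label": "Poor risk perception prior to work"},
    {"factor": "UA7", "symbol": "X7", "category": "Violations", "label": "Rescue attempted without a plan"},
    {"factor": "UA8", "symbol": "X8", "category": "Violations", "label": "Entering a confined space without assessing the air"},
    {"factor": "UA9", "symbol": "X9", "category": "Violations", "label": "Failure to observe the entry permit"},
    {"factor": "UA10", "symbol": "X10", "category": "Violations", "label": "Poor teamwork: separate operation without monitoring"},
    {"factor": "UA11", "symbol": "X11", "category": "Violations", "label": "Distracting behaviour during work"},
    {"factor": "UA12", "symbol": "X12", "category": "Violations", "label": "Long duration of work in a confined space"},
    {"factor": "UA13", "symbol": "X13", "category": "Violations", "label": "Dangerous situation not reported in time"}
  ],
  "preconditions": [
    {"factor": "UP1", "symbol": "M1", "category": "Conditions of operators", "label": "Risk-seeking with weak security awareness"},
    {"factor": "UP2", "symbol": "M2", "category": "Conditions of operators", "label": "Poor competence"},
    {"factor": "UP3", "symbol": "M3", "category": "Conditions of operators", "label": "Lack of working experience"},
    {"factor": "UP4", "symbol": "X14", "category": "Environmental factors", "label": "Multiple hazard sources"},
    {"factor": "UP5", "symbol": "X15", "category": "Environmental factors", "label": "Limitations of the operating environment"},
    {"factor": "UP6", "symbol": "X16", "category": "Environmental factors", "label": "Poor ventilation system"},
    {"factor": "UP7", "symbol": "X17", "category": "Environmental factors", "label": "Defective device"},
    {"factor": "UP8", "symbol": "X18", "category": "Environmental factors", "label": "Improper pipeline interconnection"},
    {"factor": "UP9", "symbol": "X19", "category": "Environmental factors", "label": "Failure of safety equipment"}
  ],
  "unsafe_supervision": [
    {"factor": "US1", "symbol": "M4", "category": "Supervision", "label": "Lax daily safety management and inspection"},
    {"factor": "US2", "symbol": "M5", "category": "Supervision", "label": "Failure to implement the safety management system and operating procedures"},
    {"factor": "US3", "symbol": "M6", "category": "Supervision", "label": "Unreasonable ship-repair planning"},
    {"factor": "US4", "symbol": "M7", "category": "Supervision", "label": "Inadequate guidelines for emergency rescue"},
    {"factor": "US5", "symbol": "M8", "category": "Supervision", "label": "Inadequate on-site control"}
  ],
  "organizational_influences": [
    {"factor": "OI1", "symbol": "M9", "category": "Resource management", "label": "Inadequate safety briefing and training"},
    {"factor": "OI2", "symbol": "M10", "category": "Resource management", "label": "Lack of team communication and cooperation"},
    {"factor": "OI3", "symbol": "OC", "category": "Organizational climate", "label": "No positive safety culture and atmosphere"},
    {"factor": "OI4", "symbol": "OP", "category": "Organizational process", "label": "Safety management system needs modification"}
  ]
}
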