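[
  ["X1", "X2", "X3", "X5", "X6", "X7", "X8", "X9", "X10", "X11", "X12"],
  ["X1", "X2", "X3", "X5", "X6", "X8", "X9", "X10", "X11", "X12", "X13"],
  ["X1", "X2", "X3", "X5", "X7", "X8", "X9", "X11", "X12", "X14"],
  ["X1", "X2", "X3", "X5", "X7", "X8", "X9", "X11", "X12", "X15"],
  ["X1", "X2", "X3", "X5", "X7", "X8", "X9", "X11", "X12", "X16", "X17", "X18", "X19"],
  ["X1", "X2", "X3", "X5", "X8", "X9", "X11", "X12", "X13", "X14"],
  ["X1", "X2", "X3", "X5", "X8", "X9", "X11", "X12", "X13", "X15"],
  ["X1", "X2", "X3", "X5", "X8", "X9", "X11", "X12", "X13", "X16", "X17", "X18", "X19"],
  ["X1", "X2", "X4", "X5", "X6", "X7", "X8", "X9", "X10", "X11", "X12"],
  ["X1", "X2", "X4", "X5", "X6", "X8", "X9", "X10", "X11", "X12", "X13"],
  ["X1", "X2", "X4", "X5", "X7", "X8", "X9", "X11", "X12", "X13"],
  ["X1", "X2", "X4", "X5", "X7", "X8", "X9", "X11", "X12", "X14"],
  ["X1", "X2", "X4", "X5", "X7", "X8", "X9", "X11", "X12", "X15"],
  ["X1", "X2", "X4", "X5", "X7", "X8", "X9", "X11", "X12", "X16", "X17", "X18", "X19"],
  ["X1", "X2", "X4", "X5", "X8", "X9", "X11", "X12", "X13", "X14"],
  ["X1", "X2", "X4", "X5", "X8", "X9", "X11", "X12", "X13", "X15"],
  ["X1", "X2", "X4", "X5", "X8", "X9", "X11", "X12", "X13", "X16", "X17", "X18", "X19"]
]
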