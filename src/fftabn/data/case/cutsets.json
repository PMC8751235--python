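[
  ["X1"],
  ["X2"],
  ["X5"],
  ["X8"],
  ["X9"],
  ["X11"],
  ["X12"],
  ["X3", "X4"],
  ["X7", "X13"],
  ["X4", "X6", "X14", "X15", "X16"],
  ["X4", "X6", "X14", "X15", "X17"],
  ["X4", "X6", "X14", "X15", "X18"],
  ["X4", "X6", "X14", "X15", "X19"],
  ["X4", "X10", "X14", "X15", "X16"],
  ["X4", "X10", "X14", "X15", "X17"],
  ["X4", "X10", "X14", "X15", "X18"],
  ["X4", "X10", "X14", "X15", "X19"],
  ["X7", "X6", "X14", "X15", "X16"],
  ["X7", "X6", "X14", "X15", "X17"],
  ["X7", "X6", "X14", "X15", "X18"],
  ["X7", "X6", "X14", "X15", "X19"],
  ["X7", "X10", "X14", "X15", "X16"],
  ["X7", "X10", "X14", "X15", "X17"],
  ["X7", "X10", "X14", "X15", "X18"],
  ["X7", "X10", "X14", "X15", "X19"],
  ["X13", "X6", "X14", "X15", "X16"],
  ["X13", "X6", "X14", "X15", "X17"],
  ["X13", "X6", "X14", "X15", "X18"],
  ["X13", "X6", "X14", "X15", "X19"],
  ["X13", "X10", "X14", "X15", "X16"],
  ["X13", "X10", "X14", "X15", "X17"],
  ["X13", "X10", "X14", "X15", "X18"],
  ["X13", "X10", "X14", "X15", "X19"]
]
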