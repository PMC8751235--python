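{
  "errors_subgroup": {
    "indicators": ["X1", "X2", "X3", "X4"],
    "d_vector": [0.9277, 0.8661, 1.0, 0.8228],
    "parent_weight": 0.3324,
    "expected_sv": [0.2565, 0.2395, 0.2765, 0.2275],
    "expected_iv": [0.0853, 0.0796, 0.0919, 0.0756]
  },
  "m1_noisy_or": {
    "node": "M1",
    "parents": ["X1", "X5", "X11"],
    "links": [0.0853, 0.0396, 0.0402],
    "expected_all_active": 0.1568
  },
  "category_sv": {"Errors": 0.3324, "Violations": 0.3456, "Environmental factors": 0.3220}
}
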