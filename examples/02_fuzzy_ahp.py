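"""Run the extent-analysis fuzzy AHP chain and convert weights to probabilities.

Two stages are shown: (1) a full run from a synthetic fuzzy judgment matrix
(synthetic extents -> possibility degrees -> d-vector -> SV); (2) the bundled
case's worked subgroup, which starts from its published d-vector and ends in
Onisawa failure probabilities.
"""

from fftabn import (
    aggregate_judgments,
    failure_probability,
    integrate_iv,
    load_case,
    normalize_sv,
    weights_from_matrix,
)
from fftabn.synthetic import generate_judgment_matrix

# Stage 1: synthetic matrices for three experts, aggregated with equal weights.
matrices = [generate_judgment_matrix(seed, n=4) for seed in (1, 2, 3)]
aggregated = aggregate_judgments([m.cells for m in matrices], weights=[1 / 3] * 3)
result = weights_from_matrix(aggregated)
print("Synthetic 4-indicator example:")
print("  d-vector:", [round(v, 4) for v in result["d"]])
print("  SV      :", [round(v, 4) for v in result["sv"]])

# Stage 2: the case's documented subgroup, from its d-vector.
bundle = load_case()
ex = bundle.worked_example["errors_subgroup"]
sv = normalize_sv(ex["d_vector"])
iv = integrate_iv(ex["parent_weight"], sv)
print("\nCase subgroup (four error-type indicators):")
for name, s, i in zip(ex["indicators"], sv, iv):
    fp = failure_probability(i)
    print(f"  {name}: SV={s:.4f}  IV={i:.4f}  FP={fp:.3e}")
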