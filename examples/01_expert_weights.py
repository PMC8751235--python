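"""Score an expert panel with the credibility rubric and derive weights.

The bundled case ships a five-expert panel; each expert is scored on four
indicators (position, service years, education, job title) and the weights
are the scores normalized over the panel.
"""

from fftabn import credibility_fractions, credibility_weights, load_case, score_expert

bundle = load_case()

print("Per-expert scores (sum of four 1-5 indicator scores):")
for profile in bundle.panel:
    print(f"  {profile.id}: {score_expert(profile, bundle.rubric):2d}  "
          f"({profile.professional_position}; {profile.service_years} years)")

weights = credibility_weights(bundle.panel, bundle.rubric)
print("\nNormalized credibility weights:")
for expert_id, weight in weights.as_dict().items():
    print(f"  {expert_id}: {weight:.4f}")

print("\nAs exact rationals:")
for expert_id, frac in credibility_fractions(bundle.panel, bundle.rubric).items():
    print(f"  {expert_id}: {frac}")
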