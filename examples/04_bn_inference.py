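"""Map the case fault tree to a Bayesian network and run exact inference.

The mapping keeps repeated basic events as single shared nodes, renders OR
gates as Noisy-OR conditional tables (links from the possibility weights,
per the documented case configuration) and AND gates as deterministic
conjunctions.  Inference is exact variable elimination.
"""

from fftabn import build_case_bn, load_case, marginals, posterior

bundle = load_case()
net = build_case_bn(bundle)
print(f"Network: {len(net.nodes)} nodes, roots {len(net.roots())}")

p_te = posterior(net, "TE", {})
print(f"\nPrior probability of the top event: {p_te:.4f}")

print("\nDiagnosis: posteriors P(node | accident observed) for the organizational nodes:")
post = marginals(net, {"TE": True}, nodes=["RM", "OC", "OP", "M9", "M10"])
prior = marginals(net, {}, nodes=["RM", "OC", "OP", "M9", "M10"])
for node in post:
    print(f"  {node}: {prior[node]:.4f} -> {post[node]:.4f}")

print("\nPrediction: forcing an operating error (X3 observed True):")
print(f"  P(TE | X3) = {posterior(net, 'TE', {'X3': True}):.4f}  (prior {p_te:.4f})")
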