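# fftabn

Fuzzy fault-tree analysis mapped to Bayesian networks, for human-factor risk
modelling.

`fftabn` implements a complete quantitative risk pipeline for systems where
failure probabilities must be elicited from experts rather than measured:

1. **Expert credibility weighting** — experts are scored on a four-indicator
   rubric (professional position, service years, education, job title, each
   1–5); normalized scores become credibility weights, computed in exact
   rational arithmetic.
2. **Fuzzy AHP (extent analysis)** — per-expert pairwise comparisons are
   triangular fuzzy numbers on a linguistic scale; weighted aggregation,
   fuzzy synthetic extents, possibility degrees, and min-normalization yield
   crisp indicator weights (SV), integrated down the hierarchy (IV).
3. **Possibility → probability** — the Onisawa transform
   `FP = 10^(−K)`, `K = 2.301·((1−P)/P)^(1/3)` converts possibility weights
   to failure probabilities on a log-like scale.
4. **Fault-tree analysis** — typed AND/OR trees with validation; minimal cut
   sets by top-down expansion with Boolean absorption; minimal path sets by
   tree dualization or Berge's minimal-hitting-set transversal; top-event
   probability by bottom-up evaluation, inclusion–exclusion, or exact state
   enumeration when basic events repeat.
5. **Fault tree → Bayesian network** — events become binary nodes, repeated
   basic events become single shared parents; OR gates get Noisy-OR (or
   leaky Noisy-OR) conditional tables, AND gates deterministic ones.  With
   deterministic gates the network's top marginal provably equals the
   fault-tree probability — a property the test suite checks.
6. **Exact inference** — sum-product variable elimination (min-degree
   ordering, deterministic tie-breaks), validated against brute-force joint
   enumeration.
7. **Path ranking & sensitivity** — mutual-information scoring of
   cause-to-accident chains (bottleneck or total), ratio-of-change (RoC)
   sensitivity under evidence, and Pareto key-factor selection.

A fully worked case study — a suffocation accident during confined-space
ship repair, with 19 basic events, 13 intermediate events and a five-expert
panel — ships as a validated fixture and doubles as the regression baseline.

## Quick start

```python
from fftabn import (
    load_case, verify_reconstruction, build_case_bn,
    posterior, rank_paths, roc_analysis, pareto_key_factors,
)

bundle = load_case()
print(verify_reconstruction(bundle).ok)     # True — fixture self-check
tree = bundle.tree
print(len(tree.minimal_cut_sets()))         # 33
print(len(tree.minimal_path_sets()))        # 17

net = build_case_bn(bundle)
print(round(posterior(net, "TE", {}), 4))   # 0.0255 — prior accident probability

for r in rank_paths(net, paths=list(bundle.config.highlight_paths), score="min-edge"):
    print(round(r.min_edge, 4), " -> ".join(r.path))
```

Output:

```
True
33
17
0.0255
0.0168 X3 -> M2 -> M9 -> RM -> TE
0.0129 X1 -> M1 -> OC -> TE
0.0 X4 -> M7 -> OP -> TE
```

The operating-errors chain (X3 → poor competence → inadequate training →
resource management) is the dominant propagation path; observing the
accident raises the three organizational nodes' probabilities the most:

```python
records = roc_analysis(net, {"TE": True})
print([r.node for r in records[:3]])        # ['OC', 'RM', 'OP']
print([r.node for r in pareto_key_factors(records, 0.2, exclude=("RM", "OC", "OP"))])
# ['M10', 'M3', 'M9', 'M1', 'M5', 'M2']
```

More narrative walkthroughs live in `examples/` (one script per
capability); each prints its results when run directly.

## Command line

A thin CLI wraps the same functions:

```bash
fftabn convert --possibility 0.0919        # 1.15431e-05
fftabn cutsets                             # 33 minimal cut sets (JSON)
fftabn weights                             # expert credibility weights
fftabn sensitivity --round 4               # RoC ranking + Pareto key factors
fftabn reproduce-case --out report.json    # full pipeline, diffed vs fixtures
```

Run `fftabn --help` for all subcommands (`weights`, `ahp`, `convert`,
`cutsets`, `pathsets`, `build-bn`, `infer`, `mi-paths`, `sensitivity`,
`simulate`, `reproduce-case`).

## Repository layout

- `src/fftabn/` — the library; `data/case/` holds the case fixtures
  (plain JSON/CSV).
- `examples/` — short narrative scripts.
- `tests/` — unit, property-based (hypothesis) and acceptance tests.
  `tests/test_acceptance.py` contains one test per acceptance criterion;
  one documented criterion (Pareto key-factor membership) is intentionally
  left failing because it is unattainable in a probabilistically consistent
  network — see `docs/methods.md`.
- `scripts/acceptance.py` — recomputes the numeric acceptance targets from
  scratch: `python scripts/acceptance.py --seed 1 --out results/acceptance.json`.
- `docs/methods.md` — methods note: model conventions, the case
  configuration and its rationale, numerical choices, and limitations.

## Verification

```bash
pytest -q                 # full suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
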