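# Methods note

This note records the mathematical conventions, the bundled case
configuration, the synthetic-generator scope, the numerical choices, and
the known limitations of `fftabn`.

## 1. Model

### 1.1 Expert credibility

Each expert is scored on four indicators (professional position, service
years, education level, job title), each mapped to an integer 1–5 by a
rubric table.  An expert's comprehensive score is the sum (4–20); the
panel weights are the scores normalized by the panel total.  Because the
inputs are small integers, normalization is done in exact rational
arithmetic (`fractions.Fraction`) and only converted to floats at the API
boundary; the bundled panel's weights are exactly 19/80, 14/80, 15/80,
19/80, 13/80.

### 1.2 Fuzzy judgments and aggregation

Judgments are triangular fuzzy numbers (TFNs) `(l, m, u)` with tent
membership.  Arithmetic is componentwise for addition and multiplication;
the fuzzy inverse is the triangular approximation `(1/u, 1/m, 1/l)`.
Per-expert reciprocal matrices are aggregated by the credibility-weighted
arithmetic mean of the **upper triangle only**; the lower triangle is then
rebuilt as the TFN inverse, because a convex combination of reciprocal
matrices is not itself reciprocal.

### 1.3 Extent-analysis AHP

For an aggregated matrix, row sums are normalized by the inverted grand
sum to give fuzzy synthetic extents `D_i`.  The possibility degree
`V(a ≥ b)` is 1 when `m_a ≥ m_b`, 0 when the supports are disjoint with
`b` above `a`, and otherwise the intersection height
`(l_b − u_a) / ((m_a − u_a) − (m_b − l_b))` — the geometric definition.
(Printed restatements of this formula sometimes drop a sign and leave the
unit interval; the geometric form is the one whose numbers the bundled
worked example reproduces.)  The d-vector is `d_i = min_{j≠i} V(D_i ≥ D_j)`;
normalizing gives the standard values SV; multiplying by the parent
weight (itself a product down the hierarchy) gives globally comparable
integrated values IV.

### 1.4 Possibility → probability

The Onisawa transform `FP = 10^(−K)`, `K = 2.301·((1−P)/P)^(1/3)`, with
`FP(0) = 0` by continuity.  It is strictly increasing on (0, 1] and maps
`P = 0.5` to about `5·10⁻³`.  The bundled weight table stores both the
possibility (IV) and probability (FP) columns; all 22 rows round-trip
within 1% relative error, which is the comparison tolerance used
throughout (the stored FP values carry 3 significant figures).

### 1.5 Fault trees

Trees are typed: one top event, intermediate events with exactly one gate
and one parent each, AND/OR gates, basic events that may feed several
gates (shared/repeated events).  Validation checks acyclicity, single
definition, dangling references, and reachability.

* **Minimal cut sets (MCS)** — top-down gate expansion (OR splits rows,
  AND joins columns) with Boolean absorption after every round.
* **Minimal path sets (MPS)** — either dualize the tree (swap AND/OR) and
  take its MCS, or compute minimal hitting sets of the MCS family by
  Berge's incremental transversal; both routes are implemented and
  cross-checked.
* **Top-event probability** — bottom-up evaluation when no basic event
  repeats (exact by independence); otherwise inclusion–exclusion over the
  MCS family (small families) or exact enumeration of basic-event states
  (≤ 24 basic events).  The bundled case tree has repeats and 33 cut
  sets, so it uses enumeration.

Cut/path-set families are kept as antichains sorted by (cardinality,
lexicographic member ids), making serialization deterministic.

### 1.6 Mapping to a Bayesian network

Every event becomes a binary node (True = occurs/fails).  A repeated
basic event becomes a single root node with converging arcs, which is the
point where the network generalizes the tree.  Gate tables:

* AND → deterministic conjunction.
* OR → Noisy-OR: `P(child | parents) = 1 − Π_{active} (1 − c_i)` with one
  link probability `c_i` per arc; the leaky variant multiplies in a leak
  term `(1 − l)` so the child can fire with all parents inactive.  The
  leak defaults to 0 and is configurable per gate.

With all links 1 and leak 0 the OR table is deterministic, and the
network's top-event marginal equals the fault-tree probability — the
"determinism limit" property tested on random trees.

### 1.7 Inference, information, sensitivity

Inference is exact sum-product variable elimination with a min-degree
elimination heuristic and deterministic (sorted-name) tie-breaking,
validated against brute-force joint enumeration on networks of ≤ 15–20
nodes at 1e-9 tolerance.  Entropies are in nats; mutual information is
`I(X;Y) = H(X) − H(X|Y)` from exact pairwise joints, clipped at 0 against
rounding.  A propagation path is a chain of arcs from a root cause to the
accident node, scored by its minimum-MI edge (bottleneck; the default) or
by the total.  Ratio of change is `RoC = (ξ − ζ)/ζ` for prior ζ and
posterior ξ under evidence (signed by default; a magnitude convention is
available).  Pareto key factors are the top `ceil(0.2·n)` of the RoC
ranking after excluding a configured node set.

## 2. The bundled case

The case models a suffocation accident during confined-space ship repair:
31 human factors in four layers (13 unsafe acts, 9 preconditions, 5
supervision, 4 organizational), of which 19 map to basic events X1–X19,
10 to intermediate events M1–M10, and the organizational categories to
RM/OC/OP under the top event.

### 2.1 Fault-tree reconstruction

The fixture tree was reconstructed from documented structural facts: the
event and gate counts (19 BE / 13 IE / 10 OR / 4 AND), the documented
parent sets (TE = OR(RM, OC, OP), M1 = OR(X1, X5, X11)), the documented
cause-chains, and — decisively — the transcribed list of 33 minimal cut
sets, whose 24 five-element members factor exactly as
`(X4∨X7∨X13) ∧ (X6∨X10) ∧ X14 ∧ X15 ∧ (X16∨X17∨X18∨X19)`.
These constraints pin the tree uniquely up to input order.
`verify_reconstruction` re-derives the MCS family from the tree on every
load and fails loudly on any mismatch; the dualized family reproduces the
17 transcribed path sets, 4 of which contain 13 basic events.  One
transcription cell was corrected: the source transcription lists a five-element
cut set containing X1, which would be absorbed by the singleton {X1} and
break the antichain (and the count of 33); the consistent reading is X16,
matching the X16–X19 enumeration pattern of the neighbouring sets.

### 2.2 Case configuration

The raw per-expert fuzzy matrices behind the weight table are not part of
the bundle, so the case pipeline starts from the documented d-vector /
SV / IV values (the elicitation stages are exercised by synthetic data
instead).  The network build follows `data/case/case_config.json`:

| setting | value | rationale |
|---|---|---|
| `prior_source`, `link_source` | `possibility` | the documented Noisy-OR worked row uses possibility weights as links; priors use the same scale for internal consistency |
| `ie_link` | 0.9 | intermediate-to-intermediate links are not documented; a high link keeps aggregation near-deterministic while distinguishing multi-cause gates |
| `top_link` | 1.0 | the accident is defined as the disjunction of its three categories |
| `leak` | 0.0 | the leak value is not documented; zero is the documented default |
| `evidence` | `TE = True` | diagnostic analysis of the observed accident |
| `roc_convention` | `signed` | with confirming evidence, signed and magnitude orderings coincide |
| `path_score` | `min-edge` | a chain is as strong as its weakest dependence |
| `pareto_threshold`, `pareto_exclude` | 0.2, {RM, OC, OP} | top-20% after removing the aggregate organizational nodes |

Under this configuration the pipeline reproduces the documented *ordinal*
claims: the three organizational nodes occupy the top three RoC ranks
strictly, and the operating-errors chain X3→M2→M9→RM→TE outranks the
other two documented representative chains (X1→M1→OC→TE and
X4→M7→OP→TE) under bottleneck-MI scoring.

### 2.3 A documented claim that cannot hold (left RED)

The bundled reference analysis also asserts that the Pareto key factors
include {M10, X3, X7, M7, X8}.  This is unattainable in any
probabilistically consistent configuration of this model, for a
structural reason: under top-event evidence, an OR-aggregate intermediate
event is (weakly) more probable than each of its basic-event causes both
a priori and a posteriori, and its ratio of change is correspondingly at
least as large; with priors on the possibility scale the six intermediate
events M1–M3, M5, M9, M10 strictly outrank every X node, filling the
six-slot top-20% quota (29 candidate nodes) before X3, X7 or X8 can
enter.  Likewise, inside the AND gate M2 = X3 ∧ X4, the less probable
parent always carries *more* mutual information with the gate (because
`H(Bern(p))/p` is decreasing), so variants of the claim that rank X3
above X4 within that branch by MI are equally impossible.  The
corresponding acceptance test (`test_criterion_7_pareto_membership`) is
intentionally left failing — not skipped and not weakened — to record the
discrepancy; the reference ranking was evidently produced under
additional, undocumented modelling choices (leak values, node grouping)
that are not recoverable from the available material.

## 3. Synthetic generators

`generate_tree(seed, n_be, n_ie, and_fraction)` emits valid trees with
every basic event reachable from the top; `generate_panel` and
`generate_judgment_matrix` emit rubric-consistent profiles and
reciprocal fuzzy matrices.  All generators use one named
`numpy.random.default_rng` stream per call with the seed explicit in the
API and logs, and are bit-reproducible per seed.  They exist to exercise
the elicitation and structural stages at arbitrary scale (property tests
run the full pipeline for 50 seeds); they make no attempt to mimic the
statistics of real expert panels.

## 4. Numerical choices

* Exact rational arithmetic for credibility weights; floats elsewhere.
* Matrix reciprocity checked to 1e-6 (aggregated inverses are triangular
  approximations); probability identities asserted at 1e-9 to 1e-12.
* Comparisons against stored 3-significant-figure probabilities use 1%
  relative tolerance; 4-decimal weight tables use 5e-5 absolute.
* Enumeration guards: brute-force joints ≤ 20 nodes, basic-event state
  enumeration ≤ 24 events, inclusion–exclusion ≤ 18 cut sets.
* Elimination order: min-degree with lexicographic tie-break, so results
  and runtimes are machine-independent.

## 5. Limitations

* **Ordinal, not cardinal, sensitivity validation.**  The case RoC
  magnitudes depend on undocumented leak and link values; only rank
  properties are asserted.  The qualitative checks do not validate the
  absolute posterior scale of the case network.
* **Possibility-scale priors.**  The case configuration deliberately uses
  possibility weights (not Onisawa probabilities) as priors and links, to
  match the documented worked row; the resulting marginals are risk
  *indices*, not frequencies.  Switching `prior_source`/`link_source` to
  `probability` gives frequency-scale outputs but changes every number.
* **Extent-analysis AHP caveats.**  Chang's method can assign zero weight
  to alternatives whose extents are dominated (visible in the synthetic
  example); this is a property of the method, not a bug.
* **Tree reconstruction.**  The fixture tree is the unique structure
  consistent with all documented constraints, but the original drawing
  was not available; labels on intermediate events follow the documented
  factor taxonomy interpretation (three organizational categories plus
  M9/M10 under resource management).
* **No continuous or multi-state variables.**  Everything is binary;
  degradation states and common-cause groups are out of scope.
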