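"""Binary Bayesian networks mapped from fault trees, with canonical CPTs.

Mapping rules: every fault-tree event becomes a binary node (``True`` =
occurrence/failure), arcs run from gate inputs to the gated event
(cause → consequence), basic events keep their priors, and each gate is
replaced by an equivalent conditional probability table:

* OR gates use the Noisy-OR canonical model,
  ``P(Y=T | X) = 1 - (1 - l) * prod_{Xi active} (1 - p_i)``,
  where ``p_i`` is the per-parent link probability and ``l`` an optional
  leak absorbing causes outside the model (``l = 0`` recovers the plain
  Noisy-OR; all ``p_i = 1`` with ``l = 0`` recovers the deterministic gate);
* AND gates are deterministic: the child is ``True`` iff all parents are.

Repeated basic events become shared parents (converging arcs), not
duplicated nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np

from .faulttree import AND, OR, FaultTree


@dataclass(frozen=True)
class NoisyOrSpec:
    """Per-parent link probabilities and a leak for one OR-type node."""

    link: tuple[float, ...]
    leak: float = 0.0

    def __post_init__(self) -> None:
        if any(not (0.0 <= p <= 1.0) for p in self.link):
            raise ValueError("link probabilities must lie in [0, 1]")
        if not (0.0 <= self.leak <= 1.0):
            raise ValueError("leak must lie in [0, 1]")


def noisy_or_row(spec: NoisyOrSpec, active: Sequence[bool]) -> float:
    """P(child = True) for one parent configuration under plain Noisy-OR."""
    if len(active) != len(spec.link):
        raise ValueError("one activity flag per parent is required")
    prod = 1.0
    for p, a in zip(spec.link, active):
        if a:
            prod *= 1.0 - p
    return 1.0 - prod


def leaky_noisy_or_row(spec: NoisyOrSpec, active: Sequence[bool]) -> float:
    """P(child = True) under leaky Noisy-OR; equals the plain row at leak 0."""
    return 1.0 - (1.0 - spec.leak) * (1.0 - noisy_or_row(spec, active))


class BayesNode:
    """One binary node: ordered parents and a CPT giving P(True | parents).

    ``cpt`` maps each tuple of parent booleans (in parent order) to
    P(node = True); root nodes hold a single prior under the empty tuple.
    """

    def __init__(self, name: str, parents: Sequence[str], cpt: Mapping[tuple, float]):
        self.name = name
        self.parents = tuple(parents)
        expected = set(product((False, True), repeat=len(self.parents)))
        if set(cpt) != expected:
            raise ValueError(
                f"node {name!r}: CPT must cover all {len(expected)} parent configurations"
            )
        bad = {k: v for k, v in cpt.items() if not (0.0 <= v <= 1.0)}
        if bad:
            raise ValueError(f"node {name!r}: CPT entries outside [0, 1]: {bad}")
        self.cpt = dict(cpt)

    def p_true(self, parent_states: Sequence[bool]) -> float:
        return self.cpt[tuple(bool(s) for s in parent_states)]

    def prob(self, state: bool, parent_states: Sequence[bool]) -> float:
        p = self.p_true(parent_states)
        return p if state else 1.0 - p


class BayesNet:
    """A DAG of binary :class:`BayesNode` objects with True/False states."""

    def __init__(self, nodes: Sequence[BayesNode]):
        self.nodes = {n.name: n for n in nodes}
        if len(self.nodes) != len(nodes):
            raise ValueError("duplicate node names")
        for n in nodes:
            for p in n.parents:
                if p not in self.nodes:
                    raise ValueError(f"node {n.name!r} has unknown parent {p!r}")
        self.order = self._topological_order()

    def _topological_order(self) -> list[str]:
        indeg = {name: len(n.parents) for name, n in self.nodes.items()}
        children: dict[str, list[str]] = {name: [] for name in self.nodes}
        for n in self.nodes.values():
            for p in n.parents:
                children[p].append(n.name)
        frontier = sorted(name for name, d in indeg.items() if d == 0)
        order: list[str] = []
        while frontier:
            name = frontier.pop(0)
            order.append(name)
            for c in children[name]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    frontier.append(c)
            frontier.sort()
        if len(order) != len(self.nodes):
            raise ValueError("the network graph contains a cycle")
        return order

    def roots(self) -> list[str]:
        return [name for name, n in self.nodes.items() if not n.parents]

    def joint_probability(self, assignment: Mapping[str, bool]) -> float:
        """Probability of one full state map: the product of CPT lookups."""
        missing = set(self.nodes) - set(assignment)
        if missing:
            raise KeyError(f"assignment missing nodes: {sorted(missing)}")
        p = 1.0
        for name, node in self.nodes.items():
            parent_states = [assignment[q] for q in node.parents]
            p *= node.prob(bool(assignment[name]), parent_states)
        return p

    def to_dict(self) -> dict:
        out = {"nodes": []}
        for name in self.order:
            node = self.nodes[name]
            out["nodes"].append(
                {
                    "name": name,
                    "parents": list(node.parents),
                    "cpt": {
                        "|".join("T" if s else "F" for s in key): val
                        for key, val in sorted(node.cpt.items())
                    },
                }
            )
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "BayesNet":
        nodes = []
        for spec in data["nodes"]:
            cpt = {
                tuple(tok == "T" for tok in key.split("|")) if key else (): val
                for key, val in spec["cpt"].items()
            }
            nodes.append(BayesNode(spec["name"], spec["parents"], cpt))
        return cls(nodes)


# -- gate policies -------------------------------------------------------


@dataclass
class GatePolicy:
    """How to turn fault-tree gates into CPTs.

    ``links``: per (child, parent) link probability for OR gates.  Entries
    may be filled explicitly, or generated from ``default_link`` /
    ``be_link`` / ``ie_link`` values.  ``or_mode`` selects plain
    ``"noisy-or"`` or ``"leaky"`` rows (the leaky model is the fallback the
    canonical-model workflow prescribes when the all-parents-active Noisy-OR
    row is below 1 and unmodelled causes should be absorbed).  AND gates are
    always deterministic.
    """

    links: dict[tuple[str, str], float] = field(default_factory=dict)
    leak: float | Mapping[str, float] = 0.0
    or_mode: str = "noisy-or"  # "noisy-or" | "leaky" | "deterministic"

    def leak_for(self, child: str) -> float:
        if isinstance(self.leak, Mapping):
            return float(self.leak.get(child, 0.0))
        return float(self.leak)

    def link_for(self, child: str, parent: str) -> float:
        try:
            return self.links[(child, parent)]
        except KeyError:
            raise KeyError(
                f"no link probability configured for OR gate {child!r} <- {parent!r}"
            ) from None


def and_gate_cpt(n_parents: int) -> dict[tuple, float]:
    """Deterministic AND table: P(True) = 1 iff every parent is True."""
    if n_parents < 1:
        raise ValueError("an AND gate needs at least one parent")
    return {
        key: 1.0 if all(key) else 0.0
        for key in product((False, True), repeat=n_parents)
    }


def or_gate_cpt(spec: NoisyOrSpec, use_leak: bool | None = None) -> dict[tuple, float]:
    """(Leaky) Noisy-OR table over all parent configurations.

    When ``use_leak`` is None the leaky rows are used exactly when the
    exhaustiveness check fails — i.e. the all-parents-active plain row is
    below 1 — and a nonzero leak is configured; this mirrors the canonical
    equivalent-CPT workflow.
    """
    n = len(spec.link)
    if use_leak is None:
        all_active_row = noisy_or_row(spec, [True] * n)
        use_leak = all_active_row < 1.0 and spec.leak > 0.0
    row = leaky_noisy_or_row if use_leak else noisy_or_row
    return {key: row(spec, key) for key in product((False, True), repeat=n)}


def equivalent_cpt(
    gate_type: str,
    parents: Sequence[str],
    child: str,
    policy: GatePolicy,
) -> dict[tuple, float]:
    """Equivalent CPT for one gate under the configured policy."""
    if gate_type == AND:
        return and_gate_cpt(len(parents))
    if gate_type != OR:
        raise ValueError(f"unknown gate type {gate_type!r}")
    if policy.or_mode == "deterministic":
        spec = NoisyOrSpec(link=tuple(1.0 for _ in parents), leak=0.0)
        return or_gate_cpt(spec, use_leak=False)
    spec = NoisyOrSpec(
        link=tuple(policy.link_for(child, p) for p in parents),
        leak=policy.leak_for(child),
    )
    if policy.or_mode == "leaky":
        return or_gate_cpt(spec, use_leak=True)
    return or_gate_cpt(spec, use_leak=None)


def map_ft_to_bn(
    tree: FaultTree,
    priors: Mapping[str, float],
    policy: GatePolicy | None = None,
) -> BayesNet:
    """Map a fault tree into a Bayesian network.

    Every event becomes one node; gate inputs become parents (a repeated
    basic event yields converging arcs from a single shared node); basic
    events carry ``priors`` as root priors; each gate contributes its
    equivalent CPT.  With the ``deterministic`` OR mode and zero leak, the
    TE marginal of the network equals the fault tree's analytic top-event
    probability.
    """
    if policy is None:
        policy = GatePolicy(or_mode="deterministic")
    missing = [b for b in tree.basic_events if b not in priors]
    if missing:
        raise KeyError(f"missing priors for basic events: {sorted(missing)}")
    nodes = [
        BayesNode(b, (), {(): float(priors[b])}) for b in tree.basic_events
    ]
    for event, gate in tree.gates.items():
        cpt = equivalent_cpt(gate.type, gate.inputs, event, policy)
        nodes.append(BayesNode(event, gate.inputs, cpt))
    return BayesNet(nodes)
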