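"""Exact inference on binary Bayesian networks by variable elimination.

The networks this package builds are small (a few dozen binary nodes) and
sparse, so exact sum-product variable elimination with a min-degree
elimination order is both simple and fast.  The same machinery answers
single-node posteriors, multi-node joint queries (needed for mutual
information), and evidence likelihoods.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

from .bn import BayesNet


class ImpossibleEvidenceError(ValueError):
    """Raised when the observed evidence has zero probability under the model."""


class _Factor:
    """A dense factor over an ordered tuple of binary variables."""

    __slots__ = ("vars", "table")

    def __init__(self, variables: Sequence[str], table: np.ndarray):
        self.vars = tuple(variables)
        self.table = np.asarray(table, dtype=float).reshape([2] * len(self.vars))

    def multiply(self, other: "_Factor") -> "_Factor":
        merged = list(self.vars) + [v for v in other.vars if v not in self.vars]
        a = self._broadcast(merged)
        b = other._broadcast(merged)
        return _Factor(merged, a * b)

    def _broadcast(self, merged: Sequence[str]) -> np.ndarray:
        # Move own axes into the merged layout, adding singleton axes for
        # variables this factor does not mention.
        shape = [2 if v in self.vars else 1 for v in merged]
        src_axes = [merged.index(v) for v in self.vars]
        out = self.table
        if self.vars:
            order = np.argsort(src_axes)
            out = np.transpose(out, axes=order)
        return out.reshape([s if s == 2 else 1 for s in shape])

    def marginalize(self, var: str) -> "_Factor":
        axis = self.vars.index(var)
        remaining = tuple(v for v in self.vars if v != var)
        return _Factor(remaining, self.table.sum(axis=axis))

    def reduce(self, var: str, value: bool) -> "_Factor":
        axis = self.vars.index(var)
        remaining = tuple(v for v in self.vars if v != var)
        taken = np.take(self.table, 1 if value else 0, axis=axis)
        return _Factor(remaining, taken)


def _node_factor(net: BayesNet, name: str) -> _Factor:
    node = net.nodes[name]
    variables = list(node.parents) + [name]
    shape = [2] * len(variables)
    table = np.empty(shape, dtype=float)
    for key in product((False, True), repeat=len(node.parents)):
        p = node.p_true(key)
        idx = tuple(1 if s else 0 for s in key)
        table[idx + (0,)] = 1.0 - p
        table[idx + (1,)] = p
    return _Factor(variables, table)


def _check_evidence(net: BayesNet, evidence: Mapping[str, bool]) -> dict[str, bool]:
    ev = {}
    for k, v in (evidence or {}).items():
        if k not in net.nodes:
            raise KeyError(f"evidence node {k!r} is not in the network")
        if isinstance(v, str):
            token = v.strip().lower()
            if token not in ("true", "false"):
                raise ValueError(f"evidence state for {k!r} must be True or False, got {v!r}")
            v = token == "true"
        ev[k] = bool(v)
    return ev


def _eliminate(
    factors: list[_Factor], keep: set[str], tiebreak: Sequence[str]
) -> _Factor:
    """Sum out all variables not in ``keep`` using min-degree ordering."""
    rank = {v: i for i, v in enumerate(tiebreak)}
    while True:
        hidden = sorted(
            {v for f in factors for v in f.vars} - keep,
            key=lambda v: rank.get(v, len(rank)),
        )
        if not hidden:
            break
        # min-degree: eliminate the hidden variable appearing with the
        # fewest distinct neighbours; deterministic tie-break by node id.
        def degree(v: str) -> int:
            neigh = set()
            for f in factors:
                if v in f.vars:
                    neigh.update(f.vars)
            return len(neigh - {v})

        var = min(hidden, key=lambda v: (degree(v), rank.get(v, len(rank))))
        involved = [f for f in factors if var in f.vars]
        rest = [f for f in factors if var not in f.vars]
        prod = involved[0]
        for f in involved[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.marginalize(var)]
    out = factors[0]
    for f in factors[1:]:
        out = out.multiply(f)
    return out


def joint_query(
    net: BayesNet,
    query: Sequence[str],
    evidence: Mapping[str, bool] | None = None,
    order: Sequence[str] | None = None,
) -> _Factor:
    """Unnormalized-then-normalized joint posterior over ``query`` nodes.

    Returns a factor whose table sums to 1 over the query variables.
    Raises :class:`ImpossibleEvidenceError` when the evidence has zero
    likelihood.
    """
    ev = _check_evidence(net, evidence or {})
    for q in query:
        if q not in net.nodes:
            raise KeyError(f"query node {q!r} is not in the network")
        if q in ev:
            raise ValueError(f"node {q!r} is both query and evidence")
    factors = []
    for name in net.order:
        f = _node_factor(net, name)
        for e, val in ev.items():
            if e in f.vars:
                f = f.reduce(e, val)
        factors.append(f)
    tiebreak = order if order is not None else sorted(net.nodes)
    result = _eliminate(factors, set(query), tiebreak)
    # reorder axes to match the requested query order
    if tuple(result.vars) != tuple(query):
        axes = [result.vars.index(q) for q in query]
        result = _Factor(query, np.transpose(result.table, axes=axes))
    z = result.table.sum()
    if z <= 0.0:
        raise ImpossibleEvidenceError("evidence has zero probability under the model")
    return _Factor(result.vars, result.table / z)


def posterior(
    net: BayesNet,
    node: str,
    evidence: Mapping[str, bool] | None = None,
    order: Sequence[str] | None = None,
) -> float:
    """P(node = True | evidence); the prior P(True) with empty evidence."""
    ev = _check_evidence(net, evidence or {})
    if node in ev:
        return 1.0 if ev[node] else 0.0
    f = joint_query(net, [node], ev, order=order)
    return float(f.table[1])


def marginals(
    net: BayesNet,
    evidence: Mapping[str, bool] | None = None,
    nodes: Iterable[str] | None = None,
) -> dict[str, float]:
    """P(True) for every requested node (default: all) given the evidence."""
    targets = list(nodes) if nodes is not None else list(net.order)
    return {t: posterior(net, t, evidence) for t in targets}


def evidence_probability(net: BayesNet, evidence: Mapping[str, bool]) -> float:
    """Marginal likelihood P(evidence)."""
    ev = _check_evidence(net, evidence)
    if not ev:
        return 1.0
    factors = []
    for name in net.order:
        f = _node_factor(net, name)
        for e, val in ev.items():
            if e in f.vars:
                f = f.reduce(e, val)
        factors.append(f)
    result = _eliminate(factors, set(), sorted(net.nodes))
    return float(result.table)


def brute_force_joint(net: BayesNet) -> dict[tuple, float]:
    """Full joint table by enumeration; the small-network oracle."""
    names = list(net.order)
    if len(names) > 20:
        raise ValueError("brute-force enumeration is limited to 20 nodes")
    out = {}
    for states in product((False, True), repeat=len(names)):
        assignment = dict(zip(names, states))
        out[states] = net.joint_probability(assignment)
    return out
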