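"""Shared fixtures and oracles for the test suite."""

from __future__ import annotations

from itertools import chain, combinations, product

import numpy as np
import pytest

from fftabn.bn import BayesNet, BayesNode
from fftabn.case import load_case


@pytest.fixture(scope="session")
def bundle():
    return load_case()


def truth_table_mcs(tree):
    """Minimal true points of the tree's structure function (oracle)."""
    bes = tree.basic_events
    assert len(bes) <= 12, "oracle is exponential; keep trees small"
    true_sets = []
    for states in product((False, True), repeat=len(bes)):
        assignment = dict(zip(bes, states))
        if tree.evaluate(assignment):
            true_sets.append(frozenset(b for b, s in assignment.items() if s))
    return _minimal(true_sets)


def truth_table_mps(tree):
    """Minimal false points: complements of maximal non-failing states."""
    bes = tree.basic_events
    assert len(bes) <= 12
    false_sets = []
    for states in product((False, True), repeat=len(bes)):
        assignment = dict(zip(bes, states))
        if not tree.evaluate(assignment):
            false_sets.append(frozenset(b for b, s in assignment.items() if not s))
    return _minimal(false_sets)


def _minimal(family):
    out = []
    for s in sorted(set(family), key=len):
        if not any(t <= s for t in out):
            out.append(s)
    return set(out)


def random_binary_net(seed: int, n_nodes: int, max_parents: int = 3) -> BayesNet:
    """Random DAG of binary nodes with random CPTs, deterministic per seed."""
    rng = np.random.default_rng(seed)
    names = [f"N{i}" for i in range(n_nodes)]
    nodes = []
    for i, name in enumerate(names):
        k = int(rng.integers(0, min(i, max_parents) + 1))
        parents = tuple(sorted(rng.choice(names[:i], size=k, replace=False))) if k else ()
        cpt = {
            states: float(rng.uniform(0.05, 0.95))
            for states in product((False, True), repeat=len(parents))
        }
        nodes.append(BayesNode(name, parents, cpt))
    return BayesNet(nodes)


def powerset(iterable):
    s = list(iterable)
    return chain.from_iterable(combinations(s, r) for r in range(len(s) + 1))
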