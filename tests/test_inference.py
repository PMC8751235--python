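"""Exact inference: variable elimination against brute-force enumeration."""

from itertools import product

import pytest

from fftabn import (
    ImpossibleEvidenceError,
    brute_force_joint,
    evidence_probability,
    joint_query,
    marginals,
    posterior,
)
from fftabn.bn import BayesNode, BayesNet

from conftest import random_binary_net


def bf_marginal(net, node, evidence=None):
    """Posterior from the enumerated joint (the oracle)."""
    evidence = evidence or {}
    names = list(net.order)
    joint = brute_force_joint(net)
    num = den = 0.0
    for states, p in joint.items():
        assignment = dict(zip(names, states))
        if any(assignment[k] != v for k, v in evidence.items()):
            continue
        den += p
        if assignment[node]:
            num += p
    return num / den


@pytest.mark.parametrize("seed", range(10))
def test_ve_matches_brute_force_priors(seed):
    net = random_binary_net(seed, n_nodes=9)
    for node in net.order:
        assert posterior(net, node, {}) == pytest.approx(bf_marginal(net, node), abs=1e-9)


@pytest.mark.parametrize("seed", range(6))
def test_ve_matches_brute_force_with_evidence(seed):
    net = random_binary_net(seed + 100, n_nodes=8)
    ev_node = net.order[-1]
    evidence = {ev_node: True}
    for node in net.order[:-1]:
        assert posterior(net, node, evidence) == pytest.approx(
            bf_marginal(net, node, evidence), abs=1e-9
        )


def test_larger_net_spot_check():
    net = random_binary_net(7, n_nodes=15)
    ev = {net.order[-1]: False}
    for node in (net.order[0], net.order[5], net.order[10]):
        assert posterior(net, node, ev) == pytest.approx(bf_marginal(net, node, ev), abs=1e-9)


def test_joint_query_normalized_and_ordered():
    net = random_binary_net(3, n_nodes=6)
    a, b = net.order[0], net.order[3]
    f = joint_query(net, [a, b])
    assert f.vars == (a, b)
    assert f.table.sum() == pytest.approx(1.0, abs=1e-12)
    g = joint_query(net, [b, a])
    assert g.table[0, 1] == pytest.approx(f.table[1, 0], abs=1e-12)


def test_evidence_probability_matches_enumeration():
    net = random_binary_net(11, n_nodes=7)
    ev = {net.order[2]: True, net.order[-1]: False}
    joint = brute_force_joint(net)
    names = list(net.order)
    expect = sum(
        p
        for states, p in joint.items()
        if all(dict(zip(names, states))[k] == v for k, v in ev.items())
    )
    assert evidence_probability(net, ev) == pytest.approx(expect, abs=1e-12)


def test_impossible_evidence_raises():
    a = BayesNode("A", (), {(): 0.5})
    b = BayesNode("B", ("A",), {(False,): 0.0, (True,): 1.0})  # B == A
    c = BayesNode("C", (), {(): 0.5})
    net = BayesNet([a, b, c])
    with pytest.raises(ImpossibleEvidenceError):
        joint_query(net, ["C"], {"A": False, "B": True})


def test_query_node_cannot_be_evidence():
    net = random_binary_net(17, n_nodes=4)
    n = net.order[0]
    with pytest.raises(ValueError):
        joint_query(net, [n], {n: True})


def test_marginals_cover_requested_nodes():
    net = random_binary_net(5, n_nodes=6)
    out = marginals(net, {}, nodes=net.order[:3])
    assert list(out) == net.order[:3]


def test_evidence_node_posterior_is_indicator():
    net = random_binary_net(9, n_nodes=5)
    n = net.order[0]
    assert posterior(net, n, {n: True}) == 1.0
    assert posterior(net, n, {n: False}) == 0.0


def test_string_evidence_accepted():
    net = random_binary_net(13, n_nodes=5)
    n0, n1 = net.order[0], net.order[1]
    assert posterior(net, n1, {n0: "True"}) == pytest.approx(
        posterior(net, n1, {n0: True}), abs=1e-12
    )
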