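"""Entropy, mutual information, and path ranking."""

import math

import pytest

from fftabn import (
    BayesNet,
    BayesNode,
    conditional_entropy,
    entropy,
    mutual_information,
    node_entropy,
    rank_paths,
    score_path,
)
from fftabn.infotheory import enumerate_root_paths

from conftest import random_binary_net


def test_entropy_basics():
    assert entropy([0.5, 0.5]) == pytest.approx(math.log(2))
    assert entropy([1.0, 0.0]) == 0.0
    with pytest.raises(ValueError):
        entropy([0.6, 0.6])
    with pytest.raises(ValueError):
        entropy([-0.1, 1.1])


def test_self_information_is_entropy():
    net = random_binary_net(1, n_nodes=5)
    n = net.order[2]
    assert mutual_information(net, n, n) == pytest.approx(node_entropy(net, n), abs=1e-12)
    assert conditional_entropy(net, n, n) == 0.0


@pytest.mark.parametrize("seed", range(6))
def test_mi_symmetric_and_nonnegative(seed):
    net = random_binary_net(seed + 30, n_nodes=7)
    nodes = net.order
    for x in nodes[:4]:
        for y in nodes[3:6]:
            mi_xy = mutual_information(net, x, y)
            mi_yx = mutual_information(net, y, x)
            assert mi_xy >= 0.0
            assert mi_xy == pytest.approx(mi_yx, abs=1e-9)


@pytest.mark.parametrize("seed", range(6))
def test_conditioning_cannot_increase_entropy(seed):
    net = random_binary_net(seed + 60, n_nodes=7)
    nodes = net.order
    for x in nodes[:4]:
        for y in nodes[4:]:
            assert conditional_entropy(net, x, y) <= node_entropy(net, x) + 1e-9


def test_independent_nodes_have_zero_mi():
    a = BayesNode("A", (), {(): 0.3})
    b = BayesNode("B", (), {(): 0.6})
    net = BayesNet([a, b])
    assert mutual_information(net, "A", "B") == pytest.approx(0.0, abs=1e-12)


def test_deterministic_copy_has_full_mi():
    a = BayesNode("A", (), {(): 0.3})
    b = BayesNode("B", ("A",), {(False,): 0.0, (True,): 1.0})
    net = BayesNet([a, b])
    assert mutual_information(net, "A", "B") == pytest.approx(node_entropy(net, "A"), abs=1e-9)


def test_score_path_requires_arcs():
    net = random_binary_net(2, n_nodes=6)
    root = net.roots()[0]
    # A non-arc pair must be rejected.
    others = [n for n in net.order if n != root and root not in net.nodes[n].parents]
    with pytest.raises(ValueError):
        score_path(net, [root, others[0]])


def test_rank_paths_on_case(bundle):
    from fftabn import build_case_bn

    net = build_case_bn(bundle)
    reports = rank_paths(net, paths=list(bundle.config.highlight_paths), score="min-edge")
    scores = [r.min_edge for r in reports]
    assert scores == sorted(scores, reverse=True)
    assert all(len(r.edge_mi) == len(r.path) - 1 for r in reports)


def test_enumerate_root_paths_small():
    a = BayesNode("A", (), {(): 0.3})
    b = BayesNode("B", (), {(): 0.4})
    c = BayesNode("C", ("A", "B"), {k: 0.5 for k in [(False, False), (False, True), (True, False), (True, True)]})
    net = BayesNet([a, b, c])
    assert enumerate_root_paths(net, "C") == [("A", "C"), ("B", "C")]


def test_path_report_scores():
    net = random_binary_net(4, n_nodes=6)
    # find any arc
    child = next(n for n in net.order if net.nodes[n].parents)
    parent = net.nodes[child].parents[0]
    rep = score_path(net, [parent, child])
    assert rep.score("min-edge") == rep.min_edge
    assert rep.score("total") == rep.total
    with pytest.raises(ValueError):
        rep.score("median")
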