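"""Bayesian-network construction and the fault-tree mapping."""

import pytest

from fftabn import (
    BayesNet,
    BayesNode,
    FaultTree,
    Gate,
    GatePolicy,
    NoisyOrSpec,
    and_gate_cpt,
    leaky_noisy_or_row,
    map_ft_to_bn,
    noisy_or_row,
    or_gate_cpt,
    posterior,
)
from fftabn.synthetic import generate_tree


def test_noisy_or_m1_worked_row(bundle):
    ex = bundle.worked_example["m1_noisy_or"]
    spec = NoisyOrSpec(link=tuple(ex["links"]), leak=0.0)
    value = noisy_or_row(spec, (True, True, True))
    assert round(value, 4) == ex["expected_all_active"]


def test_noisy_or_inactive_parents_do_not_contribute():
    spec = NoisyOrSpec(link=(0.3, 0.5), leak=0.0)
    assert noisy_or_row(spec, (False, False)) == 0.0
    assert noisy_or_row(spec, (True, False)) == pytest.approx(0.3)
    assert noisy_or_row(spec, (False, True)) == pytest.approx(0.5)
    assert noisy_or_row(spec, (True, True)) == pytest.approx(1 - 0.7 * 0.5)


def test_leaky_noisy_or_adds_leak():
    spec = NoisyOrSpec(link=(0.3,), leak=0.1)
    assert leaky_noisy_or_row(spec, (False,)) == pytest.approx(0.1)
    assert leaky_noisy_or_row(spec, (True,)) == pytest.approx(1 - 0.9 * 0.7)


def test_and_gate_cpt_is_deterministic_conjunction():
    cpt = and_gate_cpt(2)
    assert cpt[(True, True)] == 1.0
    assert cpt[(True, False)] == 0.0
    assert cpt[(False, False)] == 0.0


def test_or_gate_cpt_deterministic_with_unit_links():
    spec = NoisyOrSpec(link=(1.0, 1.0), leak=0.0)
    cpt = or_gate_cpt(spec, use_leak=False)
    assert cpt[(False, False)] == 0.0
    assert cpt[(True, False)] == 1.0
    assert cpt[(True, True)] == 1.0


def test_node_requires_complete_cpt():
    with pytest.raises(ValueError):
        BayesNode("A", ("P",), {(True,): 0.5})
    with pytest.raises(ValueError):
        BayesNode("A", (), {(): 1.5})


def test_net_rejects_cycles():
    a = BayesNode("A", ("B",), {(False,): 0.1, (True,): 0.9})
    b = BayesNode("B", ("A",), {(False,): 0.1, (True,): 0.9})
    with pytest.raises(ValueError):
        BayesNet([a, b])


def test_joint_probability_factorizes():
    a = BayesNode("A", (), {(): 0.2})
    b = BayesNode("B", ("A",), {(False,): 0.1, (True,): 0.7})
    net = BayesNet([a, b])
    assert net.joint_probability({"A": True, "B": True}) == pytest.approx(0.2 * 0.7)
    assert net.joint_probability({"A": False, "B": False}) == pytest.approx(0.8 * 0.9)


def test_map_shares_repeated_basic_events():
    t = FaultTree(
        ["A", "B"],
        [
            Gate("TE", "or", ("M1", "M2")),
            Gate("M1", "and", ("A", "B")),
            Gate("M2", "and", ("A", "B")),
        ],
        "TE",
    )
    net = map_ft_to_bn(t, {"A": 0.1, "B": 0.2})
    children_of_a = [n for n in net.nodes.values() if "A" in n.parents]
    assert {n.name for n in children_of_a} == {"M1", "M2"}


@pytest.mark.parametrize("seed", range(8))
def test_deterministic_mapping_matches_ft_probability(seed):
    t = generate_tree(seed, n_be=7, n_ie=3, and_fraction=0.5)
    probs = {b: 0.03 + 0.015 * i for i, b in enumerate(t.basic_events)}
    net = map_ft_to_bn(t, probs)
    assert posterior(net, t.top, {}) == pytest.approx(
        t.top_event_probability(probs), abs=1e-12
    )


def test_map_requires_all_priors():
    t = FaultTree(["A", "B"], [Gate("TE", "or", ("A", "B"))], "TE")
    with pytest.raises(KeyError):
        map_ft_to_bn(t, {"A": 0.1})


def test_gate_policy_lookup():
    policy = GatePolicy(links={("TE", "A"): 0.4}, leak=0.05, or_mode="noisy-or")
    assert policy.link_for("TE", "A") == 0.4
    assert policy.leak_for("TE") == 0.05
    with pytest.raises(KeyError):
        policy.link_for("TE", "B")


def test_net_serialization_roundtrip(bundle):
    from fftabn import build_case_bn

    net = build_case_bn(bundle)
    again = BayesNet.from_dict(net.to_dict())
    assert posterior(again, "TE", {}) == pytest.approx(posterior(net, "TE", {}), abs=1e-12)
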