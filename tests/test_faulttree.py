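"""Fault-tree structure, cut/path sets, and top-event probability."""

import pytest

from fftabn import CutSetCollection, FaultTree, Gate, inclusion_exclusion, minimal_path_sets_from_mcs
from fftabn.synthetic import generate_tree

from conftest import truth_table_mcs, truth_table_mps


def small_tree():
    # TE = OR(A, M); M = AND(B, C)
    return FaultTree(
        ["A", "B", "C"],
        [Gate("TE", "or", ("A", "M")), Gate("M", "and", ("B", "C"))],
        "TE",
    )


def test_validate_catches_cycles_and_dangling():
    with pytest.raises(ValueError, match="cycle|refers|reach"):
        FaultTree(
            ["A"],
            [Gate("TE", "or", ("M",)), Gate("M", "or", ("TE",))],
            "TE",
        )
    with pytest.raises(ValueError):
        FaultTree(["A"], [Gate("TE", "or", ("A", "GHOST"))], "TE")


def test_gate_validation():
    with pytest.raises(ValueError):
        Gate("TE", "xor", ("A",))
    with pytest.raises(ValueError):
        Gate("TE", "or", ())


def test_mcs_small_tree():
    mcs = small_tree().minimal_cut_sets()
    assert set(mcs.sets) == {frozenset({"A"}), frozenset({"B", "C"})}


def test_absorption():
    c = CutSetCollection([["A"], ["A", "B"], ["B", "C"], ["C", "B"]])
    assert set(c.sets) == {frozenset({"A"}), frozenset({"B", "C"})}


def test_mps_dual_and_hitting_agree():
    t = small_tree()
    assert t.minimal_path_sets(method="dual") == t.minimal_path_sets(method="hitting")
    assert set(t.minimal_path_sets().sets) == {
        frozenset({"A", "B"}),
        frozenset({"A", "C"}),
    }


def test_dual_swaps_gates():
    d = small_tree().dual()
    assert d.gates["TE"].type == "and"
    assert d.gates["M"].type == "or"


@pytest.mark.parametrize("seed", range(12))
def test_mcs_mps_match_truth_table_oracle(seed):
    t = generate_tree(seed, n_be=6, n_ie=3, and_fraction=0.4)
    assert set(t.minimal_cut_sets().sets) == truth_table_mcs(t)
    assert set(t.minimal_path_sets().sets) == truth_table_mps(t)


def test_repeated_events_detected(bundle):
    assert bundle.tree.has_repeated_basic_events()
    assert not small_tree().has_repeated_basic_events()


def test_top_event_probability_methods_agree():
    t = small_tree()
    probs = {"A": 0.1, "B": 0.2, "C": 0.3}
    p_bu = t.top_event_probability(probs, method="bottom-up")
    p_ie = t.top_event_probability(probs, method="inclusion-exclusion")
    p_en = t.top_event_probability(probs, method="enumerate")
    expect = 1 - (1 - 0.1) * (1 - 0.2 * 0.3)
    assert p_bu == pytest.approx(expect, abs=1e-12)
    assert p_ie == pytest.approx(expect, abs=1e-12)
    assert p_en == pytest.approx(expect, abs=1e-12)


@pytest.mark.parametrize("seed", range(6))
def test_probability_enumerate_matches_inclusion_exclusion(seed):
    t = generate_tree(seed, n_be=6, n_ie=3, and_fraction=0.4)
    probs = {b: 0.05 + 0.02 * i for i, b in enumerate(t.basic_events)}
    p_en = t.top_event_probability(probs, method="enumerate")
    p_auto = t.top_event_probability(probs)
    assert p_auto == pytest.approx(p_en, abs=1e-9)


def test_inclusion_exclusion_direct():
    mcs = CutSetCollection([["A"], ["B", "C"]])
    p = inclusion_exclusion(mcs, {"A": 0.1, "B": 0.2, "C": 0.3})
    assert p == pytest.approx(0.1 + 0.06 - 0.1 * 0.06, abs=1e-12)


def test_mps_from_mcs_is_involutive_on_small_tree():
    t = small_tree()
    mcs = t.minimal_cut_sets()
    mps = minimal_path_sets_from_mcs(mcs)
    back = minimal_path_sets_from_mcs(mps.to_lists())
    assert set(back.sets) == set(mcs.sets)


def test_serialization_roundtrip():
    t = small_tree()
    again = FaultTree.from_json(t.to_json())
    assert again.to_dict() == t.to_dict()
    assert "digraph" in t.to_dot()


def test_cutset_collection_ordering_deterministic():
    c = CutSetCollection([["C", "B"], ["C"], ["A", "B"]])
    assert c.to_lists() == [["C"], ["A", "B"]]


def test_case_tree_structure(bundle):
    t = bundle.tree
    counts = t.gate_counts()
    assert len(t.basic_events) == 19
    assert len(t.intermediate_events) == 13
    assert counts["or"] == 10 and counts["and"] == 4
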