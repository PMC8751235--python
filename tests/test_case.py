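"""The bundled shipyard case fixture and its reconstruction gate."""

import pytest

from fftabn import (
    CaseIntegrityError,
    FaultTree,
    Gate,
    build_case_bn,
    load_case,
    posterior,
    reproduce_case,
    verify_reconstruction,
)
from fftabn.case import CaseBundle


def test_load_case_invariants(bundle):
    assert sum(len(v) for v in bundle.taxonomy.values()) == 31
    assert len(bundle.panel) == 5
    assert len(bundle.mcs_transcription) == 33
    assert len(bundle.mps_transcription) == 17
    x3 = bundle.weight_row("X3")
    assert (x3.sv, x3.iv, x3.fp) == (0.2765, 0.0919, 1.15e-5)


def test_basic_event_values_sources(bundle):
    iv = bundle.basic_event_values("possibility")
    fp = bundle.basic_event_values("probability")
    assert set(iv) == set(fp) == {f"X{i}" for i in range(1, 20)}
    assert iv["X3"] == 0.0919 and fp["X3"] == 1.15e-5
    with pytest.raises(ValueError):
        bundle.basic_event_values("frequency")


def test_reconstruction_checks_pass(bundle):
    report = verify_reconstruction(bundle)
    assert report.ok, report.failures()


def _with_tree(bundle, tree):
    return CaseBundle(
        taxonomy=bundle.taxonomy,
        rubric=bundle.rubric,
        panel=bundle.panel,
        weights=bundle.weights,
        tree=tree,
        mcs_transcription=bundle.mcs_transcription,
        mps_transcription=bundle.mps_transcription,
        config=bundle.config,
        worked_example=bundle.worked_example,
    )


def test_flipped_gate_fails_reconstruction(bundle):
    gates = dict(bundle.tree.gates)
    m10 = gates["M10"]
    gates["M10"] = Gate("M10", "or", m10.inputs)  # AND -> OR perturbation
    perturbed = FaultTree(bundle.tree.basic_events, gates, bundle.tree.top)
    report = verify_reconstruction(_with_tree(bundle, perturbed))
    assert not report.ok
    assert any("MCS" in f or "AND" in f or "OR" in f for f in report.failures())


def test_altered_m1_parents_fail_reconstruction(bundle):
    gates = dict(bundle.tree.gates)
    gates["M1"] = Gate("M1", "or", ("X1", "X5", "X11", "X2"))
    perturbed = FaultTree(bundle.tree.basic_events, gates, bundle.tree.top)
    report = verify_reconstruction(_with_tree(bundle, perturbed))
    failures = report.failures()
    assert any("M1" in f for f in failures)


def test_case_bn_structure(bundle):
    net = build_case_bn(bundle)
    assert set(net.nodes) == set(bundle.tree.basic_events) | set(bundle.tree.gates)
    # Repeated basic events appear as shared parents.
    children_of_x4 = {n.name for n in net.nodes.values() if "X4" in n.parents}
    assert children_of_x4 == {"M2", "M7"}
    # Priors follow the configured source column.
    assert net.nodes["X3"].cpt[()] == 0.0919


def test_case_bn_inference_is_consistent(bundle):
    net = build_case_bn(bundle)
    p_te = posterior(net, "TE", {})
    assert 0.0 < p_te < 1.0
    # Observing the accident raises every organizational node's probability.
    for node in ("RM", "OC", "OP"):
        assert posterior(net, node, {"TE": True}) > posterior(net, node, {})


def test_reproduce_case_report(bundle):
    report = reproduce_case(bundle)
    assert report["ok"]
    assert report["structure"]["n_mcs"] == 33
    assert report["structure"]["n_mps"] == 17
    assert report["sensitivity"]["top3"] == ["OC", "RM", "OP"]


def test_load_case_is_idempotent(bundle):
    again = load_case()
    assert again.tree.to_dict() == bundle.tree.to_dict()
    assert again.mcs_transcription == bundle.mcs_transcription
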