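"""Synthetic generators: determinism, validity, and the end-to-end pipeline."""

import pytest

from fftabn import (
    aggregate_judgments,
    credibility_weights,
    failure_probability,
    map_ft_to_bn,
    mutual_information,
    posterior,
    roc_analysis,
    weights_from_matrix,
)
from fftabn.synthetic import (
    generate_judgment_matrix,
    generate_panel,
    generate_panel_and_judgments,
    generate_tree,
)

from conftest import truth_table_mcs


def test_tree_generation_deterministic():
    a = generate_tree(1, 6, 3, 0.5)
    b = generate_tree(1, 6, 3, 0.5)
    assert a.to_dict() == b.to_dict()
    c = generate_tree(2, 6, 3, 0.5)
    assert a.to_dict() != c.to_dict()


@pytest.mark.parametrize("seed", range(10))
def test_generated_trees_are_valid_and_fully_reachable(seed):
    t = generate_tree(seed, 8, 4, 0.3)
    assert t.validate() == []
    # Every basic event participates in the structure function.
    reachable = set()
    stack = [t.top]
    while stack:
        e = stack.pop()
        for child in t.gates[e].inputs if e in t.gates else ():
            if child in t.gates:
                stack.append(child)
            else:
                reachable.add(child)
    assert reachable == set(t.basic_events)


def test_all_or_tree_mcs_are_singletons():
    t = generate_tree(2, 8, 4, and_fraction=0.0)
    mcs = t.minimal_cut_sets()
    assert all(len(s) == 1 for s in mcs.sets)
    assert set(t.minimal_cut_sets().sets) == truth_table_mcs(t)


def test_generation_parameter_validation():
    with pytest.raises(ValueError):
        generate_tree(1, 1, 3)
    with pytest.raises(ValueError):
        generate_tree(1, 6, 0)
    with pytest.raises(ValueError):
        generate_tree(1, 6, 3, and_fraction=1.5)


def test_panel_generation(bundle):
    panel = generate_panel(5, 4, bundle.rubric)
    assert [p.id for p in panel] == ["E1", "E2", "E3", "E4"]
    again = generate_panel(5, 4, bundle.rubric)
    assert panel == again
    for p in panel:
        assert p.professional_position in bundle.rubric.tables["professional_position"]


def test_judgment_matrices_are_reciprocal():
    for seed in range(5):
        m = generate_judgment_matrix(seed, 4)  # constructor enforces reciprocity
        assert m.n == 4


def test_panel_and_judgments_deterministic(bundle):
    p1, m1 = generate_panel_and_judgments(3, 3, 4, rubric=bundle.rubric)
    p2, m2 = generate_panel_and_judgments(3, 3, 4, rubric=bundle.rubric)
    assert p1 == p2
    for a, b in zip(m1, m2):
        for i in range(4):
            for j in range(4):
                assert a[i, j].as_tuple() == b[i, j].as_tuple()


@pytest.mark.parametrize("seed", range(50))
def test_end_to_end_pipeline_runs(seed, bundle):
    """Judgments -> SV/IV -> FP -> tree priors -> BN -> inference -> MI -> RoC."""
    n_indicators = 4
    profiles, matrices = generate_panel_and_judgments(seed, 3, n_indicators, rubric=bundle.rubric)
    weights = credibility_weights(profiles, bundle.rubric)
    agg = aggregate_judgments([m.cells for m in matrices], weights)
    result = weights_from_matrix(agg)
    ivs = list(result["iv"])
    tree = generate_tree(seed, n_be=n_indicators, n_ie=2, and_fraction=0.3)
    priors = {
        b: max(float(failure_probability(iv)), 1e-9)
        for b, iv in zip(tree.basic_events, ivs)
    }
    net = map_ft_to_bn(tree, priors)
    p_te = posterior(net, tree.top, {})
    assert 0.0 <= p_te <= 1.0
    mi = mutual_information(net, tree.basic_events[0], tree.top)
    assert mi >= 0.0
    if 0.0 < p_te < 1.0:
        records = roc_analysis(net, {tree.top: True})
        assert records
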