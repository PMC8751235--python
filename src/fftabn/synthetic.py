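"""Deterministic synthetic generators for trees, panels, and judgments.

These exist so the elicitation and structural stages can be exercised at
any scale without real expert data: every generator takes an explicit seed
and is reproducible bit-for-bit for that seed.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np

from .ahp import DEFAULT_LINGUISTIC_SCALE, JudgmentMatrix
from .faulttree import AND, OR, FaultTree, Gate
from .panel import RUBRIC_INDICATORS, CredibilityRubric, ExpertProfile
from .tfn import TFN

logger = logging.getLogger(__name__)


def generate_tree(seed: int, n_be: int, n_ie: int, and_fraction: float = 0.5) -> FaultTree:
    """Random valid fault tree with ``n_be`` basic and ``n_ie`` non-top events.

    The top event plus ``n_ie`` intermediate events each get one gate whose
    type is AND with probability ``and_fraction``.  Every basic event is
    reachable from the top event: events are laid out in a fixed topological
    order (TE, IE1..IEn, then BEs) and each non-top event is wired as input
    to one earlier gate, after which each gate receives 0–2 extra inputs
    from strictly later events.
    """
    if n_be < 2:
        raise ValueError("need at least 2 basic events")
    if n_ie < 1:
        raise ValueError("need at least 1 intermediate event")
    if not (0.0 <= and_fraction <= 1.0):
        raise ValueError("and_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    logger.info("generate_tree(seed=%d, n_be=%d, n_ie=%d, and_fraction=%.3f)", seed, n_be, n_ie, and_fraction)

    top = "TE"
    ies = [f"M{i}" for i in range(1, n_ie + 1)]
    bes = [f"X{i}" for i in range(1, n_be + 1)]
    gate_events = [top] + ies

    inputs: dict[str, list[str]] = {e: [] for e in gate_events}
    # Chain every event below one earlier gate so the whole tree is reachable.
    for i, e in enumerate(ies):
        parent = gate_events[int(rng.integers(0, i + 1))]
        inputs[parent].append(e)
    for b in bes:
        parent = gate_events[int(rng.integers(0, len(gate_events)))]
        inputs[parent].append(b)
    # Optional extra arcs, always from earlier gate to strictly later event,
    # keeping the graph acyclic and each IE single-parented (so extras are BEs).
    for gi, e in enumerate(gate_events):
        for _ in range(int(rng.integers(0, 3))):
            candidates = [b for b in bes if b not in inputs[e]]
            if candidates:
                inputs[e].append(candidates[int(rng.integers(0, len(candidates)))])
    # A gate must have at least one input; top up from basic events.
    for e in gate_events:
        if not inputs[e]:
            inputs[e].append(bes[int(rng.integers(0, len(bes)))])

    gates = [
        Gate(e, AND if rng.random() < and_fraction else OR, tuple(inputs[e]))
        for e in gate_events
    ]
    return FaultTree(bes, gates, top)


def generate_panel(seed: int, n_experts: int, rubric: CredibilityRubric) -> list[ExpertProfile]:
    """Random expert profiles drawn from the rubric's categories."""
    if n_experts < 1:
        raise ValueError("need at least one expert")
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(1, n_experts + 1):
        fields = {}
        for indicator in RUBRIC_INDICATORS:
            cats = rubric.categories(indicator)
            fields[indicator] = cats[int(rng.integers(0, len(cats)))]
        profiles.append(ExpertProfile(id=f"E{i}", **fields))
    return profiles


def generate_judgment_matrix(seed: int, n: int, scale=None) -> JudgmentMatrix:
    """Random reciprocal fuzzy judgment matrix over the linguistic scale."""
    if n < 2:
        raise ValueError("judgment matrices need at least 2 alternatives")
    scale = list(scale or DEFAULT_LINGUISTIC_SCALE.values())
    rng = np.random.default_rng(seed)
    upper: dict[tuple[int, int], TFN] = {}
    for i in range(n):
        for j in range(i + 1, n):
            term = scale[int(rng.integers(0, len(scale)))]
            # Flip a coin for orientation: either the term or its reciprocal.
            upper[(i, j)] = term if rng.random() < 0.5 else term.inverse()
    return JudgmentMatrix.from_upper_triangle(n, upper)


def generate_panel_and_judgments(
    seed: int,
    n_experts: int,
    n_indicators: int,
    rubric: CredibilityRubric | None = None,
) -> tuple[list[ExpertProfile], list[JudgmentMatrix]]:
    """Profiles plus one judgment matrix per expert, all from one seed.

    Without an explicit rubric, the bundled case rubric is used for the
    profile categories.
    """
    if rubric is None:
        from .case import load_case

        rubric = load_case().rubric
    profiles = generate_panel(seed, n_experts, rubric)
    matrices = [
        generate_judgment_matrix(seed * 100003 + k, n_indicators) for k in range(n_experts)
    ]
    return profiles, matrices


def uniform_weights(n: int) -> list[Fraction]:
    """Exact uniform panel weights, handy for symmetry tests."""
    return [Fraction(1, n)] * n
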