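"""Bundled shipyard-suffocation case study.

The package ships a fully worked risk-model case: a human-factor taxonomy
for confined-space ship repair, a five-expert credibility panel, the fuzzy
AHP weight table, a reconstructed fault tree for the suffocation top event,
and the transcribed minimal cut/path sets.  ``load_case`` reads and validates
the bundle; ``verify_reconstruction`` proves the fault-tree reconstruction
consistent with the documented structural facts; ``build_case_bn`` maps the
tree to a Bayesian network under the documented case configuration.

All fixtures are plain JSON/CSV under ``fftabn/data/case`` and are loaded
via :mod:`importlib.resources`, so the bundle works from an installed wheel.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping

from .bn import BayesNet, GatePolicy, map_ft_to_bn
from .faulttree import CutSetCollection, FaultTree
from .panel import CredibilityRubric, ExpertProfile

class CaseIntegrityError(ValueError):
    """A bundled fixture failed its consistency checks."""


def _read_text(name: str) -> str:
    return resources.files("fftabn").joinpath("data", "case", name).read_text(encoding="utf-8")


def _read_json(name: str) -> Any:
    try:
        return json.loads(_read_text(name))
    except json.JSONDecodeError as exc:  # pragma: no cover - corruption guard
        raise CaseIntegrityError(f"fixture {name} is not valid JSON: {exc}") from exc


@dataclass(frozen=True)
class WeightRow:
    """One Table-style row: possibility weights and failure probability."""

    indicator: str
    category: str
    sv: float
    iv: float | None
    fp: float


@dataclass(frozen=True)
class CaseConfig:
    """Documented modelling conventions for the bundled case.

    ``prior_source``/``link_source`` select whether Bayesian-network priors
    and Noisy-OR links come from the possibility weights (IV column) or the
    Onisawa failure probabilities (FP column).  ``ie_link`` is the fixed
    link strength used for intermediate-event parents of OR gates, and
    ``top_link`` the one for the top gate (1.0 = deterministic OR).
    """

    prior_source: str = "possibility"
    link_source: str = "possibility"
    ie_link: float = 0.9
    top_link: float = 1.0
    leak: float = 0.0
    or_mode: str = "noisy-or"
    evidence: Mapping[str, bool] = field(default_factory=dict)
    roc_convention: str = "signed"
    path_score: str = "min-edge"
    pareto_threshold: float = 0.2
    pareto_exclude: tuple[str, ...] = ()
    highlight_paths: tuple[tuple[str, ...], ...] = ()


@dataclass(frozen=True)
class CaseBundle:
    """The complete validated case fixture."""

    taxonomy: Mapping[str, list[dict]]
    rubric: CredibilityRubric
    panel: tuple[ExpertProfile, ...]
    weights: tuple[WeightRow, ...]
    tree: FaultTree
    mcs_transcription: CutSetCollection
    mps_transcription: CutSetCollection
    config: CaseConfig
    worked_example: Mapping[str, Any]

    def weight_row(self, indicator: str) -> WeightRow:
        for row in self.weights:
            if row.indicator == indicator:
                return row
        raise KeyError(indicator)

    def basic_event_values(self, source: str) -> dict[str, float]:
        """Per-basic-event priors from either weight column.

        ``source`` is ``"possibility"`` (the IV column) or
        ``"probability"`` (the Onisawa FP column).
        """
        if source not in ("possibility", "probability"):
            raise ValueError(f"unknown value source {source!r}")
        out = {}
        for row in self.weights:
            if row.indicator.startswith("X"):
                out[row.indicator] = row.iv if source == "possibility" else row.fp
        return out


def _load_taxonomy() -> Mapping[str, list[dict]]:
    tax = _read_json("taxonomy.json")
    layers = ("unsafe_acts", "preconditions", "unsafe_supervision", "organizational_influences")
    counts = {"unsafe_acts": 13, "preconditions": 9, "unsafe_supervision": 5, "organizational_influences": 4}
    total = 0
    for layer in layers:
        if layer not in tax:
            raise CaseIntegrityError(f"taxonomy.json missing layer {layer!r}")
        n = len(tax[layer])
        if n != counts[layer]:
            raise CaseIntegrityError(f"taxonomy layer {layer} has {n} factors, expected {counts[layer]}")
        total += n
    if total != 31:
        raise CaseIntegrityError(f"taxonomy holds {total} factors, expected 31")
    # The layer mapping onto tree symbols must be bijective on its domain.
    symbols = [f["symbol"] for layer in layers for f in tax[layer]]
    if len(set(symbols)) != len(symbols):
        raise CaseIntegrityError("taxonomy maps two factors to one tree symbol")
    return tax


def _load_weights() -> tuple[WeightRow, ...]:
    rows = []
    for rec in csv.DictReader(_read_text("weights.csv").splitlines()):
        rows.append(
            WeightRow(
                indicator=rec["indicator"],
                category=rec["category"],
                sv=float(rec["sv"]),
                iv=float(rec["iv"]) if rec["iv"] else None,
                fp=float(rec["fp"]),
            )
        )
    indicator_rows = [r for r in rows if r.indicator.startswith("X")]
    if len(indicator_rows) != 19:
        raise CaseIntegrityError(f"weights.csv lists {len(indicator_rows)} indicators, expected 19")
    for r in indicator_rows:
        if r.iv is None or not (0.0 < r.iv < 1.0) or not (0.0 < r.fp < 1.0):
            raise CaseIntegrityError(f"weights.csv row {r.indicator} out of range")
        # IV must equal category weight x SV (both printed at 4 d.p.).
        cat = next(c for c in rows if c.indicator == r.category)
        if abs(r.iv - cat.sv * r.sv) > 5e-4:
            raise CaseIntegrityError(f"weights.csv row {r.indicator}: IV inconsistent with SV x category weight")
    return tuple(rows)


def load_case() -> CaseBundle:
    """Load and validate the bundled case fixture."""
    taxonomy = _load_taxonomy()
    rubric = CredibilityRubric(_read_json("rubric.json"))
    panel = tuple(ExpertProfile(**p) for p in _read_json("panel.json"))
    if len(panel) != 5:
        raise CaseIntegrityError(f"panel.json lists {len(panel)} experts, expected 5")
    weights = _load_weights()
    try:
        tree = FaultTree.from_dict(_read_json("fault_tree.json"))
    except ValueError as exc:
        raise CaseIntegrityError(f"fault_tree.json invalid: {exc}") from exc
    mcs = CutSetCollection.from_lists(_read_json("cutsets.json"), kind="MCS")
    mps = CutSetCollection.from_lists(_read_json("pathsets.json"), kind="MPS")
    raw = _read_json("case_config.json")
    config = CaseConfig(
        prior_source=raw["prior_source"],
        link_source=raw["link_source"],
        ie_link=raw["ie_link"],
        top_link=raw["top_link"],
        leak=raw["leak"],
        or_mode=raw["or_mode"],
        evidence=dict(raw["evidence"]),
        roc_convention=raw["roc_convention"],
        path_score=raw["path_score"],
        pareto_threshold=raw["pareto_threshold"],
        pareto_exclude=tuple(raw["pareto_exclude"]),
        highlight_paths=tuple(tuple(p) for p in raw["highlight_paths"]),
    )
    worked = _read_json("worked_example.json")
    return CaseBundle(
        taxonomy=taxonomy,
        rubric=rubric,
        panel=panel,
        weights=weights,
        tree=tree,
        mcs_transcription=mcs,
        mps_transcription=mps,
        config=config,
        worked_example=worked,
    )


@dataclass(frozen=True)
class ReconstructionReport:
    """Outcome of checking the fixture tree against its documented facts."""

    checks: tuple[tuple[str, bool, str], ...]

    @property
    def ok(self) -> bool:
        return all(passed for _, passed, _ in self.checks)

    def failures(self) -> list[str]:
        return [f"{name}: {detail}" for name, passed, detail in self.checks if not passed]


def verify_reconstruction(bundle: CaseBundle) -> ReconstructionReport:
    """Check the reconstructed fault tree against the documented structure.

    Asserts the event/gate counts (13 intermediate events, 19 basic events,
    10 OR and 4 AND gates), the known parent sets (top event = OR of the
    three organizational nodes; M1 = OR(X1, X5, X11)), and that the tree's
    computed minimal cut sets equal the transcribed 33-set family.
    """
    tree = bundle.tree
    checks: list[tuple[str, bool, str]] = []

    n_be = len(tree.basic_events)
    n_ie = len(tree.intermediate_events)
    gate_types = [g.type for g in tree.gates.values()]
    checks.append(("basic-event count", n_be == 19, f"found {n_be}, expected 19"))
    checks.append(("intermediate-event count", n_ie == 13, f"found {n_ie}, expected 13"))
    checks.append(("OR-gate count", gate_types.count("or") == 10, f"found {gate_types.count('or')}, expected 10"))
    checks.append(("AND-gate count", gate_types.count("and") == 4, f"found {gate_types.count('and')}, expected 4"))

    top = tree.gates.get(tree.top)
    top_ok = top is not None and top.type == "or" and set(top.inputs) == {"RM", "OC", "OP"}
    checks.append(("top gate", top_ok, f"top gate is {top}"))

    m1 = tree.gates.get("M1")
    m1_ok = m1 is not None and m1.type == "or" and set(m1.inputs) == {"X1", "X5", "X11"}
    checks.append(("M1 parent set", m1_ok, f"M1 gate is {m1}"))

    computed = tree.minimal_cut_sets()
    checks.append(
        (
            "MCS equals transcription",
            computed == bundle.mcs_transcription,
            f"computed {len(computed)} sets, transcription {len(bundle.mcs_transcription)}",
        )
    )
    return ReconstructionReport(tuple(checks))


def case_gate_policy(bundle: CaseBundle) -> GatePolicy:
    """The documented gate policy for the case network.

    Basic-event links into OR gates take each parent's weight (per the
    configured ``link_source``); intermediate-event parents use the fixed
    ``ie_link``; the top gate uses ``top_link`` (1.0 makes it a plain OR).
    AND gates are always deterministic.
    """
    cfg = bundle.config
    tree = bundle.tree
    be_values = bundle.basic_event_values(cfg.link_source)
    links: dict[tuple[str, str], float] = {}
    for gate in tree.gates.values():
        if gate.type != "or":
            continue
        for parent in gate.inputs:
            if parent in be_values:
                links[(gate.event, parent)] = be_values[parent]
            elif gate.event == tree.top:
                links[(gate.event, parent)] = cfg.top_link
            else:
                links[(gate.event, parent)] = cfg.ie_link
    return GatePolicy(links=links, leak=cfg.leak, or_mode=cfg.or_mode)


def build_case_bn(bundle: CaseBundle | None = None) -> BayesNet:
    """Map the case fault tree to its Bayesian network.

    Priors come from the configured ``prior_source`` column of the weight
    table; gate conditional-probability tables follow
    :func:`case_gate_policy`.
    """
    if bundle is None:
        bundle = load_case()
    priors = bundle.basic_event_values(bundle.config.prior_source)
    return map_ft_to_bn(bundle.tree, priors, policy=case_gate_policy(bundle))


def reproduce_case(bundle: CaseBundle | None = None) -> dict[str, Any]:
    """Run the full case pipeline and diff computed against bundled values.

    Returns a JSON-serializable report covering credibility weights, the
    fuzzy-AHP worked subgroup, the possibility-to-probability transform,
    cut/path sets, the network build, information-theoretic path ranking,
    and the RoC/Pareto sensitivity analysis.
    """
    from .ahp import integrate_iv, normalize_sv
    from .infotheory import rank_paths
    from .onisawa import failure_probability
    from .panel import credibility_weights, score_expert
    from .sensitivity import pareto_key_factors, roc_analysis

    if bundle is None:
        bundle = load_case()
    report: dict[str, Any] = {}

    scores = {p.id: score_expert(p, bundle.rubric) for p in bundle.panel}
    weights = credibility_weights(bundle.panel, bundle.rubric).as_dict()
    report["credibility"] = {"scores": scores, "weights": weights}

    ex = bundle.worked_example["errors_subgroup"]
    sv = normalize_sv(ex["d_vector"])
    iv = integrate_iv(ex["parent_weight"], sv)
    report["extent_ahp"] = {
        "sv": list(sv.values),
        "iv": list(iv.values),
        "sv_max_abs_err": max(abs(a - b) for a, b in zip(sv.values, ex["expected_sv"])),
        "iv_max_abs_err": max(abs(a - b) for a, b in zip(iv.values, ex["expected_iv"])),
    }

    conversions = {}
    max_rel = 0.0
    for row in bundle.weights:
        possibility = row.iv if row.iv is not None else row.sv
        fp = float(failure_probability(possibility))
        rel = abs(fp - row.fp) / row.fp
        max_rel = max(max_rel, rel)
        conversions[row.indicator] = {"possibility": possibility, "fp": fp, "bundled_fp": row.fp, "rel_err": rel}
    report["onisawa"] = {"rows": conversions, "max_rel_err": max_rel}

    recon = verify_reconstruction(bundle)
    mps = bundle.tree.minimal_path_sets()
    report["structure"] = {
        "reconstruction_ok": recon.ok,
        "failures": recon.failures(),
        "n_mcs": len(bundle.tree.minimal_cut_sets()),
        "n_mps": len(mps),
        "mps_matches_transcription": mps == bundle.mps_transcription,
        "n_mps_with_13_bes": sum(1 for s in mps.sets if len(s) == 13),
    }

    net = build_case_bn(bundle)
    cfg = bundle.config
    paths = rank_paths(
        net, paths=[p for p in cfg.highlight_paths], score=cfg.path_score
    )
    report["paths"] = [
        {"path": list(p.path), "score": p.score(cfg.path_score), "edge_mi": list(p.edge_mi)}
        for p in paths
    ]

    evidence = dict(cfg.evidence)
    records = roc_analysis(net, evidence, convention=cfg.roc_convention)
    key = pareto_key_factors(records, threshold=cfg.pareto_threshold, exclude=cfg.pareto_exclude)
    report["sensitivity"] = {
        "evidence": evidence,
        "top3": [r.node for r in records[:3]],
        "roc": {r.node: r.roc for r in records},
        "pareto_key_factors": [r.node for r in key],
    }
    report["ok"] = bool(
        recon.ok
        and report["structure"]["mps_matches_transcription"]
        and report["extent_ahp"]["sv_max_abs_err"] < 5e-5
        and report["extent_ahp"]["iv_max_abs_err"] < 5e-5
        and max_rel < 0.01
        and math.isclose(weights["E1"], 0.2375)
    )
    return report
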