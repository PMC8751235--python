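"""Static fault trees: validation, minimal cut/path sets, and probabilities.

A fault tree is a DAG whose leaves are basic events (BEs), whose internal
nodes are intermediate events (IEs) each owning exactly one AND/OR gate, and
whose root is the top event (TE).  A basic event may feed several gates
(repeated events); each intermediate event has exactly one parent gate.

Qualitative analysis enumerates the *minimal cut sets* (MCSs; minimal BE sets
whose joint occurrence triggers the TE) by top-down MOCUS-style gate
substitution followed by idempotence and absorption, and the dual *minimal
path sets* (MPSs; minimal BE sets whose joint non-occurrence blocks the TE)
either by swapping gates in the dual tree or as minimal hitting sets of the
MCS family.  Quantitative analysis computes the exact TE probability under
independent BEs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

AND = "and"
OR = "or"


@dataclass(frozen=True)
class Gate:
    """One logic gate: the event it defines, its type, and its ordered inputs."""

    event: str
    type: str
    inputs: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.type not in (AND, OR):
            raise ValueError(f"gate type must be 'and' or 'or', got {self.type!r}")
        if not self.inputs:
            raise ValueError(f"gate for {self.event!r} has no inputs")


class FaultTree:
    """A typed fault tree with one top event.

    Parameters
    ----------
    basic_events : iterable of BE ids
    gates : mapping or iterable of :class:`Gate`; exactly one gate per IE/TE
    top : id of the top event
    """

    def __init__(
        self,
        basic_events: Iterable[str],
        gates: Iterable[Gate] | Mapping[str, Gate],
        top: str,
    ):
        self.basic_events = list(dict.fromkeys(basic_events))
        if isinstance(gates, Mapping):
            self.gates = dict(gates)
        else:
            self.gates = {}
            for g in gates:
                if g.event in self.gates:
                    raise ValueError(f"event {g.event!r} has more than one gate")
                self.gates[g.event] = g
        self.top = top
        violations = self.validate()
        if violations:
            raise ValueError("invalid fault tree: " + "; ".join(violations))

    # -- structure -------------------------------------------------------

    @property
    def intermediate_events(self) -> list[str]:
        return [e for e in self.gates if e != self.top]

    def gate_counts(self) -> dict[str, int]:
        counts = {AND: 0, OR: 0}
        for g in self.gates.values():
            counts[g.type] += 1
        return counts

    def validate(self) -> list[str]:
        """Structural checks; returns a list of violations (empty = valid)."""
        problems: list[str] = []
        be_set = set(self.basic_events)
        if self.top not in self.gates:
            problems.append(f"top event {self.top!r} has no gate")
        if self.top in be_set:
            problems.append("top event cannot be a basic event")
        overlap = be_set & set(self.gates)
        if overlap:
            problems.append(f"events are both basic and gated: {sorted(overlap)}")
        known = be_set | set(self.gates)
        ie_parents: dict[str, list[str]] = {}
        for g in self.gates.values():
            for child in g.inputs:
                if child not in known:
                    problems.append(f"gate {g.event!r} references unknown event {child!r}")
                if child in self.gates:
                    ie_parents.setdefault(child, []).append(g.event)
        for ie, parents in ie_parents.items():
            if len(parents) > 1:
                problems.append(f"intermediate event {ie!r} has several parents: {parents}")
        # acyclicity + reachability via DFS from the top
        if self.top in self.gates:
            state: dict[str, int] = {}

            def dfs(node: str) -> None:
                if node not in self.gates:
                    return
                mark = state.get(node, 0)
                if mark == 1:
                    problems.append(f"cycle through event {node!r}")
                    return
                if mark == 2:
                    return
                state[node] = 1
                for child in self.gates[node].inputs:
                    dfs(child)
                state[node] = 2

            dfs(self.top)
            unreachable = [e for e in self.gates if state.get(e, 0) != 2]
            if unreachable:
                problems.append(f"gated events unreachable from the top: {sorted(unreachable)}")
        return problems

    # -- qualitative analysis -------------------------------------------

    def minimal_cut_sets(self) -> "CutSetCollection":
        """MOCUS-style top-down expansion with idempotence and absorption."""
        rows: list[frozenset[str]] = [frozenset([self.top])]
        # Substitute gates until only basic events remain.  Each substitution
        # step rewrites every row containing the chosen event.
        pending = True
        while pending:
            pending = False
            new_rows: list[frozenset[str]] = []
            for row in rows:
                gated = next((e for e in row if e in self.gates), None)
                if gated is None:
                    new_rows.append(row)
                    continue
                pending = True
                g = self.gates[gated]
                rest = row - {gated}
                if g.type == AND:
                    new_rows.append(rest | set(g.inputs))
                else:
                    new_rows.extend(rest | {child} for child in g.inputs)
            rows = new_rows
            if pending:
                rows = _absorb(rows)
        return CutSetCollection(_absorb(rows), kind="MCS")

    def dual(self) -> "FaultTree":
        """The dual (success) tree: AND and OR gates swapped."""
        dual_gates = [
            Gate(g.event, AND if g.type == OR else OR, g.inputs)
            for g in self.gates.values()
        ]
        return FaultTree(self.basic_events, dual_gates, self.top)

    def minimal_path_sets(self, method: str = "dual") -> "CutSetCollection":
        """Minimal path sets, via the dual tree or by hypergraph transversal.

        Both methods return the same antichain; ``method`` selects between
        ``"dual"`` (MCS of the AND/OR-swapped tree) and ``"hitting"``
        (Berge-style minimal hitting sets of this tree's MCS family).
        """
        if method == "dual":
            mcs = self.dual().minimal_cut_sets()
            return CutSetCollection(mcs.sets, kind="MPS")
        if method == "hitting":
            return minimal_path_sets_from_mcs(self.minimal_cut_sets())
        raise ValueError(f"unknown MPS method {method!r}")

    # -- quantitative analysis ------------------------------------------

    def has_repeated_basic_events(self) -> bool:
        seen: set[str] = set()
        for g in self.gates.values():
            for child in g.inputs:
                if child in self.basic_events:
                    if child in seen:
                        return True
                    seen.add(child)
        return False

    def top_event_probability(
        self, be_probs: Mapping[str, float], method: str = "auto"
    ) -> float:
        """Exact TE probability under independent basic events.

        ``method``: ``"bottom-up"`` (linear time, valid only when no BE
        repeats), ``"inclusion-exclusion"`` (over the MCS family; exponential
        in the family size, so only for small families), ``"enumerate"``
        (sum over all BE state combinations; exponential in the number of
        BEs), or ``"auto"`` (bottom-up when exact, otherwise the cheaper of
        the exact fallbacks).
        """
        missing = [b for b in self._used_basic_events() if b not in be_probs]
        if missing:
            raise KeyError(f"missing probabilities for basic events: {sorted(missing)}")
        bad = {b: p for b, p in be_probs.items() if not (0.0 <= p <= 1.0)}
        if bad:
            raise ValueError(f"probabilities outside [0, 1]: {bad}")
        if method == "auto":
            if not self.has_repeated_basic_events():
                method = "bottom-up"
            else:
                mcs = self.minimal_cut_sets()
                method = "inclusion-exclusion" if len(mcs) <= 18 else "enumerate"
        if method == "bottom-up":
            if self.has_repeated_basic_events():
                raise ValueError("bottom-up evaluation is not exact with repeated basic events")
            return self._prob_bottom_up(self.top, be_probs)
        if method == "inclusion-exclusion":
            mcs = self.minimal_cut_sets()
            if len(mcs) > 24:
                raise ValueError(
                    f"inclusion-exclusion over {len(mcs)} cut sets is intractable; "
                    "use method='enumerate'"
                )
            return inclusion_exclusion(mcs, be_probs)
        if method == "enumerate":
            used = sorted(self._used_basic_events())
            if len(used) > 24:
                raise ValueError(f"enumeration over {len(used)} basic events is intractable")
            total = 0.0
            for mask in range(1 << len(used)):
                state = {b: bool(mask >> i & 1) for i, b in enumerate(used)}
                if self.evaluate(state):
                    p = 1.0
                    for b in used:
                        p *= be_probs[b] if state[b] else 1.0 - be_probs[b]
                    total += p
            return total
        raise ValueError(f"unknown probability method {method!r}")

    def evaluate(self, be_states: Mapping[str, bool], event: str | None = None) -> bool:
        """Boolean value of an event (default: the TE) for given BE states."""
        event = self.top if event is None else event
        if event not in self.gates:
            return bool(be_states[event])
        g = self.gates[event]
        values = (self.evaluate(be_states, c) for c in g.inputs)
        return all(values) if g.type == AND else any(values)

    def _used_basic_events(self) -> set[str]:
        used: set[str] = set()
        for g in self.gates.values():
            used.update(c for c in g.inputs if c in set(self.basic_events))
        return used

    def _prob_bottom_up(self, event: str, be_probs: Mapping[str, float]) -> float:
        if event not in self.gates:
            return float(be_probs[event])
        g = self.gates[event]
        child_p = [self._prob_bottom_up(c, be_probs) for c in g.inputs]
        if g.type == AND:
            out = 1.0
            for p in child_p:
                out *= p
            return out
        out = 1.0
        for p in child_p:
            out *= 1.0 - p
        return 1.0 - out

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        events = [{"id": b, "kind": "basic"} for b in self.basic_events]
        events += [
            {"id": e, "kind": "top" if e == self.top else "intermediate"}
            for e in self.gates
        ]
        gates = [
            {"event": g.event, "type": g.type, "inputs": list(g.inputs)}
            for g in self.gates.values()
        ]
        return {"events": events, "gates": gates}

    @classmethod
    def from_dict(cls, data: Mapping) -> "FaultTree":
        basics = [e["id"] for e in data["events"] if e["kind"] == "basic"]
        tops = [e["id"] for e in data["events"] if e["kind"] == "top"]
        if len(tops) != 1:
            raise ValueError(f"fault tree must declare exactly one top event, got {tops}")
        gates = [
            Gate(g["event"], g["type"].lower(), tuple(g["inputs"])) for g in data["gates"]
        ]
        return cls(basics, gates, tops[0])

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "FaultTree":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                data = json.loads(text)
            else:
                with open(text) as fh:
                    data = json.load(fh)
        return cls.from_dict(data)

    def to_dot(self) -> str:
        """Graphviz DOT text for the tree (gates drawn inside event nodes)."""
        lines = ["digraph faulttree {", "  rankdir=BT;"]
        for b in self.basic_events:
            lines.append(f'  "{b}" [shape=circle];')
        for e, g in self.gates.items():
            shape = "box" if e != self.top else "doubleoctagon"
            lines.append(f'  "{e}" [shape={shape}, label="{e}\\n{g.type.upper()}"];')
        for e, g in self.gates.items():
            for child in g.inputs:
                lines.append(f'  "{child}" -> "{e}";')
        lines.append("}")
        return "\n".join(lines)


# -- cut-set collections -------------------------------------------------


class CutSetCollection:
    """An antichain family of basic-event sets (MCS or MPS).

    Members are stored sorted by (cardinality, lexicographic ids) so that
    serialization is deterministic.
    """

    def __init__(self, sets: Iterable[Iterable[str]], kind: str = "MCS"):
        if kind not in ("MCS", "MPS"):
            raise ValueError(f"kind must be 'MCS' or 'MPS', got {kind!r}")
        family = [frozenset(s) for s in sets]
        if any(not s for s in family):
            raise ValueError("cut/path sets must be nonempty")
        family = _absorb(family)
        self.kind = kind
        self.sets = sorted(family, key=lambda s: (len(s), sorted(s)))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __contains__(self, item) -> bool:
        return frozenset(item) in set(self.sets)

    def __eq__(self, other) -> bool:
        if isinstance(other, CutSetCollection):
            return set(self.sets) == set(other.sets)
        return set(self.sets) == {frozenset(s) for s in other}

    def __hash__(self):
        return hash(frozenset(self.sets))

    def size_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for s in self.sets:
            hist[len(s)] = hist.get(len(s), 0) + 1
        return dict(sorted(hist.items()))

    def singletons(self) -> list[str]:
        return sorted(e for s in self.sets if len(s) == 1 for e in s)

    def largest(self) -> list[frozenset[str]]:
        if not self.sets:
            return []
        top = max(len(s) for s in self.sets)
        return [s for s in self.sets if len(s) == top]

    def to_lists(self) -> list[list[str]]:
        return [sorted(s) for s in self.sets]

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_lists(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_text(self) -> str:
        """One set per line, members sorted and comma-separated."""
        return "\n".join(",".join(sorted(s)) for s in self.sets)

    @classmethod
    def from_lists(cls, lists: Iterable[Iterable[str]], kind: str = "MCS") -> "CutSetCollection":
        return cls(lists, kind=kind)


def _absorb(family: Sequence[frozenset[str]]) -> list[frozenset[str]]:
    """Remove duplicates and supersets, leaving the minimal antichain."""
    unique = sorted(set(family), key=len)
    kept: list[frozenset[str]] = []
    for s in unique:
        if not any(k <= s for k in kept):
            kept.append(s)
    return kept


def minimal_path_sets_from_mcs(mcs: CutSetCollection | Iterable[Iterable[str]]) -> CutSetCollection:
    """Minimal hitting sets (Berge transversal) of an MCS family.

    Processes one cut set at a time, distributing its members over the
    partial transversals and re-minimizing, which keeps intermediate families
    small for the shallow trees this package targets.
    """
    family = list(mcs.sets if isinstance(mcs, CutSetCollection) else map(frozenset, mcs))
    if not family:
        raise ValueError("cannot dualize an empty cut-set family")
    transversals: list[frozenset[str]] = [frozenset()]
    for cut in sorted(family, key=len):
        extended = []
        for t in transversals:
            if t & cut:
                extended.append(t)
            else:
                extended.extend(t | {e} for e in cut)
        transversals = _absorb(extended)
    return CutSetCollection(transversals, kind="MPS")


def inclusion_exclusion(
    mcs: CutSetCollection | Iterable[Iterable[str]], be_probs: Mapping[str, float]
) -> float:
    """Exact top-event probability from an MCS family by inclusion–exclusion."""
    family = list(mcs.sets if isinstance(mcs, CutSetCollection) else map(frozenset, mcs))
    total = 0.0
    for r in range(1, len(family) + 1):
        sign = 1.0 if r % 2 else -1.0
        for combo in combinations(family, r):
            union: frozenset[str] = frozenset().union(*combo)
            p = 1.0
            for e in union:
                p *= be_probs[e]
            total += sign * p
    return total


@dataclass(frozen=True)
class StructuralReport:
    """Counts and shape summaries of a fault tree's MCS/MPS families."""

    mcs_count: int
    mps_count: int
    mcs_size_histogram: dict
    mps_size_histogram: dict
    singleton_mcs: list
    largest_mps: list

    def to_dict(self) -> dict:
        return {
            "mcs_count": self.mcs_count,
            "mps_count": self.mps_count,
            "mcs_size_histogram": self.mcs_size_histogram,
            "mps_size_histogram": self.mps_size_histogram,
            "singleton_mcs": self.singleton_mcs,
            "largest_mps": [sorted(s) for s in self.largest_mps],
        }


def structural_report(mcs: CutSetCollection, mps: CutSetCollection) -> StructuralReport:
    """Summarize the failure and success structure of a system."""
    return StructuralReport(
        mcs_count=len(mcs),
        mps_count=len(mps),
        mcs_size_histogram=mcs.size_histogram(),
        mps_size_histogram=mps.size_histogram(),
        singleton_mcs=mcs.singletons(),
        largest_mps=mps.largest(),
    )
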