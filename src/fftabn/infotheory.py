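"""Information-theoretic dependence measures over network variables.

Entropies are in nats.  Mutual information between two nodes is computed
from their exact joint posterior, ``I(X,Y) = H(X) - H(X|Y)``, and a risk
propagation path (a chain of arcs from a basic event up to the top event)
is scored from the mutual information of its edges — by its weakest edge
(bottleneck) by default, or by the total over edges.  The dominant path is
the one whose failure chain carries the most dependence, i.e. the likeliest
domino sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .bn import BayesNet
from .inference import joint_query


def entropy(dist: Sequence[float]) -> float:
    """Shannon entropy (nats) of a discrete distribution; 0 * ln 0 = 0."""
    p = np.asarray(dist, dtype=float)
    if np.any(p < -1e-12):
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"distribution must sum to 1, got {p.sum()!r}")
    p = np.clip(p, 0.0, 1.0)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _binary_entropy(p: float) -> float:
    return entropy([1.0 - p, p])


def node_entropy(net: BayesNet, node: str, evidence: Mapping[str, bool] | None = None) -> float:
    """Entropy of one node's exact (posterior) marginal."""
    f = joint_query(net, [node], evidence or {})
    return entropy(f.table.ravel())


def conditional_entropy(net: BayesNet, target: str, given: str) -> float:
    """H(target | given) from the exact pairwise joint; 0 when target == given."""
    if target == given:
        return 0.0
    joint = joint_query(net, [target, given]).table  # axes: target, given
    h = 0.0
    for y in (0, 1):
        p_y = float(joint[:, y].sum())
        if p_y > 0:
            h += p_y * entropy(joint[:, y] / p_y)
    return float(h)


def mutual_information(net: BayesNet, x: str, y: str) -> float:
    """I(X, Y) = H(X) - H(X|Y), clipped at 0 against rounding noise."""
    if x == y:
        return node_entropy(net, x)
    h_x = node_entropy(net, x)
    return max(0.0, h_x - conditional_entropy(net, x, y))


@dataclass(frozen=True)
class PathReport:
    """One cause→consequence chain with its per-edge dependence."""

    path: tuple[str, ...]
    edge_mi: tuple[float, ...]

    @property
    def min_edge(self) -> float:
        return min(self.edge_mi)

    @property
    def total(self) -> float:
        return float(sum(self.edge_mi))

    def score(self, kind: str = "min-edge") -> float:
        if kind == "min-edge":
            return self.min_edge
        if kind == "total":
            return self.total
        raise ValueError(f"unknown path score {kind!r}")

    def to_dict(self) -> dict:
        return {
            "path": list(self.path),
            "edge_mi_nats": list(self.edge_mi),
            "min_edge": self.min_edge,
            "total": self.total,
        }


def enumerate_root_paths(net: BayesNet, target: str) -> list[tuple[str, ...]]:
    """All directed chains from a root (parentless) node to ``target``."""
    paths: list[tuple[str, ...]] = []

    def walk(node: str, suffix: tuple[str, ...]) -> None:
        chain = (node,) + suffix
        parents = net.nodes[node].parents
        if not parents:
            paths.append(chain)
        for p in parents:
            walk(p, chain)

    walk(target, ())
    return sorted(paths)


def score_path(net: BayesNet, path: Sequence[str]) -> PathReport:
    """Per-edge mutual information along one chain of arcs."""
    for a, b in zip(path, path[1:]):
        if a not in net.nodes[b].parents:
            raise ValueError(f"{a!r} -> {b!r} is not an arc of the network")
    edge_mi = tuple(mutual_information(net, a, b) for a, b in zip(path, path[1:]))
    return PathReport(tuple(path), edge_mi)


def rank_paths(
    net: BayesNet,
    paths: Sequence[Sequence[str]] | None = None,
    target: str | None = None,
    score: str = "min-edge",
) -> list[PathReport]:
    """Score and rank propagation chains by dependence, strongest first.

    ``paths`` may be given explicitly; otherwise every root-to-``target``
    chain is enumerated from the network arcs.  Ties and serialization order
    are broken lexicographically on the path itself.
    """
    if paths is None:
        if target is None:
            raise ValueError("either explicit paths or a target node is required")
        paths = enumerate_root_paths(net, target)
    if not paths:
        return []
    reports = [score_path(net, p) for p in paths]
    return sorted(reports, key=lambda r: (-r.score(score), r.path))


def paths_frame(reports: Sequence[PathReport], score: str = "min-edge"):
    """Tabulate ranked paths as a pandas DataFrame (path, edge, mi, score)."""
    import pandas as pd

    rows = []
    for rank, rep in enumerate(reports, start=1):
        label = "->".join(rep.path)
        for (a, b), mi in zip(zip(rep.path, rep.path[1:]), rep.edge_mi):
            rows.append(
                {
                    "rank": rank,
                    "path": label,
                    "edge": f"{a}->{b}",
                    "mi_nats": mi,
                    "score": rep.score(score),
                }
            )
    return pd.DataFrame(rows)
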