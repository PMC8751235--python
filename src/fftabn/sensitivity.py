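"""Ratio-of-change sensitivity and Pareto key-factor selection.

Entering evidence (typically observing the accident node) updates every
other node's occurrence probability from its prior ζ to a posterior ξ; the
ratio of change RoC = (ξ − ζ) / ζ measures how strongly the evidence bears
on that factor.  Under the signed convention confirming evidence gives
positive RoC and disconfirming evidence negative; the magnitude convention
ranks by |RoC|, which is useful when the evidence direction is debatable
but the ordering is what matters.

Key factors are then picked by the Pareto principle: after excluding a
configured node set (e.g. the top-level organizational nodes, which are
aggregates rather than actionable factors), the top fraction of the RoC
ranking is flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .bn import BayesNet
from .inference import marginals

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SensitivityRecord:
    """Prior ζ, posterior ξ, and ratio of change of one node."""

    node: str
    zeta: float
    xi: float
    roc: float
    rank: int = 0
    pareto: bool = False


def roc_analysis(
    net: BayesNet,
    evidence: Mapping[str, bool],
    convention: str = "signed",
    nodes: Iterable[str] | None = None,
) -> list[SensitivityRecord]:
    """Per-node RoC under the evidence, sorted descending.

    Nodes with zero prior are skipped with a warning (the ratio is
    undefined); evidence nodes themselves are never reported.  With
    ``convention="magnitude"`` the ordering and the reported RoC use
    ``|ξ − ζ| / ζ``.
    """
    if convention not in ("signed", "magnitude"):
        raise ValueError(f"unknown RoC convention {convention!r}")
    targets = [n for n in (nodes if nodes is not None else net.order) if n not in evidence]
    priors = marginals(net, {}, nodes=targets)
    posts = marginals(net, evidence, nodes=targets)
    records = []
    for n in targets:
        zeta, xi = priors[n], posts[n]
        if zeta <= 0.0:
            logger.warning("node %s has zero prior; skipped in RoC analysis", n)
            continue
        roc = (xi - zeta) / zeta
        if convention == "magnitude":
            roc = abs(roc)
        records.append(SensitivityRecord(n, zeta, xi, roc))
    records.sort(key=lambda r: (-r.roc, r.node))
    return [
        SensitivityRecord(r.node, r.zeta, r.xi, r.roc, rank=i + 1, pareto=r.pareto)
        for i, r in enumerate(records)
    ]


def pareto_key_factors(
    reports: Sequence[SensitivityRecord],
    threshold: float = 0.2,
    exclude: Iterable[str] = (),
) -> list[SensitivityRecord]:
    """Top ``threshold`` fraction of the RoC ranking, after exclusions.

    The selection count is the ceiling of ``threshold * n_remaining``; ties
    are already broken deterministically (by RoC, then node id) in the
    ranking.  Returns the selected records re-ranked and flagged.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("pareto threshold must lie in (0, 1]")
    if not reports:
        raise ValueError("no sensitivity reports to select from")
    excluded = set(exclude)
    remaining = [r for r in reports if r.node not in excluded]
    count = math.ceil(threshold * len(remaining))
    remaining.sort(key=lambda r: (-r.roc, r.node))
    return [
        SensitivityRecord(r.node, r.zeta, r.xi, r.roc, rank=i + 1, pareto=True)
        for i, r in enumerate(remaining[:count])
    ]


def sensitivity_frame(reports: Sequence[SensitivityRecord]):
    """Tabulate sensitivity records as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "node": r.node,
                "zeta": r.zeta,
                "xi": r.xi,
                "roc": r.roc,
                "rank": r.rank,
                "pareto_flag": r.pareto,
            }
            for r in reports
        ]
    )
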