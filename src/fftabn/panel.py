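"""Expert panels: credibility scoring and multi-expert judgment aggregation.

Expert elicitation in group fuzzy AHP is only as good as the panel, so each
expert profile is scored against a four-indicator rubric (professional
position, length of service, education level, job title; each category worth
an integer 1..5).  The comprehensive reliability of an expert is the sum of
the four indicator scores, and the panel credibility weights are the scores
normalized to sum to one.  Those weights then enter the entrywise aggregation
of the experts' triangular-fuzzy judgment matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

from .tfn import TFN

RUBRIC_INDICATORS = (
    "professional_position",
    "service_years",
    "education_level",
    "job_title",
)


@dataclass(frozen=True)
class ExpertProfile:
    """One expert, described by the four rubric categories."""

    id: str
    professional_position: str
    service_years: str
    education_level: str
    job_title: str


class CredibilityRubric:
    """Maps each indicator's categories to integer scores in 1..5."""

    def __init__(self, tables: Mapping[str, Mapping[str, int]]):
        missing = set(RUBRIC_INDICATORS) - set(tables)
        if missing:
            raise ValueError(f"rubric missing indicator tables: {sorted(missing)}")
        for name in RUBRIC_INDICATORS:
            for cat, score in tables[name].items():
                if not (isinstance(score, int) and 1 <= score <= 5):
                    raise ValueError(
                        f"rubric score for {name}/{cat!r} must be an integer in 1..5, got {score!r}"
                    )
        self.tables = {name: dict(tables[name]) for name in RUBRIC_INDICATORS}

    def score(self, indicator: str, category: str) -> int:
        table = self.tables[indicator]
        if category not in table:
            raise KeyError(
                f"unknown category {category!r} for rubric indicator {indicator!r}; "
                f"known: {sorted(table)}"
            )
        return table[category]

    def categories(self, indicator: str) -> list[str]:
        return list(self.tables[indicator])


def score_expert(profile: ExpertProfile, rubric: CredibilityRubric) -> int:
    """Comprehensive reliability of one expert: sum of the four indicator scores (4..20)."""
    return sum(
        rubric.score(indicator, getattr(profile, indicator))
        for indicator in RUBRIC_INDICATORS
    )


@dataclass(frozen=True)
class PanelWeights:
    """Normalized per-expert credibility weights (positive, summing to 1)."""

    expert_ids: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.expert_ids) != len(self.weights):
            raise ValueError("expert_ids and weights length mismatch")
        if any(w <= 0 for w in self.weights):
            raise ValueError("credibility weights must be positive")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("credibility weights must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.expert_ids, self.weights))

    def __getitem__(self, expert_id: str) -> float:
        return self.as_dict()[expert_id]


def credibility_weights(
    profiles: Sequence[ExpertProfile], rubric: CredibilityRubric
) -> PanelWeights:
    """Normalized credibility weight of each expert: own score over the panel total.

    Scores are small integers, so the normalization is done in exact rational
    arithmetic before conversion to float.
    """
    if not profiles:
        raise ValueError("cannot weight an empty expert panel")
    scores = [score_expert(p, rubric) for p in profiles]
    total = sum(scores)
    fractions = [Fraction(s, total) for s in scores]
    return PanelWeights(
        expert_ids=tuple(p.id for p in profiles),
        weights=tuple(float(f) for f in fractions),
    )


def credibility_fractions(
    profiles: Sequence[ExpertProfile], rubric: CredibilityRubric
) -> dict[str, Fraction]:
    """Exact rational credibility weights, for callers that need them unrounded."""
    scores = {p.id: score_expert(p, rubric) for p in profiles}
    total = sum(scores.values())
    return {eid: Fraction(s, total) for eid, s in scores.items()}


def aggregate_judgments(
    matrices: Sequence[Sequence[Sequence[TFN]]],
    weights: PanelWeights | Sequence[float] | None = None,
    method: str = "weighted-mean",
):
    """Aggregate per-expert TFN judgment matrices into a single matrix.

    ``method`` is ``"weighted-mean"`` (credibility-weighted arithmetic mean of
    TFN components, the default) or ``"unweighted-mean"``.  The aggregated
    upper triangle is computed first and the lower triangle is rebuilt as its
    TFN inverse, because a convex combination of reciprocal matrices is not
    itself reciprocal.

    Returns a :class:`fftabn.ahp.JudgmentMatrix`.
    """
    from .ahp import JudgmentMatrix  # local import to avoid a cycle

    if not matrices:
        raise ValueError("no judgment matrices to aggregate")
    n = len(matrices[0])
    for mat in matrices:
        if len(mat) != n or any(len(row) != n for row in mat):
            raise ValueError("all judgment matrices must share the same dimension")

    if method == "unweighted-mean" or weights is None:
        lam = [1.0 / len(matrices)] * len(matrices)
    elif method == "weighted-mean":
        lam = list(weights.weights if isinstance(weights, PanelWeights) else weights)
        if len(lam) != len(matrices):
            raise ValueError("one weight per expert matrix is required")
    else:
        raise ValueError(f"unknown aggregation method {method!r}")

    cells: list[list[TFN]] = [[TFN.crisp(1.0)] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            agg_l = sum(w * mat[i][j].l for w, mat in zip(lam, matrices))
            agg_m = sum(w * mat[i][j].m for w, mat in zip(lam, matrices))
            agg_u = sum(w * mat[i][j].u for w, mat in zip(lam, matrices))
            cells[i][j] = TFN(agg_l, agg_m, agg_u)
            cells[j][i] = cells[i][j].inverse()
    return JudgmentMatrix(cells)
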