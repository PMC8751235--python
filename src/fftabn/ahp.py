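"""Extent-analysis fuzzy AHP (Chang's method).

Given a reciprocal matrix of triangular-fuzzy pairwise comparisons, the
method computes, per indicator:

1. the *synthetic extent* ``D_i`` — the fuzzy row sum normalized by the
   fuzzy grand sum (componentwise, with the triangular approximation of the
   fuzzy inverse);
2. pairwise *possibility degrees* ``V(D_i >= D_j)`` — the height of the
   intersection of the two tent membership functions, 1 when the first mode
   dominates;
3. the *d-vector* ``d(X_i) = min_j V(D_i >= D_j)``;
4. the normalized *standard values* SV (sum to one), and
5. *integrated values* IV — SV scaled by the product of the normalized
   weights of the ancestors in a multi-level hierarchy, so leaf weights are
   comparable across branches.

The possibility degree implemented is the standard intersection-height
formula ``(l_b - u_a) / ((m_a - u_a) - (m_b - l_b))`` on the overlapping
branch.  Some statements of the formula in the literature drop a sign and produce
values outside [0, 1]; this implementation keeps the geometric definition,
which is the one the method's worked numbers require.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tfn import TFN, tfn_sum

#: A conventional 9-level linguistic scale mapping verbal comparison terms to
#: TFNs.  Intermediate even levels fill the gaps; the extremes are crisp.
DEFAULT_LINGUISTIC_SCALE: dict[str, TFN] = {
    "equal": TFN(1, 1, 1),
    "weak": TFN(1, 2, 3),
    "moderate": TFN(2, 3, 4),
    "moderate_plus": TFN(3, 4, 5),
    "strong": TFN(4, 5, 6),
    "strong_plus": TFN(5, 6, 7),
    "very_strong": TFN(6, 7, 8),
    "very_very_strong": TFN(7, 8, 9),
    "absolute": TFN(9, 9, 9),
}

RECIPROCITY_TOL = 1e-9


class JudgmentMatrix:
    """An ``n x n`` reciprocal matrix of TFN pairwise comparisons.

    The diagonal must be crisp 1 and each lower-triangle entry must be the
    TFN inverse of its mirror entry (within tolerance).
    """

    def __init__(self, cells: Sequence[Sequence[TFN]], check: bool = True):
        self.cells = [[TFN.from_any(c) for c in row] for row in cells]
        n = len(self.cells)
        if any(len(row) != n for row in self.cells):
            raise ValueError("judgment matrix must be square")
        if check:
            self._check_reciprocity()

    @property
    def n(self) -> int:
        return len(self.cells)

    def _check_reciprocity(self) -> None:
        for i in range(self.n):
            d = self.cells[i][i]
            if max(abs(d.l - 1), abs(d.m - 1), abs(d.u - 1)) > RECIPROCITY_TOL:
                raise ValueError(f"diagonal entry ({i},{i}) must be crisp 1, got {d}")
            for j in range(i + 1, self.n):
                inv = self.cells[i][j].inverse()
                other = self.cells[j][i]
                err = max(abs(inv.l - other.l), abs(inv.m - other.m), abs(inv.u - other.u))
                if err > 1e-6:
                    raise ValueError(
                        f"entries ({i},{j}) and ({j},{i}) are not reciprocal (error {err:.2e})"
                    )

    def __getitem__(self, idx: tuple[int, int]) -> TFN:
        return self.cells[idx[0]][idx[1]]

    @classmethod
    def from_upper_triangle(cls, n: int, upper: dict[tuple[int, int], TFN]) -> "JudgmentMatrix":
        """Build a reciprocal matrix from its strict upper triangle."""
        cells = [[TFN.crisp(1.0)] * n for _ in range(n)]
        for (i, j), v in upper.items():
            if not i < j:
                raise ValueError("upper triangle keys must have i < j")
            v = TFN.from_any(v)
            cells[i][j] = v
            cells[j][i] = v.inverse()
        return cls(cells)


@dataclass(frozen=True)
class WeightVector:
    """An ordered crisp weight vector with its role in the AHP pipeline."""

    values: tuple[float, ...]
    role: str = "d-vector"  # "d-vector" | "SV" | "IV"
    labels: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.role not in ("d-vector", "SV", "IV"):
            raise ValueError(f"unknown weight-vector role {self.role!r}")
        if any(v < 0 for v in self.values):
            raise ValueError("weight-vector entries must be nonnegative")
        if self.role == "SV" and abs(sum(self.values) - 1.0) > 1e-9:
            raise ValueError("standard values must sum to 1")

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)


def synthetic_extents(matrix: JudgmentMatrix) -> list[TFN]:
    """Fuzzy synthetic extent ``D_i`` of each row: row sum times inverted grand sum."""
    row_sums = [tfn_sum(row) for row in matrix.cells]
    grand = tfn_sum(row_sums)
    grand_inv = grand.inverse()
    return [rs * grand_inv for rs in row_sums]


def possibility_degree(a: TFN, b: TFN) -> float:
    """Degree of possibility ``V(a >= b)``: intersection height of the two tents.

    1 when ``a``'s mode is at least ``b``'s; 0 when the supports are disjoint
    with ``b`` entirely above ``a``; otherwise the height at which the falling
    edge of ``a`` crosses the rising edge of ``b``.
    """
    if a.m >= b.m:
        return 1.0
    if b.l >= a.u:
        return 0.0
    denom = (a.m - a.u) - (b.m - b.l)
    # m_a < m_b and b.l < a.u here, so denom < 0 strictly.
    return (b.l - a.u) / denom


def d_vector(extents: Sequence[TFN]) -> WeightVector:
    """Pre-normalization weight of each extent: its minimum possibility degree
    of being at least every other extent."""
    if len(extents) < 2:
        raise ValueError("d_vector needs at least two synthetic extents")
    values = []
    for i, di in enumerate(extents):
        values.append(
            min(possibility_degree(di, dj) for j, dj in enumerate(extents) if j != i)
        )
    return WeightVector(tuple(values), role="d-vector")


def normalize_sv(d: WeightVector | Sequence[float]) -> WeightVector:
    """Standard values: the d-vector divided by its sum (so it sums to one)."""
    values = tuple(d.values if isinstance(d, WeightVector) else d)
    total = sum(values)
    if total <= 0:
        raise ValueError("cannot normalize an all-zero d-vector")
    return WeightVector(tuple(v / total for v in values), role="SV")


def integrate_iv(parent_weight: float, sv: WeightVector | Sequence[float]) -> WeightVector:
    """Integrated values: local standard values scaled by the parent's weight.

    In a multi-level hierarchy the parent weight is itself the product of the
    normalized weights along the root-to-parent path, so IV entries of all
    leaves are globally comparable.
    """
    if not (0.0 <= parent_weight <= 1.0):
        raise ValueError("parent weight must lie in [0, 1]")
    values = tuple(sv.values if isinstance(sv, WeightVector) else sv)
    return WeightVector(tuple(parent_weight * v for v in values), role="IV")


def weights_from_matrix(matrix: JudgmentMatrix, parent_weight: float = 1.0) -> dict:
    """Run the full extent-analysis chain on one matrix.

    Returns a dict with keys ``extents``, ``d``, ``sv`` and ``iv``.
    """
    extents = synthetic_extents(matrix)
    d = d_vector(extents)
    sv = normalize_sv(d)
    iv = integrate_iv(parent_weight, sv)
    return {"extents": extents, "d": d, "sv": sv, "iv": iv}


def weights_frame(labels: Sequence[str], d: WeightVector, sv: WeightVector, iv: WeightVector):
    """Tabulate AHP results as a pandas DataFrame (indicator, d, sv, iv)."""
    import pandas as pd

    return pd.DataFrame(
        {"indicator": list(labels), "d": list(d), "sv": list(sv), "iv": list(iv)}
    )
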