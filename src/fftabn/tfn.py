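"""Triangular fuzzy numbers (TFNs) and their extent arithmetic.

A TFN ``(l, m, u)`` with ``l <= m <= u`` encodes an imprecise judgment whose
most plausible value is the mode ``m``; the membership function is the usual
piecewise-linear tent, 1 at ``m`` and 0 outside ``[l, u]``.  When ``u == l``
the judgment is crisp.

The arithmetic implemented here is the *extent* (componentwise) arithmetic of
fuzzy group decision making: the product and inverse are the standard
triangular approximations (the true fuzzy product of two TFNs is not
triangular).  All weight calculations this package reproduces rely
on exactly these approximations, so they are implemented as such and not
"corrected".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator


@dataclass(frozen=True, order=False)
class TFN:
    """A triangular fuzzy number ``(l, m, u)`` with ``l <= m <= u``."""

    l: float
    m: float
    u: float

    def __post_init__(self) -> None:
        if not (self.l <= self.m <= self.u):
            raise ValueError(f"TFN requires l <= m <= u, got ({self.l}, {self.m}, {self.u})")

    # -- membership ------------------------------------------------------

    def membership(self, x: float) -> float:
        """Tent membership degree of ``x``: 1 at the mode, 0 outside [l, u]."""
        if x < self.l or x > self.u:
            return 0.0
        if x == self.m:
            return 1.0
        if x < self.m:
            return (x - self.l) / (self.m - self.l)
        return (self.u - x) / (self.u - self.m)

    @property
    def is_crisp(self) -> bool:
        return self.u == self.l

    # -- extent arithmetic ----------------------------------------------

    def __add__(self, other: "TFN") -> "TFN":
        return TFN(self.l + other.l, self.m + other.m, self.u + other.u)

    def __mul__(self, other: "TFN | float | int") -> "TFN":
        if isinstance(other, TFN):
            return TFN(self.l * other.l, self.m * other.m, self.u * other.u)
        return self.scale(float(other))

    __rmul__ = __mul__

    def scale(self, lam: float) -> "TFN":
        """Scalar product ``lam * (l, m, u)``; ``lam`` must be positive."""
        if lam < 0:
            raise ValueError("scalar for a TFN must be nonnegative")
        return TFN(lam * self.l, lam * self.m, lam * self.u)

    def inverse(self) -> "TFN":
        """Approximate reciprocal ``(1/u, 1/m, 1/l)``; components must be > 0."""
        if self.l <= 0:
            raise ValueError(f"cannot invert a TFN touching zero: {self}")
        return TFN(1.0 / self.u, 1.0 / self.m, 1.0 / self.l)

    # -- serialization ---------------------------------------------------

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.l, self.m, self.u)

    def __iter__(self) -> Iterator[float]:
        return iter(self.as_tuple())

    @classmethod
    def crisp(cls, x: float) -> "TFN":
        return cls(x, x, x)

    @classmethod
    def from_any(cls, value: "TFN | float | int | Iterable[float]") -> "TFN":
        """Coerce a TFN, a crisp number, or a length-3 iterable into a TFN."""
        if isinstance(value, TFN):
            return value
        if isinstance(value, (int, float)):
            return cls.crisp(float(value))
        seq = list(value)
        if len(seq) != 3:
            raise ValueError(f"expected [l, m, u], got {seq!r}")
        return cls(*map(float, seq))


def tfn_sum(values: Iterable[TFN]) -> TFN:
    """Componentwise sum of one or more TFNs."""
    total: TFN | None = None
    for v in values:
        total = v if total is None else total + v
    if total is None:
        raise ValueError("tfn_sum of an empty sequence")
    return total
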