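"""Triangular fuzzy numbers (TFNs) and their arithmetic.

A TFN ``(a1, a2, a3)`` with ``a1 <= a2 <= a3`` represents a fuzzy quantity
whose membership rises linearly from 0 at ``a1`` to 1 at the vertex ``a2``
and falls back to 0 at ``a3``.  Degenerate triples ``(c, c, c)`` embed crisp
numbers, so ordinary values and thresholds live in the same algebra.

Arithmetic follows interval (α-cut) rules on the support with the vertex
tracked exactly; products are re-triangularised from the support endpoints
(see :func:`multiply`).  All operations accept either :class:`TFN` instances
or any 3-sequence and return :class:`TFN`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "TFN",
    "AlphaInterval",
    "make_tfn",
    "alpha_cut",
    "add",
    "subtract",
    "multiply",
    "scale",
    "expected_value",
    "defuzzify_cog",
    "width",
    "tfn_error",
]


@dataclass(frozen=True)
class TFN:
    """Triangular fuzzy number defined by its support endpoints and vertex.

    Parameters
    ----------
    a1, a2, a3 : float
        Lower support endpoint, vertex, and upper support endpoint;
        must satisfy ``a1 <= a2 <= a3`` (equalities encode crisp values).
    """

    a1: float
    a2: float
    a3: float

    def __post_init__(self) -> None:
        for name, v in (("a1", self.a1), ("a2", self.a2), ("a3", self.a3)):
            if not np.isfinite(v):
                raise ValueError(f"TFN component {name} must be finite, got {v!r}")
        if self.a1 > self.a2:
            raise ValueError(
                f"TFN ordering violated: a1={self.a1} > a2={self.a2}"
            )
        if self.a2 > self.a3:
            raise ValueError(
                f"TFN ordering violated: a2={self.a2} > a3={self.a3}"
            )

    def membership(self, x: float) -> float:
        """Triangular membership μ(x): 1 at the vertex, 0 outside the support."""
        if x < self.a1 or x > self.a3:
            return 0.0
        if x == self.a2:
            return 1.0
        if x < self.a2:
            return (x - self.a1) / (self.a2 - self.a1)
        return (self.a3 - x) / (self.a3 - self.a2)

    @property
    def is_crisp(self) -> bool:
        return self.a1 == self.a2 == self.a3

    @property
    def is_symmetric(self) -> bool:
        return np.isclose(self.a2 - self.a1, self.a3 - self.a2)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.a1, self.a2, self.a3)

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3], dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {"a1": self.a1, "a2": self.a2, "a3": self.a3}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "TFN":
        return cls(float(d["a1"]), float(d["a2"]), float(d["a3"]))

    # Operator sugar; the functional API below is the documented surface.
    def __add__(self, other: "TFN | Iterable[float]") -> "TFN":
        return add(self, other)

    def __sub__(self, other: "TFN | Iterable[float]") -> "TFN":
        return subtract(self, other)

    def __mul__(self, other: "TFN | Iterable[float] | float") -> "TFN":
        if isinstance(other, (int, float)):
            return scale(self, float(other))
        return multiply(self, other)

    __rmul__ = __mul__


@dataclass(frozen=True)
class AlphaInterval:
    """The α-cut ``[lower, upper]`` of a TFN: points with membership ≥ α."""

    lower: float
    upper: float
    alpha: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(
                f"alpha-cut interval inverted: lower={self.lower} > upper={self.upper}"
            )


def _coerce(a: "TFN | Iterable[float]") -> TFN:
    if isinstance(a, TFN):
        return a
    vals = tuple(float(v) for v in a)
    if len(vals) != 3:
        raise ValueError(f"expected 3 components for a TFN, got {len(vals)}")
    return TFN(*vals)


def make_tfn(a1: float, a2: float, a3: float) -> TFN:
    """Construct a validated TFN from its three defining points."""
    return TFN(float(a1), float(a2), float(a3))


def alpha_cut(a: "TFN | Iterable[float]", alpha: float) -> AlphaInterval:
    """Return the α-cut interval ``[a1 + α(a2−a1), a3 − α(a3−a2)]``.

    ``alpha=0`` gives the support, ``alpha=1`` the degenerate vertex interval.
    """
    a = _coerce(a)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    lo = a.a1 + alpha * (a.a2 - a.a1)
    hi = a.a3 - alpha * (a.a3 - a.a2)
    return AlphaInterval(lo, hi, alpha)


def add(a: "TFN | Iterable[float]", b: "TFN | Iterable[float]") -> TFN:
    """Fuzzy addition: componentwise sum of the defining triples."""
    a, b = _coerce(a), _coerce(b)
    return TFN(a.a1 + b.a1, a.a2 + b.a2, a.a3 + b.a3)


def subtract(a: "TFN | Iterable[float]", b: "TFN | Iterable[float]") -> TFN:
    """Fuzzy subtraction ``a ⊖ b = (a1−b3, a2−b2, a3−b1)`` (interval rule)."""
    a, b = _coerce(a), _coerce(b)
    return TFN(a.a1 - b.a3, a.a2 - b.a2, a.a3 - b.a1)


def multiply(a: "TFN | Iterable[float]", b: "TFN | Iterable[float]") -> TFN:
    """Fuzzy product, re-triangularised.

    The exact product of two TFNs is not triangular; we keep the exact
    vertex ``a2·b2`` and the exact support (the α=0 interval product, i.e.
    the min and max of the four endpoint products), then read the result as
    a TFN again.  Membership between vertex and support is thus a linear
    approximation of the true (quadratic-sided) product.
    """
    a, b = _coerce(a), _coerce(b)
    corners = (a.a1 * b.a1, a.a1 * b.a3, a.a3 * b.a1, a.a3 * b.a3)
    lo, hi = min(corners), max(corners)
    v = a.a2 * b.a2
    # The vertex of the exact product always lies inside the support product,
    # so ordering holds; clip only to absorb floating-point round-off.
    v = min(max(v, lo), hi)
    return TFN(lo, v, hi)


def scale(a: "TFN | Iterable[float]", c: float) -> TFN:
    """Multiply a TFN by a crisp scalar (sign-aware endpoint swap)."""
    a = _coerce(a)
    if c >= 0:
        return TFN(c * a.a1, c * a.a2, c * a.a3)
    return TFN(c * a.a3, c * a.a2, c * a.a1)


def expected_value(a: "TFN | Iterable[float]") -> float:
    """Mean value of a TFN: ``(a1 + 2·a2 + a3) / 4``.

    This is the midpoint of the interval-valued fuzzy mean of Dubois-Prade
    type; for symmetric TFNs it coincides with the vertex.
    """
    a = _coerce(a)
    return (a.a1 + 2.0 * a.a2 + a.a3) / 4.0


def defuzzify_cog(a: "TFN | Iterable[float]") -> float:
    """Centre-of-gravity defuzzification: equal-weight mean ``(a1+a2+a3)/3``."""
    a = _coerce(a)
    return (a.a1 + a.a2 + a.a3) / 3.0


def width(a: "TFN | Iterable[float]") -> float:
    """Support length ``a3 − a1``, the degree of fuzziness of the TFN."""
    a = _coerce(a)
    return a.a3 - a.a1


def tfn_error(
    a: "TFN | Iterable[float]",
    b: "TFN | Iterable[float]",
    kind: str = "absolute",
    vertex_only: bool = False,
) -> float:
    """Pointwise discrepancy between two TFNs.

    Averages ``|a_i − b_i|`` (``kind='absolute'``) or ``(a_i − b_i)**2``
    (``kind='squared'``) over the three defining points.  With
    ``vertex_only=True`` only the vertices are compared.
    """
    a, b = _coerce(a), _coerce(b)
    if kind not in ("absolute", "squared"):
        raise ValueError(f"kind must be 'absolute' or 'squared', got {kind!r}")
    d = a.as_array() - b.as_array()
    if vertex_only:
        d = d[1:2]
    if kind == "absolute":
        return float(np.mean(np.abs(d)))
    return float(np.mean(d * d))
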