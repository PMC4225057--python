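"""Linear-combination (LC) quadratures on the observation interval.

An LC rule estimates the area under the concentration curve as
``Q = sum_i w_i C(t_i)`` with sampling times (knots) ``t_i`` and real
weights ``w_i``.  The class contains the trapezoid rule, its
extrapolated-to-zero variant, Gauss-Legendre and Clenshaw-Curtis rules,
and the minimax-optimal designs produced by :mod:`aucquad.minimax`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.polynomial.legendre import leggauss

from .pk_models import T_END

__all__ = [
    "Quadrature",
    "trapezoid_weights",
    "extrapolate_to_zero_adjustment",
    "gauss_legendre",
    "clenshaw_curtis",
    "estimate",
]

#: minimum admissible knot separation (h); avoids degenerate trapezoid panels
MIN_KNOT_GAP = 1e-6

KINDS = ("trapezoid", "trapezoid_extrapolated", "gauss_legendre",
         "clenshaw_curtis", "optimal_lc")


def _check_knots(knots: np.ndarray, interval=(0.0, T_END)) -> np.ndarray:
    knots = np.atleast_1d(np.asarray(knots, dtype=float))
    if knots.ndim != 1 or knots.size < 1:
        raise ValueError("knots must be a non-empty 1-d sequence")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    lo, hi = interval
    if knots[0] < lo - 1e-12 or knots[-1] > hi + 1e-12:
        raise ValueError(f"knots must lie within [{lo}, {hi}]")
    return knots


@dataclass
class Quadrature:
    """An LC rule: ordered knots (h) with matching real weights (h)."""

    knots: np.ndarray
    weights: np.ndarray
    kind: str = "optimal_lc"

    def __post_init__(self):
        self.knots = _check_knots(self.knots)
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if self.weights.shape != self.knots.shape:
            raise ValueError("weights must match knots in length")
        if self.kind not in KINDS:
            raise ValueError(f"unknown quadrature kind {self.kind!r}")
        if self.kind.startswith("trapezoid") and abs(self.knots[-1] - T_END) > 1e-9:
            raise ValueError("trapezoid rules must place the last knot at t=24")

    @property
    def n(self) -> int:
        """Sample size: the number of measured concentrations (knots)."""
        return self.knots.size

    def estimate(self, concentrations) -> float:
        return estimate(self, concentrations)

    # -- serialization ------------------------------------------------------

    def to_dict(self, **extra) -> dict:
        d = {
            "kind": self.kind,
            "n": self.n,
            "knots": self.knots.tolist(),
            "weights": self.weights.tolist(),
        }
        d.update(extra)
        return d

    def save(self, path, **extra) -> None:
        Path(path).write_text(json.dumps(self.to_dict(**extra), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "Quadrature":
        return cls(knots=np.array(d["knots"], dtype=float),
                   weights=np.array(d["weights"], dtype=float),
                   kind=d.get("kind", "optimal_lc"))

    @classmethod
    def load(cls, path) -> "Quadrature":
        return cls.from_dict(json.loads(Path(path).read_text()))


def trapezoid_weights(knots) -> np.ndarray:
    """Trapezoid-rule weights for ordered knots: the first and last weights
    are half the adjacent gap, interior weights half the bracketing span.
    They always sum to ``t_n - t_1``."""
    knots = _check_knots(knots)
    if knots.size < 2:
        raise ValueError("the trapezoid rule needs at least two knots")
    w = np.empty_like(knots)
    w[0] = (knots[1] - knots[0]) / 2.0
    w[-1] = (knots[-1] - knots[-2]) / 2.0
    if knots.size > 2:
        w[1:-1] = (knots[2:] - knots[:-2]) / 2.0
    return w


def extrapolate_to_zero_adjustment(knots) -> np.ndarray:
    """Weight increments that extend a trapezoid rule starting at t_1 > 0
    down to t = 0 by linear extrapolation through the first two samples.

    The extrapolated triangle-plus-trapezoid area on [0, t_1] is itself a
    linear combination of C(t_1) and C(t_2), so the adjusted rule stays in
    the LC class:  dw_1 = t_1 + t_1^2 / (2 (t_2 - t_1)),
    dw_2 = -t_1^2 / (2 (t_2 - t_1)).  Meaningful only for models with
    C(0) > 0.  Returns a length-n increment vector (zeros beyond the first
    two entries); all-zero when t_1 == 0.
    """
    knots = _check_knots(knots)
    if knots.size < 2:
        raise ValueError("extrapolation needs at least two knots")
    dw = np.zeros_like(knots)
    t1, t2 = knots[0], knots[1]
    if t1 <= 0.0:
        return dw
    gap = t2 - t1
    dw[0] = t1 + t1**2 / (2.0 * gap)
    dw[1] = -(t1**2) / (2.0 * gap)
    return dw


def gauss_legendre(n: int, interval=(0.0, T_END)) -> Quadrature:
    """Gauss-Legendre rule with ``n`` knots mapped onto the interval; exact
    for polynomials up to degree 2n - 1."""
    if n < 1:
        raise ValueError("Gauss-Legendre needs n >= 1")
    x, w = leggauss(int(n))
    a, b = interval
    half = (b - a) / 2.0
    return Quadrature(knots=a + half * (x + 1.0), weights=half * w,
                      kind="gauss_legendre")


def clenshaw_curtis(n: int, interval=(0.0, T_END)) -> Quadrature:
    """Closed Clenshaw-Curtis rule with ``n`` knots (Chebyshev extrema,
    endpoints included) mapped onto the interval; exact for polynomials up
    to degree n - 1 (and better in practice)."""
    if n < 2:
        raise ValueError("Clenshaw-Curtis needs n >= 2")
    n = int(n)
    N = n - 1
    theta = np.pi * np.arange(n) / N
    x = -np.cos(theta)  # ascending on [-1, 1]
    w = np.empty(n)
    # classical closed-rule weights via the cosine expansion
    for k in range(n):
        s = 0.0
        for j in range(1, N // 2 + 1):
            b = 1.0 if 2 * j == N else 2.0
            s += b / (4.0 * j * j - 1.0) * np.cos(2.0 * j * theta[k])
        c = 1.0 if k in (0, N) else 2.0
        w[k] = c / N * (1.0 - s)
    a, b = interval
    half = (b - a) / 2.0
    return Quadrature(knots=a + half * (x + 1.0), weights=half * w,
                      kind="clenshaw_curtis")


def estimate(quad: Quadrature, concentrations) -> float:
    """Apply the LC rule: the dot product of weights with the measured
    concentrations at the knots."""
    conc = np.asarray(concentrations, dtype=float)
    if conc.shape[-1] != quad.n:
        raise ValueError(
            f"expected {quad.n} concentrations, got {conc.shape[-1]}"
        )
    return conc @ quad.weights
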