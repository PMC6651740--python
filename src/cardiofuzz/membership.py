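"""Piecewise-linear fuzzy sets and linguistic variables.

A fuzzy set on a real universe is represented by a trapezoidal membership
function described by four knots ``a <= b <= c <= d``: membership rises
linearly from 0 at *a* to 1 at *b*, stays at 1 on ``[b, c]``, and falls
linearly back to 0 at *d*.  Two degenerate shapes cover everything the
heart-rate systems need:

* triangle — ``b == c`` (a single apex);
* shoulder — ``a == b`` (left) or ``c == d`` (right); the unit plateau
  extends past the degenerate edge, so readings beyond the knot keep
  membership 1.  Combined with universe clamping this makes the extreme
  terms of a variable absorb out-of-range physiological readings instead
  of dropping to zero.

A :class:`LinguisticVariable` bundles an ordered family of labelled terms
over a closed universe, e.g. resting heart rate partitioned from
``Sportsman`` up to ``Poor`` on [50, 90] bpm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

__all__ = ["PiecewiseLinearMF", "LinguisticVariable"]


@dataclass(frozen=True)
class PiecewiseLinearMF:
    """Trapezoid/triangle membership function given by four ordered knots."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        knots = (self.a, self.b, self.c, self.d)
        if not all(math.isfinite(k) for k in knots):
            raise ValueError(f"membership knots must be finite, got {knots}")
        if not (self.a <= self.b <= self.c <= self.d):
            raise ValueError(f"membership knots must be ordered a<=b<=c<=d, got {knots}")
        if self.a == self.d:
            raise ValueError("membership function has zero-width support")

    @property
    def is_left_shoulder(self) -> bool:
        return self.a == self.b

    @property
    def is_right_shoulder(self) -> bool:
        return self.c == self.d

    @property
    def support(self) -> Tuple[float, float]:
        return (self.a, self.d)

    def __call__(self, x):
        """Membership degree at ``x`` (scalar or array), always in [0, 1].

        For a left shoulder the unit plateau extends below ``a``; for a
        right shoulder above ``d``.  Callers that want hard-zero behaviour
        outside a closed universe should clamp first (see
        :meth:`LinguisticVariable.fuzzify`).
        """
        arr = np.asarray(x, dtype=float)
        if self.is_left_shoulder:
            rising = np.ones_like(arr)
        else:
            rising = (arr - self.a) / (self.b - self.a)
        if self.is_right_shoulder:
            falling = np.ones_like(arr)
        else:
            falling = (self.d - arr) / (self.d - self.c)
        mu = np.clip(np.minimum(rising, falling), 0.0, 1.0)
        return float(mu) if np.isscalar(x) or arr.ndim == 0 else mu


# grid used to check that the terms jointly cover the universe
_COVERAGE_POINTS = 2001


@dataclass(frozen=True)
class LinguisticVariable:
    """Named universe with an ordered family of labelled fuzzy terms.

    ``terms`` is ordered along the universe (worst/lowest first for the
    packaged systems); adjacency-based invariants such as "at most two
    terms overlap and they are neighbours" refer to this order.
    """

    name: str
    universe: Tuple[float, float]
    terms: Tuple[Tuple[str, PiecewiseLinearMF], ...]

    def __post_init__(self) -> None:
        lo, hi = self.universe
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValueError(f"{self.name}: universe must be a finite interval, got {self.universe}")
        if not self.terms:
            raise ValueError(f"{self.name}: variable needs at least one term")
        labels = [label for label, _ in self.terms]
        if len(set(labels)) != len(labels):
            raise ValueError(f"{self.name}: duplicate term labels {labels}")
        for label, mf in self.terms:
            s_lo, s_hi = mf.support
            if s_hi <= lo or s_lo >= hi:
                raise ValueError(f"{self.name}: term {label!r} support {mf.support} misses universe {self.universe}")
        grid = np.linspace(lo, hi, _COVERAGE_POINTS)
        total = np.zeros_like(grid)
        for _, mf in self.terms:
            total = np.maximum(total, mf(grid))
        if not np.all(total > 0.0):
            gap = grid[np.argmin(total)]
            raise ValueError(f"{self.name}: no term covers universe point {gap:g}")

    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple(label for label, _ in self.terms)

    def __getitem__(self, label: str) -> PiecewiseLinearMF:
        for lab, mf in self.terms:
            if lab == label:
                return mf
        raise KeyError(f"{self.name}: unknown term {label!r}")

    def clamp(self, x: float) -> float:
        """Clamp a reading into the closed universe."""
        if not math.isfinite(x):
            raise ValueError(f"{self.name}: reading must be finite, got {x}")
        lo, hi = self.universe
        return min(max(float(x), lo), hi)

    def membership(self, label: str, x: float) -> float:
        return self[label](self.clamp(x))

    def fuzzify(self, x: float) -> Dict[str, float]:
        """Degrees of every term at a crisp reading (clamped to the universe)."""
        xc = self.clamp(x)
        return {label: float(mf(xc)) for label, mf in self.terms}
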