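"""Shared fixtures and independent numerical oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import quad

from cardiofuzz import build_cel_system, build_treadmill_system, study_cohort


@pytest.fixture(scope="session")
def treadmill():
    return build_treadmill_system()


@pytest.fixture(scope="session")
def cel():
    return build_cel_system()


@pytest.fixture(scope="session")
def cohort():
    return study_cohort()


def trapezoid_mu(knots):
    """Independent membership evaluator used only as a test oracle."""
    a, b, c, d = knots

    def mu(x):
        if a == b and x <= c:
            return 1.0
        if c == d and x >= b:
            return 1.0
        if x <= a or x >= d:
            return 0.0
        if x < b:
            return (x - a) / (b - a)
        if x <= c:
            return 1.0
        return (d - x) / (d - c)

    return mu


def continuous_cog(clipped_terms, universe):
    """Continuous centre of gravity of max-of-clipped-trapezoids, via quadrature.

    ``clipped_terms`` is a list of (knots, activation) pairs.  This is the
    continuous-integral oracle the discrete COG must converge to.
    """
    mus = [(trapezoid_mu(k), level) for k, level in clipped_terms]

    def envelope(x):
        return max((min(level, mu(x)) for mu, level in mus), default=0.0)

    lo, hi = universe
    # integrate piecewise to keep quadrature honest across kinks
    breakpoints = sorted({lo, hi, *(k for knots, _ in clipped_terms for k in knots
                                    if lo <= k <= hi)})
    num = den = 0.0
    for left, right in zip(breakpoints[:-1], breakpoints[1:]):
        num += quad(lambda x: x * envelope(x), left, right, limit=200)[0]
        den += quad(envelope, left, right, limit=200)[0]
    return num / den


def max_drift_against_trend(values, decreasing=True):
    """Largest cumulative move against the expected trend along a sweep.

    For a nominally non-increasing sweep this is the biggest rise from a
    running minimum; Mamdani systems whose extreme rule cells share one
    consequent show a small such drift from clip-level changes alone.
    """
    seq = values if decreasing else [-v for v in values]
    worst, running_min = 0.0, seq[0]
    for v in seq:
        running_min = min(running_min, v)
        worst = max(worst, v - running_min)
    return worst


def brute_population_std(values):
    """Loop-based population standard deviation (oracle, no numpy)."""
    n = len(values)
    mean = sum(values) / n
    return (sum((v - mean) ** 2 for v in values) / n) ** 0.5
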