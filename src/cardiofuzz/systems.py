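"""The two concrete heart-rate fuzzy systems and their crisp reference maps.

Treadmill-speed recommender
    inputs  RHR (resting heart rate, bpm, universe [50, 90]) and planned
            exercise Time (min, [10, 70]);
    output  TS (treadmill speed, km/h, [0, 12]) over seven speed terms
            from Special Slow to Special Quick; 7 x 5 = 35 rules.

Endurance-level evaluator
    inputs  HRR (heart rate recovery, bpm, [20, 70]) and RHR;
    output  CEL (cardiorespiratory endurance level, 0-100) over five
            terms Please Strengthen / Medium / Good / Excellent /
            Special Excellent; 35 rules.

Both rule bases are also available in crisp matrix form (the reference
maps); the matrices are by construction the rule grids laid out row by
row, and the test suite asserts that equivalence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Dict, Optional, Tuple

from .engine import MamdaniSystem, defuzzify_cog
from .io import load_system

__all__ = [
    "CELResult",
    "SpeedRecommendation",
    "build_treadmill_system",
    "build_cel_system",
    "recommend_speed",
    "evaluate_endurance",
    "crisp_lookup_speed_term",
    "crisp_lookup_cel_term",
    "SPEED_REFERENCE",
    "CEL_REFERENCE",
    "cel_display_name",
]

# RHR term order as printed in the reference-map column headers
_RHR_COLS = ("P", "BA", "A", "AA", "G", "E", "S")

# Treadmill-speed reference map: row = Time term, column = RHR term.
SPEED_REFERENCE: Dict[str, Dict[str, str]] = {
    time_term: dict(zip(_RHR_COLS, row.split()))
    for time_term, row in {
        "VF": "S O Q LQ LQ SQ SQ",
        "F": "LS S O Q Q LQ SQ",
        "S": "LS S O O Q Q LQ",
        "M": "SS LS S O O Q Q",
        "VM": "SS SS LS LS S O O",
    }.items()
}

# Endurance-level reference map: row = HRR term, column = RHR term.
CEL_REFERENCE: Dict[str, Dict[str, str]] = {
    hrr_term: dict(zip(_RHR_COLS, row.split()))
    for hrr_term, row in {
        "O": "PS PS PS M M G G",
        "SO": "PS PS M M G G E",
        "Q": "PS M M G G E E",
        "SY": "M M G G E E SE",
        "Y": "M G G E E SE SE",
    }.items()
}


@dataclass(frozen=True)
class SpeedRecommendation:
    """Crisp treadmill speed plus the speed terms that fired (diagnostic)."""

    speed_kmh: float
    fired_terms: Dict[str, float]


@dataclass(frozen=True)
class CELResult:
    """Defuzzified endurance score with its linguistic label.

    ``label`` is the output term with maximal membership at ``score``;
    an exact tie at a 0.5 crossover resolves toward the higher (better)
    category.  ``memberships`` holds every term's degree at the score.
    """

    score: float
    label: str
    memberships: Dict[str, float]

    @property
    def display_label(self) -> str:
        return cel_display_name(self.label)


def _load_packaged(filename: str) -> MamdaniSystem:
    ref = resources.files("cardiofuzz.data").joinpath(filename)
    with ref.open("r", encoding="utf-8") as fh:
        return load_system(json.load(fh))


def build_treadmill_system() -> MamdaniSystem:
    """The packaged RHR x Time -> TS system (35 rules)."""
    return _load_packaged("treadmill_speed.json")


def build_cel_system() -> MamdaniSystem:
    """The packaged HRR x RHR -> CEL system (35 rules)."""
    return _load_packaged("endurance_level.json")


@lru_cache(maxsize=None)
def _default_treadmill() -> MamdaniSystem:
    return build_treadmill_system()


@lru_cache(maxsize=None)
def _default_cel() -> MamdaniSystem:
    return build_cel_system()


def cel_display_name(label: str) -> str:
    names = _default_cel().display_names.get(label)
    return names[0] if names else label


def _check_reading(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise ValueError(f"{name} must be a positive finite reading, got {value}")
    return value


def recommend_speed(rhr_bpm: float, time_min: float,
                    system: Optional[MamdaniSystem] = None,
                    cog_samples: Optional[int] = None) -> SpeedRecommendation:
    """Recommend a treadmill speed (km/h) from resting HR and planned time.

    Readings outside the modelled universes are clamped, so e.g. an RHR
    of 95 bpm is treated like the worst modelled value rather than
    rejected.
    """
    rhr = _check_reading("rhr_bpm", rhr_bpm)
    time = _check_reading("time_min", time_min)
    sys_ = system if system is not None else _default_treadmill()
    readings = {sys_.inputs[0].name: rhr, sys_.inputs[1].name: time}
    agg = sys_.fire_rules(readings)
    n = sys_.cog_samples if cog_samples is None else cog_samples
    speed = defuzzify_cog(agg, sys_.output, n)
    return SpeedRecommendation(speed_kmh=speed, fired_terms=agg.fired)


def evaluate_endurance(rhr_bpm: float, hrr_bpm: float,
                       system: Optional[MamdaniSystem] = None,
                       cog_samples: Optional[int] = None) -> CELResult:
    """Score cardiorespiratory endurance (0-100) from RHR and HRR."""
    rhr = _check_reading("rhr_bpm", rhr_bpm)
    hrr = _check_reading("hrr_bpm", hrr_bpm)
    sys_ = system if system is not None else _default_cel()
    readings = {"RHR": rhr, "HRR": hrr}
    agg = sys_.fire_rules(readings)
    n = sys_.cog_samples if cog_samples is None else cog_samples
    score = defuzzify_cog(agg, sys_.output, n)
    memberships = sys_.output.fuzzify(score)
    label = _argmax_label(sys_.output.labels, memberships)
    return CELResult(score=score, label=label, memberships=memberships)


def _argmax_label(ordered_labels: Tuple[str, ...], memberships: Dict[str, float],
                  tie_eps: float = 1e-12) -> str:
    """Label with maximal membership; exact ties go to the higher category."""
    top = max(memberships[label] for label in ordered_labels)
    for label in reversed(ordered_labels):
        if memberships[label] >= top - tie_eps:
            return label
    raise AssertionError("unreachable: memberships cannot all be below their max")


def crisp_lookup_speed_term(rhr_term: str, time_term: str) -> str:
    """Reference-map lookup: TS term for exact (RHR term, Time term)."""
    try:
        return SPEED_REFERENCE[time_term][rhr_term]
    except KeyError as exc:
        raise KeyError(f"unknown term pair (RHR={rhr_term!r}, Time={time_term!r})") from exc


def crisp_lookup_cel_term(hrr_term: str, rhr_term: str) -> str:
    """Reference-map lookup: CEL term for exact (HRR term, RHR term)."""
    try:
        return CEL_REFERENCE[hrr_term][rhr_term]
    except KeyError as exc:
        raise KeyError(f"unknown term pair (HRR={hrr_term!r}, RHR={rhr_term!r})") from exc


def reference_map_matches_rules(system: MamdaniSystem,
                                reference: Dict[str, Dict[str, str]],
                                row_var: str, col_var: str) -> bool:
    """True when every rule's consequent equals its reference-map cell."""
    for rule in system.rule_base:
        clauses = dict(rule.antecedent)
        if reference[clauses[row_var]][clauses[col_var]] != rule.consequent[1]:
            return False
    return True
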