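"""Closed-form exercise-physiology formulas and reference tables.

Covers the scalar layer around the fuzzy systems: the age-predicted
maximal heart rate, a polynomial VO2 estimate from heart rate, the two
pre/post training indicators

    DRHR = (pre RHR - post RHR) / pre RHR * 100   (decrease rate of RHR)
    GHRR = (post HRR - pre HRR) / pre HRR * 100   (growth rate of HRR)

and small banded lookups: resting-heart-rate category, the HRR-based
physiological-age interpretation, the %MHR -> %VO2max map, the activity
index score bands, and the week-by-week aerobic exercise prescription.

Reported percentages in the study tables are integers; the matching
rounding convention is half away from zero (``round_half_away``), and
every indicator is exposed both raw and rounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "round_half_away",
    "round1",
    "max_heart_rate",
    "estimate_vo2",
    "drhr",
    "drhr_pct",
    "ghrr",
    "ghrr_pct",
    "classify_rhr_category",
    "RHR_CATEGORIES",
    "hrr_age_interpretation",
    "vo2max_pct_from_mhr_pct",
    "activity_index_category",
    "aerobic_prescription",
    "PrescriptionStage",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (17.5 -> 18)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def round1(x: float) -> float:
    """Round to one decimal, halves away from zero (72.05 -> 72.1)."""
    return math.copysign(math.floor(abs(x) * 10 + 0.5), x) / 10


def _require_positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise ValueError(f"{name} must be positive and finite, got {value}")
    return value


def max_heart_rate(age_years: float) -> float:
    """Age-predicted maximal heart rate: 208 - 0.7 * age (bpm)."""
    age = _require_positive("age_years", age_years)
    return 208.0 - 0.7 * age


def estimate_vo2(hr_bpm: float) -> float:
    """Oxygen uptake (L/min) from heart rate: 0.002*HR^2 - 0.13*HR + 2.3."""
    hr = _require_positive("hr_bpm", hr_bpm)
    return 0.002 * hr * hr - 0.13 * hr + 2.3


def drhr(pre_rhr: float, post_rhr: float) -> float:
    """Decrease rate of resting heart rate, signed percent (unrounded)."""
    pre = _require_positive("pre_rhr", pre_rhr)
    return (pre - float(post_rhr)) / pre * 100.0


def drhr_pct(pre_rhr: float, post_rhr: float) -> int:
    """DRHR rounded to integer percent, halves away from zero."""
    return round_half_away(drhr(pre_rhr, post_rhr))


def ghrr(pre_hrr: float, post_hrr: float) -> float:
    """Growth rate of heart rate recovery, signed percent (unrounded)."""
    pre = _require_positive("pre_hrr", pre_hrr)
    return (float(post_hrr) - pre) / pre * 100.0


def ghrr_pct(pre_hrr: float, post_hrr: float) -> int:
    """GHRR rounded to integer percent, halves away from zero."""
    return round_half_away(ghrr(pre_hrr, post_hrr))


RHR_CATEGORIES = ("over-80", "70s", "below-70")


def classify_rhr_category(rhr_bpm: float) -> str:
    """Resting-HR band used for the study breakdown.

    >= 80 bpm -> "over-80"; [70, 80) -> "70s"; < 70 -> "below-70".
    Exactly one category applies to every positive reading.
    """
    rhr = _require_positive("rhr_bpm", rhr_bpm)
    if rhr >= 80.0:
        return "over-80"
    if rhr >= 70.0:
        return "70s"
    return "below-70"


def hrr_age_interpretation(hrr_bpm: float) -> str:
    """Physiological-age reading of a heart-rate-recovery value (bpm)."""
    hrr = _require_positive("hrr_bpm", hrr_bpm)
    if hrr < 22:
        return "physiological age is older than the actual age"
    if hrr < 53:
        return "physiological age is equivalent to the actual age"
    if hrr < 59:
        return "physiological age is slightly younger than the actual age"
    if hrr < 66:
        return "physiological age is younger than the actual age"
    return "physiological age is much younger than the actual age"


# %MHR -> %VO2max anchor pairs (intensity equivalence map)
_MHR_PCT = np.array([66, 70, 74, 77, 81, 85, 88, 92, 96, 98, 100], dtype=float)
_VO2_PCT = np.array([50, 55, 60, 65, 70, 75, 80, 85, 90, 95, 100], dtype=float)


def vo2max_pct_from_mhr_pct(mhr_pct: float) -> float:
    """%VO2max from %MHR by piecewise-linear interpolation on [66, 100]."""
    pct = float(mhr_pct)
    if not math.isfinite(pct) or pct < _MHR_PCT[0] or pct > _MHR_PCT[-1]:
        raise ValueError(f"mhr_pct must lie in [{_MHR_PCT[0]:g}, {_MHR_PCT[-1]:g}], got {mhr_pct}")
    return float(np.interp(pct, _MHR_PCT, _VO2_PCT))


def activity_index_category(intensity_score: float, time_score: float,
                            freq_score: float) -> str:
    """Lifestyle category from the activity index product.

    Total score = intensity * time * frequency; bands >100 / 80-100 /
    40-80 / 20-40 / <20, with boundary scores assigned to the higher band.
    """
    total = (_require_positive("intensity_score", intensity_score)
             * _require_positive("time_score", time_score)
             * _require_positive("freq_score", freq_score))
    if total > 100:
        return "Very good"
    if total >= 80:
        return "Good"
    if total >= 40:
        return "Normal"
    if total >= 20:
        return "Bad"
    return "Very Bad"


@dataclass(frozen=True)
class PrescriptionStage:
    """One column of the aerobic-prescription schedule.

    ``weeks`` is the inclusive week range; ``None`` as the upper bound
    means open-ended.  Durations are minutes; intensity is percent of
    MHR.  The warm-up/cool-down rows are stored verbatim from the
    source schedule; where they disagree with the stated session total,
    ``total_min`` is the authoritative figure.
    """

    weeks: Tuple[int, Optional[int]]
    stage: str
    frequency_per_week: int
    warmup_min: float
    main_min: float
    cooldown_min: float
    total_min: float
    intensity_pct_mhr: float
    open_ended_duration: bool = False


AEROBIC_PRESCRIPTION: Tuple[PrescriptionStage, ...] = (
    PrescriptionStage((1, 2), "begin", 3, 5, 10, 20, 20, 55),
    PrescriptionStage((3, 4), "begin", 3, 5, 13, 23, 23, 55),
    PrescriptionStage((5, 6), "begin", 3, 5, 15, 25, 25, 60),
    PrescriptionStage((7, 8), "begin", 3, 6, 15, 27, 27, 60),
    PrescriptionStage((9, 10), "improvement", 3, 6, 20, 32, 32, 65),
    PrescriptionStage((11, 12), "improvement", 3, 7, 20, 34, 34, 65),
    PrescriptionStage((13, 14), "improvement", 4, 7, 23, 37, 37, 65),
    PrescriptionStage((15, 16), "improvement", 4, 8, 25, 40, 40, 70),
    PrescriptionStage((17, 18), "improvement", 4, 8, 28, 43, 43, 70),
    PrescriptionStage((19, 20), "improvement", 4, 8, 30, 45, 45, 70),
    PrescriptionStage((21, None), "maintain", 5, 8, 35, 7, 50, 75, True),
)


def aerobic_prescription(week: int) -> PrescriptionStage:
    """The prescription stage covering a training week (week >= 1)."""
    if week < 1 or week != int(week):
        raise ValueError(f"week must be a positive integer, got {week}")
    for stage in AEROBIC_PRESCRIPTION:
        lo, hi = stage.weeks
        if week >= lo and (hi is None or week <= hi):
            return stage
    raise AssertionError("unreachable: final stage is open-ended")
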