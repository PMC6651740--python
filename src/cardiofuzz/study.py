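"""Pre/post training-study pipeline: per-subject indicators and group stats.

Input is a cohort table (CSV) with one row per participant::

    code,group,pre_rhr,pre_hrr,post_rhr,post_hrr

where ``group`` is ``reference`` (participants who also adjusted speed
by their own judgement) or ``control`` (participants who followed the
recommender); the packaged study keeps those labels as given.  The
pipeline computes, per subject, the integer-rounded DRHR/GHRR
indicators, the pre-test resting-HR category and (optionally) the
fuzzy endurance score from the post-test readings; per group, pre/post
means and population standard deviations (one decimal), the mean
pre-to-post difference, and the group's average improvement as the
rounded mean of per-subject rounded percentages; and cohort-level
category ratios and overall improvement averages.

Statistical conventions (chosen to be explicit, and validated against
the packaged study in the test suite):

* standard deviations divide by n (population form), not n - 1;
* displayed means are rounded half away from zero to one decimal, and
  the mean difference is the difference of the rounded means;
* a group's improvement percentage is the half-away-rounded mean of the
  per-subject half-away-rounded integer percentages;
* the spread of the paired differences is reported as the population
  standard deviation of (post - pre) per subject, named
  ``paired_diff_std``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .physiology import (
    classify_rhr_category,
    drhr_pct,
    ghrr_pct,
    round1,
    round_half_away,
    RHR_CATEGORIES,
)
from .systems import CELResult, evaluate_endurance

__all__ = [
    "GROUPS",
    "ParticipantRecord",
    "SubjectMetrics",
    "GroupSummary",
    "CohortRatios",
    "read_cohort",
    "write_cohort",
    "per_subject_metrics",
    "group_summary",
    "overall_improvements",
    "category_ratios",
    "report",
]

GROUPS = ("reference", "control")
_COLUMNS = ("code", "group", "pre_rhr", "pre_hrr", "post_rhr", "post_hrr")


@dataclass(frozen=True)
class ParticipantRecord:
    """One subject's group assignment and pre/post RHR and HRR readings."""

    code: str
    group: str
    pre_rhr: float
    pre_hrr: float
    post_rhr: float
    post_hrr: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"{self.code}: group must be one of {GROUPS}, got {self.group!r}")
        for field_name in ("pre_rhr", "pre_hrr", "post_rhr", "post_hrr"):
            value = getattr(self, field_name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{self.code}: {field_name} must be positive, got {value}")


@dataclass(frozen=True)
class SubjectMetrics:
    """Per-subject training indicators (integer percents) and category."""

    code: str
    group: str
    drhr_pct: int
    ghrr_pct: int
    rhr_category: str
    cel: Optional[CELResult] = None


@dataclass(frozen=True)
class GroupSummary:
    """One group x one indicator (RHR or HRR): pre/post stats, one decimal."""

    group: str
    indicator: str
    n: int
    pre_mean: float
    pre_std: float
    post_mean: float
    post_std: float
    mean_diff: float
    paired_diff_std: float
    improvement_pct: int


@dataclass(frozen=True)
class CohortRatios:
    """Fraction of the cohort in each pre-test resting-HR category."""

    counts: Dict[str, int]
    fractions: Dict[str, float]


def read_cohort(path: Union[str, Path]) -> List[ParticipantRecord]:
    """Read a cohort CSV into validated records; empty file -> empty list."""
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    missing = [col for col in _COLUMNS if col not in frame.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing column(s) {missing}")
    if frame.empty:
        return []
    for col in _COLUMNS[2:]:
        values = pd.to_numeric(frame[col], errors="coerce")
        if values.isna().any():
            bad = frame.loc[values.isna(), "code"].tolist()
            raise ValueError(f"non-numeric {col} for subject(s) {bad}")
        frame[col] = values
    codes = frame["code"].astype(str)
    dupes = codes[codes.duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate subject code(s) {sorted(set(dupes))}")
    return [
        ParticipantRecord(
            code=str(row.code), group=str(row.group),
            pre_rhr=float(row.pre_rhr), pre_hrr=float(row.pre_hrr),
            post_rhr=float(row.post_rhr), post_hrr=float(row.post_hrr),
        )
        for row in frame.itertuples(index=False)
    ]


def write_cohort(records: Sequence[ParticipantRecord], path: Union[str, Path]) -> None:
    """Write records back to CSV (inverse of :func:`read_cohort`)."""
    frame = pd.DataFrame([asdict(r) for r in records], columns=list(_COLUMNS))
    frame.to_csv(path, index=False)


def per_subject_metrics(cohort: Sequence[ParticipantRecord],
                        include_cel: bool = True) -> List[SubjectMetrics]:
    """DRHR/GHRR percents, pre-RHR category and (optionally) the fuzzy CEL.

    The endurance score is evaluated on the post-test readings — the
    state of the subject after training.
    """
    out = []
    for rec in cohort:
        cel = evaluate_endurance(rec.post_rhr, rec.post_hrr) if include_cel else None
        out.append(SubjectMetrics(
            code=rec.code,
            group=rec.group,
            drhr_pct=drhr_pct(rec.pre_rhr, rec.post_rhr),
            ghrr_pct=ghrr_pct(rec.pre_hrr, rec.post_hrr),
            rhr_category=classify_rhr_category(rec.pre_rhr),
            cel=cel,
        ))
    return out


def _summarize(group: str, indicator: str, pre: np.ndarray, post: np.ndarray,
               improvements: Sequence[int]) -> GroupSummary:
    pre_mean, post_mean = round1(pre.mean()), round1(post.mean())
    return GroupSummary(
        group=group,
        indicator=indicator,
        n=len(pre),
        pre_mean=pre_mean,
        pre_std=round1(pre.std(ddof=0)),
        post_mean=post_mean,
        post_std=round1(post.std(ddof=0)),
        mean_diff=round1(post_mean - pre_mean),
        paired_diff_std=round1((post - pre).std(ddof=0)),
        improvement_pct=round_half_away(float(np.mean(improvements))),
    )


def group_summary(cohort: Sequence[ParticipantRecord]) -> Dict[str, Dict[str, GroupSummary]]:
    """Per-group RHR and HRR summaries keyed ``[group][indicator]``."""
    summaries: Dict[str, Dict[str, GroupSummary]] = {}
    for group in GROUPS:
        members = [r for r in cohort if r.group == group]
        if not members:
            raise ValueError(f"group {group!r} is empty")
        pre_rhr = np.array([r.pre_rhr for r in members])
        post_rhr = np.array([r.post_rhr for r in members])
        pre_hrr = np.array([r.pre_hrr for r in members])
        post_hrr = np.array([r.post_hrr for r in members])
        summaries[group] = {
            "RHR": _summarize(group, "RHR", pre_rhr, post_rhr,
                              [drhr_pct(r.pre_rhr, r.post_rhr) for r in members]),
            "HRR": _summarize(group, "HRR", pre_hrr, post_hrr,
                              [ghrr_pct(r.pre_hrr, r.post_hrr) for r in members]),
        }
    return summaries


def overall_improvements(summaries: Dict[str, Dict[str, GroupSummary]]) -> Tuple[float, float]:
    """Unweighted mean of the two groups' improvement percents (RHR, HRR)."""
    rhr = np.mean([summaries[g]["RHR"].improvement_pct for g in GROUPS])
    hrr = np.mean([summaries[g]["HRR"].improvement_pct for g in GROUPS])
    return float(rhr), float(hrr)


def category_ratios(cohort: Sequence[ParticipantRecord]) -> CohortRatios:
    """Share of subjects per pre-test resting-HR band; fractions sum to 1."""
    if not cohort:
        raise ValueError("cohort is empty")
    counts = {cat: 0 for cat in RHR_CATEGORIES}
    for rec in cohort:
        counts[classify_rhr_category(rec.pre_rhr)] += 1
    n = len(cohort)
    return CohortRatios(counts=counts,
                        fractions={cat: counts[cat] / n for cat in RHR_CATEGORIES})


def _cel_dict(cel: Optional[CELResult]) -> Optional[dict]:
    if cel is None:
        return None
    return {"score": round(cel.score, 2), "label": cel.label,
            "display_label": cel.display_label}


def report(cohort: Sequence[ParticipantRecord],
           path: Optional[Union[str, Path]] = None,
           include_cel: bool = True) -> dict:
    """Full machine-readable study report; optionally written as JSON.

    The JSON serialization is byte-stable for fixed inputs (sorted keys,
    fixed separators, trailing newline).
    """
    metrics = per_subject_metrics(cohort, include_cel=include_cel)
    summaries = group_summary(cohort)
    rhr_overall, hrr_overall = overall_improvements(summaries)
    ratios = category_ratios(cohort)
    doc = {
        "n_subjects": len(cohort),
        "subjects": [
            {
                "code": m.code,
                "group": m.group,
                "drhr_pct": m.drhr_pct,
                "ghrr_pct": m.ghrr_pct,
                "rhr_category": m.rhr_category,
                **({"cel": _cel_dict(m.cel)} if include_cel else {}),
            }
            for m in metrics
        ],
        "groups": {
            group: {ind: asdict(summ) for ind, summ in inds.items()}
            for group, inds in summaries.items()
        },
        "overall_improvement_pct": {"RHR": rhr_overall, "HRR": hrr_overall},
        "rhr_category_ratios": {
            "counts": ratios.counts,
            "fractions": {k: round(v, 6) for k, v in ratios.fractions.items()},
        },
    }
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True, separators=(",", ": "))
            fh.write("\n")
    return doc
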