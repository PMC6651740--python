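"""Packaged study data and a synthetic pre/post cohort generator.

:func:`study_cohort` returns the packaged 25-subject training study
(12 reference + 13 control) verbatim.  :func:`generate_cohort` draws
synthetic cohorts from a :class:`CohortModel`: pre-test RHR and HRR are
truncated normals on a plausible bpm range, and training effects (RHR
decrease, HRR increase) are normal draws applied per subject, with
post-test values clipped back into the bpm bounds.  The default model
(:meth:`CohortModel.from_study`) takes each group's means and
population standard deviations directly from the packaged study, so a
generated cohort statistically resembles the real one.

Truncated normals are the natural choice here because group mean and
standard deviation are the only distributional facts the study reports,
and heart-rate readings live on a bounded physiological range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import List, Optional, Tuple

import numpy as np
from scipy import stats

from .study import GROUPS, ParticipantRecord, read_cohort

__all__ = ["GroupModel", "CohortModel", "study_cohort", "generate_cohort"]

# plausible resting-heart-rate range (bpm); RHR readings never leave this
RHR_BOUNDS = (40.0, 120.0)
# heart rate recovery is a *drop* in bpm over two minutes, so its plausible
# range sits much lower than an absolute heart rate
HRR_BOUNDS = (5.0, 90.0)


def study_cohort() -> List[ParticipantRecord]:
    """The packaged 25-subject pre/post training study, verbatim."""
    ref = resources.files("cardiofuzz.data").joinpath("study_cohort.csv")
    with resources.as_file(ref) as path:
        return read_cohort(path)


@dataclass(frozen=True)
class GroupModel:
    """Generative parameters for one group (all heart rates in bpm)."""

    n: int
    pre_rhr_mean: float
    pre_rhr_sd: float
    pre_hrr_mean: float
    pre_hrr_sd: float
    rhr_decrease_mean: float
    rhr_decrease_sd: float
    hrr_increase_mean: float
    hrr_increase_sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group size must be >= 1, got {self.n}")
        for name in ("pre_rhr_sd", "pre_hrr_sd", "rhr_decrease_sd", "hrr_increase_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (RHR_BOUNDS[0] <= self.pre_rhr_mean <= RHR_BOUNDS[1]):
            raise ValueError(
                f"pre_rhr_mean={self.pre_rhr_mean} outside plausible range {RHR_BOUNDS}")
        if not (HRR_BOUNDS[0] <= self.pre_hrr_mean <= HRR_BOUNDS[1]):
            raise ValueError(
                f"pre_hrr_mean={self.pre_hrr_mean} outside plausible range {HRR_BOUNDS}")


@dataclass(frozen=True)
class CohortModel:
    """Two-group cohort model with bpm bounds and a reproducibility seed."""

    reference: GroupModel
    control: GroupModel
    rhr_bounds: Tuple[float, float] = RHR_BOUNDS
    hrr_bounds: Tuple[float, float] = HRR_BOUNDS
    seed: int = 0

    @classmethod
    def from_study(cls, seed: int = 0) -> "CohortModel":
        """Default model: group statistics measured from the packaged study.

        Pre-test distributions use each group's mean and population SD;
        effect distributions use the mean and population SD of the
        per-subject paired differences.
        """
        cohort = study_cohort()
        groups = {}
        for group in GROUPS:
            members = [r for r in cohort if r.group == group]
            pre_rhr = np.array([r.pre_rhr for r in members])
            pre_hrr = np.array([r.pre_hrr for r in members])
            rhr_drop = np.array([r.pre_rhr - r.post_rhr for r in members])
            hrr_gain = np.array([r.post_hrr - r.pre_hrr for r in members])
            groups[group] = GroupModel(
                n=len(members),
                pre_rhr_mean=float(pre_rhr.mean()), pre_rhr_sd=float(pre_rhr.std(ddof=0)),
                pre_hrr_mean=float(pre_hrr.mean()), pre_hrr_sd=float(pre_hrr.std(ddof=0)),
                rhr_decrease_mean=float(rhr_drop.mean()), rhr_decrease_sd=float(rhr_drop.std(ddof=0)),
                hrr_increase_mean=float(hrr_gain.mean()), hrr_increase_sd=float(hrr_gain.std(ddof=0)),
            )
        return cls(reference=groups["reference"], control=groups["control"], seed=seed)

    def with_sizes(self, n_reference: int, n_control: int) -> "CohortModel":
        return replace(self,
                       reference=replace(self.reference, n=n_reference),
                       control=replace(self.control, n=n_control))


def _truncated_normal(mean: float, sd: float, n: int, bounds: Tuple[float, float],
                      rng: np.random.Generator) -> np.ndarray:
    if sd == 0.0:
        return np.full(n, mean)
    lo, hi = bounds
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(model: CohortModel, seed: Optional[int] = None) -> List[ParticipantRecord]:
    """Draw a synthetic cohort; identical seeds give identical cohorts."""
    rng = np.random.default_rng(model.seed if seed is None else seed)
    records: List[ParticipantRecord] = []
    for prefix, group, gm in (("R", "reference", model.reference),
                              ("C", "control", model.control)):
        pre_rhr = _truncated_normal(gm.pre_rhr_mean, gm.pre_rhr_sd, gm.n, model.rhr_bounds, rng)
        pre_hrr = _truncated_normal(gm.pre_hrr_mean, gm.pre_hrr_sd, gm.n, model.hrr_bounds, rng)
        rhr_drop = (np.full(gm.n, gm.rhr_decrease_mean) if gm.rhr_decrease_sd == 0.0
                    else rng.normal(gm.rhr_decrease_mean, gm.rhr_decrease_sd, gm.n))
        hrr_gain = (np.full(gm.n, gm.hrr_increase_mean) if gm.hrr_increase_sd == 0.0
                    else rng.normal(gm.hrr_increase_mean, gm.hrr_increase_sd, gm.n))
        post_rhr = np.clip(pre_rhr - rhr_drop, *model.rhr_bounds)
        post_hrr = np.clip(pre_hrr + hrr_gain, *model.hrr_bounds)
        for i in range(gm.n):
            records.append(ParticipantRecord(
                code=f"{prefix}{i + 1}", group=group,
                pre_rhr=float(pre_rhr[i]), pre_hrr=float(pre_hrr[i]),
                post_rhr=float(post_rhr[i]), post_hrr=float(post_hrr[i]),
            ))
    return records
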