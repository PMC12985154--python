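"""Quality-adjusted life years over the trial horizon.

QALYs are the area under the utility–time curve (trapezoid rule) with
assessment times in weeks converted to years. The between-arm comparison is
ANCOVA on the patient-level QALY with the centred baseline utility as the
covariate, which is the standard correction for chance baseline imbalance in
trial-based analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .inference import GroupDifference, group_difference

#: Weeks per year used to convert the assessment grid to years (365.25 / 7).
WEEKS_PER_YEAR: float = 365.25 / 7.0


@dataclass(frozen=True)
class UtilityTrajectory:
    """Utilities at ascending assessment weeks, first week = 0."""

    times: tuple[float, ...]
    utilities: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        u = np.asarray(self.utilities, dtype=float)
        if t.size < 2:
            raise ValidationError("a utility trajectory needs at least 2 assessment points")
        if t.size != u.size:
            raise ValidationError("times and utilities must have equal length")
        if t[0] != 0:
            raise ValidationError("the first assessment must be at week 0")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("assessment weeks must be strictly increasing")
        if np.any(u < -1) or np.any(u > 1):
            raise ValidationError("utilities must lie in [-1, 1]")


def qaly_auc(traj: UtilityTrajectory | tuple, utilities=None, *,
             weeks_per_year: float = WEEKS_PER_YEAR) -> float:
    """Trapezoid-rule area under the utility curve, in years.

    Accepts a :class:`UtilityTrajectory` or ``qaly_auc(times, utilities)``.
    """
    if utilities is not None:
        traj = UtilityTrajectory(tuple(traj), tuple(utilities))
    elif not isinstance(traj, UtilityTrajectory):
        raise ValidationError("pass a UtilityTrajectory or (times, utilities)")
    t = np.asarray(traj.times, dtype=float)
    u = np.asarray(traj.utilities, dtype=float)
    return float(np.trapezoid(u, t)) / weeks_per_year


def qaly_auc_matrix(times, utilities, *, weeks_per_year: float = WEEKS_PER_YEAR) -> np.ndarray:
    """Vectorised trapezoid QALY for an (n_patients, n_times) utility array."""
    t = np.asarray(times, dtype=float)
    u = np.asarray(utilities, dtype=float)
    return np.trapezoid(u, t, axis=1) / weeks_per_year


@dataclass
class QALYResult:
    """Baseline-adjusted per-arm mean QALYs and their difference."""

    arm_means: dict[str, float]
    difference: float
    ci_low: float
    ci_high: float
    p_value: float
    se: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.difference <= self.ci_high):
            raise ValidationError("CI must bracket the difference")


def baseline_adjusted_difference(qalys, arms, baseline_utilities, *,
                                 trt: str = "PPT", ref: str = "PT",
                                 alpha: float = 0.05) -> QALYResult:
    """ANCOVA-adjusted QALY difference (``trt`` − ``ref``).

    Fits ``QALY ~ arm + (baseline − mean(baseline))``; the adjusted arm
    means are the model predictions at the grand-mean baseline, so their
    difference is the arm coefficient. If the baselines are constant the
    covariate is dropped and the result reduces to the raw mean difference.
    """
    q = pd.Series(np.asarray(qalys, dtype=float))
    b = pd.Series(np.asarray(baseline_utilities, dtype=float))
    gd: GroupDifference = group_difference(q, arms, covariates=b, trt=trt, ref=ref, alpha=alpha)
    return QALYResult(
        arm_means=gd.adjusted_means,
        difference=gd.estimate,
        ci_low=gd.ci_low,
        ci_high=gd.ci_high,
        p_value=gd.p_value,
        se=gd.se,
    )
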