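"""The patient-level trial container and its wide analysis layout.

A :class:`TrialDataset` bundles four tidy tables:

* ``patients`` — one row per patient: arm, demographics, wage, attendance,
  and the per-visit transport cost and door-to-door minutes surveyed at
  week 1.
* ``visits``   — one row per patient × assessment week: EQ-5D-5L and SF-6D
  utilities (optionally the raw 5-digit EQ-5D profile).
* ``wpai``     — one row per patient × period: WPAI 7-day-recall responses.
* ``resource`` — one row per patient × period: additional provider visits
  and the out-of-pocket amount they cost.

``analysis_frame`` flattens this to one row per patient with the derived
impairment fractions — the layout the imputation, costing and bootstrap
stages operate on. Missing values are NaN throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costing import PERIODS
from .exceptions import ValidationError

ARMS: tuple[str, str] = ("PPT", "PT")

PATIENT_COLUMNS = ("patient_id", "arm", "sex", "age", "bmi", "employed",
                   "weekly_wage", "sessions_received", "weeks_attended",
                   "minutes_per_visit", "transport_per_visit")
VISIT_COLUMNS = ("patient_id", "week", "eq5d_utility", "sf6d_utility")
WPAI_COLUMNS = ("patient_id", "period", "hours_missed", "hours_worked",
                "work_degree", "activity_degree")
RESOURCE_COLUMNS = ("patient_id", "period", "additional_visits", "additional_oop")

#: Maximum sessions: twice weekly for 6 weeks.
MAX_SESSIONS = 12


@dataclass
class TrialDataset:
    """Visit-level records for a two-arm pragmatic trial."""

    patients: pd.DataFrame
    visits: pd.DataFrame
    wpai: pd.DataFrame
    resource: pd.DataFrame
    assessment_weeks: tuple[int, ...] = (0, 7, 13)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, df, required in (("patients", self.patients, PATIENT_COLUMNS),
                                   ("visits", self.visits, VISIT_COLUMNS),
                                   ("wpai", self.wpai, WPAI_COLUMNS),
                                   ("resource", self.resource, RESOURCE_COLUMNS)):
            missing = [c for c in required if c not in df.columns]
            if missing:
                raise ValidationError(f"table {name!r} is missing columns {missing}")
        p = self.patients
        if p["patient_id"].duplicated().any():
            raise ValidationError("duplicate patient ids")
        bad_arm = set(p["arm"]) - set(ARMS)
        if bad_arm:
            raise ValidationError(f"unknown arm labels: {sorted(bad_arm)}")
        if (p["sessions_received"] > MAX_SESSIONS).any():
            raise ValidationError(f"sessions_received exceeds {MAX_SESSIONS} (twice weekly, 6 weeks)")
        for col in ("eq5d_utility", "sf6d_utility"):
            vals = self.visits[col].dropna()
            if ((vals < -1) | (vals > 1)).any():
                raise ValidationError(f"{col} outside [-1, 1]")
        base = self.visits[self.visits["week"] == self.assessment_weeks[0]]
        if base["eq5d_utility"].isna().any() or base["sf6d_utility"].isna().any():
            raise ValidationError("baseline utilities must never be missing")
        self._check_monotone()

    def _check_monotone(self) -> None:
        """A patient missing at an earlier post-baseline week is missing later."""
        weeks = list(self.assessment_weeks[1:])
        wide = self.visits.pivot(index="patient_id", columns="week", values="eq5d_utility")
        for earlier, later in zip(weeks[:-1], weeks[1:]):
            if earlier in wide.columns and later in wide.columns:
                broken = wide[earlier].isna() & wide[later].notna()
                if broken.any():
                    raise ValidationError(
                        f"non-monotone missingness: patients {list(wide.index[broken])} "
                        f"observed at week {later} but missing at week {earlier}")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def arm_sizes(self) -> dict[str, int]:
        return self.patients["arm"].value_counts().to_dict()

    def copy(self) -> "TrialDataset":
        return TrialDataset(self.patients.copy(), self.visits.copy(),
                            self.wpai.copy(), self.resource.copy(),
                            self.assessment_weeks)

    def equals(self, other: "TrialDataset") -> bool:
        try:
            pd.testing.assert_frame_equal(self.patients.reset_index(drop=True),
                                          other.patients.reset_index(drop=True))
            pd.testing.assert_frame_equal(self.visits.reset_index(drop=True),
                                          other.visits.reset_index(drop=True))
            pd.testing.assert_frame_equal(self.wpai.reset_index(drop=True),
                                          other.wpai.reset_index(drop=True))
            pd.testing.assert_frame_equal(self.resource.reset_index(drop=True),
                                          other.resource.reset_index(drop=True))
        except AssertionError:
            return False
        return self.assessment_weeks == other.assessment_weeks

    def subset(self, patient_ids) -> "TrialDataset":
        ids = pd.Index(patient_ids)
        return TrialDataset(
            self.patients[self.patients["patient_id"].isin(ids)].reset_index(drop=True),
            self.visits[self.visits["patient_id"].isin(ids)].reset_index(drop=True),
            self.wpai[self.wpai["patient_id"].isin(ids)].reset_index(drop=True),
            self.resource[self.resource["patient_id"].isin(ids)].reset_index(drop=True),
            self.assessment_weeks,
        )


def _wpai_impairment(wpai: pd.DataFrame, employed: pd.Series) -> pd.DataFrame:
    """Vectorised WPAI scoring → selected impairment per patient × period.

    Mirrors :func:`trialcea.costing.wpai_scores` + ``select_impairment``
    (base rule): overall work impairment for employed patients, activity
    impairment otherwise. NaN responses propagate to NaN impairment.
    """
    w = wpai.copy()
    denom = w["hours_missed"] + w["hours_worked"]
    absent = np.where(denom > 0, w["hours_missed"] / denom.replace(0, np.nan), 0.0)
    absent = pd.Series(absent, index=w.index)
    absent[w["hours_missed"].isna() | w["hours_worked"].isna()] = np.nan
    present = w["work_degree"] / 10.0
    overall = absent + (1.0 - absent) * present
    activity = w["activity_degree"] / 10.0
    emp = w["patient_id"].map(employed).astype(bool)
    w["impairment"] = np.where(emp, overall, activity)
    return w.pivot(index="patient_id", columns="period", values="impairment")


def analysis_frame(dataset: TrialDataset) -> pd.DataFrame:
    """One row per patient with every analysis input, NaN where missing.

    Columns: patient attributes; ``eq5d_w{k}`` / ``sf6d_w{k}`` utilities per
    assessment week; per-period selected WPAI impairment (``imp_int``,
    ``imp_fu``), additional visits/out-of-pocket (``add_visits_*``,
    ``oop_*``) and trial-site visit counts (``visits_*``).
    """
    p = dataset.patients.set_index("patient_id")
    frame = p[["arm", "sex", "age", "bmi", "employed", "weekly_wage",
               "minutes_per_visit", "transport_per_visit"]].copy()
    frame["sessions"] = p["sessions_received"]
    frame["weeks_attended"] = p["weeks_attended"]
    frame["visits_int"] = p["sessions_received"]
    frame["visits_fu"] = 0

    for measure in ("eq5d", "sf6d"):
        wide = dataset.visits.pivot(index="patient_id", columns="week",
                                    values=f"{measure}_utility")
        for week in dataset.assessment_weeks:
            frame[f"{measure}_w{week}"] = wide[week]

    emp = p["employed"]
    imp = _wpai_impairment(dataset.wpai, emp)
    frame["imp_int"] = imp["intervention"]
    frame["imp_fu"] = imp["followup"]

    res = dataset.resource.pivot(index="patient_id", columns="period")
    frame["add_visits_int"] = res[("additional_visits", "intervention")]
    frame["add_visits_fu"] = res[("additional_visits", "followup")]
    frame["oop_int"] = res[("additional_oop", "intervention")]
    frame["oop_fu"] = res[("additional_oop", "followup")]
    return frame


def imputable_columns(dataset: TrialDataset) -> list[str]:
    """Post-baseline analysis-frame columns that dropout can leave missing."""
    cols = []
    for week in dataset.assessment_weeks[1:]:
        cols += [f"eq5d_w{week}", f"sf6d_w{week}"]
    cols += ["imp_int", "imp_fu", "add_visits_int", "add_visits_fu", "oop_int", "oop_fu"]
    return cols
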