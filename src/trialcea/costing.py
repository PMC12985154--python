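"""Cost assembly: unit costs, WPAI productivity scoring, and perspectives.

Costs are organised as a per-patient × per-period (intervention weeks 0–6,
follow-up thereafter) × per-category ledger in USD. Categories:

* ``intervention_medical`` — trial-intervention billing (session fees,
  first/recursive consultations, weekly syndrome-differentiation fee).
* ``additional_medical`` — out-of-pocket spending at other providers plus
  the matched sex/age-stratified payer benefit.
* ``transport`` / ``time`` — direct non-medical costs of attending visits.
* ``productivity`` — human-capital productivity loss: a WPAI impairment
  fraction times the sex/age standard weekly wage times the period length.

A *perspective* selects which categories count: the societal perspective
includes everything, the healthcare-system perspective direct medical costs
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, ValidationError
from .inference import GroupDifference, group_difference

PERIODS: tuple[str, str] = ("intervention", "followup")
CATEGORIES: tuple[str, ...] = (
    "intervention_medical", "additional_medical", "transport", "time", "productivity",
)
MEDICAL_CATEGORIES: tuple[str, ...] = ("intervention_medical", "additional_medical")
NONMEDICAL_CATEGORIES: tuple[str, ...] = ("transport", "time")


# ---------------------------------------------------------------------------
# unit costs and currency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCostTable:
    """Base-case unit costs (USD) and the KRW→USD exchange rate."""

    pharmacopuncture_session: float = 16.0
    physical_therapy_session: float = 7.0
    consult_km_first: float = 12.0
    consult_km_recursive: float = 8.0
    consult_wm_first: float = 15.0
    consult_wm_recursive: float = 11.0
    syndrome_differentiation_weekly: float = 3.0
    krw_per_usd: float = 1264.5

    def __post_init__(self) -> None:
        for name in ("pharmacopuncture_session", "physical_therapy_session",
                     "consult_km_first", "consult_km_recursive",
                     "consult_wm_first", "consult_wm_recursive",
                     "syndrome_differentiation_weekly"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"unit cost {name} must be >= 0")
        if self.krw_per_usd <= 0:
            raise ConfigurationError("exchange rate must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "UnitCostTable":
        with open(path) as fh:
            return cls(**{k: float(v) for k, v in yaml.safe_load(fh).items()})

    def to_dict(self) -> dict:
        return {
            "pharmacopuncture_session": self.pharmacopuncture_session,
            "physical_therapy_session": self.physical_therapy_session,
            "consult_km_first": self.consult_km_first,
            "consult_km_recursive": self.consult_km_recursive,
            "consult_wm_first": self.consult_wm_first,
            "consult_wm_recursive": self.consult_wm_recursive,
            "syndrome_differentiation_weekly": self.syndrome_differentiation_weekly,
            "krw_per_usd": self.krw_per_usd,
        }


def convert_currency(amount_krw, uc: UnitCostTable | float) -> float:
    """KRW → USD at the configured exchange rate."""
    rate = uc.krw_per_usd if isinstance(uc, UnitCostTable) else float(uc)
    if rate <= 0:
        raise ConfigurationError("exchange rate must be > 0")
    return amount_krw / rate


# ---------------------------------------------------------------------------
# sex/age-stratified lookup tables (standard wages, payer benefits)
# ---------------------------------------------------------------------------

@dataclass
class StratifiedTable:
    """Mapping (sex, age band) → a USD amount, bands partitioning 19–69."""

    label: str
    values: dict[str, dict[str, float]]
    age_min: int = 19
    age_max: int = 69

    def __post_init__(self) -> None:
        self._bands: dict[str, list[tuple[int, int, float]]] = {}
        for sex, table in self.values.items():
            bands = []
            for band, amount in table.items():
                lo_s, hi_s = str(band).split("-")
                lo, hi = int(lo_s), int(hi_s)
                if hi < lo:
                    raise ConfigurationError(f"{self.label}: bad age band {band!r}")
                if float(amount) < 0:
                    raise ConfigurationError(f"{self.label}: negative amount in band {band!r}")
                bands.append((lo, hi, float(amount)))
            bands.sort()
            lo0 = bands[0][0]
            hi_last = bands[-1][1]
            contiguous = all(bands[i + 1][0] == bands[i][1] + 1 for i in range(len(bands) - 1))
            if lo0 > self.age_min or hi_last < self.age_max or not contiguous:
                raise ConfigurationError(
                    f"{self.label}: bands for sex {sex!r} must partition "
                    f"{self.age_min}-{self.age_max}")
            self._bands[sex] = bands

    def lookup(self, sex: str, age: float) -> float:
        if sex not in self._bands:
            raise ConfigurationError(f"{self.label}: no stratum for sex {sex!r}")
        for lo, hi, amount in self._bands[sex]:
            if lo <= age <= hi:
                return amount
        raise ConfigurationError(f"{self.label}: no band covers age {age}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StratifiedTable":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(label=str(d.get("label", Path(path).stem)),
                   values={s: dict(t) for s, t in d["values"].items()})


WageTable = StratifiedTable
BenefitTable = StratifiedTable


# ---------------------------------------------------------------------------
# WPAI scoring and productivity costs (human capital approach)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WPAIResponse:
    """One WPAI 7-day-recall response.

    Degrees are the instrument's 0–10 ratings of how much the health problem
    affected work (presenteeism) and regular activities.
    """

    employed: bool
    hours_missed_problem: float = 0.0
    hours_missed_other: float = 0.0
    hours_worked: float = 0.0
    work_impairment_degree: int = 0
    activity_impairment_degree: int = 0

    def __post_init__(self) -> None:
        for name in ("hours_missed_problem", "hours_missed_other", "hours_worked"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("work_impairment_degree", "activity_impairment_degree"):
            v = getattr(self, name)
            if not 0 <= v <= 10:
                raise ValidationError(f"{name} must be within 0-10, got {v}")


@dataclass(frozen=True)
class WPAIScores:
    """WPAI outcomes as fractions of productive time lost."""

    absenteeism: float
    presenteeism: float
    overall_work_impairment: float
    activity_impairment: float

    def __post_init__(self) -> None:
        for name in ("absenteeism", "presenteeism", "overall_work_impairment",
                     "activity_impairment"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.overall_work_impairment < self.absenteeism - 1e-12:
            raise ValidationError("overall work impairment cannot be below absenteeism")


def overall_work_impairment(absenteeism: float, presenteeism: float) -> float:
    """Complement form of the overall score: 1 − (1 − abs)(1 − pres).

    Algebraically identical to ``abs + (1 − abs) × pres``; both forms are
    exposed so the identity can be asserted.
    """
    return 1.0 - (1.0 - absenteeism) * (1.0 - presenteeism)


def wpai_scores(r: WPAIResponse) -> WPAIScores:
    """Score a WPAI response into the four impairment fractions.

    Absenteeism is hours missed due to the problem over (missed + worked),
    defined as 0 when no work time was at stake; presenteeism and activity
    impairment are the 0–10 degrees over 10; overall work impairment is
    absenteeism plus the presenteeism share of time actually worked.
    """
    denom = r.hours_missed_problem + r.hours_worked
    absent = r.hours_missed_problem / denom if denom > 0 else 0.0
    present = r.work_impairment_degree / 10.0
    overall = absent + (1.0 - absent) * present
    return WPAIScores(
        absenteeism=absent,
        presenteeism=present,
        overall_work_impairment=overall,
        activity_impairment=r.activity_impairment_degree / 10.0,
    )


def select_impairment(scores: WPAIScores, employed: bool, mode: str = "base"):
    """Pick the impairment fraction driving productivity cost.

    ``base``: overall work impairment for employed patients, activity
    impairment otherwise. ``employed_only``: overall work impairment for
    employed patients, ``None`` (zero cost) otherwise.
    """
    if mode not in ("base", "employed_only"):
        raise ConfigurationError(f"unknown productivity mode {mode!r}")
    if employed:
        return scores.overall_work_impairment
    return scores.activity_impairment if mode == "base" else None


def productivity_cost(impairment: float | None, weekly_wage: float, weeks: float) -> float:
    """Human-capital productivity loss: impairment × weekly wage × weeks."""
    if impairment is None:
        return 0.0
    if not 0.0 <= impairment <= 1.0:
        raise ValidationError(f"impairment must lie in [0, 1], got {impairment}")
    if weekly_wage < 0 or weeks < 0:
        raise ValidationError("wage and weeks must be >= 0")
    return impairment * weekly_wage * weeks


# ---------------------------------------------------------------------------
# per-item cost operations
# ---------------------------------------------------------------------------

def intervention_cost(arm: str, sessions: int, weeks_attended: int,
                      uc: UnitCostTable, fee_multiplier: float = 1.0) -> float:
    """Trial-intervention billing for one patient.

    PPT: Korean-medicine first + recursive consultations, pharmacopuncture
    session fee (scaled by ``fee_multiplier``), and the weekly syndrome-
    differentiation fee per attended week. PT: Western-medicine first +
    recursive consultations and the physical-therapy session fee. Zero
    sessions bills nothing.
    """
    if fee_multiplier <= 0:
        raise ConfigurationError("fee multiplier must be > 0")
    if sessions < 0 or weeks_attended < 0:
        raise ValidationError("sessions and weeks attended must be >= 0")
    if sessions == 0:
        return 0.0
    if arm == "PPT":
        return (uc.consult_km_first
                + uc.consult_km_recursive * (sessions - 1)
                + uc.pharmacopuncture_session * fee_multiplier * sessions
                + uc.syndrome_differentiation_weekly * weeks_attended)
    if arm == "PT":
        return (uc.consult_wm_first
                + uc.consult_wm_recursive * (sessions - 1)
                + uc.physical_therapy_session * sessions)
    raise ValidationError(f"unknown arm {arm!r}")


def additional_visit_cost(out_of_pocket: float, sex: str, age: float,
                          benefit_lookup: StratifiedTable) -> float:
    """Out-of-pocket payment plus the matched mean payer benefit (per visit)."""
    if out_of_pocket < 0:
        raise ValidationError("out-of-pocket amount must be >= 0")
    return out_of_pocket + benefit_lookup.lookup(sex, age)


def time_cost(minutes_total_per_visit: float, visits: int, weekly_wage: float,
              weekly_hours: float = 40.0) -> float:
    """Patient time valued at the standard wage: (min/60) × hourly wage × visits."""
    if min(minutes_total_per_visit, visits, weekly_wage) < 0:
        raise ValidationError("time-cost inputs must be >= 0")
    if weekly_hours <= 0:
        raise ConfigurationError("weekly working hours must be > 0")
    return (minutes_total_per_visit / 60.0) * (weekly_wage / weekly_hours) * visits


def transport_cost(cost_per_visit: float, visits: int) -> float:
    """Surveyed per-visit transportation cost times the number of visits."""
    if cost_per_visit < 0 or visits < 0:
        raise ValidationError("transport inputs must be >= 0")
    return cost_per_visit * visits


# ---------------------------------------------------------------------------
# ledger and perspectives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerspectiveSpec:
    """Which cost categories an economic viewpoint counts."""

    name: str
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = [c for c in self.categories if c not in CATEGORIES]
        if unknown:
            raise ConfigurationError(f"unknown cost categories: {unknown}")


PERSPECTIVES: dict[str, PerspectiveSpec] = {
    "societal": PerspectiveSpec("societal", CATEGORIES),
    "healthcare": PerspectiveSpec("healthcare", MEDICAL_CATEGORIES),
    "healthcare_plus_nonmedical": PerspectiveSpec(
        "healthcare_plus_nonmedical", MEDICAL_CATEGORIES + NONMEDICAL_CATEGORIES),
}


def get_perspective(perspective: str | PerspectiveSpec) -> PerspectiveSpec:
    if isinstance(perspective, PerspectiveSpec):
        return perspective
    try:
        return PERSPECTIVES[perspective]
    except KeyError:
        raise ConfigurationError(
            f"unknown perspective {perspective!r}; choose from {sorted(PERSPECTIVES)}")


@dataclass
class CostLedger:
    """Per-patient, per-period, per-category amounts in USD.

    ``amounts`` is indexed by (patient_id, period) with one column per
    category; ``arms`` maps patient_id → arm label.
    """

    amounts: pd.DataFrame
    arms: pd.Series

    def __post_init__(self) -> None:
        missing = [c for c in CATEGORIES if c not in self.amounts.columns]
        if missing:
            raise ConfigurationError(f"ledger is missing categories: {missing}")
        if (self.amounts[list(CATEGORIES)] < 0).any().any():
            raise ValidationError("ledger amounts must be >= 0")
        patients = self.amounts.index.get_level_values(0).unique()
        for period in PERIODS:
            have = self.amounts.xs(period, level=1).index
            if not patients.isin(have).all():
                raise ValidationError(f"every patient must appear in period {period!r}")

    @property
    def patients(self) -> pd.Index:
        return self.arms.index

    def patient_totals(self, perspective: str | PerspectiveSpec = "societal",
                       period: str | None = None) -> pd.Series:
        """Per-patient totals over the perspective's categories."""
        spec = get_perspective(perspective)
        df = self.amounts if period is None else self.amounts.xs(period, level=1, drop_level=False)
        totals = df[list(spec.categories)].sum(axis=1).groupby(level=0).sum()
        return totals.reindex(self.patients)


@dataclass
class CostSummary:
    """Arm-level cost summary for one perspective (a cost-table block)."""

    perspective: str
    arm_means: dict[str, float]
    period_arm_means: pd.DataFrame
    difference: GroupDifference
    patient_totals: pd.Series


def assemble_costs(ledger: CostLedger, perspective: str | PerspectiveSpec = "societal",
                   *, trt: str = "PPT", ref: str = "PT") -> CostSummary:
    """Per-patient and per-arm totals for one perspective, with t-based CI.

    Totals are sums over the included categories; the between-arm difference
    (trt − ref) uses the independent two-sample t comparison.
    """
    spec = get_perspective(perspective)
    totals = ledger.patient_totals(spec)
    arms = ledger.arms.reindex(totals.index)
    diff = group_difference(totals.to_numpy(), arms.to_numpy(), trt=trt, ref=ref)
    arm_means = {arm: float(totals[arms == arm].mean()) for arm in (trt, ref)}
    per_period = {}
    for period in PERIODS:
        pt = ledger.patient_totals(spec, period=period)
        per_period[period] = {arm: float(pt[arms == arm].mean()) for arm in (trt, ref)}
    period_arm_means = pd.DataFrame(per_period).T
    return CostSummary(
        perspective=spec.name, arm_means=arm_means,
        period_arm_means=period_arm_means, difference=diff,
        patient_totals=totals,
    )


def build_ledger(frame: pd.DataFrame, uc: UnitCostTable, benefits: StratifiedTable, *,
                 fee_multiplier: float = 1.0, productivity_mode: str = "base",
                 period_weeks: Mapping[str, float] | None = None,
                 weekly_hours: float = 40.0) -> CostLedger:
    """Assemble the cost ledger from a completed per-patient analysis frame.

    The frame is the wide layout produced by
    :func:`trialcea.datasets.analysis_frame` (one row per patient, all cost
    inputs and impairment fractions filled in, e.g. after imputation).
    """
    pw = {"intervention": 6.0, "followup": 6.0}
    if period_weeks:
        pw.update(period_weeks)
    rows = []
    for pid, r in frame.iterrows():
        for period, suffix in (("intervention", "int"), ("followup", "fu")):
            visits = int(r[f"visits_{suffix}"])
            add_visits = int(round(r[f"add_visits_{suffix}"]))
            oop = float(r[f"oop_{suffix}"])
            imp = float(r[f"imp_{suffix}"])
            if productivity_mode == "employed_only" and not bool(r["employed"]):
                prod_imp = None
            else:
                prod_imp = imp
            all_visits = visits + add_visits
            interv = 0.0
            if period == "intervention":
                interv = intervention_cost(r["arm"], int(r["sessions"]),
                                           int(r["weeks_attended"]), uc,
                                           fee_multiplier=fee_multiplier)
            add_med = 0.0
            if add_visits > 0:
                per_visit_oop = oop / add_visits
                add_med = add_visits * additional_visit_cost(
                    per_visit_oop, r["sex"], float(r["age"]), benefits)
            rows.append({
                "patient_id": pid, "period": period,
                "intervention_medical": interv,
                "additional_medical": add_med,
                "transport": transport_cost(float(r["transport_per_visit"]), all_visits),
                "time": time_cost(float(r["minutes_per_visit"]), all_visits,
                                  float(r["weekly_wage"]), weekly_hours),
                "productivity": productivity_cost(prod_imp, float(r["weekly_wage"]),
                                                  pw[period]),
            })
    amounts = pd.DataFrame(rows).set_index(["patient_id", "period"])
    return CostLedger(amounts=amounts, arms=frame["arm"].copy())
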