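"""Synthetic two-arm pragmatic-trial generator.

Emulates the statistical structure a within-trial cost–utility analysis
assumes: two arms randomised ≈1:1, utilities assessed at baseline and two
post-baseline weeks with a small additive arm effect, twice-weekly treatment
sessions over six weeks, WPAI productivity responses with substantial
non-employment, sex/age demographics with standard weekly wages, sparse
additional provider use, and a small amount of monotone dropout.

Defaults mirror a 50-patient pilot trial (24 vs 26, assessments at weeks
0/7/13, ≈4% cumulative dropout). All randomness flows from ``config.seed``
through independent spawned streams, so equal configs give byte-identical
datasets and dropout patterns.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .costing import StratifiedTable
from .datasets import TrialDataset
from .exceptions import ConfigurationError
from .scoring import SF6DCoefficients, ValueSet

_DEFAULT_COST_PARAMS = {
    "transport_mean": 3.0,    # USD per visit (surveyed)
    "transport_sd": 1.0,
    "minutes_ppt": 100.0,     # door-to-door minutes per visit, by arm
    "minutes_pt": 120.0,
    "minutes_sd": 25.0,
    "addl_visit_rate": 0.1,   # Poisson mean additional provider visits/period
    "addl_oop_mean": 20.0,    # USD out-of-pocket per additional visit
}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    n_ppt: int = 24
    n_pt: int = 26
    assessment_weeks: tuple[int, ...] = (0, 7, 13)
    utility_baseline_mean: float = 0.70
    utility_arm_effect: float = 0.08      # additive post-baseline shift, PPT arm
    utility_followup_gain: float = 0.06   # both arms improve after baseline
    utility_sd: float = 0.12
    sf6d_offset: float = -0.09            # SF-6D runs below EQ-5D-5L here
    sessions_planned: int = 12            # twice weekly, 6 weeks
    attendance_prob: float = 0.95
    employment_prob: float = 0.44         # 22 of 50 in paid employment
    wage_mean_weekly: float = 500.0       # USD/week
    wage_sd: float = 100.0
    impairment_means: tuple[float, float] = (0.37, 0.62)  # (PPT, PT)
    impairment_sd: float = 0.15
    cost_params: dict = field(default_factory=dict)
    dropout_week7_prob: float = 0.02
    dropout_week12_prob: float = 0.02
    female_prob: float = 0.72
    age_range: tuple[int, int] = (40, 69)
    bmi_mean: float = 24.0
    bmi_sd: float = 3.0
    emit_profiles: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        merged = dict(_DEFAULT_COST_PARAMS)
        merged.update(self.cost_params or {})
        self.cost_params = merged
        self.assessment_weeks = tuple(int(w) for w in self.assessment_weeks)
        self.impairment_means = tuple(float(v) for v in self.impairment_means)
        self.age_range = tuple(int(v) for v in self.age_range)
        self.validate()

    def validate(self) -> None:
        for name in ("attendance_prob", "employment_prob", "dropout_week7_prob",
                     "dropout_week12_prob", "female_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability in [0, 1], got {v}")
        if self.n_ppt < 2 or self.n_pt < 2:
            raise ConfigurationError("each arm needs at least 2 patients")
        w = self.assessment_weeks
        if len(w) < 2 or w[0] != 0 or any(b <= a for a, b in zip(w, w[1:])):
            raise ConfigurationError("assessment_weeks must be strictly increasing and start at 0")
        if self.sessions_planned < 0 or self.sessions_planned % 2:
            raise ConfigurationError("sessions_planned must be a non-negative even count (2/week)")
        if self.utility_sd < 0 or self.impairment_sd < 0 or self.wage_sd < 0:
            raise ConfigurationError("spreads must be >= 0")
        for v in self.impairment_means:
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError("impairment means must lie in [0, 1]")

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["assessment_weeks"] = list(self.assessment_weeks)
        d["impairment_means"] = list(self.impairment_means)
        d["age_range"] = list(self.age_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _trunc_normal(rng: np.random.Generator, mean, sd: float, lo: float, hi: float,
                  size: int) -> np.ndarray:
    """Truncated-normal draws; degenerate at the (clipped) mean when sd = 0."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    if sd == 0:
        return np.clip(mean, lo, hi).copy()
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.random(size)
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _profile_from_utility(rng: np.random.Generator, u: np.ndarray) -> list[str]:
    """Record a plausible 5-digit EQ-5D profile for a given utility.

    Higher severity (lower utility) shifts every dimension toward worse
    levels; the jitter makes dimensions disagree the way real responses do.
    """
    sev = np.clip((1.0 - u) / 0.6, 0.0, 1.0)
    states = []
    for s in sev:
        levels = np.clip(np.rint(1 + 4 * s + rng.normal(0.0, 0.7, size=5)), 1, 5).astype(int)
        states.append("".join(map(str, levels)))
    return states


def generate_cohort(config: SimConfig, value_set: ValueSet | None = None) -> TrialDataset:
    """Draw a complete synthetic trial dataset (no missingness).

    The arm effect shifts only post-baseline utilities of the PPT arm. With
    ``emit_profiles`` the visits table additionally records 5-digit EQ-5D
    profiles consistent with the drawn utilities (scored through
    ``value_set``, default the toy tariff, purely as instrument-level
    plumbing — the analysis consumes the utilities).
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed).spawn(3)[0]))
    cp = config.cost_params
    n = config.n_ppt + config.n_pt
    arms = np.array(["PPT"] * config.n_ppt + ["PT"] * config.n_pt)
    pids = np.array([f"P{i + 1:03d}" for i in range(n)])

    sex = np.where(rng.random(n) < config.female_prob, "F", "M")
    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    bmi = rng.normal(config.bmi_mean, config.bmi_sd, size=n)
    employed = rng.random(n) < config.employment_prob
    wage = np.maximum(0.0, config.wage_mean_weekly + (
        rng.normal(0.0, config.wage_sd, size=n) if config.wage_sd > 0 else 0.0))

    # attendance: two scheduled sessions per treatment week
    weeks_treat = config.sessions_planned // 2
    attended = rng.random((n, weeks_treat, 2)) < config.attendance_prob
    sessions = attended.sum(axis=(1, 2))
    weeks_attended = attended.any(axis=2).sum(axis=1)

    minutes = np.where(arms == "PPT", cp["minutes_ppt"], cp["minutes_pt"])
    if cp["minutes_sd"] > 0:
        minutes = np.maximum(10.0, minutes + rng.normal(0.0, cp["minutes_sd"], size=n))
    transport = np.maximum(0.0, cp["transport_mean"] + (
        rng.normal(0.0, cp["transport_sd"], size=n) if cp["transport_sd"] > 0 else 0.0))

    patients = pd.DataFrame({
        "patient_id": pids, "arm": arms, "sex": sex, "age": age, "bmi": bmi,
        "employed": employed, "weekly_wage": wage,
        "sessions_received": sessions, "weeks_attended": weeks_attended,
        "minutes_per_visit": minutes, "transport_per_visit": transport,
    })

    # utilities: shared patient effect + visit noise, truncated to the scale
    eff_sd, noise_sd = 0.6 * config.utility_sd, 0.8 * config.utility_sd
    pat_eff = rng.normal(0.0, eff_sd, size=n) if eff_sd > 0 else np.zeros(n)
    visit_rows = []
    eq_by_week: dict[int, np.ndarray] = {}
    for week in config.assessment_weeks:
        post = week > 0
        shift = (config.utility_followup_gain if post else 0.0) + \
                (config.utility_arm_effect if post else 0.0) * (arms == "PPT")
        mu_eq = config.utility_baseline_mean + shift + pat_eff
        mu_sf = mu_eq + config.sf6d_offset
        eq = _trunc_normal(rng, mu_eq, noise_sd, -1.0, 1.0, n)
        sf = _trunc_normal(rng, mu_sf, noise_sd, 0.05, 1.0, n)
        eq_by_week[week] = eq
        visit_rows.append(pd.DataFrame({
            "patient_id": pids, "week": week, "eq5d_utility": eq, "sf6d_utility": sf,
        }))
    visits = pd.concat(visit_rows, ignore_index=True)

    if config.emit_profiles:
        vs = value_set if value_set is not None else toy_value_set()
        prof_rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed).spawn(3)[2]))
        states = []
        for week in config.assessment_weeks:
            states.extend(_profile_from_utility(prof_rng, eq_by_week[week]))
        visits["eq5d_state"] = states
        visits.attrs["value_set_label"] = vs.label

    # WPAI: patient-level impairment propensity, degree responses per period
    imp_mean = np.where(arms == "PPT", config.impairment_means[0], config.impairment_means[1])
    p_imp = _trunc_normal(rng, imp_mean, config.impairment_sd, 0.0, 1.0, n)
    wpai_rows = []
    for period in ("intervention", "followup"):
        if config.impairment_sd == 0:
            degree = np.rint(10 * p_imp).astype(float)
            missed = np.zeros(n)
        else:
            degree = rng.binomial(10, p_imp).astype(float)
            missed = np.where(rng.random(n) < 0.25, np.round(rng.uniform(0, 12, n) * 2) / 2, 0.0)
        worked = np.maximum(0.0, 40.0 - missed)
        wpai_rows.append(pd.DataFrame({
            "patient_id": pids, "period": period,
            "hours_missed": np.where(employed, missed, np.nan),
            "hours_worked": np.where(employed, worked, np.nan),
            "work_degree": np.where(employed, degree, np.nan),
            "activity_degree": degree,
        }))
    wpai = pd.concat(wpai_rows, ignore_index=True)

    res_rows = []
    for period in ("intervention", "followup"):
        add_visits = rng.poisson(cp["addl_visit_rate"], size=n)
        oop = np.array([rng.gamma(4.0, cp["addl_oop_mean"] / 4.0, size=k).sum()
                        for k in add_visits])
        res_rows.append(pd.DataFrame({
            "patient_id": pids, "period": period,
            "additional_visits": add_visits.astype(float), "additional_oop": oop,
        }))
    resource = pd.concat(res_rows, ignore_index=True)

    return TrialDataset(patients, visits, wpai, resource,
                        assessment_weeks=config.assessment_weeks)


def apply_dropout(dataset: TrialDataset, config: SimConfig) -> TrialDataset:
    """Impose monotone missing-at-random dropout per the two probabilities.

    A week-7 dropout loses every post-baseline field (both assessment
    weeks, both WPAI periods, both resource periods); a week-13 dropout
    loses only the final assessment and the follow-up period. Baseline is
    never missing. Deterministic given ``config.seed`` (a stream
    independent of the cohort draw).
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed).spawn(3)[1]))
    out = dataset.copy()
    pids = out.patients["patient_id"].to_numpy()
    n = len(pids)
    drop7 = rng.random(n) < config.dropout_week7_prob
    drop13 = ~drop7 & (rng.random(n) < config.dropout_week12_prob)

    weeks = dataset.assessment_weeks
    post_weeks = [w for w in weeks if w > 0]
    last_week = weeks[-1]
    utility_cols = ["eq5d_utility", "sf6d_utility"]
    if "eq5d_state" in out.visits.columns:
        utility_cols.append("eq5d_state")
    wpai_fields = ["hours_missed", "hours_worked", "work_degree", "activity_degree"]
    res_fields = ["additional_visits", "additional_oop"]

    gone7 = set(pids[drop7])
    gone13 = set(pids[drop13])

    v = out.visits
    mask = v["patient_id"].isin(gone7) & v["week"].isin(post_weeks)
    mask |= v["patient_id"].isin(gone13) & (v["week"] == last_week)
    v.loc[mask, utility_cols] = np.nan

    w = out.wpai
    wmask = w["patient_id"].isin(gone7)
    wmask |= w["patient_id"].isin(gone13) & (w["period"] == "followup")
    w.loc[wmask, wpai_fields] = np.nan

    r = out.resource
    rmask = r["patient_id"].isin(gone7)
    rmask |= r["patient_id"].isin(gone13) & (r["period"] == "followup")
    r.loc[rmask, res_fields] = np.nan

    out.validate()
    return out


# ---------------------------------------------------------------------------
# toy (synthetic) configuration fixtures shipped with the package
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(resources.files("trialcea").joinpath("data", name))  # type: ignore[arg-type]


def toy_value_set() -> ValueSet:
    """A small synthetic additive tariff — NOT any national value set."""
    return ValueSet.from_yaml(_data_path("toy_eq5d_valueset.yaml"))


def toy_sf6d_coefficients() -> SF6DCoefficients:
    """A small synthetic SF-6D style equation — NOT the published algorithm."""
    return SF6DCoefficients.from_yaml(_data_path("toy_sf6d_coefficients.yaml"))


def toy_wage_table() -> StratifiedTable:
    """Synthetic sex/age standard weekly wages (USD)."""
    return StratifiedTable.from_yaml(_data_path("toy_wages.yaml"))


def toy_benefit_table() -> StratifiedTable:
    """Synthetic sex/age mean payer benefit per additional visit (USD)."""
    return StratifiedTable.from_yaml(_data_path("toy_benefits.yaml"))
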