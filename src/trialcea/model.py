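"""Model / results objects tying the pipeline together.

:class:`CostUtilityAnalysis` is built from a :class:`~trialcea.datasets.TrialDataset`
plus configuration (unit costs, payer benefits, WTP, scenario); ``fit()``
runs multiple imputation → QALY construction → cost assembly →
residual-bootstrap-within-MI → CEAC and returns a :class:`CEAResults`
holding the incremental estimates, their uncertainty, the bootstrap clouds
and a printable summary table, in the spirit of the statsmodels
model/results split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import (IncrementalCloud, OutcomeSet, ScenarioSpec, WTPConfig,
                  ce_plane_summary, ceac, icer, residual_bootstrap)
from .costing import (CostLedger, StratifiedTable, UnitCostTable, build_ledger,
                      get_perspective)
from .datasets import TrialDataset
from .exceptions import EstimationError
from .impute import ImputationSpec, ImputedStack, impute
from .inference import PooledEstimate, group_difference, rubin_pool
from .qaly import WEEKS_PER_YEAR, qaly_auc_matrix

MEASURES: tuple[str, str] = ("eq5d", "sf6d")


def extrapolate_one_year(frame: pd.DataFrame, ledger: CostLedger, *,
                         final_week: int = 13,
                         followup_weeks: float = 6.0,
                         weeks_per_year: float = WEEKS_PER_YEAR):
    """One-year extrapolation of final-assessment values.

    Annual QALY per patient = final-week utility sustained for one year;
    annual costs keep the intervention period once and scale the follow-up
    period to its weekly rate times weeks-per-year.
    Returns ``({measure: Series}, CostLedger)``.
    """
    qalys = {m: frame[f"{m}_w{final_week}"].astype(float).copy() for m in MEASURES}
    amounts = ledger.amounts.copy()
    fu = amounts.index.get_level_values(1) == "followup"
    amounts.loc[fu, :] = amounts.loc[fu, :] * (weeks_per_year / followup_weeks)
    return qalys, CostLedger(amounts=amounts, arms=ledger.arms.copy())


@dataclass
class CEAOutcome:
    """Incremental result for one (perspective, utility measure) cell."""

    scenario: str
    perspective: str
    measure: str
    delta_cost: PooledEstimate
    delta_qaly: PooledEstimate
    icer: float | str
    cloud: IncrementalCloud
    quadrants: dict[str, float]
    ceac_grid: np.ndarray
    ceac_probs: np.ndarray
    prob_at_threshold: float


@dataclass
class ArmSummary:
    """Pooled arm-level means and the pooled (trt − ref) difference."""

    arm_means: dict[str, float]
    difference: PooledEstimate


class CEAResults:
    """Fitted results: estimates, uncertainty, clouds, and summary table."""

    def __init__(self, model: "CostUtilityAnalysis", outcomes: dict,
                 qaly_results: dict, cost_summaries: dict,
                 stack: ImputedStack, seed: int, m: int, B: int):
        self.model = model
        self.outcomes = outcomes              # {(perspective, measure): CEAOutcome}
        self.qaly_results = qaly_results      # {measure: ArmSummary}
        self.cost_summaries = cost_summaries  # {perspective: ArmSummary}
        self.stack = stack
        self.seed = seed
        self.m = m
        self.B = B

    def outcome(self, perspective: str, measure: str) -> CEAOutcome:
        return self.outcomes[(perspective, measure)]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for (persp, measure), o in self.outcomes.items():
            c_lo, c_hi = o.delta_cost.ci()
            q_lo, q_hi = o.delta_qaly.ci()
            rows.append({
                "scenario": o.scenario,
                "perspective": persp,
                "measure": {"eq5d": "EQ-5D-5L", "sf6d": "SF-6D"}[measure],
                "delta_cost": round(o.delta_cost.estimate, 1),
                "cost_ci": f"({c_lo:.0f}, {c_hi:.0f})",
                "delta_qaly": round(o.delta_qaly.estimate, 4),
                "qaly_ci": f"({q_lo:.4f}, {q_hi:.4f})",
                "icer": o.icer if isinstance(o.icer, str) else round(o.icer, 0),
                "prob_ce_at_wtp": round(100.0 * o.prob_at_threshold, 1),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.summary_frame()
        head = (f"Cost-utility analysis — scenario {self.model.scenario.name!r}, "
                f"m={self.m}, B={self.B}, seed={self.seed}, "
                f"WTP=${self.model.wtp.threshold:,.0f}/QALY\n")
        return head + df.to_string(index=False)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.summary()

    # plotting (thin wrappers; see trialcea.plotting)
    def plot_ce_plane(self, perspective: str = "societal", measure: str = "eq5d", ax=None):
        from .plotting import plot_ce_plane
        o = self.outcome(perspective, measure)
        return plot_ce_plane(o.cloud, wtp=self.model.wtp, ax=ax,
                             title=f"CE plane — {perspective}, {o.measure}")

    def plot_ceac(self, perspective: str = "societal", measure: str = "eq5d", ax=None):
        from .plotting import plot_ceac
        o = self.outcome(perspective, measure)
        return plot_ceac(o.ceac_grid, o.ceac_probs, threshold=self.model.wtp.threshold,
                         ax=ax, title=f"CEAC — {perspective}, {o.measure}")


class CostUtilityAnalysis:
    """Trial-based cost–utility model for a two-arm dataset.

    Parameters
    ----------
    dataset : TrialDataset
        Patient-level trial data (may contain monotone post-baseline
        missingness; it is multiply imputed during ``fit``).
    unit_costs, benefit_table : config objects
        Billing unit costs and the sex/age payer-benefit lookup (defaults:
        base-case unit costs; synthetic toy benefit table).
    wtp : WTPConfig
        Willingness-to-pay threshold and CEAC grid.
    scenario : ScenarioSpec or str
        Base case (``"main"``) or one of the sensitivity scenarios.
    perspectives : tuple of str, optional
        Cost perspectives to evaluate; defaults to the scenario's own set.
    """

    def __init__(self, dataset: TrialDataset, *,
                 unit_costs: UnitCostTable | None = None,
                 benefit_table: StratifiedTable | None = None,
                 wtp: WTPConfig | None = None,
                 scenario: ScenarioSpec | str | None = None,
                 perspectives: tuple[str, ...] | None = None,
                 imputation: ImputationSpec | None = None,
                 period_weeks: dict[str, float] | None = None,
                 weeks_per_year: float = WEEKS_PER_YEAR,
                 weekly_hours: float = 40.0,
                 trt: str = "PPT", ref: str = "PT"):
        from .simulate import toy_benefit_table
        self.dataset = dataset
        self.unit_costs = unit_costs or UnitCostTable()
        self.benefit_table = benefit_table or toy_benefit_table()
        self.wtp = wtp or WTPConfig()
        if scenario is None:
            scenario = ScenarioSpec()
        elif isinstance(scenario, str):
            scenario = ScenarioSpec.named(scenario)
        self.scenario = scenario
        self.perspectives = tuple(perspectives) if perspectives else scenario.perspectives
        for p in self.perspectives:
            get_perspective(p)
        self.imputation = imputation
        self.period_weeks = {"intervention": 6.0, "followup": 6.0}
        if period_weeks:
            self.period_weeks.update(period_weeks)
        self.weeks_per_year = weeks_per_year
        self.weekly_hours = weekly_hours
        self.trt, self.ref = trt, ref

    @classmethod
    def from_tables(cls, directory, **kwargs) -> "CostUtilityAnalysis":
        """Build the model from the four delimited tables in ``directory``."""
        from .io import load_trial_tables
        return cls(load_trial_tables(directory), **kwargs)

    # ------------------------------------------------------------------
    def _scenario_dataset(self) -> TrialDataset:
        sc = self.scenario
        if sc.min_sessions <= 0:
            return self.dataset
        keep = self.dataset.patients.loc[
            self.dataset.patients["sessions_received"] >= sc.min_sessions, "patient_id"]
        sub = self.dataset.subset(keep)
        sizes = sub.arm_sizes()
        if sizes.get(self.trt, 0) < 2 or sizes.get(self.ref, 0) < 2:
            raise EstimationError(
                f"per-protocol filter (>= {sc.min_sessions} sessions) leaves an arm "
                f"with fewer than 2 patients: {sizes}")
        return sub

    def _frame_outcomes(self, frame: pd.DataFrame):
        """Per-patient QALYs (per measure) and cost totals (per perspective)."""
        sc = self.scenario
        weeks = self.dataset.assessment_weeks
        ledger = build_ledger(frame, self.unit_costs, self.benefit_table,
                              fee_multiplier=sc.fee_multiplier,
                              productivity_mode=sc.productivity_mode,
                              period_weeks=self.period_weeks,
                              weekly_hours=self.weekly_hours)
        if sc.extrapolate:
            qalys, ledger = extrapolate_one_year(
                frame, ledger, final_week=weeks[-1],
                followup_weeks=self.period_weeks["followup"],
                weeks_per_year=self.weeks_per_year)
        else:
            qalys = {}
            for measure in MEASURES:
                cols = [f"{measure}_w{w}" for w in weeks]
                qalys[measure] = pd.Series(
                    qaly_auc_matrix(weeks, frame[cols].to_numpy(dtype=float),
                                    weeks_per_year=self.weeks_per_year),
                    index=frame.index)
        costs = {p: ledger.patient_totals(p) for p in self.perspectives}
        return qalys, costs

    def fit(self, m: int = 20, B: int = 500, seed: int = 0) -> CEAResults:
        """Run the full pipeline; deterministic given (config, seed)."""
        data = self._scenario_dataset()
        root = np.random.SeedSequence(seed)
        derived = [int(s) & 0x7FFFFFFF for s in root.generate_state(16)]
        spec = self.imputation or ImputationSpec(m=m, seed=derived[0])
        if spec.m != m or spec.seed != derived[0]:
            spec = ImputationSpec(m=m, covariates=spec.covariates,
                                  donor_pool=spec.donor_pool,
                                  iterations=spec.iterations, seed=derived[0])
        stack = impute(data, spec)

        per_set = []  # (qalys, costs) per imputed frame
        for frame in stack.frames:
            per_set.append(self._frame_outcomes(frame))

        baseline_week = self.dataset.assessment_weeks[0]
        outcomes: dict = {}
        combo_i = 1
        for persp in self.perspectives:
            for measure in MEASURES:
                sets = []
                cost_ests, cost_vars = [], []
                qaly_ests, qaly_vars = [], []
                for frame, (qalys, costs) in zip(stack.frames, per_set):
                    arm_ind = (frame["arm"] == self.trt).to_numpy(dtype=float)
                    baseline = frame[f"{measure}_w{baseline_week}"].to_numpy(dtype=float)
                    sets.append(OutcomeSet(cost=costs[persp].to_numpy(),
                                           qaly=qalys[measure].to_numpy(),
                                           arm_indicator=arm_ind, baseline=baseline))
                    gd_c = group_difference(costs[persp], frame["arm"],
                                            trt=self.trt, ref=self.ref)
                    gd_q = group_difference(qalys[measure], frame["arm"],
                                            covariates=baseline,
                                            trt=self.trt, ref=self.ref)
                    cost_ests.append(gd_c.estimate)
                    cost_vars.append(gd_c.se ** 2)
                    qaly_ests.append(gd_q.estimate)
                    qaly_vars.append(gd_q.se ** 2)
                pooled_c = rubin_pool(cost_ests, cost_vars)
                pooled_q = rubin_pool(qaly_ests, qaly_vars)
                cloud = residual_bootstrap(sets, B=B, seed=derived[combo_i])
                combo_i += 1
                grid, probs, at_thr = ceac(cloud, self.wtp)
                outcomes[(persp, measure)] = CEAOutcome(
                    scenario=self.scenario.name, perspective=persp, measure=measure,
                    delta_cost=pooled_c, delta_qaly=pooled_q,
                    icer=icer(pooled_c.estimate, pooled_q.estimate),
                    cloud=cloud, quadrants=ce_plane_summary(cloud),
                    ceac_grid=grid, ceac_probs=probs, prob_at_threshold=at_thr)

        qaly_results = {}
        for measure in MEASURES:
            ests, vars_, means_t, means_r = [], [], [], []
            for frame, (qalys, _) in zip(stack.frames, per_set):
                baseline = frame[f"{measure}_w{baseline_week}"].to_numpy(dtype=float)
                gd = group_difference(qalys[measure], frame["arm"],
                                      covariates=baseline, trt=self.trt, ref=self.ref)
                ests.append(gd.estimate)
                vars_.append(gd.se ** 2)
                means_t.append(gd.adjusted_means[self.trt])
                means_r.append(gd.adjusted_means[self.ref])
            qaly_results[measure] = ArmSummary(
                arm_means={self.trt: float(np.mean(means_t)),
                           self.ref: float(np.mean(means_r))},
                difference=rubin_pool(ests, vars_))

        cost_summaries = {}
        for persp in self.perspectives:
            ests, vars_, means_t, means_r = [], [], [], []
            for frame, (_, costs) in zip(stack.frames, per_set):
                gd = group_difference(costs[persp], frame["arm"],
                                      trt=self.trt, ref=self.ref)
                ests.append(gd.estimate)
                vars_.append(gd.se ** 2)
                means_t.append(gd.adjusted_means[self.trt])
                means_r.append(gd.adjusted_means[self.ref])
            cost_summaries[persp] = ArmSummary(
                arm_means={self.trt: float(np.mean(means_t)),
                           self.ref: float(np.mean(means_r))},
                difference=rubin_pool(ests, vars_))

        return CEAResults(self, outcomes, qaly_results, cost_summaries,
                          stack, seed=seed, m=m, B=B)


def run_scenario(dataset: TrialDataset, scenario: ScenarioSpec | str,
                 *, m: int = 20, B: int = 500, seed: int = 0,
                 **model_kwargs) -> CEAResults:
    """Run one named analysis scenario end-to-end.

    With neutral parameters (the ``"main"`` scenario) this is exactly the
    base-case pipeline: given the same seed the results are bit-identical.
    """
    model = CostUtilityAnalysis(dataset, scenario=scenario, **model_kwargs)
    return model.fit(m=m, B=B, seed=seed)
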