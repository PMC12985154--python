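"""Incremental cost-effectiveness machinery.

The uncertainty engine is a residual bootstrap run inside each multiply
imputed dataset: per completed dataset, cost and QALY are regressed on the
arm (QALY additionally on the centred baseline utility), fitted values and
residuals are kept, and each bootstrap replicate resamples patient indices
once — applying the same indices to both residual vectors so the
within-patient cost–effect correlation survives — and re-estimates both arm
contrasts on the pseudo-outcomes. With m imputed sets and B replicates the
incremental cloud holds m × B (ΔQALY, ΔCost) pairs; its empirical
distribution drives the cost-effectiveness plane and the acceptability
curve P(λ·ΔE − ΔC > 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError, EstimationError, ValidationError

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class WTPConfig:
    """Willingness-to-pay threshold and evaluation grid (USD per QALY)."""

    threshold: float = 26374.0
    grid: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ConfigurationError("WTP threshold must be > 0")
        if not self.grid:
            object.__setattr__(self, "grid",
                               tuple(np.linspace(0.0, 2.0 * self.threshold, 101)))
        g = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(g) < 0):
            raise ConfigurationError("WTP grid must be ascending")


def icer(delta_cost: float, delta_qaly: float) -> float | str:
    """ICER or dominance label for an incremental (ΔC, ΔE) point.

    ΔC/ΔE when both have the same sign; ``"dominant"`` (cheaper, more
    effective) and ``"dominated"`` (costlier, less effective) otherwise;
    ``"undefined"`` at ΔE = 0.
    """
    if not (np.isfinite(delta_cost) and np.isfinite(delta_qaly)):
        raise ValidationError("ICER inputs must be finite")
    if delta_qaly == 0:
        return UNDEFINED
    if delta_cost < 0 and delta_qaly > 0:
        return DOMINANT
    if delta_cost > 0 and delta_qaly < 0:
        return DOMINATED
    return delta_cost / delta_qaly


@dataclass
class OutcomeSet:
    """Per-patient outcomes of one completed (imputed) dataset."""

    cost: np.ndarray
    qaly: np.ndarray
    arm_indicator: np.ndarray        # 1 = treatment (PPT), 0 = comparator
    baseline: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cost = np.asarray(self.cost, dtype=float)
        self.qaly = np.asarray(self.qaly, dtype=float)
        self.arm_indicator = np.asarray(self.arm_indicator, dtype=float)
        n = self.cost.size
        if self.qaly.size != n or self.arm_indicator.size != n:
            raise EstimationError("outcome vectors must share one length")
        if self.baseline is not None:
            self.baseline = np.asarray(self.baseline, dtype=float)
            if self.baseline.size != n:
                raise EstimationError("baseline covariate length mismatch")
        if self.arm_indicator.sum() < 2 or (1 - self.arm_indicator).sum() < 2:
            raise EstimationError("each arm needs n >= 2")


@dataclass
class IncrementalCloud:
    """m × B paired bootstrap draws of (ΔQALY, ΔCost)."""

    delta_qaly: np.ndarray
    delta_cost: np.ndarray
    point_delta_qaly: float
    point_delta_cost: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.delta_qaly = np.asarray(self.delta_qaly, dtype=float)
        self.delta_cost = np.asarray(self.delta_cost, dtype=float)
        if self.delta_qaly.size != self.delta_cost.size or self.delta_qaly.size == 0:
            raise ValidationError("cloud needs equal-length, non-empty pair vectors")
        if not (np.isfinite(self.delta_qaly).all() and np.isfinite(self.delta_cost).all()):
            raise ValidationError("cloud pairs must be finite")

    @property
    def size(self) -> int:
        return int(self.delta_qaly.size)

    def percentile_interval(self, which: str = "cost", level: float = 0.95) -> tuple[float, float]:
        v = self.delta_cost if which == "cost" else self.delta_qaly
        lo, hi = np.percentile(v, [50 * (1 - level), 100 - 50 * (1 - level)])
        return float(lo), float(hi)


def _arm_contrasts(s: OutcomeSet):
    """Fitted values, residuals, and point contrasts for one outcome set."""
    n = s.cost.size
    Xc = np.column_stack([np.ones(n), s.arm_indicator])
    cols = [np.ones(n), s.arm_indicator]
    if s.baseline is not None and np.ptp(s.baseline) > 0:
        cols.append(s.baseline - s.baseline.mean())
    Xq = np.column_stack(cols)
    pinv_c = np.linalg.pinv(Xc)
    pinv_q = np.linalg.pinv(Xq)
    beta_c = pinv_c @ s.cost
    beta_q = pinv_q @ s.qaly
    fit_c, fit_q = Xc @ beta_c, Xq @ beta_q
    return (Xc, Xq, pinv_c, pinv_q, fit_c, s.cost - fit_c, fit_q, s.qaly - fit_q,
            float(beta_c[1]), float(beta_q[1]))


def residual_bootstrap(outcome_sets: Sequence[OutcomeSet], B: int = 500,
                       seed: int = 0) -> IncrementalCloud:
    """Residual bootstrap within each imputed set → m × B incremental pairs.

    Point estimates are the means of the per-set arm contrasts (Rubin's
    point-combination); each replicate resamples one index vector and
    applies it to both the cost and QALY residuals (joint resampling).
    """
    if B < 1:
        raise ConfigurationError("bootstrap replications B must be >= 1")
    if len(outcome_sets) < 1:
        raise EstimationError("at least one outcome set required")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    dq_all, dc_all, pt_q, pt_c = [], [], [], []
    for s in outcome_sets:
        (Xc, Xq, pinv_c, pinv_q, fit_c, res_c, fit_q, res_q,
         point_c, point_q) = _arm_contrasts(s)
        pt_c.append(point_c)
        pt_q.append(point_q)
        n = fit_c.size
        idx = rng.integers(0, n, size=(B, n))
        pseudo_c = fit_c[None, :] + res_c[idx]       # (B, n)
        pseudo_q = fit_q[None, :] + res_q[idx]
        dc_all.append(pinv_c[1] @ pseudo_c.T)        # arm coefficient per replicate
        dq_all.append(pinv_q[1] @ pseudo_q.T)
    return IncrementalCloud(
        delta_qaly=np.concatenate(dq_all),
        delta_cost=np.concatenate(dc_all),
        point_delta_qaly=float(np.mean(pt_q)),
        point_delta_cost=float(np.mean(pt_c)),
        seed=seed,
    )


#: CE-plane quadrants, keyed by compass direction (x = ΔE, y = ΔC).
QUADRANTS = ("NE", "SE", "SW", "NW")


def ce_plane_summary(cloud: IncrementalCloud) -> dict[str, float]:
    """Fraction of bootstrap pairs in each cost-effectiveness-plane quadrant.

    Boundary pairs (ΔE = 0 or ΔC = 0) join the adjacent clockwise quadrant
    — i.e. ΔE = 0 counts as "less effective", ΔC = 0 as "cheaper" — so the
    four fractions always partition the cloud.
    """
    dq, dc = cloud.delta_qaly, cloud.delta_cost
    ne = np.mean((dq > 0) & (dc > 0))
    se = np.mean((dq > 0) & (dc <= 0))
    sw = np.mean((dq <= 0) & (dc <= 0))
    nw = np.mean((dq <= 0) & (dc > 0))
    return {"NE": float(ne), "SE": float(se), "SW": float(sw), "NW": float(nw)}


def ceac(cloud: IncrementalCloud, wtp: WTPConfig | None = None):
    """Cost-effectiveness acceptability curve from the bootstrap cloud.

    For each willingness-to-pay λ the acceptability is the fraction of
    pairs with positive incremental net monetary benefit λ·ΔE − ΔC.
    Returns ``(grid, probabilities, probability_at_threshold)``.
    """
    wtp = wtp or WTPConfig()
    grid = np.asarray(wtp.grid, dtype=float)
    nmb = grid[:, None] * cloud.delta_qaly[None, :] - cloud.delta_cost[None, :]
    probs = (nmb > 0).mean(axis=1)
    at_threshold = float(np.mean(
        wtp.threshold * cloud.delta_qaly - cloud.delta_cost > 0))
    return grid, probs, at_threshold


# ---------------------------------------------------------------------------
# sensitivity scenarios
# ---------------------------------------------------------------------------

SCENARIO_NAMES = ("main", "pp", "healthcare_plus_nonmedical",
                  "fee_1.5x", "fee_2x", "employed_only", "one_year")


@dataclass(frozen=True)
class ScenarioSpec:
    """One named analysis scenario and its parameters.

    ``main`` is the base case; the five sensitivity scenarios are the
    per-protocol filter (≥ ``min_sessions`` sessions), the
    healthcare-plus-non-medical perspective, pharmacopuncture fee
    multipliers, productivity loss restricted to employed patients, and
    one-year extrapolation of week-13 values.
    """

    name: str = "main"
    min_sessions: int = 0
    fee_multiplier: float = 1.0
    productivity_mode: str = "base"
    extrapolate: bool = False

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ConfigurationError(f"unknown scenario {self.name!r}; choose from {SCENARIO_NAMES}")
        if self.fee_multiplier <= 0:
            raise ConfigurationError("fee multiplier must be > 0")
        if self.min_sessions < 0:
            raise ConfigurationError("min_sessions must be >= 0")
        if self.productivity_mode not in ("base", "employed_only"):
            raise ConfigurationError("productivity mode must be 'base' or 'employed_only'")
        expected = _named(self.name)
        for f in ("min_sessions", "fee_multiplier", "productivity_mode", "extrapolate"):
            if getattr(self, f) != getattr(expected, f):
                raise ConfigurationError(
                    f"scenario {self.name!r}: parameter {f} inconsistent with its name")

    @classmethod
    def named(cls, name: str) -> "ScenarioSpec":
        return _named(name)

    @property
    def perspectives(self) -> tuple[str, ...]:
        if self.name == "healthcare_plus_nonmedical":
            return ("healthcare_plus_nonmedical",)
        if self.name == "employed_only":
            return ("societal",)
        return ("societal", "healthcare")


_SCENARIO_PARAMS: dict[str, dict] = {
    "main": {},
    "pp": {"min_sessions": 9},
    "healthcare_plus_nonmedical": {},
    "fee_1.5x": {"fee_multiplier": 1.5},
    "fee_2x": {"fee_multiplier": 2.0},
    "employed_only": {"productivity_mode": "employed_only"},
    "one_year": {"extrapolate": True},
}


def _named(name: str) -> "ScenarioSpec":
    # construct without re-entering __post_init__'s consistency check
    if name not in _SCENARIO_PARAMS:
        raise ConfigurationError(f"unknown scenario {name!r}")
    kw = _SCENARIO_PARAMS[name]
    obj = object.__new__(ScenarioSpec)
    object.__setattr__(obj, "name", name)
    object.__setattr__(obj, "min_sessions", kw.get("min_sessions", 0))
    object.__setattr__(obj, "fee_multiplier", kw.get("fee_multiplier", 1.0))
    object.__setattr__(obj, "productivity_mode", kw.get("productivity_mode", "base"))
    object.__setattr__(obj, "extrapolate", kw.get("extrapolate", False))
    return obj
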