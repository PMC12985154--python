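"""Between-arm inference and multiple-imputation pooling helpers.

`group_difference` is the work-horse: an independent two-sample comparison
(equivalently OLS on an arm indicator) with an optional ANCOVA covariate.
`rubin_pool` combines estimates across multiply-imputed datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EstimationError


@dataclass
class GroupDifference:
    """A (trt − ref) mean difference with normal-theory uncertainty."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    df: float
    adjusted_means: dict[str, float]


def group_difference(values, arms, covariates=None, *, trt: str = "PPT",
                     ref: str = "PT", alpha: float = 0.05) -> GroupDifference:
    """Mean difference (trt − ref) with t-based CI and p-value.

    Without covariates this is the pooled-variance independent t-test.
    With a covariate vector it is ANCOVA: the covariate is centred so that
    the arm coefficient is the difference of adjusted means at the grand
    mean of the covariate. A constant covariate is dropped (the centred
    column would be identically zero), recovering the raw comparison.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(arms)
    if y.shape[0] != a.shape[0]:
        raise EstimationError("values and arms must have equal length")
    is_trt = a == trt
    is_ref = a == ref
    if not np.array_equal(is_trt | is_ref, np.ones(len(a), dtype=bool)):
        unknown = sorted(set(a) - {trt, ref})
        raise EstimationError(f"unknown arm label(s): {unknown}")
    n1, n0 = int(is_trt.sum()), int(is_ref.sum())
    if n1 < 2 or n0 < 2:
        raise EstimationError(f"each arm needs n >= 2 (got {trt}={n1}, {ref}={n0})")

    cols = [np.ones(len(y)), is_trt.astype(float)]
    if covariates is not None:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        for j in range(c.shape[1]):
            col = c[:, j] - c[:, j].mean()
            if np.ptp(col) > 0:
                cols.append(col)
    X = np.column_stack(cols)
    dof = len(y) - X.shape[1]
    if dof < 1:
        raise EstimationError("degenerate design: no residual degrees of freedom")

    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise EstimationError("degenerate (rank-deficient) design matrix")
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    est = float(beta[1])

    if se == 0.0:
        p = 1.0 if est == 0.0 else 0.0
        ci_low = ci_high = est
    else:
        tcrit = stats.t.ppf(1 - alpha / 2, dof)
        ci_low, ci_high = est - tcrit * se, est + tcrit * se
        p = float(2 * stats.t.sf(abs(est / se), dof))

    adj_ref = float(beta[0])
    return GroupDifference(
        estimate=est, se=se, ci_low=float(ci_low), ci_high=float(ci_high),
        p_value=p, df=float(dof),
        adjusted_means={ref: adj_ref, trt: adj_ref + est},
    )


@dataclass
class PooledEstimate:
    """Rubin-combined estimate across m imputed datasets."""

    estimate: float
    within_variance: float
    between_variance: float
    total_variance: float
    se: float
    m: int

    def ci(self, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.ppf(1 - alpha / 2)
        return self.estimate - z * self.se, self.estimate + z * self.se

    @property
    def p_value(self) -> float:
        if self.se == 0.0:
            return 1.0 if self.estimate == 0.0 else 0.0
        return float(2 * stats.norm.sf(abs(self.estimate / self.se)))


def rubin_pool(estimates, within_variances=None) -> PooledEstimate:
    """Combine per-dataset estimates: mean, within + (1 + 1/m) × between.

    ``within_variances`` defaults to zero (pooling a variance-free summary).
    """
    est = np.asarray(estimates, dtype=float)
    m = est.size
    if m < 2:
        raise EstimationError("pooling requires m >= 2 imputed datasets")
    if within_variances is None:
        w = np.zeros(m)
    else:
        w = np.asarray(within_variances, dtype=float)
        if w.size != m:
            raise EstimationError("one within-variance per estimate required")
    qbar = float(est.mean())
    wbar = float(w.mean())
    between = float(est.var(ddof=1))
    total = wbar + (1.0 + 1.0 / m) * between
    return PooledEstimate(
        estimate=qbar, within_variance=wbar, between_variance=between,
        total_variance=total, se=float(np.sqrt(total)), m=m,
    )
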