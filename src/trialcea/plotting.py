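"""Cost-effectiveness plane and acceptability-curve plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .cea import IncrementalCloud, WTPConfig


def plot_ce_plane(cloud: IncrementalCloud, wtp: WTPConfig | None = None,
                  ax=None, title: str | None = None):
    """Scatter the bootstrap (ΔQALY, ΔCost) pairs with the WTP slope."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(cloud.delta_qaly, cloud.delta_cost, s=4, alpha=0.25,
               color="tab:blue", rasterized=True)
    ax.axhline(0, color="0.4", lw=0.8)
    ax.axvline(0, color="0.4", lw=0.8)
    if wtp is not None:
        x = np.array(ax.get_xlim())
        ax.plot(x, wtp.threshold * x, color="tab:red", lw=1.0, ls="--",
                label=f"WTP ${wtp.threshold:,.0f}/QALY")
        ax.legend(loc="best", fontsize=8)
    ax.plot([cloud.point_delta_qaly], [cloud.point_delta_cost], marker="D",
            color="black", ms=5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (USD)")
    if title:
        ax.set_title(title, fontsize=10)
    return ax


def plot_ceac(grid, probs, threshold: float | None = None, ax=None,
              title: str | None = None):
    """Probability of cost-effectiveness against willingness to pay."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(grid, probs, color="tab:blue")
    if threshold is not None:
        ax.axvline(threshold, color="tab:red", lw=1.0, ls="--",
                   label=f"WTP ${threshold:,.0f}/QALY")
        ax.legend(loc="best", fontsize=8)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("Willingness to pay (USD per QALY)")
    ax.set_ylabel("P(cost-effective)")
    if title:
        ax.set_title(title, fontsize=10)
    return ax
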