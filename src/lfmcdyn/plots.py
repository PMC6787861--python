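"""Thin plotting layer: residual panels and prediction/derivative curves.

All statistics shown here are computed by :mod:`lfmcdyn.diagnostics` and the
results objects; this module only arranges them on axes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .diagnostics import compute_residuals, residual_summaries  # noqa: E402

__all__ = ["residual_panels", "prediction_panels"]


def residual_panels(fit, level="plot"):
    """Four assumption-check panels: standardized residuals vs fitted, vs
    time, by leaf type, and a normal Q-Q plot."""
    res = compute_residuals(fit, level=level)
    fitted = fit.fittedvalues(level=level)
    summ = residual_summaries(res, fitted=fitted)
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    ax = axes[0, 0]
    ax.scatter(fitted, res.normalized, s=8, alpha=0.6)
    ax.axhline(0, color="k", lw=0.6)
    ax.set_xlabel("fitted LFMC (%)")
    ax.set_ylabel("normalized residual")
    ax = axes[0, 1]
    ax.scatter(res.day, res.normalized, s=8, alpha=0.6)
    ax.axhline(0, color="k", lw=0.6)
    ax.set_xlabel("day")
    ax.set_ylabel("normalized residual")
    ax = axes[1, 0]
    groups = pd.DataFrame({"lt": res.leaf_type, "r": res.normalized}).groupby("lt")
    ax.boxplot([g["r"].to_numpy() for _, g in groups], tick_labels=[k for k, _ in groups])
    ax.axhline(0, color="k", lw=0.6)
    ax.set_xlabel("leaf type")
    ax.set_ylabel("normalized residual")
    ax = axes[1, 1]
    qq = summ["qq"]
    ax.scatter(qq["theoretical"], qq["observed"], s=8, alpha=0.6)
    lim = [qq.min().min(), qq.max().max()]
    ax.plot(lim, lim, color="k", lw=0.6)
    ax.set_xlabel("normal quantiles")
    ax.set_ylabel("observed quantiles")
    fig.suptitle(f"Residual diagnostics ({fit.model.spec.label or fit.model.spec.mean})")
    fig.tight_layout()
    return fig


def prediction_panels(fit, days=None):
    """Population curves, plot-level curves and drying-rate curves per leaf type."""
    des = fit.model.design
    days = np.linspace(0, float(des.t.max()), 200) if days is None else np.asarray(days)
    leaf_types = des.leaf_levels
    fig, axes = plt.subplots(3, len(leaf_types), figsize=(3.0 * len(leaf_types), 8),
                             squeeze=False, sharex=True)
    data = fit.model.data.table
    for c, lt in enumerate(leaf_types):
        nd = pd.DataFrame({"leaf_type": lt, "day": days})
        pop = fit.predict(nd, level="population")
        ax = axes[0, c]
        sub = data[data["leaf_type"] == lt]
        ax.scatter(sub["day"], sub["lfmc"], s=6, alpha=0.4, color="gray")
        ax.plot(days, pop, lw=1.5)
        ax.set_title(lt)
        if c == 0:
            ax.set_ylabel("LFMC (%)\npopulation")
        ax = axes[1, c]
        site = "W" if lt == "GW" else "E"
        for pk in [p for p in des.plot_keys if p.startswith(site)]:
            ndp = nd.assign(plot_key=pk)
            ax.plot(days, fit.predict(ndp, level="plot"), lw=1.0)
        if c == 0:
            ax.set_ylabel("LFMC (%)\nper plot")
        ax = axes[2, c]
        ax.plot(days, fit.drying_speed(nd), lw=1.5)
        ax.axhline(0, color="k", lw=0.5)
        if c == 0:
            ax.set_ylabel("drying rate\n(%/day)")
        ax.set_xlabel("days since first measurement")
    fig.tight_layout()
    return fig
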