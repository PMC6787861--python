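"""Residual diagnostics backing the model-assumption checks.

Three residual flavours are computed at the plot level (conditional on the
random-effect modes): raw residuals in LFMC %, Pearson residuals (raw
divided by the modelled per-observation SD) and normalized residuals
(Pearson residuals pre-multiplied by the inverse Cholesky factor of the
modelled within-series correlation, so a correctly specified fit leaves
them iid standard normal).  For independence structures the normalized and
Pearson residuals coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular
from scipy.stats import norm

from .covariance import ARMASpec, arma_acf
from .model import LfmcResults

__all__ = ["ResidualSet", "compute_residuals", "residual_summaries", "intraclass_correlation"]


@dataclass
class ResidualSet:
    """Aligned residual vectors with their design labels."""

    raw: np.ndarray
    pearson: np.ndarray
    normalized: np.ndarray
    leaf_type: np.ndarray
    plot: np.ndarray
    day: np.ndarray
    series_id: np.ndarray  # -1 where no series structure applies

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "raw": self.raw, "pearson": self.pearson, "normalized": self.normalized,
            "leaf_type": self.leaf_type, "plot": self.plot, "day": self.day,
            "series_id": self.series_id,
        })


def _model_sds(fit: LfmcResults) -> np.ndarray:
    model = fit.model
    sigma = float(fit.params["sigma"])
    if model.spec.varident:
        ratios = np.concatenate(([1.0],
                                 [float(fit.params[f"delta({lt})"])
                                  for lt in model.design.leaf_offsets]))
        return sigma * ratios[model.design.row_leaf]
    return np.full(model.nobs, sigma)


def compute_residuals(fit: LfmcResults, level: str = "plot") -> ResidualSet:
    """Raw / Pearson / normalized residuals of a fit on its own data.

    ``level="plot"`` (default) subtracts plot-conditional fitted values;
    ``level="population"`` uses fixed effects only.
    """
    model = fit.model
    df = model.data.table
    raw = df["lfmc"].to_numpy(dtype=float) - fit.fittedvalues(level=level)
    sds = _model_sds(fit)
    pearson = raw / sds
    normalized = pearson.copy()
    series_id = np.full(len(df), -1)
    if model.spec.arma is not None:
        u, v = model.spec.arma
        ar = ARMASpec(order=model.spec.arma,
                      rho=float(fit.params.get("rho", 0.0)) if u else 0.0,
                      theta=float(fit.params.get("theta", 0.0)) if v else 0.0)
        sid = 0
        for pos, rows, plots in model.design.patterns:
            lagmat = np.abs(pos[:, None] - pos[None, :])
            L = cholesky(arma_acf(ar, lagmat), lower=True)
            normalized[rows] = solve_triangular(L, pearson[rows], lower=True)
            for c in range(rows.shape[1]):
                series_id[rows[:, c]] = sid
                sid += 1
    return ResidualSet(
        raw=raw, pearson=pearson, normalized=normalized,
        leaf_type=df["leaf_type"].to_numpy(), plot=df["plot_key"].to_numpy(),
        day=df["day"].to_numpy(), series_id=series_id,
    )


def residual_summaries(res: ResidualSet, fitted: Optional[np.ndarray] = None,
                       max_lag: int = 3) -> Dict[str, pd.DataFrame]:
    """Numeric summaries of a residual set.

    Returns per-stratum SDs of the Pearson residuals, per-series lag-1..3
    autocorrelations of the normalized residuals (NaN where a series is too
    short), normal-quantile pairs for a Q-Q display, and a location-scale
    trend statistic (the correlation of |normalized residual| with the
    fitted value, when fitted values are supplied).
    """
    df = res.frame()
    strata = (df.groupby("leaf_type")["pearson"].agg(["std", "count"])
              .rename(columns={"std": "sd", "count": "n"}))

    # serial structure: fall back to plot x leaf type x day-ordered groups
    # when the fit had no explicit series
    if (df["series_id"] >= 0).any():
        groups = df[df["series_id"] >= 0].groupby("series_id")
    else:
        df = df.sort_values("day", kind="stable")
        groups = df.groupby(["plot", "leaf_type"])
    acs = []
    for key, g in groups:
        x = g.sort_values("day", kind="stable")["normalized"].to_numpy()
        row = {"series": str(key), "n": len(x)}
        for lag in range(1, max_lag + 1):
            if len(x) > lag + 1 and np.std(x) > 0:
                row[f"acf{lag}"] = float(np.corrcoef(x[:-lag], x[lag:])[0, 1])
            else:
                row[f"acf{lag}"] = np.nan
        acs.append(row)
    acf_tab = pd.DataFrame(acs)

    z = np.sort(res.normalized)
    n = z.size
    theo = norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    qq = pd.DataFrame({"theoretical": theo, "observed": z})

    trend = np.nan
    if fitted is not None and np.std(fitted) > 0:
        trend = float(np.corrcoef(np.abs(res.normalized), fitted)[0, 1])
    scalar = pd.DataFrame({"statistic": ["abs_resid_vs_fitted_corr"], "value": [trend]})
    return {"stratum_sd": strata, "series_acf": acf_tab, "qq": qq, "trend": scalar}


def intraclass_correlation(fit: LfmcResults, n_pairs: int = 10_000,
                           seed: int = 0) -> float:
    """Descriptive within-plot intraclass correlation under the fitted model.

    Simulates ``n_pairs`` pairs of same-plot observations (common random
    effects, independent residuals) at design rows resampled from the data,
    subtracts the fixed-effect mean of each row, and returns the Pearson
    correlation of the paired deviations.  Purely descriptive: the nonlinear
    model induces no single closed-form intraclass correlation.
    """
    from .model import _mean_value

    model = fit.model
    rng = np.random.default_rng(seed)
    df = model.data.table
    idx = rng.integers(0, len(df), size=n_pairs)
    rows = df.iloc[idx]
    sds = _model_sds(fit)[idx]
    t = rows["day"].to_numpy(dtype=float)
    P0 = model._resolve_params(rows, fit.params, None, "population")
    mu0 = _mean_value(model.spec.mean, t, dict(P0))
    P = dict(P0)
    for p in model.spec.random:
        P[p] = P[p] + rng.normal(0.0, float(fit.params[f"sd({p})"]), size=n_pairs)
    mu = _mean_value(model.spec.mean, t, P)
    d1 = (mu - mu0) + sds * rng.standard_normal(n_pairs)
    d2 = (mu - mu0) + sds * rng.standard_normal(n_pairs)
    return float(np.corrcoef(d1, d2)[0, 1])
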