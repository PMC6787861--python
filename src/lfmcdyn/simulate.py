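"""Synthetic LFMC datasets emulating the two-site Patagonian field design.

The design: two sites along an aridity gradient (W wet, E dry), three
500 x 500 m plots per site, seven sampling dates spanning the ~90-day fire
season, and three within-plot sampling points per plot x date x leaf type.
Grasses-west (GW) are measured only at site W; grasses-east (GE) and the two
shrubs (SM = M. spinosum, SS = S. filaginoides) only at site E — 252 design
cells, of which a handful (5 by default) are lost at random, giving n = 247.

Responses are generated from the full drying-curve model: leaf-type-specific
four-parameter logistic means, an independent plot random effect on the
upper asymptote A (optionally on other parameters), leaf-type-specific
residual SDs (varIdent) and optional ARMA serial correlation along each
plot x leaf-type x replicate series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from scipy.signal import lfilter

from .covariance import ARMASpec, VarIdentSpec, correlation_at_positions, varident_sd
from .data import LfmcDataset
from .exceptions import InvalidParameterError
from .logistic import LogisticParams

__all__ = [
    "DesignSpec",
    "GeneratingParams",
    "generate_design",
    "simulate_dataset",
    "simulate_arma",
    "recovery_experiment",
]

#: seven sampling dates spread as evenly as integers allow over [0, 89] days
DEFAULT_DAYS = (0, 15, 30, 44, 59, 74, 89)


@dataclass(frozen=True)
class DesignSpec:
    """Field-design layout for the synthetic generator."""

    plots_per_site: int = 3
    days: Tuple[int, ...] = DEFAULT_DAYS
    points: int = 3
    leaf_types_by_site: Tuple[Tuple[str, Tuple[str, ...]], ...] = (
        ("W", ("GW",)), ("E", ("GE", "SM", "SS")),
    )
    n_lost: int = 5

    @property
    def n_cells(self) -> int:
        per_date_point = sum(len(lts) for _, lts in self.leaf_types_by_site)
        return per_date_point * self.plots_per_site * len(self.days) * self.points

    def __post_init__(self):
        if self.n_lost < 0 or self.n_lost >= max(self.n_cells, 1):
            raise InvalidParameterError("n_lost must be in [0, n_cells)")


@dataclass
class GeneratingParams:
    """Truth values for the generator.

    Defaults are the fitted drying-curve estimates for this design: curve
    parameters per leaf type (GW reference plus offsets), a plot random-effect
    SD on A of 9.4%, reference residual SD 7.1% with leaf-type ratios
    (GE 0.9, SM 3.2, SS 3.0), and no serial correlation.
    """

    curves: Dict[str, LogisticParams] = field(default_factory=lambda: {
        "GW": LogisticParams(A=54.3, w=29.1, m=30.9, s=-16.1),
        "GE": LogisticParams(A=54.3 + 30.9, w=29.1 - 20.7, m=30.9, s=-16.1),
        "SM": LogisticParams(A=54.3 + 223.4, w=29.1 + 31.7, m=30.9, s=-16.1),
        "SS": LogisticParams(A=54.3 + 240.3, w=29.1 + 26.7, m=30.9, s=-16.1),
    })
    random_sds: Dict[str, float] = field(default_factory=lambda: {"A": 9.4})
    sigma_base: float = 7.1
    delta: Dict[str, float] = field(default_factory=lambda: {"GE": 0.9, "SM": 3.2, "SS": 3.0})
    rho: Optional[float] = None
    theta: Optional[float] = None

    def __post_init__(self):
        for p, sd in self.random_sds.items():
            if sd < 0:
                raise InvalidParameterError(f"random-effect SD for {p} must be >= 0")
        if self.sigma_base < 0:
            raise InvalidParameterError("sigma_base must be >= 0")

    @property
    def arma_order(self) -> Tuple[int, int]:
        return (int(self.rho is not None), int(self.theta is not None))

    def varident_spec(self) -> VarIdentSpec:
        return VarIdentSpec(sigma_base=max(self.sigma_base, 1e-300), delta=dict(self.delta))

    def fixed_effect_values(self) -> Dict[str, float]:
        """Truth on the coefficient scale used by the model (GW reference
        plus leaf-type offsets), for recovery experiments."""
        ref = self.curves["GW"]
        out = {"A0": ref.A, "w0": ref.w, "m": ref.m, "s": ref.s}
        for lt in ("GE", "SM", "SS"):
            c = self.curves[lt]
            out[f"A[{lt}]"] = c.A - ref.A
            out[f"w[{lt}]"] = c.w - ref.w
        return out


def generate_design(spec: DesignSpec = DesignSpec()) -> pd.DataFrame:
    """One row per design cell (site, plot, point, leaf_type, day); the
    response column is absent — :func:`simulate_dataset` fills it in."""
    rows = []
    for site, lts in spec.leaf_types_by_site:
        for plot in range(1, spec.plots_per_site + 1):
            for day in spec.days:
                for lt in lts:
                    for point in range(1, spec.points + 1):
                        rows.append((site, str(plot), str(point), lt, int(day)))
    return pd.DataFrame(rows, columns=["site", "plot", "point", "leaf_type", "day"])


def simulate_arma(n: int, rho: float = 0.0, theta: float = 0.0,
                  rng: Optional[np.random.Generator] = None,
                  burn: int = 1000) -> np.ndarray:
    """Simulate a unit-variance ARMA(1,1) series of length ``n`` recursively
    (x_t = rho x_{t-1} + eta_t + theta eta_{t-1}); AR(1)/MA(1)/white noise
    arise by zeroing coefficients."""
    order = ARMASpec(order=(int(rho != 0.0), int(theta != 0.0)), rho=rho, theta=theta)
    rng = rng if rng is not None else np.random.default_rng()
    eta = rng.standard_normal(n + burn)
    x = lfilter([1.0, order.theta], [1.0, -order.rho], eta)[burn:]
    # scale to unit marginal variance
    g0 = (1.0 + 2.0 * order.rho * order.theta + order.theta**2) / (1.0 - order.rho**2) \
        if order.order[0] else (1.0 + order.theta**2)
    return x / np.sqrt(g0)


def simulate_dataset(design, truth: GeneratingParams = None, seed=None,
                     n_lost: Optional[int] = None) -> LfmcDataset:
    """Draw a full synthetic dataset.

    Parameters
    ----------
    design : DesignSpec or DataFrame
        Either a design specification or a pre-built skeleton from
        :func:`generate_design`.
    truth : GeneratingParams
        Generative truth (defaults to the fitted-model values).
    seed : int or numpy Generator
        Every random draw (plot effects, noise, lost rows) flows from it.
    n_lost : int, optional
        Overrides the design's loss count (ignored for DataFrame input,
        where it defaults to 0 unless given).
    """
    truth = truth if truth is not None else GeneratingParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(design, DesignSpec):
        skel = generate_design(design)
        lost = design.n_lost if n_lost is None else int(n_lost)
    else:
        skel = design.copy().reset_index(drop=True)
        lost = 0 if n_lost is None else int(n_lost)
    df = skel.copy()
    df["plot_key"] = df["site"].astype(str) + df["plot"].astype(str)
    plot_keys = sorted(df["plot_key"].unique())

    # plot random effects, independent across curve parameters
    re_draws = {p: dict(zip(plot_keys, rng.normal(0.0, sd, size=len(plot_keys))))
                for p, sd in truth.random_sds.items() if sd > 0}

    # deterministic means plus plot deviations
    t = df["day"].to_numpy(dtype=float)
    mu = np.empty(len(df))
    for lt in df["leaf_type"].unique():
        if lt not in truth.curves:
            raise InvalidParameterError(f"no generating curve for leaf type {lt!r}")
    for i, (lt, pk, ti) in enumerate(zip(df["leaf_type"], df["plot_key"], t)):
        c = truth.curves[lt]
        kw = c.as_dict()
        for p, draws in re_draws.items():
            kw[p] = kw[p] + draws[pk]
        z = (kw["m"] - ti) / kw["s"]
        mu[i] = kw["w"] + (kw["A"] - kw["w"]) / (1.0 + np.exp(z))

    # residual noise: varIdent SDs, optionally ARMA-correlated along series
    if truth.sigma_base > 0:
        sds = varident_sd(truth.varident_spec(), df["leaf_type"])
    else:
        sds = np.zeros(len(df))
    eps = np.zeros(len(df))
    order = truth.arma_order
    if order != (0, 0) and truth.sigma_base > 0:
        ar = ARMASpec(order=order, rho=truth.rho or 0.0, theta=truth.theta or 0.0)
        day_rank = {d: r for r, d in enumerate(np.sort(df["day"].unique()))}
        df["_rank"] = df["day"].map(day_rank)
        df["_rep"] = (df.sort_values("point", kind="stable")
                        .groupby(["plot_key", "leaf_type", "day"]).cumcount()
                        .reindex(df.index))
        for _, g in df.groupby(["plot_key", "leaf_type", "_rep"], sort=True):
            g = g.sort_values("_rank", kind="stable")
            C = correlation_at_positions(ar, g["_rank"].to_numpy())
            L = cholesky(C, lower=True)
            eps[g.index] = L @ rng.standard_normal(len(g))
        df = df.drop(columns=["_rank", "_rep"])
    elif truth.sigma_base > 0:
        eps = rng.standard_normal(len(df))

    # Gaussian tails may dip just below zero for the driest stratum; keep the
    # exact generative law rather than truncating it.
    df["lfmc"] = mu + sds * eps

    if lost:
        drop = rng.choice(len(df), size=lost, replace=False)
        df = df.drop(df.index[drop]).reset_index(drop=True)
    return LfmcDataset.from_frame(df.drop(columns=["plot_key"]), require_nonnegative=False)


def recovery_experiment(truth: GeneratingParams = None,
                        design: DesignSpec = DesignSpec(),
                        n_reps: int = 50, seed: int = 0,
                        spec=None, keep_fits: bool = False):
    """Simulate-and-refit experiment at the study design scale.

    Fits the generating model structure to ``n_reps`` independent synthetic
    datasets and tabulates, per fixed-effect coefficient: bias, empirical SD,
    RMSE and 95% Wald-interval coverage.  Non-converged replicates are
    excluded and counted.

    Returns
    -------
    table : DataFrame indexed by coefficient
    info : dict with ``n_reps``, ``n_used``, ``n_failed`` and (if
        ``keep_fits``) the per-replicate results objects.
    """
    from .model import LfmcModel, ModelSpec  # deferred: avoid cycle

    if n_reps < 2:
        raise InvalidParameterError("n_reps must be >= 2")
    truth = truth if truth is not None else GeneratingParams()
    if spec is None:
        spec = ModelSpec.final_lfmc()
    true_fe = truth.fixed_effect_values()
    rng = np.random.default_rng(seed)
    rows, fits, n_failed = [], [], 0
    for rep in range(n_reps):
        ds = simulate_dataset(design, truth, seed=rng)
        try:
            res = LfmcModel(ds, spec).fit(seed=int(rng.integers(2**31 - 1)))
        except Exception:
            n_failed += 1
            continue
        if not res.converged:
            n_failed += 1
            continue
        ci = res.conf_int()
        rec = {}
        for nm, tv in true_fe.items():
            if nm not in res.params.index:
                continue
            rec[nm] = (float(res.params[nm]),
                       bool(ci.loc[nm, "lower"] <= tv <= ci.loc[nm, "upper"]))
        rows.append(rec)
        if keep_fits:
            fits.append(res)
    if not rows:
        raise InvalidParameterError("every replicate failed to converge")
    names = [nm for nm in true_fe if nm in rows[0]]
    est = np.array([[r[nm][0] for nm in names] for r in rows])
    cover = np.array([[r[nm][1] for nm in names] for r in rows])
    tv = np.array([true_fe[nm] for nm in names])
    table = pd.DataFrame({
        "truth": tv,
        "mean_estimate": est.mean(axis=0),
        "bias": est.mean(axis=0) - tv,
        "empirical_sd": est.std(axis=0, ddof=1),
        "rmse": np.sqrt(((est - tv) ** 2).mean(axis=0)),
        "coverage95": cover.mean(axis=0),
    }, index=names)
    info = {"n_reps": n_reps, "n_used": len(rows), "n_failed": n_failed}
    if keep_fits:
        info["fits"] = fits
    return table, info
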