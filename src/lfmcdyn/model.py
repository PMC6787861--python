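"""Maximum-likelihood nonlinear mixed-effects engine for LFMC drying curves.

The statistical model: observation ``i`` in plot ``j`` is

    LFMC_ji ~ N(mu_i, sigma_i^2)

with ``mu_i`` a four-parameter logistic (or linear/constant) function of the
sampling day whose curve parameters resolve, per observation, to fixed-effect
coefficients (a reference level for grasses-west plus leaf-type offsets,
optionally plot offsets) plus independent mean-zero normal plot random
effects on a chosen subset of parameters.  Residual SDs follow a varIdent
variance function by leaf type and residuals may be serially correlated
within measurement series through a stationary ARMA(u, v) structure.

Estimation is exact maximum likelihood (ML, not REML): plot random effects
are integrated out by adaptive Gauss-Hermite quadrature (7 nodes per
dimension, centred and scaled at the per-plot conditional mode) for up to
two random-effect dimensions, and by a Laplace approximation beyond that.
For models with no random effects the residual SD is profiled out in closed
form, leaving a GLS-type concentrated likelihood.

The public surface follows the statsmodels idiom::

    model = LfmcModel(dataset, ModelSpec(...))
    res = model.fit()
    res.summary(); res.predict(newdata, level="plot"); res.aic
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import least_squares, minimize
from scipy.special import logsumexp
from scipy.stats import norm

from .covariance import ARMASpec, arma_acf
from .data import LEAF_TYPES, LfmcDataset
from .exceptions import (
    ConvergenceError,
    InvalidParameterError,
    LabelingError,
    UnsupportedOperationError,
)
from .logistic import LogisticParams, _curve, _rate, self_start

__all__ = ["ModelSpec", "LfmcModel", "LfmcResults", "MEAN_PARAMS"]

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))

#: curve parameters of each supported mean function, in canonical order
MEAN_PARAMS = {
    "logistic": ("A", "w", "m", "s"),
    "linear": ("b0", "b1"),
    "constant": ("b0",),
}


def _mean_value(mean: str, t: np.ndarray, P: Dict[str, np.ndarray]) -> np.ndarray:
    if mean == "logistic":
        return _curve(t, P["A"], P["w"], P["m"], P["s"])
    if mean == "linear":
        return P["b0"] + P["b1"] * t
    if mean == "constant":
        return P["b0"] * np.ones_like(t)
    raise InvalidParameterError(f"unknown mean function {mean!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Which effects and covariance structures enter the model.

    Parameters
    ----------
    mean : {"logistic", "linear", "constant"}
    fixed : mapping curve-parameter -> {"common", "by_leaf_type"}
        Missing parameters default to ``by_leaf_type`` for the logistic and
        linear means and ``common`` for the constant mean.
    random : tuple of curve-parameter names
        Parameters receiving an independent plot-level random effect.
    varident : bool
        Leaf-type-specific residual SDs (reference stratum GW).
    arma : (u, v) or None
        Serial-correlation order along within-plot measurement series.
    plot_fixed : tuple of curve-parameter names
        Parameters receiving *fixed* plot offsets (used by the purely
        fixed-effects alternative models).
    label : str
        Cosmetic tag used in comparison tables and logs.
    """

    mean: str = "logistic"
    fixed: Tuple[Tuple[str, str], ...] = ()
    random: Tuple[str, ...] = ("A",)
    varident: bool = True
    arma: Optional[Tuple[int, int]] = None
    plot_fixed: Tuple[str, ...] = ()
    label: str = ""

    def __post_init__(self):
        if self.mean not in MEAN_PARAMS:
            raise InvalidParameterError(f"unknown mean function {self.mean!r}")
        params = MEAN_PARAMS[self.mean]
        fixed = dict(self.fixed)
        for p, coding in fixed.items():
            if p not in params:
                raise InvalidParameterError(f"{p!r} is not a parameter of the {self.mean} mean")
            if coding not in ("common", "by_leaf_type"):
                raise InvalidParameterError(f"bad coding {coding!r} for {p!r}")
        for p in self.random:
            if p not in params:
                raise InvalidParameterError(f"random effect on unknown parameter {p!r}")
        for p in self.plot_fixed:
            if p not in params:
                raise InvalidParameterError(f"plot offsets on unknown parameter {p!r}")
        if self.arma is not None:
            ARMASpec(order=tuple(self.arma))  # validates order
        object.__setattr__(self, "fixed", tuple(sorted(fixed.items())))
        object.__setattr__(self, "random", tuple(p for p in params if p in self.random))
        object.__setattr__(self, "plot_fixed", tuple(p for p in params if p in self.plot_fixed))

    # convenient dict-style access to the coding of each curve parameter
    def coding(self, p: str) -> str:
        fixed = dict(self.fixed)
        default = "common" if self.mean == "constant" else "by_leaf_type"
        return fixed.get(p, default)

    def with_(self, **kw) -> "ModelSpec":
        return replace(self, **kw)

    @classmethod
    def final_lfmc(cls) -> "ModelSpec":
        """The selected drying-curve model: leaf-type effects on both
        asymptotes, a single inflection time and steepness, a plot random
        effect on the upper asymptote, and leaf-type residual SDs."""
        return cls(
            mean="logistic",
            fixed=(("A", "by_leaf_type"), ("w", "by_leaf_type"),
                   ("m", "common"), ("s", "common")),
            random=("A",),
            varident=True,
            arma=None,
            label="M1",
        )


# ---------------------------------------------------------------------------
# internal design / parameter layout
# ---------------------------------------------------------------------------


class _Design:
    """Per-observation design: coefficient matrices for each curve parameter,
    plot grouping, and (when ARMA is requested) the series structure."""

    def __init__(self, spec: ModelSpec, data: LfmcDataset):
        df = data.table
        self.spec = spec
        self.n = len(df)
        self.t = df["day"].to_numpy(dtype=float)
        self.y = df["lfmc"].to_numpy(dtype=float)

        self.leaf_levels = [lt for lt in LEAF_TYPES if lt in set(df["leaf_type"])]
        self.leaf_ref = self.leaf_levels[0]
        self.leaf_offsets = self.leaf_levels[1:]
        leaf_idx = {lt: k for k, lt in enumerate(self.leaf_levels)}
        self.row_leaf = df["leaf_type"].map(leaf_idx).to_numpy()

        self.plot_keys = sorted(df["plot_key"].unique())
        self.J = len(self.plot_keys)
        pk_idx = {pk: j for j, pk in enumerate(self.plot_keys)}
        self.row_plot = df["plot_key"].map(pk_idx).to_numpy()
        self.n_per_plot = np.bincount(self.row_plot, minlength=self.J)

        # fixed-effect coefficient matrices per curve parameter
        self.D: Dict[str, np.ndarray] = {}
        self.coef_names: Dict[str, list] = {}
        for p in MEAN_PARAMS[spec.mean]:
            cols = [np.ones(self.n)]
            plain = spec.coding(p) == "common" and p not in spec.plot_fixed
            names = [p if plain else f"{p}0"]
            if spec.coding(p) == "by_leaf_type":
                for lt in self.leaf_offsets:
                    cols.append((df["leaf_type"] == lt).to_numpy(float))
                    names.append(f"{p}[{lt}]")
            if p in spec.plot_fixed:
                for pk in self.plot_keys[1:]:
                    cols.append((df["plot_key"] == pk).to_numpy(float))
                    names.append(f"{p}[plot:{pk}]")
            self.D[p] = np.column_stack(cols)
            self.coef_names[p] = names

        # ARMA series structure: plot x leaf type x replicate rank, ordered
        # by the rank of the sampling date; positions are integer date ranks.
        self.patterns = None
        if spec.arma is not None:
            day_rank = {d: r for r, d in enumerate(np.sort(df["day"].unique()))}
            work = df[["plot_key", "leaf_type", "day", "point"]].copy()
            work["date_rank"] = work["day"].map(day_rank)
            work["rep"] = (
                work.sort_values("point", kind="stable")
                .groupby(["plot_key", "leaf_type", "day"])
                .cumcount()
                .reindex(work.index)
            )
            groups: Dict[tuple, list] = {}
            for row, key in enumerate(zip(work["plot_key"], work["leaf_type"], work["rep"])):
                groups.setdefault(key, []).append(row)
            patt: Dict[tuple, list] = {}
            ranks = work["date_rank"].to_numpy()
            for key, rows in groups.items():
                rows = np.asarray(rows)
                order = np.argsort(ranks[rows], kind="stable")
                rows = rows[order]
                pos = tuple(int(r) for r in ranks[rows])
                patt.setdefault(pos, []).append((rows, self.row_plot[rows[0]]))
            # pattern -> (rows matrix (L, n_series), plot index per series)
            self.patterns = []
            for pos, entries in sorted(patt.items()):
                rows_mat = np.column_stack([e[0] for e in entries])
                plots = np.array([e[1] for e in entries])
                self.patterns.append((np.asarray(pos), rows_mat, plots))


class _Layout:
    """Packing/unpacking of the optimizer vector (transformed scale) and the
    full natural parameter vector used for reporting.

    Transformed scale: fixed-effect coefficients are untransformed, SDs and
    variance ratios are log-transformed, ARMA coefficients pass through
    atanh (so stationarity is automatic)."""

    def __init__(self, spec: ModelSpec, design: _Design, profile_sigma: bool):
        self.spec = spec
        self.profile_sigma = profile_sigma
        self.beta_names: list = []
        self.beta_slices: Dict[str, slice] = {}
        k = 0
        for p in MEAN_PARAMS[spec.mean]:
            names = design.coef_names[p]
            self.beta_slices[p] = slice(k, k + len(names))
            self.beta_names.extend(names)
            k += len(names)
        self.n_beta = k
        self.re_names = [f"sd({p})" for p in spec.random]
        self.delta_names = [f"delta({lt})" for lt in design.leaf_offsets] if spec.varident else []
        self.corr_names = []
        if spec.arma is not None:
            u, v = spec.arma
            if u:
                self.corr_names.append("rho")
            if v:
                self.corr_names.append("theta")
        # optimizer vector: beta | log re sds | [log sigma] | log deltas | atanh corr
        self.opt_names = list(self.beta_names) + list(self.re_names)
        if not profile_sigma:
            self.opt_names.append("sigma")
        self.opt_names += self.delta_names + self.corr_names
        # full natural vector (always includes sigma)
        self.full_names = (
            list(self.beta_names) + list(self.re_names) + ["sigma"]
            + self.delta_names + self.corr_names
        )
        self.k = len(self.full_names)

    def transform_kind(self, name: str) -> str:
        if name in self.beta_names:
            return "id"
        if name in ("rho", "theta"):
            return "tanh"
        return "log"

    def bounds(self, names) -> list:
        out = []
        for nm in names:
            kind = self.transform_kind(nm)
            if kind == "id":
                out.append((None, None))
            elif kind == "tanh":
                out.append((-3.8, 3.8))
            elif nm in self.re_names:
                # floor a vanishing random-effect SD at ~2.5e-3 (indistinguishable
                # from 0 against residual SDs of order 1-20); flagged as boundary
                out.append((-6.0, 8.0))
            else:
                out.append((-12.0, 8.0))
        return out

    def to_natural(self, values, names) -> np.ndarray:
        nat = np.array(values, dtype=float)
        for i, nm in enumerate(names):
            kind = self.transform_kind(nm)
            if kind == "log":
                nat[i] = np.exp(nat[i])
            elif kind == "tanh":
                nat[i] = np.tanh(nat[i])
        return nat

    def to_transformed(self, natural, names) -> np.ndarray:
        th = np.array(natural, dtype=float)
        for i, nm in enumerate(names):
            kind = self.transform_kind(nm)
            if kind == "log":
                th[i] = np.log(max(th[i], 1e-300))
            elif kind == "tanh":
                th[i] = np.arctanh(np.clip(th[i], -0.99999, 0.99999))
        return th

    def jacobian_diag(self, theta_full: np.ndarray) -> np.ndarray:
        """d(natural)/d(transformed) for the full vector."""
        d = np.ones(self.k)
        for i, nm in enumerate(self.full_names):
            kind = self.transform_kind(nm)
            if kind == "log":
                d[i] = np.exp(theta_full[i])
            elif kind == "tanh":
                d[i] = 1.0 - np.tanh(theta_full[i]) ** 2
        return d


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(7)
_PENALTY = 1e12


class LfmcModel:
    """Nonlinear mixed-effects model of LFMC drying built from a dataset.

    Parameters
    ----------
    data : LfmcDataset or pandas.DataFrame
        Observation table (a DataFrame is validated on the way in).
    spec : ModelSpec, optional
        Defaults to the selected drying-curve structure
        (:meth:`ModelSpec.final_lfmc`).
    """

    def __init__(self, data, spec: Optional[ModelSpec] = None):
        if isinstance(data, pd.DataFrame):
            data = LfmcDataset.from_frame(data)
        self.data = data
        self.spec = spec if spec is not None else ModelSpec.final_lfmc()
        self.design = _Design(self.spec, data)
        self.has_re = len(self.spec.random) > 0
        self.layout = _Layout(self.spec, self.design, profile_sigma=not self.has_re)
        self.nobs = self.design.n

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: Optional[ModelSpec] = None) -> "LfmcModel":
        return cls(LfmcDataset.from_frame(df), spec)

    # -- design expansion ------------------------------------------------
    def expand_design(self) -> Dict[str, Tuple[list, np.ndarray]]:
        """Per-observation fixed-effect expansion: for each curve parameter,
        the coefficient names and the 0/1 design matrix resolving it."""
        return {p: (list(self.design.coef_names[p]), self.design.D[p].copy())
                for p in MEAN_PARAMS[self.spec.mean]}

    @property
    def k_params(self) -> int:
        """Total estimated parameters: fixed coefficients + random-effect SDs
        + residual SD + variance ratios + correlation coefficients."""
        return self.layout.k

    # -- likelihood ------------------------------------------------------
    def _unpack_opt(self, theta):
        lay = self.layout
        theta = np.asarray(theta, dtype=float)
        i = lay.n_beta
        beta = theta[:i]
        d = len(lay.re_names)
        re_sds = np.exp(theta[i:i + d])
        i += d
        if lay.profile_sigma:
            sigma = 1.0
        else:
            sigma = np.exp(theta[i])
            i += 1
        deltas = np.exp(theta[i:i + len(lay.delta_names)])
        i += len(lay.delta_names)
        corr = np.tanh(theta[i:])
        return beta, re_sds, sigma, deltas, corr

    def _context(self, beta, sigma, deltas, corr):
        """Quantities fixed within one likelihood evaluation: base parameter
        values, per-row SDs, whitening matrices and per-plot constants."""
        des, spec = self.design, self.spec
        P0 = {p: des.D[p] @ beta[self.layout.beta_slices[p]]
              for p in MEAN_PARAMS[spec.mean]}
        if spec.varident:
            ratios = np.concatenate(([1.0], deltas))
            sd = sigma * ratios[des.row_leaf]
        else:
            sd = np.full(des.n, sigma)
        const = 0.5 * des.n_per_plot * _LOG2PI + np.bincount(
            des.row_plot, weights=np.log(sd), minlength=des.J
        )
        whiten = None
        if spec.arma is not None:
            u, v = spec.arma
            ar = ARMASpec(order=spec.arma,
                          rho=corr[0] if u else 0.0,
                          theta=corr[-1] if v else 0.0)
            whiten = []
            for pos, rows, plots in des.patterns:
                lagmat = np.abs(pos[:, None] - pos[None, :])
                C = arma_acf(ar, lagmat)
                L = cholesky(C, lower=True)
                Linv = solve_triangular(L, np.eye(len(pos)), lower=True)
                logdet = float(np.sum(np.log(np.diag(L))))
                whiten.append((rows, plots, Linv))
                np.add.at(const, plots, logdet)
        return P0, sd, const, whiten

    @property
    def _plot_onehot(self) -> np.ndarray:
        oh = getattr(self, "_plot_onehot_", None)
        if oh is None:
            des = self.design
            oh = np.zeros((des.n, des.J))
            oh[np.arange(des.n), des.row_plot] = 1.0
            self._plot_onehot_ = oh
        return oh

    def _cond_nll(self, P0, sd, const, whiten, B):
        """Per-plot Gaussian -loglik conditional on random effects ``B``
        (shape (J, d) or None).  Vectorised over plots."""
        Bs = None if B is None or B.size == 0 else B[None, ...]
        return self._cond_nll_multi(P0, sd, const, whiten, Bs)[0]

    def _cond_nll_multi(self, P0, sd, const, whiten, B_stack):
        """Per-plot conditional -loglik for a stack of random-effect values
        ``B_stack`` of shape (Q, J, d) (or None), returned as (Q, J).
        One vectorised pass over all Q evaluation points."""
        des, spec = self.design, self.spec
        if B_stack is None:
            P = P0
            Q = 1
        else:
            Q = B_stack.shape[0]
            P = dict(P0)
            for k, p in enumerate(spec.random):
                P = {**P, p: P0[p][None, :] + B_stack[:, des.row_plot, k]}
        mu = _mean_value(spec.mean, des.t, P)
        z = (des.y - mu) / sd
        z = np.atleast_2d(z)
        if whiten is None:
            quad = (z * z) @ self._plot_onehot
        else:
            quad = np.zeros((z.shape[0], des.J))
            for rows, plots, Linv in whiten:
                U = np.einsum("kl,qls->qks", Linv, z[:, rows])
                np.add.at(quad.T, plots, np.einsum("qks,qks->sq", U, U))
        out = 0.5 * quad + const[None, :]
        return out if B_stack is not None else out[:1]

    def _marginal_nll_parts(self, theta, want_modes=False):
        """Marginal -loglik per plot; optionally also the conditional modes."""
        lay, des, spec = self.layout, self.design, self.spec
        beta, re_sds, sigma, deltas, corr = self._unpack_opt(theta)
        try:
            P0, sd, const, whiten = self._context(beta, sigma, deltas, corr)
        except np.linalg.LinAlgError:
            return None, None
        d = len(spec.random)
        if d == 0:
            val = self._cond_nll(P0, sd, const, whiten, None)
            return val, np.zeros((des.J, 0))

        log_prior_const = np.sum(np.log(re_sds)) + 0.5 * d * _LOG2PI
        inv_var = 1.0 / re_sds**2

        def gm(Bs):
            pen = 0.5 * np.einsum("qjk,k->qj", Bs * Bs, inv_var) + log_prior_const
            return self._cond_nll_multi(P0, sd, const, whiten, Bs) + pen

        warm = getattr(self, "_warm_modes", None)
        B0 = warm if warm is not None and warm.shape == (des.J, d) else None
        B, H, gB = self._find_modes(gm, re_sds, des.J, d, B0=B0)
        self._warm_modes = B.copy()
        if d <= 2:
            nll = self._agq(gm, B, gB, H, d)
        else:
            sign, logdet = np.linalg.slogdet(H)
            if np.any(sign <= 0):
                return None, None
            nll = gB + 0.5 * logdet - 0.5 * d * _LOG2PI
        return nll, (B if want_modes else None)

    def _find_modes(self, gm, re_sds, J, d, B0=None):
        """Vectorised per-plot Newton search for the conditional modes.
        Returns modes (J, d), finite-difference Hessians (J, d, d) and the
        objective at the modes (J,).  ``gm`` maps (Q, J, d) -> (Q, J)."""
        h = 1e-3 * np.maximum(re_sds, 1e-2)
        B = np.zeros((J, d)) if B0 is None else np.asarray(B0, dtype=float).copy()
        gB = gm(B[None])[0]
        cross = None  # off-diagonal curvature, refreshed only periodically
        for it in range(60):
            # one batched stencil evaluation: +/-h on each axis
            stencil = np.zeros((2 * d, J, d))
            for k in range(d):
                stencil[2 * k, :, k] = h[k]
                stencil[2 * k + 1, :, k] = -h[k]
            vals = gm(B[None] + stencil)
            grad = np.zeros((J, d))
            H = np.zeros((J, d, d))
            for k in range(d):
                gp, gmn = vals[2 * k], vals[2 * k + 1]
                grad[:, k] = (gp - gmn) / (2 * h[k])
                H[:, k, k] = (gp - 2 * gB + gmn) / h[k] ** 2
            if d > 1 and (cross is None or it % 5 == 0):
                pairs = [(k, l) for k in range(d) for l in range(k + 1, d)]
                stc = np.zeros((4 * len(pairs), J, d))
                for q, (k, l) in enumerate(pairs):
                    for r, (sk, sl) in enumerate(((1, 1), (1, -1), (-1, 1), (-1, -1))):
                        stc[4 * q + r, :, k] = sk * h[k]
                        stc[4 * q + r, :, l] = sl * h[l]
                cv = gm(B[None] + stc)
                cross = np.zeros((J, d, d))
                for q, (k, l) in enumerate(pairs):
                    Hkl = (cv[4 * q] - cv[4 * q + 1] - cv[4 * q + 2] + cv[4 * q + 3]) \
                        / (4 * h[k] * h[l])
                    cross[:, k, l] = cross[:, l, k] = Hkl
            if d > 1:
                H = H + cross
            # ensure positive-definite curvature before stepping
            ridge = np.maximum(0.0, 1e-8 - np.linalg.eigvalsh(H).min(axis=1))
            H[:, np.arange(d), np.arange(d)] += ridge[:, None]
            step = -np.linalg.solve(H, grad[..., None])[..., 0]
            # backtracking, accepted plot-wise
            scale = np.ones(J)
            for _ls in range(12):
                Bn = B + scale[:, None] * step
                gn = gm(Bn[None])[0]
                worse = gn > gB + 1e-12
                if not np.any(worse):
                    break
                scale[worse] *= 0.5
            accept = gn <= gB + 1e-12
            B = np.where(accept[:, None], Bn, B)
            gB = np.where(accept, gn, gB)
            if np.max(np.abs(step)) < 1e-9 * max(1.0, np.max(np.abs(B))):
                break
        return B, H, gB

    def _agq(self, gm, B, gB, H, d):
        """Adaptive Gauss-Hermite quadrature around the conditional modes,
        evaluated as one batched pass over all nodes."""
        J = B.shape[0]
        if d == 1:
            Hd = np.maximum(H[:, 0, 0], 1e-12)
            st = 1.0 / np.sqrt(Hd)
            Bq = B[None] + (np.sqrt(2.0) * st[None, :] * _GH_NODES[:, None])[..., None]
            logs = (np.log(_GH_WEIGHTS) + _GH_NODES**2)[:, None] - gm(Bq)
            return -(logsumexp(logs, axis=0) + 0.5 * np.log(2.0) + np.log(st))
        # d == 2: tensor-product nodes, scaled by H^{-1/2}
        evals, evecs = np.linalg.eigh(H)
        evals = np.maximum(evals, 1e-12)
        C = evecs * (evals[:, None, :] ** -0.5)  # (J, d, d): C = Q diag(l^-1/2)
        logdetC = -0.5 * np.sum(np.log(evals), axis=1)
        X = np.array([(x1, x2) for x1 in _GH_NODES for x2 in _GH_NODES])
        logW = np.add.outer(np.log(_GH_WEIGHTS), np.log(_GH_WEIGHTS)).ravel()
        Bq = B[None] + np.sqrt(2.0) * np.einsum("jkl,ql->qjk", C, X)
        logs = (logW + np.sum(X * X, axis=1))[:, None] - gm(Bq)
        return -(logsumexp(logs, axis=0) + np.log(2.0) + logdetC)

    def nloglik(self, theta) -> float:
        """Marginal negative log-likelihood at an optimizer-scale vector.

        For models without random effects the residual SD is profiled out,
        so ``theta`` omits ``sigma`` (see ``layout.opt_names``)."""
        if self.layout.profile_sigma:
            return self._profiled_from_unit(theta)
        parts, _ = self._marginal_nll_parts(theta)
        if parts is None or not np.all(np.isfinite(parts)):
            return _PENALTY
        return float(np.sum(parts))

    def _profiled_from_unit(self, theta) -> float:
        """Concentrated -loglik with sigma profiled out at its MLE:
        nll* = 0.5 [n log(2 pi Q/n) + n] + 0.5 logdet(C_unit), where Q is the
        quadratic form and C_unit the covariance shape at sigma = 1."""
        beta, _re, _s, deltas, corr = self._unpack_opt(theta)
        try:
            P0, sd, const, whiten = self._context(beta, 1.0, deltas, corr)
        except np.linalg.LinAlgError:
            return _PENALTY
        n = self.nobs
        parts = self._cond_nll(P0, sd, const, whiten, None)
        if not np.all(np.isfinite(parts)):
            return _PENALTY
        total = float(np.sum(parts))
        half_logdet = float(np.sum(const)) - 0.5 * n * _LOG2PI
        Q = 2.0 * (total - float(np.sum(const)))  # quadratic form at sigma=1
        if Q <= 0:
            Q = 1e-300
        return 0.5 * (n * _LOG2PI + n * np.log(Q / n) + n) + half_logdet

    def _profiled_sigma(self, theta) -> float:
        beta, _re, _s, deltas, corr = self._unpack_opt(theta)
        P0, sd, const, whiten = self._context(beta, 1.0, deltas, corr)
        parts = self._cond_nll(P0, sd, const, whiten, None)
        Q = 2.0 * (float(np.sum(parts)) - float(np.sum(const)))
        return float(np.sqrt(max(Q, 1e-300) / self.nobs))

    def nloglik_full(self, theta_full) -> float:
        """Marginal -loglik at a *full* transformed vector (sigma included
        even for models where fitting profiles it out)."""
        if not self.layout.profile_sigma:
            return self.nloglik(theta_full)
        theta_full = np.asarray(theta_full, dtype=float)
        lay = self.layout
        i = lay.n_beta + len(lay.re_names)
        log_sigma = theta_full[i]
        theta = np.delete(theta_full, i)
        beta, _re, _s, deltas, corr = self._unpack_opt(theta)
        try:
            P0, sd, const, whiten = self._context(beta, np.exp(log_sigma), deltas, corr)
        except np.linalg.LinAlgError:
            return _PENALTY
        parts = self._cond_nll(P0, sd, const, whiten, None)
        if not np.all(np.isfinite(parts)):
            return _PENALTY
        return float(np.sum(parts))

    def nloglik_natural(self, params: Dict[str, float]) -> float:
        """Marginal -loglik at named natural-scale parameters (full set)."""
        lay = self.layout
        missing = [nm for nm in lay.full_names if nm not in params]
        if missing:
            raise InvalidParameterError(f"missing parameters: {missing}")
        nat = np.array([params[nm] for nm in lay.full_names], dtype=float)
        th_full = lay.to_transformed(nat, lay.full_names)
        if not lay.profile_sigma:
            return self.nloglik(th_full)
        return self.nloglik_full(th_full)

    # -- starting values -------------------------------------------------
    def _start_values(self) -> np.ndarray:
        des, spec, lay = self.design, self.spec, self.layout
        df = self.data.table
        beta = np.zeros(lay.n_beta)

        def level_starts():
            out = {}
            for lt in des.leaf_levels:
                sub = df[df["leaf_type"] == lt]
                tt, yy = sub["day"].to_numpy(float), sub["lfmc"].to_numpy(float)
                if spec.mean == "logistic":
                    try:
                        out[lt] = self_start(tt, yy).as_dict()
                    except Exception:
                        out[lt] = None
                elif spec.mean == "linear":
                    b1, b0 = np.polyfit(tt, yy, 1)
                    out[lt] = {"b0": b0, "b1": b1}
                else:
                    out[lt] = {"b0": float(np.mean(yy))}
            good = [v for v in out.values() if v is not None]
            if not good:
                raise ConvergenceError("self-start failed for every leaf type")
            pooled = {p: float(np.mean([v[p] for v in good])) for p in good[0]}
            return {lt: (v if v is not None else pooled) for lt, v in out.items()}, pooled

        starts, pooled = level_starts()
        for p in MEAN_PARAMS[spec.mean]:
            sl = lay.beta_slices[p]
            names = des.coef_names[p]
            vals = np.zeros(len(names))
            if spec.coding(p) == "by_leaf_type":
                ref = starts[des.leaf_ref][p]
                vals[0] = ref
                for i, lt in enumerate(des.leaf_offsets, start=1):
                    vals[i] = starts[lt][p] - ref
            else:
                vals[0] = pooled[p]
            beta[sl] = vals

        # residual scale from the start-mean residuals
        P0 = {p: des.D[p] @ beta[lay.beta_slices[p]] for p in MEAN_PARAMS[spec.mean]}
        resid = des.y - _mean_value(spec.mean, des.t, P0)
        sig = float(np.std(resid))
        sig = max(sig, 1e-3)
        parts = [beta, np.log(np.full(len(lay.re_names), 0.5 * sig))]
        if not lay.profile_sigma:
            parts.append([np.log(sig)])
        if spec.varident:
            ref_sd = max(float(np.std(resid[des.row_leaf == 0])), 1e-3)
            d0 = []
            for i, lt in enumerate(des.leaf_offsets, start=1):
                s_lt = float(np.std(resid[des.row_leaf == i]))
                d0.append(np.log(np.clip(s_lt / ref_sd, 0.2, 5.0)) if s_lt > 0 else 0.0)
            parts.append(d0)
        parts.append(np.zeros(len(lay.corr_names)) + 0.05)
        return np.concatenate([np.atleast_1d(np.asarray(x, float)) for x in parts])

    # -- fitting -----------------------------------------------------------
    def fit(self, start=None, seed: int = 0, maxiter: int = 600,
            restarts: int = 5, raise_on_failure: bool = False) -> "LfmcResults":
        """Maximise the marginal likelihood (ML) and return an
        :class:`LfmcResults`.

        ``start`` may be a mapping of natural-scale parameter values by name
        (missing entries fall back to data-driven defaults).  Up to
        ``restarts`` jittered restarts (seeded) are attempted when the
        optimizer reports failure.
        """
        lay = self.layout
        theta0 = self._start_values()
        if start:
            for i, nm in enumerate(lay.opt_names):
                if nm in start:
                    theta0[i] = lay.to_transformed([start[nm]], [nm])[0]
        rng = np.random.default_rng(seed)
        # precondition: optimize on per-coordinate-rescaled variables so the
        # quasi-Newton iteration is not dominated by the largest coefficients
        scale = np.maximum(1.0, np.abs(theta0))
        bounds = [
            (None if lo is None else lo / s, None if hi is None else hi / s)
            for (lo, hi), s in zip(lay.bounds(lay.opt_names), scale)
        ]
        obj = lambda x: self.nloglik(x * scale)  # noqa: E731
        best = None
        converged = False
        theta_try = theta0.copy()
        for attempt in range(restarts + 1):
            res = minimize(obj, theta_try / scale, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": maxiter, "maxfun": 20 * maxiter,
                                    "ftol": 1e-9, "gtol": 1e-6, "eps": 1e-7})
            res.x = res.x * scale
            gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
            ok = bool(res.success) or gnorm < 0.5
            if best is None or res.fun < best[0].fun - 1e-9:
                best = (res, gnorm, ok)
            if ok and res.fun < _PENALTY / 2:
                converged = True
                if res.fun <= best[0].fun + 1e-9:
                    best = (res, gnorm, ok)
                break
            # jittered restart
            theta_try = theta0.copy()
            nb = lay.n_beta
            theta_try[:nb] *= 1.0 + 0.05 * rng.standard_normal(nb)
            theta_try[:nb] += 0.01 * rng.standard_normal(nb)
            theta_try[nb:] += 0.2 * rng.standard_normal(len(theta_try) - nb)
            logger.info("fit restart %d (prev fun=%.4f, gnorm=%.3g)", attempt + 1,
                        res.fun, gnorm)
        res, gnorm, ok = best
        if not self.has_re:
            polished = self._polish_no_re(res.x)
            f_pol = self.nloglik(polished)
            if f_pol <= res.fun + 1e-9:
                res.x, res.fun = polished, f_pol
                converged = True
        if not converged and raise_on_failure:
            raise ConvergenceError(
                f"optimizer failed after {restarts} restarts (gnorm={gnorm:.3g})",
                best_state=res,
            )
        return self._build_results(res, gnorm, converged, seed)

    def _whitened_residuals(self, theta) -> np.ndarray:
        """Whitened residual vector at unit sigma: L^{-1} (y - mu) / (ratio SD).
        Its sum of squares is the GLS quadratic form the profiled likelihood
        concentrates on (no-random-effects models only)."""
        beta, _re, _s, deltas, corr = self._unpack_opt(theta)
        P0, sd, const, whiten = self._context(beta, 1.0, deltas, corr)
        des = self.design
        mu = _mean_value(self.spec.mean, des.t, P0)
        z = (des.y - mu) / sd
        if whiten is not None:
            out = np.empty_like(z)
            for rows, plots, Linv in whiten:
                out[rows] = Linv @ z[rows]
            return out
        return z

    def _polish_no_re(self, theta, maxiter=200):
        """Alternate exact (whitened) nonlinear least squares for the fixed
        effects with a short variance/correlation refinement.  Sharpens the
        optimum far beyond what the generic quasi-Newton pass reaches,
        especially for near-interpolating data."""
        lay = self.layout
        nb = lay.n_beta
        theta = np.asarray(theta, dtype=float).copy()
        var_bounds = lay.bounds(lay.opt_names)[nb:]
        for _ in range(3):
            def resid(beta_):
                th = theta.copy()
                th[:nb] = beta_
                return self._whitened_residuals(th)

            sol = least_squares(resid, theta[:nb], method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                max_nfev=50 * nb)
            theta[:nb] = sol.x
            if nb == len(theta):
                break

            def f_var(tv):
                th = theta.copy()
                th[nb:] = tv
                return self.nloglik(th)

            res = minimize(f_var, theta[nb:], method="L-BFGS-B",
                           bounds=var_bounds,
                           options={"maxiter": maxiter, "ftol": 1e-12,
                                    "gtol": 1e-8, "eps": 1e-7})
            if not np.any(np.abs(res.x - theta[nb:]) > 1e-10):
                theta[nb:] = res.x
                break
            theta[nb:] = res.x
        return theta

    def _assemble_full_theta(self, theta_opt) -> np.ndarray:
        lay = self.layout
        if not lay.profile_sigma:
            return np.asarray(theta_opt, dtype=float).copy()
        i = lay.n_beta + len(lay.re_names)
        sigma = self._profiled_sigma(theta_opt)
        return np.insert(np.asarray(theta_opt, dtype=float), i, np.log(sigma))

    def _build_results(self, res, gnorm, converged, seed) -> "LfmcResults":
        lay = self.layout
        theta_full = self._assemble_full_theta(res.x)
        llf = -self.nloglik_full(theta_full)
        natural = lay.to_natural(theta_full, lay.full_names)
        params = pd.Series(natural, index=lay.full_names)

        # uncertainty: numerical Hessian of the full -loglik, delta method
        cov_nat = self._cov_params(theta_full)

        # conditional modes of the plot random effects
        if self.has_re:
            _, modes = self._marginal_nll_parts(res.x, want_modes=True)
            ranef = pd.DataFrame(modes, index=self.design.plot_keys,
                                 columns=list(self.spec.random))
        else:
            ranef = pd.DataFrame(index=self.design.plot_keys, columns=[])

        boundary = bool(any(params[nm] < 5e-3 for nm in lay.re_names))
        return LfmcResults(
            model=self, params=params, cov_params_=cov_nat, llf=float(llf),
            converged=converged, grad_norm=float(gnorm),
            random_effects=ranef, boundary=boundary, seed=seed,
            theta_full=theta_full,
        )

    def _cov_params(self, theta_full) -> pd.DataFrame:
        lay = self.layout
        k = lay.k
        f0 = self.nloglik_full(theta_full)
        h = 1e-4 * np.maximum(1.0, np.abs(theta_full))
        H = np.zeros((k, k))
        fp = np.zeros(k)
        fm = np.zeros(k)
        for i in range(k):
            e = np.zeros(k); e[i] = h[i]
            fp[i] = self.nloglik_full(theta_full + e)
            fm[i] = self.nloglik_full(theta_full - e)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for i in range(k):
            for j in range(i + 1, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                fpp = self.nloglik_full(theta_full + ei + ej)
                fmm = self.nloglik_full(theta_full - ei - ej)
                H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0
                                     + fmm - fm[i] - fm[j] + f0) / (2 * h[i] * h[j])
        try:
            cov_t = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov_t = np.linalg.pinv(H)
        Jd = lay.jacobian_diag(theta_full)
        cov_n = cov_t * np.outer(Jd, Jd)
        return pd.DataFrame(cov_n, index=lay.full_names, columns=lay.full_names)

    # -- resolution of curve parameters for arbitrary design rows ---------
    def _resolve_params(self, newdata: pd.DataFrame, params: pd.Series,
                        ranef: Optional[pd.DataFrame], level: str) -> Dict[str, np.ndarray]:
        des, spec, lay = self.design, self.spec, self.layout
        n = len(newdata)
        if "leaf_type" not in newdata.columns or "day" not in newdata.columns:
            raise LabelingError("newdata needs 'leaf_type' and 'day' columns")
        unknown = set(newdata["leaf_type"].astype(str)) - set(des.leaf_levels)
        if unknown:
            raise LabelingError(f"unknown leaf type(s) {sorted(unknown)}")
        P = {}
        for p in MEAN_PARAMS[spec.mean]:
            val = np.full(n, params[des.coef_names[p][0]], dtype=float)
            for nm in des.coef_names[p][1:]:
                if nm.startswith(f"{p}[plot:"):
                    pk = nm[len(f"{p}[plot:"):-1]
                    mask = (newdata.get("plot_key", newdata.get("plot", pd.Series([""] * n)))
                            .astype(str) == pk).to_numpy()
                else:
                    lt = nm[len(p) + 1:-1]
                    mask = (newdata["leaf_type"].astype(str) == lt).to_numpy()
                val = val + params[nm] * mask
            P[p] = val
        if level == "plot" and ranef is not None and len(spec.random):
            key = "plot_key" if "plot_key" in newdata.columns else "plot"
            if key not in newdata.columns:
                raise LabelingError("plot-level prediction needs a plot column")
            pks = newdata[key].astype(str)
            unknown = set(pks) - set(ranef.index)
            if unknown:
                raise LabelingError(f"unknown plot(s) {sorted(unknown)}")
            for p in spec.random:
                P[p] = P[p] + ranef.loc[pks, p].to_numpy(dtype=float)
        return P


@dataclass
class LfmcResults:
    """Fit results: estimates, uncertainty, criteria, predictions.

    Mirrors the statsmodels Results idiom: ``params`` (natural scale, named),
    ``bse``, ``conf_int()``, ``llf``/``aic``/``bic``, ``summary()``, plus
    plot-level random-effect conditional modes in ``random_effects``.
    """

    model: LfmcModel
    params: pd.Series
    cov_params_: pd.DataFrame
    llf: float
    converged: bool
    grad_norm: float
    random_effects: pd.DataFrame
    boundary: bool
    seed: int
    theta_full: np.ndarray = field(repr=False, default=None)

    # -- criteria ---------------------------------------------------------
    @property
    def k_params(self) -> int:
        return self.model.k_params

    @property
    def df_model(self) -> int:
        return self.k_params

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + np.log(self.nobs) * self.k_params

    # -- uncertainty ------------------------------------------------------
    def cov_params(self) -> pd.DataFrame:
        return self.cov_params_

    @property
    def bse(self) -> pd.Series:
        v = np.diag(self.cov_params_.to_numpy())
        return pd.Series(np.sqrt(np.maximum(v, 0.0)), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    # -- predictions ------------------------------------------------------
    def fittedvalues(self, level: str = "plot") -> np.ndarray:
        df = self.model.data.table
        return self.predict(df, level=level)

    def predict(self, newdata: pd.DataFrame, level: str = "population") -> np.ndarray:
        """Mean LFMC for design rows (leaf_type, day[, plot]).

        ``level="population"`` uses fixed effects only; ``level="plot"`` adds
        the plot's conditional-mode random effects."""
        if level not in ("population", "plot"):
            raise InvalidParameterError(f"unknown level {level!r}")
        P = self.model._resolve_params(
            newdata, self.params,
            self.random_effects if level == "plot" else None, level)
        t = pd.to_numeric(newdata["day"]).to_numpy(dtype=float)
        return _mean_value(self.model.spec.mean, t, P)

    def drying_speed(self, newdata: pd.DataFrame, level: str = "population") -> np.ndarray:
        """Instantaneous drying speed dLFMC/dt (%/day) from the analytic
        derivative of the logistic mean at the resolved parameters."""
        if self.model.spec.mean != "logistic":
            raise UnsupportedOperationError(
                "drying speed is defined only for the logistic mean"
            )
        P = self.model._resolve_params(
            newdata, self.params,
            self.random_effects if level == "plot" else None, level)
        t = pd.to_numeric(newdata["day"]).to_numpy(dtype=float)
        return _rate(t, P["A"], P["w"], P["m"], P["s"])

    def resolved_curve(self, leaf_type: str, plot: Optional[str] = None) -> LogisticParams:
        """The logistic parameters for one leaf type (optionally one plot)."""
        if self.model.spec.mean != "logistic":
            raise UnsupportedOperationError("curve parameters require the logistic mean")
        row = pd.DataFrame({"leaf_type": [leaf_type], "day": [0.0],
                            **({"plot_key": [plot]} if plot else {})})
        P = self.model._resolve_params(
            row, self.params, self.random_effects if plot else None,
            "plot" if plot else "population")
        return LogisticParams(A=float(P["A"][0]), w=float(P["w"][0]),
                              m=float(P["m"][0]), s=float(P["s"][0]))

    # -- reporting --------------------------------------------------------
    def coef_table(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame({
            "estimate": self.params, "se": self.bse,
            "ci_low": ci["lower"], "ci_high": ci["upper"],
        })

    def summary(self) -> str:
        spec = self.model.spec
        lines = []
        lines.append("LFMC nonlinear mixed-effects fit (ML)"
                     if spec.mean == "logistic" else f"LFMC {spec.mean}-mean fit (ML)")
        lines.append("=" * 64)
        lines.append(f"mean: {spec.mean}   random: {spec.random or '()'}   "
                     f"varIdent: {spec.varident}   ARMA: {spec.arma or 'none'}")
        lines.append(f"n obs: {self.nobs}   plots: {len(self.model.design.plot_keys)}   "
                     f"parameters: {self.k_params}")
        lines.append(f"logLik: {self.llf:.1f}   AIC: {self.aic:.1f}   BIC: {self.bic:.1f}")
        lines.append(f"converged: {self.converged}   |grad|: {self.grad_norm:.2g}"
                     + ("   [RE SD near boundary]" if self.boundary else ""))
        lines.append("-" * 64)
        tab = self.coef_table()
        lines.append(f"{'parameter':<14}{'estimate':>10}{'se':>9}{'95% CI':>22}")
        for nm, row in tab.iterrows():
            lines.append(f"{nm:<14}{row['estimate']:>10.3f}{row['se']:>9.3f}"
                         f"   [{row['ci_low']:>7.2f}, {row['ci_high']:>7.2f}]")
        if len(self.random_effects.columns):
            lines.append("-" * 64)
            lines.append("plot-level conditional modes:")
            for pk, row in self.random_effects.iterrows():
                vals = "  ".join(f"{p}={v:+.2f}" for p, v in row.items())
                lines.append(f"  {pk}: {vals}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "spec": {
                "mean": self.model.spec.mean,
                "fixed": dict(self.model.spec.fixed),
                "random": list(self.model.spec.random),
                "varident": self.model.spec.varident,
                "arma": list(self.model.spec.arma) if self.model.spec.arma else None,
                "label": self.model.spec.label,
            },
            "n": int(self.nobs),
            "k": int(self.k_params),
            "logLik": float(self.llf),
            "AIC": float(self.aic),
            "BIC": float(self.bic),
            "converged": bool(self.converged),
            "params": {k: float(v) for k, v in self.params.items()},
            "se": {k: float(v) for k, v in self.bse.items()},
            "random_effects": {
                str(pk): {p: float(v) for p, v in row.items()}
                for pk, row in self.random_effects.iterrows()
            },
        }
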