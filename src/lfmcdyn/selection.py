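"""Stepwise model selection and alternative-model comparison.

The fitting protocol follows the mixed-model practice of settling the random
structure before the fixed effects, gated throughout by an AIC improvement
of more than 2 (a richer model is kept only if its AIC is lower than the
simpler model's by > 2; ties and smaller gaps keep the simpler model):

1. with the full leaf-type fixed-effects map, decide which curve parameters
   carry a plot random effect (forward additions to a random-A base, then a
   pruning pass);
2. decide the within-plot covariance: leaf-type residual SDs (varIdent) and
   serial correlation (best ARMA order among (1,0), (0,1), (1,1));
3. decide, parameter by parameter, whether leaf-type fixed effects stay or
   collapse to a common coefficient.

The alternative-model suite ranks the selected nonlinear mixed-effects model
(M1) against a nonlinear fixed-effects model (M2), a linear mixed-effects
model (M3), a classical linear regression (M4) and a null model (M5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, studentized_range

from .data import LfmcDataset
from .exceptions import UnsupportedOperationError
from .model import MEAN_PARAMS, LfmcModel, LfmcResults, ModelSpec

__all__ = [
    "ProtocolConfig",
    "SelectionResult",
    "ComparisonTable",
    "select_model",
    "fit_alternatives",
    "leaf_type_contrasts",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProtocolConfig:
    """Settings of the stepwise protocol."""

    delta_aic: float = 2.0
    random_candidates: Tuple[str, ...] = ("A", "w", "m", "s")
    arma_orders: Tuple[Tuple[int, int], ...] = ((1, 0), (0, 1), (1, 1))
    try_varident: bool = True
    seed: int = 0


@dataclass
class ComparisonTable:
    """AIC ranking of fitted models (rows sorted by AIC ascending; the best
    model's delta-AIC is 0)."""

    frame: pd.DataFrame

    @classmethod
    def from_results(cls, results: List[LfmcResults]) -> "ComparisonTable":
        rows = [{
            "model": r.model.spec.label or f"model{i}",
            "k": r.k_params,
            "logLik": r.llf,
            "AIC": r.aic,
        } for i, r in enumerate(results)]
        df = pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)
        df["dAIC"] = df["AIC"] - df["AIC"].iloc[0]
        return cls(df)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover
        return self.frame.to_string(index=False)


@dataclass
class SelectionResult:
    spec: ModelSpec
    fit: LfmcResults
    log: List[dict] = field(default_factory=list)

    def decision_log(self) -> pd.DataFrame:
        return pd.DataFrame(self.log)


def _fit(data, spec, seed, cache, log, step, note) -> Optional[LfmcResults]:
    """Fit one candidate, memoised on the spec; failures are logged and the
    candidate is skipped."""
    key = spec.with_(label="")
    if key in cache:
        res = cache[key]
    else:
        try:
            res = LfmcModel(data, spec).fit(seed=seed)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("candidate fit failed (%s): %s", note, exc)
            log.append({"step": step, "note": f"{note}: fit failed ({exc})",
                        "k": None, "AIC": None})
            cache[key] = None
            return None
        cache[key] = res
    if res is not None:
        log.append({"step": step, "note": note, "k": res.k_params,
                    "AIC": res.aic, "logLik": res.llf,
                    "spec": _describe(spec)})
    return res


def _describe(spec: ModelSpec) -> str:
    fe = ",".join(f"{p}:{spec.coding(p)[0]}" for p in MEAN_PARAMS[spec.mean])
    return (f"mean={spec.mean} fixed[{fe}] random={list(spec.random)} "
            f"varIdent={spec.varident} arma={spec.arma}")


def _prefer_richer(rich: Optional[LfmcResults], simple: Optional[LfmcResults],
                   delta: float) -> bool:
    """delta-AIC gate: keep the richer model only if AIC_simple - AIC_rich > delta."""
    if rich is None:
        return False
    if simple is None:
        return True
    return (simple.aic - rich.aic) > delta


def select_model(data: LfmcDataset, config: ProtocolConfig = ProtocolConfig(),
                 ) -> SelectionResult:
    """Run the three-step protocol and return the final spec, its fit and a
    complete decision log (every AIC consulted appears as one logged fit)."""
    seed = config.seed
    cache: dict = {}
    log: List[dict] = []
    full_fixed = tuple((p, "by_leaf_type") for p in ("A", "w", "m", "s"))

    # ---- step 1: random structure (full fixed map, iid homoscedastic) ----
    base = ModelSpec(mean="logistic", fixed=full_fixed, random=("A",),
                     varident=False, arma=None)
    current = base
    cur_fit = _fit(data, current, seed, cache, log, 1, "base: random A")
    for p in config.random_candidates:
        if p in current.random:
            continue
        cand = current.with_(random=tuple([*current.random, p]))
        cand_fit = _fit(data, cand, seed, cache, log, 1, f"add random {p}")
        if _prefer_richer(cand_fit, cur_fit, config.delta_aic):
            current, cur_fit = cand, cand_fit
            log.append({"step": 1, "note": f"kept random {p}", "k": cand_fit.k_params,
                        "AIC": cand_fit.aic})
    # pruning pass (also challenges the base random-A term)
    for p in list(current.random):
        cand = current.with_(random=tuple(q for q in current.random if q != p))
        cand_fit = _fit(data, cand, seed, cache, log, 1, f"drop random {p}")
        if not _prefer_richer(cur_fit, cand_fit, config.delta_aic):
            current, cur_fit = cand, cand_fit
            log.append({"step": 1, "note": f"dropped random {p}",
                        "k": cand_fit.k_params, "AIC": cand_fit.aic})

    # ---- step 2: variance function and serial correlation ---------------
    if config.try_varident:
        cand = current.with_(varident=True)
        cand_fit = _fit(data, cand, seed, cache, log, 2, "add varIdent")
        if _prefer_richer(cand_fit, cur_fit, config.delta_aic):
            current, cur_fit = cand, cand_fit
            log.append({"step": 2, "note": "kept varIdent", "k": cand_fit.k_params,
                        "AIC": cand_fit.aic})
    best_arma, best_arma_fit = None, None
    for order in config.arma_orders:
        cand = current.with_(arma=order)
        cand_fit = _fit(data, cand, seed, cache, log, 2, f"try ARMA{order}")
        if cand_fit is not None and (best_arma_fit is None or cand_fit.aic < best_arma_fit.aic):
            best_arma, best_arma_fit = cand, cand_fit
    if _prefer_richer(best_arma_fit, cur_fit, config.delta_aic):
        current, cur_fit = best_arma, best_arma_fit
        log.append({"step": 2, "note": f"kept ARMA{current.arma}",
                    "k": cur_fit.k_params, "AIC": cur_fit.aic})

    # ---- step 2b: revisit the random structure under the selected
    # covariance (heteroscedasticity can mask a plot effect that lives in
    # the low-variance strata, and vice versa) ----------------------------
    if current.varident or current.arma is not None:
        for p in config.random_candidates:
            if p in current.random:
                continue
            cand = current.with_(random=tuple([*current.random, p]))
            cand_fit = _fit(data, cand, seed, cache, log, 2, f"re-check: add random {p}")
            if _prefer_richer(cand_fit, cur_fit, config.delta_aic):
                current, cur_fit = cand, cand_fit
                log.append({"step": 2, "note": f"kept random {p}",
                            "k": cand_fit.k_params, "AIC": cand_fit.aic})
        for p in list(current.random):
            cand = current.with_(random=tuple(q for q in current.random if q != p))
            cand_fit = _fit(data, cand, seed, cache, log, 2, f"re-check: drop random {p}")
            if not _prefer_richer(cur_fit, cand_fit, config.delta_aic):
                current, cur_fit = cand, cand_fit
                log.append({"step": 2, "note": f"dropped random {p}",
                            "k": cand_fit.k_params, "AIC": cand_fit.aic})

    # ---- step 3: fixed effects, parameter by parameter -------------------
    for p in ("A", "w", "m", "s"):
        if current.coding(p) != "by_leaf_type":
            continue
        fixed = dict(current.fixed)
        fixed[p] = "common"
        cand = current.with_(fixed=tuple(sorted(fixed.items())))
        cand_fit = _fit(data, cand, seed, cache, log, 3, f"common {p}")
        if not _prefer_richer(cur_fit, cand_fit, config.delta_aic):
            current, cur_fit = cand, cand_fit
            log.append({"step": 3, "note": f"collapsed {p} to common",
                        "k": cand_fit.k_params, "AIC": cand_fit.aic})

    current = current.with_(label="M1")
    final_fit = _fit(data, current, seed, cache, log, 3, "final model")
    return SelectionResult(spec=current, fit=final_fit, log=log)


# ---------------------------------------------------------------------------
# alternative models
# ---------------------------------------------------------------------------


def _m2_spec() -> ModelSpec:
    """Nonlinear fixed-effects: full leaf-type logistic plus fixed plot
    offsets on both asymptotes; iid homoscedastic errors."""
    return ModelSpec(mean="logistic",
                     fixed=tuple((p, "by_leaf_type") for p in ("A", "w", "m", "s")),
                     random=(), varident=False, arma=None,
                     plot_fixed=("A", "w"), label="M2")


def _m3_spec(arma=(1, 1)) -> ModelSpec:
    """Linear mixed-effects: day x leaf type, plot random intercept,
    varIdent and ARMA serial correlation."""
    return ModelSpec(mean="linear",
                     fixed=(("b0", "by_leaf_type"), ("b1", "by_leaf_type")),
                     random=("b0",), varident=True, arma=arma, label="M3")


def _m4_spec() -> ModelSpec:
    """Classical regression: day x leaf type plus fixed plot offsets,
    iid homoscedastic errors."""
    return ModelSpec(mean="linear",
                     fixed=(("b0", "by_leaf_type"), ("b1", "by_leaf_type")),
                     random=(), varident=False, arma=None,
                     plot_fixed=("b0", "b1"), label="M4")


def _m5_spec() -> ModelSpec:
    """Null model: grand mean and a single residual variance."""
    return ModelSpec(mean="constant", fixed=(("b0", "common"),), random=(),
                     varident=False, arma=None, label="M5")


def _simplify_m3(data, seed, delta_aic, log, cache) -> Optional[LfmcResults]:
    """Apply the same delta-AIC gate to M3's variance/correlation pieces:
    the best ARMA order must beat the serially-independent fit by > delta,
    and varIdent must earn its keep the same way."""
    base_spec = _m3_spec(None)
    base = _fit(data, base_spec, seed, cache, log, "M3", "M3 without ARMA")
    best_spec, best = base_spec, base
    best_arma_spec, best_arma = None, None
    for arma in ((1, 0), (0, 1), (1, 1)):
        spec = _m3_spec(arma)
        fit = _fit(data, spec, seed, cache, log, "M3", f"M3 ARMA{arma}")
        if fit is not None and (best_arma is None or fit.aic < best_arma.aic):
            best_arma_spec, best_arma = spec, fit
    if _prefer_richer(best_arma, best, delta_aic):
        best_spec, best = best_arma_spec, best_arma
    if best is not None:
        cand = best_spec.with_(varident=False)
        cand_fit = _fit(data, cand, seed, cache, log, "M3", "M3 without varIdent")
        if not _prefer_richer(best, cand_fit, delta_aic):
            best_spec, best = cand, cand_fit
    return best


def fit_alternatives(data: LfmcDataset, config: ProtocolConfig = ProtocolConfig(),
                     m1: Optional[LfmcResults] = None,
                     ) -> Tuple[ComparisonTable, List[LfmcResults]]:
    """Fit the five-model suite and return its AIC comparison table.

    ``m1`` may carry an already-selected nonlinear mixed-effects fit
    (otherwise :func:`select_model` runs first).
    """
    seed = config.seed
    cache: dict = {}
    log: List[dict] = []
    if m1 is None:
        m1 = select_model(data, config).fit
    m1.model.spec = m1.model.spec.with_(label="M1")
    results = [m1]
    m2 = _fit(data, _m2_spec(), seed, cache, log, "M2", "nonlinear fixed-effects")
    m3 = _simplify_m3(data, seed, config.delta_aic, log, cache)
    m4 = _fit(data, _m4_spec(), seed, cache, log, "M4", "classical regression")
    m5 = _fit(data, _m5_spec(), seed, cache, log, "M5", "null model")
    for r, lab in ((m2, "M2"), (m3, "M3"), (m4, "M4"), (m5, "M5")):
        if r is not None:
            r.model.spec = r.model.spec.with_(label=lab)
            results.append(r)
    return ComparisonTable.from_results(results), results


def null_model_aic(data: LfmcDataset) -> float:
    """Closed-form AIC of the null model: with the Gaussian MLE variance
    sigma^2 = mean((y - ybar)^2), AIC = n (log(2 pi sigma^2) + 1) + 4."""
    y = data.table["lfmc"].to_numpy(dtype=float)
    n = y.size
    s2 = float(np.mean((y - y.mean()) ** 2))
    return n * (np.log(2.0 * np.pi * s2) + 1.0) + 4.0


# ---------------------------------------------------------------------------
# leaf-type contrasts
# ---------------------------------------------------------------------------


def leaf_type_contrasts(fit: LfmcResults, parameter: str = "A",
                        adjust: str = "none") -> pd.DataFrame:
    """All pairwise leaf-type differences of one curve parameter.

    Estimates and delta-method SEs come from the fixed-effect coefficients
    and their covariance (the parameter's value at level L is the reference
    coefficient plus L's offset).  ``adjust="tukey"`` applies a single-step
    studentized-range adjustment to the p-values.
    """
    spec = fit.model.spec
    if spec.coding(parameter) != "by_leaf_type":
        raise UnsupportedOperationError(
            f"parameter {parameter!r} was fitted as common to all leaf types"
        )
    des = fit.model.design
    names = {des.leaf_ref: None}
    for lt in des.leaf_offsets:
        names[lt] = f"{parameter}[{lt}]"
    levels = list(names)
    cov = fit.cov_params_
    rows = []
    k = len(levels)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[j], levels[i]  # difference a - b, later minus earlier
            vec = {}
            if names[a] is not None:
                vec[names[a]] = 1.0
            if names[b] is not None:
                vec[names[b]] = vec.get(names[b], 0.0) - 1.0
            est = sum(c * fit.params[nm] for nm, c in vec.items())
            var = 0.0
            for n1, c1 in vec.items():
                for n2, c2 in vec.items():
                    var += c1 * c2 * cov.loc[n1, n2]
            se = float(np.sqrt(max(var, 0.0)))
            z = est / se if se > 0 else 0.0
            if adjust == "tukey":
                p = float(studentized_range.sf(abs(z) * np.sqrt(2.0), k, 10_000))
            else:
                p = float(2.0 * norm.sf(abs(z)))
            rows.append({"parameter": parameter, "contrast": f"{a} - {b}",
                         "estimate": float(est), "se": se,
                         "ci_low": float(est - 1.96 * se),
                         "ci_high": float(est + 1.96 * se),
                         "z": float(z), "p": p})
    return pd.DataFrame(rows)
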