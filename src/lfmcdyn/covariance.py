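"""Within-group residual covariance building blocks.

Two structures are composed multiplicatively into the within-plot residual
covariance: a *varIdent* variance function giving each leaf-type stratum its
own residual standard deviation (a reference SD ``sigma_base`` times a
per-stratum ratio ``delta``, with the reference stratum fixed at ratio 1),
and a stationary ARMA(u, v) correlation along each within-plot measurement
series.  The assembled block is ``diag(sd) @ corr @ diag(sd)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy.linalg import toeplitz

from .exceptions import (
    InvalidParameterError,
    LabelingError,
    NonStationaryError,
    UnsupportedOrderError,
)

__all__ = [
    "VarIdentSpec",
    "ARMASpec",
    "varident_sd",
    "arma_acf",
    "arma_correlation",
    "correlation_at_positions",
    "assemble_group_covariance",
    "SUPPORTED_ARMA_ORDERS",
]

SUPPORTED_ARMA_ORDERS = ((0, 0), (1, 0), (0, 1), (1, 1))


@dataclass
class VarIdentSpec:
    """Per-stratum residual SD: ``sd(stratum) = sigma_base * delta[stratum]``.

    The reference stratum (grasses at the west site, ``GW``, by default) has
    ratio 1 and gets ``sigma_base`` exactly.
    """

    sigma_base: float = 1.0
    delta: Dict[str, float] = field(default_factory=dict)
    stratum: str = "leaf_type"
    reference: str = "GW"

    def __post_init__(self):
        if not np.isfinite(self.sigma_base) or self.sigma_base <= 0:
            raise InvalidParameterError(f"sigma_base must be > 0, got {self.sigma_base}")
        for lab, d in self.delta.items():
            if not np.isfinite(d) or d <= 0:
                raise InvalidParameterError(f"delta[{lab}] must be > 0, got {d}")
        if self.reference in self.delta and self.delta[self.reference] != 1.0:
            raise InvalidParameterError("reference stratum ratio must be 1")

    def ratio(self, label: str) -> float:
        if label == self.reference:
            return 1.0
        try:
            return float(self.delta[label])
        except KeyError:
            raise LabelingError(
                f"stratum {label!r} has no variance ratio (known: "
                f"{[self.reference, *self.delta]})"
            ) from None


def varident_sd(spec: VarIdentSpec, strata: Sequence[str]) -> np.ndarray:
    """Elementwise residual SD for a vector of stratum labels."""
    return np.array([spec.sigma_base * spec.ratio(str(s)) for s in strata], dtype=float)


@dataclass
class ARMASpec:
    """Stationary ARMA(u, v) serial correlation along a measurement series.

    A *series* is the ordered sequence of residuals sharing the grouping
    columns (default: plot x leaf type x within-date replicate rank),
    positioned by the integer rank of the sampling date.  Supported orders
    are (0,0), (1,0), (0,1) and (1,1); order (0,0) is white noise.
    """

    order: Tuple[int, int] = (0, 0)
    rho: float = 0.0
    theta: float = 0.0
    groups: Tuple[str, ...] = ("plot", "leaf_type", "rep")
    order_col: str = "date_rank"

    def __post_init__(self):
        self.order = (int(self.order[0]), int(self.order[1]))
        if self.order not in SUPPORTED_ARMA_ORDERS:
            raise UnsupportedOrderError(
                f"ARMA order {self.order} unsupported; choose one of {SUPPORTED_ARMA_ORDERS}"
            )
        u, v = self.order
        rho = float(self.rho) if u else 0.0
        theta = float(self.theta) if v else 0.0
        if u and not abs(rho) < 1:
            raise NonStationaryError(f"|rho| must be < 1, got {rho}")
        if v and not abs(theta) < 1:
            raise NonStationaryError(f"|theta| must be < 1, got {theta}")
        self.rho, self.theta = rho, theta


def arma_acf(spec: ARMASpec, lags) -> np.ndarray:
    """Stationary autocorrelation at integer ``lags`` (closed form).

    ARMA(1,1): acf(1) = (1 + rho*theta)(rho + theta) / (1 + theta^2 + 2 rho theta)
    and acf(k) = rho^(k-1) * acf(1) for k >= 1.  AR(1) (theta = 0) reduces to
    rho^k, MA(1) (rho = 0) to theta/(1 + theta^2) at lag 1 and 0 beyond.
    """
    lags = np.asarray(lags, dtype=int)
    rho, theta = spec.rho, spec.theta
    out = np.zeros(lags.shape, dtype=float)
    out[lags == 0] = 1.0
    pos = lags > 0
    if np.any(pos):
        if rho == 0.0 and theta == 0.0:
            r1 = 0.0
        else:
            r1 = (1.0 + rho * theta) * (rho + theta) / (1.0 + theta**2 + 2.0 * rho * theta)
        k = lags[pos]
        with np.errstate(divide="ignore", invalid="ignore"):
            out[pos] = np.where(k == 1, r1, r1 * rho ** (k - 1.0))
    return out


def arma_correlation(spec: ARMASpec, n: int) -> np.ndarray:
    """n x n Toeplitz correlation matrix for consecutive series positions."""
    n = int(n)
    if n < 1:
        raise InvalidParameterError("series length must be >= 1")
    col = arma_acf(spec, np.arange(n))
    return toeplitz(col)


def correlation_at_positions(spec: ARMASpec, positions: Sequence[int]) -> np.ndarray:
    """Correlation matrix for (possibly gapped) integer series positions."""
    p = np.asarray(positions, dtype=int)
    return arma_acf(spec, np.abs(p[:, None] - p[None, :]))


def assemble_group_covariance(sds, corr) -> np.ndarray:
    """Within-group covariance ``diag(sds) @ corr @ diag(sds)``."""
    sds = np.asarray(sds, dtype=float).ravel()
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (sds.size, sds.size):
        raise ValueError(f"shape mismatch: {sds.size} SDs vs corr {corr.shape}")
    if np.any(sds <= 0):
        raise InvalidParameterError("all SDs must be positive")
    return corr * np.outer(sds, sds)
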