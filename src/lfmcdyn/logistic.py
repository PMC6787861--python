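"""Four-parameter declining logistic curve for seasonal fuel-moisture drying.

The mean response over the fire season is modelled as

    y(t) = w + (A - w) / (1 + exp((m - t) / s))

where ``A`` and ``w`` are the upper and lower horizontal asymptotes (live fuel
moisture content, LFMC, in percent of dry weight at the start and the
stabilised end of the season), ``m`` is the inflection time (days since the
first measurement, the day of fastest drying) and ``s`` is a steepness scale
in days, negative for a declining curve.  The analytic first derivative of
``y`` with respect to ``t`` is the instantaneous drying speed in %/day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateDataError, InsufficientDataError, InvalidParameterError

__all__ = ["LogisticParams", "evaluate_logistic", "logistic_rate", "self_start"]


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the four-parameter logistic drying curve.

    Attributes
    ----------
    A : float
        Upper asymptote (maximum LFMC, %).
    w : float
        Lower asymptote (stabilised minimum LFMC, %).
    m : float
        Inflection time in days since the first measurement; at ``t = m``
        the curve passes exactly through ``(A + w) / 2``.
    s : float
        Steepness scale (days).  Negative for a declining curve.
    """

    A: float
    w: float
    m: float
    s: float

    def __post_init__(self):
        vals = (self.A, self.w, self.m, self.s)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite logistic parameters: {vals}")
        if self.s == 0:
            raise InvalidParameterError("steepness scale s must be nonzero")

    def as_dict(self) -> dict:
        return {"A": self.A, "w": self.w, "m": self.m, "s": self.s}

    @classmethod
    def from_dict(cls, d) -> "LogisticParams":
        return cls(A=float(d["A"]), w=float(d["w"]), m=float(d["m"]), s=float(d["s"]))


def _curve(t, A, w, m, s):
    """Vectorised logistic mean; overflow-safe for extreme ``(m - t)/s``."""
    z = (m - t) / s
    # exp overflow is harmless here: 1/(1+inf) -> 0; silence the warning.
    with np.errstate(over="ignore"):
        return w + (A - w) / (1.0 + np.exp(z))


def _rate(t, A, w, m, s):
    """Analytic d/dt of the logistic mean (drying speed).

    dy/dt = (A - w) * E / (s * (1 + E)^2),  E = exp((m - t)/s).

    E/(1+E)^2 is even in log E, so it is evaluated with exp(-|z|): exact
    symmetry about t = m, no overflow, and no cancellation in either tail.
    """
    z = (m - t) / s
    a = np.exp(-np.abs(z))
    return (A - w) * a / ((1.0 + a) ** 2 * s)


def _check_params(params: LogisticParams) -> LogisticParams:
    if not isinstance(params, LogisticParams):
        params = LogisticParams(**params) if isinstance(params, dict) else LogisticParams(*params)
    return params


def evaluate_logistic(params: LogisticParams, t):
    """Evaluate the logistic drying curve at time(s) ``t`` (days).

    Parameters
    ----------
    params : LogisticParams
    t : float or array_like
        Days since the first measurement.

    Returns
    -------
    float or ndarray
        LFMC in percent; shape follows ``t``.
    """
    params = _check_params(params)
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InvalidParameterError("t must be finite")
    out = _curve(t, params.A, params.w, params.m, params.s)
    return out if out.ndim else float(out)


def logistic_rate(params: LogisticParams, t):
    """Instantaneous drying speed dLFMC/dt (%/day) at time(s) ``t``.

    Negative everywhere for a declining curve (``A > w``, ``s < 0``), with
    its largest magnitude ``(A - w)/(4 s)`` at the inflection ``t = m``.
    """
    params = _check_params(params)
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InvalidParameterError("t must be finite")
    out = _rate(t, params.A, params.w, params.m, params.s)
    return out if out.ndim else float(out)


def self_start(t, y) -> LogisticParams:
    """Data-driven initial values for fitting the four-parameter logistic.

    Procedure: take the upper asymptote start ``A0`` from the mean of the
    largest responses and ``w0`` from the mean of the smallest, expand both
    outward by ``eps = 0.05 * range(y)`` so every observation lies strictly
    inside ``(w0, A0)``, then regress the empirical logit
    ``z = log((A0 - y)/(y - w0))`` on ``t``.  Under the logistic model
    ``z = (m - t)/s``, so ``slope = -1/s`` and ``intercept = m/s``.  The sign
    of the returned ``s0`` therefore follows the empirical trend direction
    (declining data give ``s0 < 0``).

    Raises
    ------
    InsufficientDataError
        Fewer than 5 points or fewer than 3 distinct times.
    DegenerateDataError
        Essentially constant response.
    """
    t = np.asarray(t, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if t.size != y.size:
        raise InsufficientDataError("t and y must have equal length")
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < 5 or np.unique(t).size < 3:
        raise InsufficientDataError(
            f"self_start needs >= 5 points with >= 3 distinct times, got {t.size}"
        )
    rng_y = float(np.ptp(y))
    if rng_y <= 1e-12 * max(1.0, abs(float(np.mean(y)))):
        raise DegenerateDataError("constant response: logistic start undefined")

    k = max(1, int(round(0.1 * y.size)))
    ys = np.sort(y)
    eps = 0.05 * rng_y
    # expand outward from the extreme-group means, but guarantee every y
    # lies strictly inside (w0, A0) so the logit below is defined
    w0 = min(float(np.mean(ys[:k])) - eps, float(ys[0]) - 0.01 * rng_y)
    A0 = max(float(np.mean(ys[-k:])) + eps, float(ys[-1]) + 0.01 * rng_y)

    z = np.log((A0 - y) / (y - w0))
    slope, intercept = np.polyfit(t, z, 1)
    if abs(slope) < 1e-12:
        # logit essentially flat in t: fall back to a quarter-range scale
        # signed by the raw trend of y on t.
        trend = np.polyfit(t, y, 1)[0]
        s0 = -float(np.ptp(t)) / 4.0 if trend < 0 else float(np.ptp(t)) / 4.0
        m0 = float(np.median(t))
    else:
        s0 = -1.0 / float(slope)
        m0 = float(intercept) * s0
    return LogisticParams(A=A0, w=w0, m=m0, s=s0)
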