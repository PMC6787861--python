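# Methods

`lfmcdyn` models the seasonal drying of live fuel moisture content (LFMC,
percent of dry weight) across a two-site field design in a semiarid,
fire-prone steppe: a wetter grass steppe (site W) and a drier grass–shrub
steppe (site E), with four *leaf types* — grasses at W (GW), grasses at E
(GE) and the shrubs *Mulinum spinosum* (SM) and *Senecio filaginoides* (SS).

## The model

The mean over the fire season is a four-parameter declining logistic in
time `t` (days since the first sampling date):

    mu(t) = w + (A - w) / (1 + exp((m - t) / s))

* `A` — upper asymptote: LFMC at the start of the fire season (%).
* `w` — lower asymptote: the stabilised end-of-season minimum (%).
* `m` — inflection time (days): the day of fastest drying; `mu(m) = (A+w)/2`.
* `s` — steepness scale (days), negative for a declining curve.

The drying speed is the analytic derivative
`d mu/dt = (A - w) p (1 - p) / s` with `p = 1/(1 + exp((m - t)/s))`, maximal
in magnitude at `t = m` where it equals `(A - w)/(4s)`.

The statistical model layers, on top of this mean:

* **leaf-type fixed effects** — each curve parameter is either common or
  resolves as a GW reference coefficient plus 0/1-coded offsets for GE, SM
  and SS;
* **plot random effects** — independent mean-zero normal plot deviations on
  a chosen subset of the curve parameters (plots are the spatial clusters of
  the design; the selected model carries one, on `A`);
* **varIdent residual variance** — each leaf type has its own residual SD,
  a reference SD `sigma` (stratum GW) times ratios `delta(GE)`, `delta(SM)`,
  `delta(SS)`;
* **ARMA serial correlation (optional)** — residuals within a measurement
  series follow a stationary ARMA(u, v) correlation, with orders (1,0),
  (0,1) and (1,1) supported and closed-form autocorrelation functions
  (ARMA(1,1): `acf(1) = (1 + rho·theta)(rho + theta) / (1 + theta² +
  2 rho·theta)`, `acf(k) = rho^(k-1) acf(1)`).

**Series definition.** Serial correlation needs a well-defined series, but a
plot holds three replicate points per leaf type and date, so replicates
cannot share one serial position. A series is therefore plot × leaf type ×
replicate rank (rank 1–3 by point order within each date), ordered by the
integer rank of the sampling date; lags are date-rank differences, so lost
observations leave gaps rather than shifting positions. This is
configurable through `ARMASpec.groups`/`order_col`.

## Estimation

Parameters are estimated by exact maximum likelihood (ML, not REML — the
selection protocol compares models differing in fixed effects, which
requires ML). Plot random effects are integrated out by **adaptive
Gauss–Hermite quadrature** with 7 nodes per dimension for one or two
random-effect dimensions: per likelihood evaluation, each plot's conditional
mode is found by a vectorised Newton search (finite-difference curvature,
warm-started between evaluations) and nodes are recentred and rescaled by
the mode's Hessian. Three or four dimensions fall back to a Laplace
approximation (the protocol only probes such models transiently). Because
the random effects enter the logistic mean *linearly* when they sit on `A`
or `w`, the quadrature is exact there; the test suite verifies agreement
with the closed-form Gaussian marginal likelihood to 1e-6 and with R's
`nlme::gls`/`nlme::lme` exact-ML likelihoods to ~1e-4.

The outer optimisation is L-BFGS-B on transformed parameters (log for SDs
and variance ratios, atanh for ARMA coefficients so stationarity is
automatic), with per-coordinate rescaling of the start vector for
conditioning, up to 5 seeded, jittered restarts, and a floor of exp(-6) on
random-effect SDs (indistinguishable from zero against residual SDs of
order 1–20; flagged as `boundary`). For models **without** random effects
the residual SD is profiled out analytically (GLS concentration) and the
fixed effects are polished by exact whitened nonlinear least squares —
without this, near-interpolating data (the zero-noise identifiability check)
cannot reach 1e-6 relative recovery. Standard errors come from the inverse
finite-difference Hessian of the full negative log-likelihood with a
delta-method map back to natural scale; intervals are Wald (estimate ±
1.96 SE). Conditional modes of the plot effects are reported as the
plot-level predictions; `predict(level="plot")` adds them to the fixed
curve, `predict(level="population")` does not.

Starting values come from a self-start routine: asymptote guesses from the
means of the extreme deciles, expanded by 5% of the range so every
observation lies strictly inside `(w0, A0)`, then a linear regression of the
empirical logit `log((A0 - y)/(y - w0))` on `t` gives `m0` and `s0` (the
sign of `s0` follows the trend direction).

## Model selection

The stepwise protocol settles the stochastic structure before the fixed
effects, gated by ΔAIC > 2 (a richer model is kept only if its AIC is lower
by more than 2; ties keep the simpler model):

1. with all four curve parameters leaf-type-coded, plot random effects are
   chosen by forward addition to a random-`A` base, then pruned;
2. varIdent and the best ARMA order (of (1,0), (0,1), (1,1)) are gated in;
   the random structure is then **re-checked** under the selected
   covariance — heteroscedasticity can completely mask a plot effect that
   lives in the low-variance grass strata (on synthetic data at the default
   truth, the random effect on `A` is invisible under homoscedasticity,
   AIC gap −2.0, but strongly supported once varIdent is in place, gap
   +15.8), and this re-check is what lets the protocol recover the
   generating structure;
3. each curve parameter's leaf-type coding is tested against a common
   coefficient.

Every comparison is logged with its AIC so any decision can be traced to a
fitted candidate.

The alternative-model suite ranks the selected nonlinear mixed model (M1)
against: M2, the nonlinear fixed-effects model (16 leaf-type logistic
coefficients plus fixed plot offsets on both asymptotes; 27 parameters);
M3, a linear mixed model (day × leaf type, plot random intercept, varIdent,
ARMA gated by the same rule — with ARMA(1,1) it has 15 parameters); M4,
classical linear regression with plot offsets (19 parameters); and M5, the
null model (grand mean + one variance, 2 parameters, with the closed-form
Gaussian-MLE identity `AIC = n(log(2π σ̂²) + 1) + 4`). On synthetic data at
the default truth the ranking comes out M1 < M3 < M2 < M4 < M5, and M3
absorbs the unmodelled nonlinearity into serial correlation — exactly the
behaviour expected when a linear mean confronts a sigmoidal season.

Leaf-type contrasts of `A` or `w` are Wald contrasts of the offset
coefficients with delta-method SEs from the estimate covariance; a
single-step studentized-range (Tukey-style) p-value adjustment is available
behind a flag, unadjusted being the default.

## Synthetic data

The generator reproduces the field design: 2 sites × 3 plots × 7 sampling
dates × 3 points per plot/date/leaf type, GW only at W and GE/SM/SS only at
E — 252 design cells, with 5 observations lost uniformly at random by
default (n = 247). The seven default dates are the integers spreading
[0, 89] as evenly as possible (0, 15, 30, 44, 59, 74, 89); the source
design describes roughly 80 days of sampling across a 13 Nov–10 Feb window
(an 89-day span), and the generator takes the span as configurable rather
than resolving that discrepancy. Default truth values are the fitted
estimates for this design: GW curve (A 54.3, w 29.1, m 30.9, s −16.1),
offsets A +30.9/+223.4/+240.3 and w −20.7/+31.7/+26.7 for GE/SM/SS, plot SD
on A 9.4, residual SD 7.1 with ratios 0.9/3.2/3.0, no serial correlation.
Responses follow the exact Gaussian generative law — tails may dip slightly
below zero in the driest stratum (GE's late-season mean of ~8% with SD
~6.4%), and the generator deliberately does not truncate them, so
simulated datasets are constructed with the non-negativity check relaxed.
ARMA noise, when requested, is drawn through the Cholesky factor of the
series correlation; an independent recursive simulator (`simulate_arma`)
backs the Monte-Carlo autocorrelation checks.

What the generator does **not** emulate: weather-driven year-to-year
variation, within-season rainfall pulses, measurement rounding, or any
spatial correlation beyond the plot hierarchy. Passing tests therefore show
that the machinery is correct under the design and the fitted generative
law, not that the model is adequate for any particular new field dataset.

## Diagnostics

Residuals are computed at plot level (conditional on the random-effect
modes; population level behind a flag) in three flavours: raw (%), Pearson
(raw / modelled per-observation SD) and normalized (Pearson pre-multiplied
by the inverse Cholesky factor of the modelled series correlation; equal to
Pearson under independence). Summaries: per-stratum Pearson SDs, per-series
lag-1..3 autocorrelations (reported missing for series that are too short;
note the short-series demeaned ACF is biased, so the whitening calibration
test uses a pooled non-demeaned estimator), normal Q-Q quantile pairs and a
location-scale trend statistic (correlation of |residual| with fitted
value). An approximate intraclass correlation is reported descriptively by
simulating 10^4 same-plot observation pairs under the fitted model (shared
random effects, independent residuals, fixed-effect mean partialled out) —
the nonlinear model admits no single closed-form value. Plotting
(`lfmcdyn.plots`) arranges these computed quantities on axes and carries no
logic of its own.

## Experiment sizes and numerical choices

Default experiment sizes, chosen as this package's standard configurations:
the simulate-and-refit recovery experiment and the residual-calibration
check share one 50-replicate run at full design scale (pooling the 95%
Wald coverage over the ten fixed-effect coefficients, i.e. 500 intervals);
Monte-Carlo ACF checks use a single 10^6-length series; the acceptance
script's recovery run uses 30 replicates. Optimizer tolerances: L-BFGS-B
ftol 1e-9 / gtol 1e-6 with finite-difference step 1e-7 on rescaled
coordinates; inner Newton step tolerance 1e-9; whitened-least-squares
polish tolerances 1e-14. Ties in AIC keep the simpler model by
construction of the strict ΔAIC > 2 gate.

## Known limitations

* Exact ML differs from the linearized (Lindstrom–Bates) likelihood used by
  classical NLME software; variance components can differ in the last digit
  between the two, which is why cross-checks against `nlme::nlme` are loose
  while those against `gls`/`lme` (exact ML) are tight.
* Random-effect covariances are diagonal by design; correlated random
  effects and nesting deeper than plot are out of scope, as are REML,
  non-Gaussian responses, spatial semivariogram correlation and
  power-of-mean variance functions.
* ARMA orders above (1,1) are rejected; the ARMA(1,1) likelihood surface
  has the usual near-cancellation ridge (rho ≈ −theta), which the ΔAIC gate
  handles but which can slow those candidate fits.
* Two independently terminated optimizer runs agree only to termination
  precision (~1e-3 relative on weakly identified coefficients), although
  the likelihood itself is permutation- and relabelling-invariant to
  floating-point reassociation.
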