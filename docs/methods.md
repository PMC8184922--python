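# Methods

## The model

`rsrfit` fits nonlinear spawner-recruitment (SR) curves to time series
of spawning biomass `S_t` and recruitment `R_t` under a lognormal
process-error model whose residuals are simultaneously autocorrelated
and outlier-contaminated. Log-recruitment is

    r_t = f(S_t | a, b) + eps_t,

with `f` the log of a hockey-stick `a*min(S,b)`, Beverton-Holt
`a*S/(1+S/b)`, or Ricker `a*S*exp(-S/b)` curve. The residual follows a
*scaled* AR(1) law: with per-year weights

    lam_t = exp(-phi * eps_t^2),

the residual is conditionally Gaussian,

    eps_t | eps_{t-1}  ~  N( rho * sqrt(lam_{t-1}) * eps_{t-1},  sigma^2 / lam_t ),

and the first year uses the stationary solution, mean zero and
variance `sigma^2 / (lam_1 * (1 - rho^2 * lam_bar))` with `lam_bar`
the sample mean of the weights. A year far from the curve gets a small
weight, which inflates its own variance (the likelihood tolerates it,
as in Tukey-style redescending robust losses) and damps its carry-over
into the next year's conditional mean (a single exceptional cohort
cannot masquerade as autocorrelation). `sqrt(lam_t)` can be read as
the probability that year `t` is uncontaminated. `phi = 0` recovers
the ordinary Gaussian AR(1) regression exactly.

Log-variances are assembled as `2*log(sigma) + phi*eps^2`, which is
exact and immune to the weight underflow that a literal
`sigma^2/lam_t` would suffer at gross residuals.

## Estimation

At fixed `phi`, `(a, b, sigma, rho)` are estimated by maximum
likelihood on transformed scales — `log a`, a logistic map of `b` into
`[0.5*min(S), 1.5*max(S)]`, `log sigma`, `atanh(rho)` — with
Nelder-Mead simplex search (the hockey-stick kink makes the surface
non-differentiable in `b`, so derivative-free search is the safe
default). The break-point bounds keep `b` near the observed biomass
range, where it is identifiable. A tiny ridge (`1e-6 * ||x||^2` on the
transformed scale) regularizes the exactly flat directions (`b` beyond
`max(S)` in the hockey-stick, saturated `atanh(rho)`); reported
log-likelihoods are recomputed from the decoded parameters without it.

A non-positive `rho` estimate is clipped to zero and `(a, b, sigma)`
re-optimized with `rho` fixed, so the returned point is a coherent
boundary maximum (negative lag-1 autocorrelation in recruitment is
treated as implausible). The LS comparator is the `phi = 0` fit; the
LAD comparator maximizes a Laplace AR(1) likelihood with conditional
mean `f + rho*eps_{t-1}` and a common scale — least absolute
deviations generalized to autocorrelated residuals, without weighting.
The exact objective LAD should use with autocorrelation is a design
choice; this Laplace form is the natural likelihood-based one.

### Continuation in phi

The weighted likelihood at moderate-to-large `phi` develops
statistically degenerate distant modes: `rho` near one with the curve
pushed below the data and most weights collapsed — an effective random
walk that "explains" autocorrelated data while treating the majority
of years as contaminated. A global multi-start search happily returns
these. The RSR estimate is therefore *defined by continuation*: the
`phi = 0` Gaussian AR(1) fit (located by a five-point moment-based
multi-start, where the surface is well behaved) anchors a chain of
warm-started local fits stepping up the canonical `phi` ladder
(log-spaced, -3.0 to 3.0 in steps of 0.5). This tracks the mode that
grows continuously out of the AR(1) solution, mirrors how a
gradient-based local optimizer from sensible starting values behaves,
and makes a full grid sweep cheap (one anchor plus one local fit per
grid value). The fit returned for a given `phi` depends only on ladder
values below it, so sweeps and single fits agree where their paths
coincide. Even under continuation the near-unit-root mode can capture
a fit when contamination is heavy relative to its separation from the
noise; see Limitations.

## Choosing phi: retrospective forecasting

`phi` is selected by time-series cross-validation: for fold `t`
(default `P = 10` folds, reduced with a warning down to leaving five
training years), the model is fitted to years `1..T-t` and the
held-out year forecast as `f(S | theta_hat) + rho_hat *
sqrt(lam_last) * eps_last`. The score is the geometric mean of squared
log-scale errors (`RF_R`), which a single bad fold cannot dominate;
squared errors are floored at 1e-12 before logs. Every fold refits
from scratch; non-converged folds are skipped with a warning, never
averaged in as zeros. Ties on the grid break toward the smallest
`phi`, the candidate closest to plain AR(1).

## The synthetic-data generator

Scenarios emulate a contaminated SR study:

- truth: hockey-stick `a = 1.2`, `b = 500` (variants: `a = 1.8`,
  Beverton-Holt, Ricker), `T = 30` years;
- spawning biomass: iid lognormal with median `b` and log-SD 0.6,
  truncated to `[0.05b, 4b]`, so the observed range straddles the
  break point and `b` is identifiable;
- clean residuals: stationary AR(1) with `rho` in {0, 0.8} and
  *marginal* SD `resid_sd = 0.4` (typical log-recruitment variability
  for exploited fish stocks); the innovation SD is derived as
  `resid_sd * sqrt(1 - rho^2)` so recruitment is equally variable in
  the autocorrelated and uncorrelated cells;
- contamination: each year independently an outlier with probability
  `p` (0.1 / 0.2 / 0.3; one spawner-dependent variant where `p`
  decreases linearly in the rank of `S_t` from 0.3 to 0.1), positive
  with probability `q` (0, 0.5, 1), magnitude
  `2*resid_sd + |N(0, (2*resid_sd)^2)|` — floored at two marginal
  noise SDs, i.e. gross relative to the noise floor;
- contamination is added *on top of* the clean AR process, which runs
  undisturbed through outlier years, so next-year truth
  `R_{T+1} = exp(f(S_{T+1}) + rho*omega_T + eta_{T+1})` carries the
  autocorrelation signal and never an outlier.

What the generator does **not** emulate: observation error in `S_t`,
feedback of recruitment into future spawning biomass (no closed
population loop), time-varying productivity, and autocorrelated or
regime-like contamination. Passing tests therefore demonstrate
estimator behavior under idealized process-error contamination, not
performance on any particular real stock.

## Evaluation

The Monte Carlo runner scores each method per replicate by long-term
bias `(R0_hat - R0)/R0` (asymptotic maximum recruitment, `a*b` for
hockey-stick and Beverton-Holt, `a*b/e` for Ricker) and short-term
bias `(R_hat_{T+1} - R_{T+1})/R_{T+1}` (plug-in median forecast on the
recruitment scale, no lognormal correction — matching the forecast
formula rather than a mean-unbiased predictor). Replicate `i` draws
its data from the seed stream `(seed, i)`, so every method sees
identical data (paired design); per-replicate failures are recorded,
never fatal.

## Reference points

Management quantities come from a Deriso-Schnute delay-difference
equilibrium: survival `s = 0.7`/yr, Ford growth coefficient
`g = 0.3`, recruit weight `w = 0.5` (biomass units per recruit), all
explicit configuration. With total survival `l = s*exp(-F)` the
equilibrium replacement line is `k(F)*B = R(B)`,
`k = (1 - (1+g)l + g l^2)/w`, intersected with the SR curve in closed
form; yield is `(1 - exp(-F)) * B*(F)` maximized over a fishing-rate
grid (0 to 2/yr, step 0.005). For a hockey-stick stock yield rises to
the break point and then collapses to zero — the equilibrium vanishes
once `k(F)` exceeds the curve slope `a` — which is exactly why a
positively biased `a` (LS under positive outliers) translates into an
overestimated `F_msy`. `F_msy` is invariant and `S_msy` equivariant
under a change of biomass units.

## Numerical choices

- Nelder-Mead options: `xatol = 1e-5`, `fatol = 1e-9`, 4000
  iterations; kernels are numba-jitted; invalid parameter regions
  return a large penalty (1e10) rather than raising, so simplex search
  never dies mid-run.
- `rho` is capped at `1 - 1e-6` to keep the fitted process strictly
  stationary; the `rho <= 0` boundary triggers the clip-and-refit.
- Multi-start table (anchor and comparators): moment-based center
  (`a0 = median(R/S)`, `b0 = median(S)`, `sigma0` = residual SD
  floored at 0.05) with fixed multiplicative perturbations and
  `rho0` in {0, 0.5, 0.8}; ties between starts break toward the first.
- Problem sizes in the acceptance checks (300 replicates for the
  clean-scenario recovery medians, 100 for the contaminated-scenario
  comparison, 50 for the selection-behavior check) are chosen so
  Monte Carlo error on a median is small relative to the tolerances
  while the whole suite stays desk-scale.

## Known limitations

- Under heavy one-sided contamination whose magnitude is only a few
  noise SDs, the weighted likelihood's near-unit-root mode competes
  with the interpretable mode and can win even from truth-adjacent
  starting values; `rho_hat` then disperses toward the {0, 1}
  boundaries across replicates. The separation between outliers and
  noise (an Appendix-level detail of the original study design that
  the generator must guess) controls how often this happens. The
  carry-damping factor `sqrt(lam)` also means that whenever clean-year
  weights sit below one, an unbiased effective carry requires
  `rho_hat > rho_true`, so `rho_hat` is not a calibrated estimate of
  the generating autocorrelation at large `phi`.
- On clean autocorrelated data the RF criterion is close to
  indifferent across the phi grid: small-phi forecasts under-carry
  because of the small-sample downward bias of `rho_hat` (about
  -(1+3 rho)/T for AR(1)-type estimators), while at moderate phi the
  inflated `rho_hat` combined with the redescending carry
  `rho_hat*sqrt(lam(eps))*eps` often forecasts as well or better. The
  selected phi is therefore variable rather than pinned at the grid
  minimum; this costs little forecast skill, but the selected phi
  itself should not be read as an estimate of outlier prevalence.
- No standard errors or intervals are produced (the study design
  compares point estimates across Monte Carlo replicates).
- AR(1) only; higher-order carry terms are out of scope.
- The delay-difference defaults are illustrative of a moderately
  long-lived stock, not tuned to any species; only relative
  comparisons between estimation methods should be read from them.
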