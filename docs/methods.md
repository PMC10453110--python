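# Methods

## Models

**RCINAR(p).**  `Y_t = phi_1(t) ∘ Y_{t-1} + ... + phi_p(t) ∘ Y_{t-p} + Z_t`,
with `∘` binomial thinning: given the previous count `y` and a coefficient
draw `phi`, the thinned value is Binomial(y, phi).  The `phi_j(t)` are i.i.d.
over time on [0, 1) with means `phi_j`; supported laws are a point mass
(`fixed`), Uniform[lo, hi], and Beta(a, b) with the first shape fixed at
a = 4 and b solved from the requested mean (mean 0.4 ⇒ b = 6, mean 0.2 ⇒
b = 16).  Innovations are i.i.d. non-negative integers: Poisson(mean),
geometric on {0, 1, 2, ...} with success probability p = 1/(1+mean) (mean 2 ⇒
p = 1/3), or equiprobable on a finite integer support.  Stationarity requires
`sum_j phi_j < 1`; configurations violating it are rejected at construction.

**INARCH(p).**  `Y_t | past ~ Poisson(phi_0 + sum_j phi_j Y_{t-j})` with
constant non-negative coefficients and `phi_0 > 0`.

**AR(p).**  `Y_t = phi_0 + sum_j phi_j Y_{t-j} + Z_t` with mean-zero Gaussian
or continuous-uniform innovations; real-valued output.

All three share the linear conditional mean that the selection criterion
uses — only the RCINAR likelihood is intractable, which is the point.

## Simulation protocol

Series start from zeros and discard a 500-step burn-in (geometric forgetting
under `sum phi_j < 1` makes the retained sample effectively stationary; the
burn-in length and zero start are implementation choices).  Coefficient draws
are independent across time and across lags; only their means enter the CLS
theory, so cross-lag dependence would not change any estimand, but
independence is the concrete choice made here.  Every replicate of a Monte
Carlo cell draws from its own stream
`default_rng([base_seed, T, variant_index, criterion_index, r])`, so cells are
mutually independent, individually reproducible, and identical whether run
serially or in parallel.

## Estimation

CLS minimizes `S(theta) = sum_{t=p_max+1}^{T} (Y_t - sum_j phi_j Y_{t-j} - lambda)^2`.
Because the conditional mean is linear, the minimizer solves ordinary normal
equations on the model's lag columns plus an intercept; the solve uses an
SVD-based least-squares factorization, falling back to the minimum-norm
solution with a warning when the restricted design is rank deficient (and
refusing outright for a constant series, where every lag column equals the
intercept column — selection then degenerates to the i.i.d. model with a
flag).  Estimates are deliberately unconstrained: negative thinning
coefficients are statistically meaningful evidence and are reported with a
`negative_estimates` flag rather than clipped.

Every candidate uses the common window `t = p_max+1 .. T` so that H values are
comparable across models; the penalty argument is the raw series length `T`,
not the effective sample size.

The asymptotic covariance is the sandwich `(1/n) V^{-1} W V^{-1}` with
`V = (1/n) sum X_t X_t'` and `W = (1/n) sum u_t^2 X_t X_t'` over the model's
own regressors; the second-derivative term of V vanishes because the
conditional mean is linear in the parameters.  This is robust to the
innovation law and to the coefficient randomness.

## The H statistic and selection

For submodels, H is always evaluated on the **full** (p_max+1)-dimensional
estimating-equation vector at the zero-padded estimate: the free coordinates
vanish by the normal equations, and misspecification registers in the excluded
coordinates.  This convention is what makes `H(full model) = 0` exact and the
criterion consistent.  The inner inverse is a direct linear solve, replaced by
a pseudo-inverse with a warning when the condition number exceeds 1e12;
identically-zero estimating equations give H = 0 by convention.  The quadratic
form is clamped at 0 against roundoff.

Ties within 1e-9 of the minimum criterion are resolved toward the smaller
model, then the lexicographically smaller lag set; in continuous data exact
ties essentially never occur.

The innovation-mean term counts toward the model size `|m|`; since every
candidate includes it, rankings are unaffected, but reported criterion values
include the full `P_T * |m|`.

## Likelihood baselines

The INARCH conditional Poisson likelihood (identity link) is maximized by a
damped Newton ascent started at CLS, with step halving that keeps every fitted
intensity positive.  The fit is unconstrained apart from that positivity
guard: truncating irrelevant-lag estimates at zero would replace the classical
chi-square large-sample behaviour of likelihood-ratio gains with a chi-bar-
square (half the mass at zero), roughly halving AIC's overfitting rate and
distorting the comparison with the penalized criterion.  A bound-constrained
variant (`nonnegative=True`, L-BFGS-B) is available when non-negative
parameter estimates are required.  The log-likelihood is concave on the
feasible region, so the ascent is globally convergent; tests confirm agreement
with derivative-free optimization from random feasible starts.

The AR fit is exact: least squares for the mean parameters,
`sigma_hat^2 = RSS/n`, and the closed-form Gaussian profile log-likelihood,
cross-checked against an independent OLS implementation.  AIC = 2k − 2·loglik
and BIC = k·log(n) − 2·loglik condition on the first `p_max` observations with
`n = T − p_max`; `k` counts the intercept plus included lags, plus one for
`sigma^2` in the AR family.  The conditioning convention shifts every
candidate's criterion by the same data-independent scheme, so selection
frequencies are insensitive to it.

## Monte Carlo harness and problem sizes

`run_cell` simulates R series, applies one selector, and tabulates the chosen
lag sets; degenerate replicates are counted in a diagnostics column, never
dropped or resampled (resampling would bias frequencies).  Accuracy sweeps
reuse the same cell runner per grid point; when the swept coefficient mean is
0 the correct model is scored as the reduced lag set, since a vanished
coefficient changes which model is true.

Default replicate counts: 1000 for the acceptance script (matching the
headline tables), 500 for the replication tests, 500 for figure-style sweeps.
Frequencies at R replicates are compared with 1000-replicate reference values
via three two-sample binomial standard errors,
`3 * sqrt(f(1-f)/R + f_ref(1-f_ref)/1000)` — the two-sample form because the
reference values are themselves Monte Carlo estimates, and it never collapses
to a zero band when an observed frequency hits 0 or 1.

## What the synthetic generators do and do not emulate

The generators reproduce the study designs exactly: constant/uniform/beta
coefficient laws with the stated means, Poisson/geometric/discrete-uniform
innovations, INARCH and Gaussian/uniform AR comparisons.  They do not emulate
features of real surveillance or seismicity data such as covariates, seasonal
or weekday effects, reporting delays, over-dispersion beyond what the chosen
innovation law implies, or structural breaks.  Passing tests therefore
demonstrate correctness of the estimator, statistic and selector under the
stated models — not that any particular real series follows an RCINAR process.
For real data the package reports the criterion table and sandwich standard
errors and leaves model adequacy (ACF/PACF diagnostics, dispersion checks) to
the analyst.

## Numerical choices and limitations

- Condition-number threshold 1e12 for all pseudo-inverse fallbacks.
- H clamped at zero; full-model H asserted < 1e-8 in tests.
- Tie tolerance 1e-9 (absolute) on criterion values.
- Newton convergence: max |score| below 1e-8 relative to the objective scale;
  at most 100 iterations with 40 step-halvings each.
- Only coefficient *means* are identified by CLS; the coefficient
  distribution's shape is not estimated.
- The fourth-moment assumption underlying the asymptotics is not checkable at
  run time and no check is attempted.
- Small-sample CLS estimates carry the usual O(1/T) downward autoregression
  bias, which is material for highly persistent short series (tests document a
  bias near −0.07 for persistence 0.86 at T = 61); no bias correction is
  applied.
- The weighted-chi-square limit of submodel H values under correct
  specification is not exercised; only the full-parameter chi-square_{p+1}
  calibration at the truth is tested.
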