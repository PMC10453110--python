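# rcinar-select

Lag-order selection for integer-valued autoregressive time series whose
likelihood is intractable — in particular random-coefficient INAR (RCINAR)
models built from the binomial thinning operator.

## The problem

Count time series (daily case counts of an epidemic, yearly numbers of major
earthquakes, hospital admissions) are naturally modelled with thinning-operator
autoregressions,

```
Y_t = phi_1(t) ∘ Y_{t-1} + ... + phi_p(t) ∘ Y_{t-p} + Z_t,
```

where `phi ∘ Y = sum_{i=1}^{Y} Bernoulli(phi)` is binomial thinning, each
coefficient `phi_j(t)` is an i.i.d. random draw on [0, 1) with mean `phi_j`,
and the innovations `Z_t` are i.i.d. non-negative integers with mean `lambda`.
The transition probability of this model involves a p-fold integral over the
coefficient distribution, so likelihood-based criteria such as AIC and BIC are
impractical: which lags to include has to be decided without a likelihood.

## The criterion

Only the conditional mean, `E[Y_t | past] = sum_j phi_j Y_{t-j} + lambda`, is
needed for conditional least squares (CLS).  Writing
`u_t = Y_t - sum_j phi_j Y_{t-j} - lambda` for the residual, the CLS estimating
equations are `Psi_t(theta) = u_t * (Y_{t-1}, ..., Y_{t-p}, 1)'`.  For a
candidate lag set `m` (the innovation-mean term is always included), the
constrained CLS estimate is padded with zeros to full dimension and scored by
the quadratic form

```
H(theta) = (sum_t Psi_t)' (sum_t Psi_t Psi_t')^{-1} (sum_t Psi_t),
```

which is 0 at the full model, chi-square_{p+1} at the true parameter, and
diverges faster than sqrt(T) under misspecification.  The selected model
minimizes the penalized criterion

```
H(theta_hat_CLS(m)) + P_T * |m|,
```

with `P_T` increasing and divergent, `P_T = O(sqrt(T))`, `log T / P_T = O(1)`.
Built-in penalties: `log T`, `T^(1/3)`, `T^(1/5)` (note `T^(1/5) < log T` for
all `T` in [4, 332106], so it is the most lenient choice in finite samples).
This selection is consistent under first-moment assumptions only, and because
it uses nothing but the linear conditional mean it applies unchanged to
INARCH and ordinary AR data.  The package also ships conditional Poisson
INARCH maximum likelihood and Gaussian AR fits with AIC/BIC as likelihood
baselines, the three families' simulators, and a Monte Carlo harness that
tabulates selection frequencies.

## Worked example

Simulate an RCINAR(3) series with constant coefficients (0.4, 0, 0.2) and
Poisson(2) innovations, then select the lag order:

```
$ rcinar-select simulate --config dgp.yaml --seed 11 --out counts.csv
wrote 500 observations to counts.csv (seed=11)
$ rcinar-select select --input counts.csv --pmax 3 --penalty T13
```

where `dgp.yaml` is

```yaml
family: rcinar
p_max: 3
T: 500
innovation: {kind: poisson, mean: 2}
coefficients:
  - {lag: 1, kind: fixed, mean: 0.4}
  - {lag: 3, kind: fixed, mean: 0.2}
```

The report (abridged) shows the criterion value of every candidate under the
`T^(1/3)` penalty and the fitted selected model:

```json
{
  "selected": {
    "lags": [1, 3],
    "phi":    {"1": 0.3511, "3": 0.2226},
    "phi_se": {"1": 0.0429, "3": 0.0410},
    "lambda": 2.2008, "lambda_se": 0.2634
  },
  "criteria": {
    "T13": {"iid": 80.79, "1": 43.00, "2": 69.55, "3": 63.26,
            "1,2": 49.44, "1,3": 24.15, "2,3": 64.53, "1,2,3": 31.75}
  }
}
```

The true lag set {1, 3} attains the minimum (24.15): its H value is small
because the model is correctly specified, while the full model pays the extra
penalty and every under-specified candidate pays a large H.  The coefficient
estimates recover the simulation truth (0.4, 0.2, 2.0) within about one
standard error; standard errors come from the CLS sandwich covariance
`V^{-1} W V^{-1}` and are robust to the innovation distribution.

The same workflow applies to observed data: any one-column CSV of counts can
be passed to `rcinar-select select`.  `rcinar-select table` reproduces full
selection-frequency tables from a YAML experiment config, and
`rcinar-select sweep` maps selection accuracy over a grid of coefficient
means and sample sizes.

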