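# Methods

This note summarises the statistical methods implemented in `augbin` and the
modelling conventions the package adopts.

## Setting and notation

A phase II oncology trial follows each patient over `T` post-baseline visits.
At visit `t` the tumour burden `z_t` (sum of longest diameters of target
lesions) is recorded together with an indicator `D_t` of new lesions.  All
modelling is on the log size ratio `y_t = log(z_t / z_0)` with `z_0` the
baseline burden.  Two progression mechanisms exist:

- **new-lesion progression** at time `X`, the first visit with `D_t = 1`;
- **tumour-growth progression** at time `G`, the first visit with
  `y_t >= log 1.2` (at least 20% growth over baseline).

New lesions always end follow-up.  Whether growth does too depends on the
trial design: when the endpoint places no constraint on intermediate visits,
follow-up continues through visit `T` unless a new lesion appears.  Either
way, missingness is monotone and depends only on observed history (missing
at random), so observed-data maximum likelihood is valid.

Endpoints (`EndpointSpec`):

- **fixed-time response**: at visit `T`, no new-lesion progression through
  `T`, `y_T < c_T` (default `log 0.7`, at least 30% shrinkage) and, when the
  intermediate threshold `c` is finite, `y_t < c` for all `t < T`.  The
  default `c = +inf` places no intermediate constraint.
- **best observed response (BOR)**: some visit `h` before any progression
  has `y_h < log 0.7` with all earlier visits in the stable band
  `(log 0.7, log 1.2)`; with **confirmation**, two consecutive such visits.

The binary comparator dichotomises each patient by these rules (unobserved =
non-responder) and uses a Wilson interval (single arm) or baseline-adjusted
logistic regression (two arms).  Karrison's comparator analyses a continuous
summary (worst observed log ratio if the first follow-up observation is
already a progression, otherwise the best log ratio before progression) by
baseline-adjusted least squares.

## Joint longitudinal model

Given baseline size and arm, `(Y_1, ..., Y_T)` is multivariate normal with

```
mu_t = beta_t + omega * z0 [+ eta_t * R]
```

and unstructured covariance `Sigma`.  With monotone missingness the
observed-data log likelihood is the sum of the normal log densities of each
patient's observed prefix; it is maximised directly by L-BFGS-B with an
analytic gradient, `Sigma` parameterised through its Cholesky factor
(log-diagonal) so it remains positive definite.  New-lesion progression is
modelled by independent per-visit logistic regressions on the at-risk
patients,

```
logit P(D_t = 1 | at risk) = alpha_t + gamma_t * z_{t-1} [+ lambda_t * R],
```

where `z_{t-1}` is the previous tumour size.  The full parameter vector
`theta` stacks the mean parameters, `vech(Sigma)` and the per-visit logistic
parameters.  Its estimated variance is block diagonal — exact, because the
likelihood factorises and the cross-information is identically zero — with
the normal block from the inverse numerical Hessian in the natural
parameters and the logistic blocks from the per-visit fits.

## Response probability functionals

For each patient, the probability of response given `theta` integrates the
normal density over the region of trajectories satisfying the endpoint,
weighted by the no-new-lesion chain:

- **eAugbin** evaluates the integral with the new-lesion probabilities at
  the *latent* sizes inside the integrand (`z_{t-1} = z0 * exp(y_{t-1})`),
  by quasi-Monte-Carlo cubature (scrambled Sobol points through a
  sequential-conditioning transform of the normal).
- **mAug** factorises the probability as the product of per-visit
  no-new-lesion probabilities and a multivariate normal rectangle
  probability.  The new-lesion chain uses the model value at observed
  previous sizes for visits `t <= F + 1`; beyond the observed window it
  substitutes the trimmed average of the fitted probabilities of the
  patients still on study at that visit whose observed trajectories remain
  inside the endpoint's stable region.  Rectangle probabilities come from a
  vectorised Genz-style algorithm (tensor Gauss–Legendre with a conditional
  normal tail for BOR-shaped regions; sequential-conditioning QMC in
  general), validated against `scipy.stats.multivariate_normal.cdf`.

For BOR the event is a disjoint union over the response visit `h` of region
products `Omega_1^(h-1) x Omega_2` (with `Omega_2` repeated for
confirmation), `Omega_1 = (log 0.7, log 1.2)`, `Omega_2 = (-inf, log 0.7)`;
the no-new-lesion chain runs to `h` (to `h + 1` with confirmation).

The trial-level estimate is the average of per-patient probabilities; in a
randomised trial the arm difference `m = p(R=1) - p(R=0)` averages over
*all* patients with the arm indicator overridden.

## Inference

Confidence intervals use the delta method on the logit scale: with
`l(theta) = logit p(theta)`, the interval is `expit(l +- z * se)` with
`se^2 = grad' V grad` by central finite differences through the full
parameter vector; the interval always stays inside (0, 1).  Two-arm
comparisons use a Wald statistic for `m` on the identity scale.

## Simulation studies

Scenario presets reproduce standard operating-characteristic studies:
baseline sizes uniform on (0, 1), normal log ratios with means ramping to
`log 0.7` and a Brownian-type covariance (`Cov(Y_s, Y_t)` = variance at
`min(s, t)`), and per-visit new-lesion models with intercept around −1.5
(an 18% per-visit chance).  Fixed-time scenarios do not stop follow-up at
tumour growth (the analysed endpoint places no intermediate constraint);
BOR scenarios do.  Replicates draw their RNG streams from
`SeedSequence([master_seed, replicate])`, so studies are bit-identical for
any worker count.  Truth for coverage is computed by evaluating the
endpoint on `10^6` latent trajectories from the generative law.

A note on calibration: in the single-arm fixed-time `T = 2` preset the
model-based intervals here are calibrated and efficient — the mean CI width
matches the empirical standard deviation of the estimator across replicates
(~0.042, which also matches a direct information calculation), and coverage
is at the nominal 95%.  The resulting CI width reduction versus the binary
method is ~20%, equivalent to the binary method needing roughly
`(1/0.8)^2 - 1 ≈ 56%` more patients for the same precision
(`sample_size_equivalent`).
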