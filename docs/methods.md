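# Methods

## Setting and model

`wedgepower` supports the design of *cross-sectional stepped-wedge cluster
randomized trials* (SW-CRTs) with a binary outcome when the quantity of
interest is not the overall treatment effect but the **treatment-by-covariate
interaction** — the heterogeneity of treatment effect (HTE) between two
subgroups, e.g. minority and non-minority patients in a healthcare-disparity
trial.  `I` clusters are observed over `J` periods; every cluster starts in
control and crosses to intervention at one of `J − 1` staggered steps (the
balanced schedule: `I/(J−1)` clusters per step, first period all-control,
last period all-treated).  A fresh cross-section of `m` individuals is
sampled per cluster-period.

The marginal mean model is logistic:

```
logit(mu_ijk) = theta0 + gamma_j + theta1 * W_ij + theta2 * X_ijk
                + theta3 * W_ij * X_ijk,          gamma_1 = 0
```

with `W_ij` the treatment indicator, `X_ijk` a binary individual covariate,
`theta1` the overall treatment effect and `theta3` the HTE, all on the
log-odds-ratio scale.  There are `p = J + 3` free coefficients; the design
matrix orders them `[intercept, gamma_2..gamma_J, W, X, W*X]`, so the HTE
coefficient is always the last diagonal element of any covariance matrix.

Outcome dependence within a cluster follows the **nested exchangeable**
structure `R(alpha, rho)`: correlation `alpha` (the ICC) between two
individuals in the same cluster-period and `alpha * rho` (ICC x CAC) across
periods; `rho = 1` is the simple exchangeable structure.  `R` has three
distinct eigenvalues — `1 − alpha` on within-period contrasts,
`1 − alpha + m*alpha*(1 − rho)` on period-mean contrasts, and that plus
`J*m*alpha*rho` on the grand mean — which gives closed-form inverses,
admissibility checks (all three must be positive, enforced eagerly at
specification time) and O(n)-per-column products used throughout.

## Design-stage variance and power

The GEE estimator's covariance is approximated by the inverse information
`B^{-1}`, `B = sum_i M_i' Sigma_i^{-1} M_i` with
`Sigma_i = A_i^{-1/2} R_i A_i^{-1/2}` ("GEE", the model-based/naive
approximation; an `O_P(1/I)` remainder is ignored).  Because this
understates the variance when `I` is small, two leverage-based corrections
are offered, mirroring the Kauermann–Carroll (KC) and Mancl–DeRouen (MD)
small-sample sandwich estimators evaluated at design values: with cluster
leverage `H_i = A_i M_i B^{-1} M_i' Sigma_i^{-1} A_i^{-1}`, the cluster
residual is premultiplied by `F_i = (I − H_i)^{-1/2}` (KC) or
`(I − H_i)^{-1}` (MD) and the covariance becomes the sandwich
`B^{-1} (sum_i T_i V_i T_i') B^{-1}` with `T_i = M_i' Sigma_i^{-1} A_i^{-1} F_i`
and `V_i = A_i^{1/2} R_i A_i^{1/2}`.  With `F_i = I` this collapses exactly
to `B^{-1}`; the test suite asserts the collapse to 1e-10 relative error,
and checks the whole engine against a literal dense transcription of the
formulas on a 4-cluster design.

Because `H_i` has rank at most `p`, matrix functions of `I − H_i` are
evaluated through `f(I − U W') = I + U phi(K) W'`, `K = W'U` (p x p),
`phi(lam) = (f(1 − lam) − 1)/lam`, using the eigendecomposition of `K`.
This is the principal matrix function (the standard reading of the power
−1/2, whose branch the correction itself leaves unspecified); imaginary
parts beyond 1e-8 trigger a dense Schur/`sqrtm` fallback.  All products with
`R` and `R^{-1}` use the eigenstructure, so a full KC/MD evaluation at
`m = 120` (600 x 600 per cluster) costs `O(n p^2)`.  Clusters sharing a
crossover pattern (there are exactly `J − 1` patterns) are computed once
and weighted.

Power for the two-tailed Wald test of `H0: theta3 = 0` against
`theta3 = delta` is the **full two-sided rejection probability**

```
power = F(d − q) + F(−d − q),   d = |delta| / sqrt(Var(theta3_hat))
```

with `F`/`q` standard normal, or Student-t with `df = I − 4` (the number of
clusters minus the four cluster-level coefficients) for small-`I` designs.
The second term is negligible for the z test but adds roughly half a
percentage point under t with 4 df; we include it because it is the exact
rejection probability of the two-sided test (a `tails=1` option exposes the
single-tail approximation often written in closed form).

### Design searches

* **Cluster size**: smallest `m` on a grid with predicted power at or above
  target.  The default grid step is the smallest integer making
  `m * prevalence` integral (10 at 30%, 2 at 50%, 3 at 1/3), which keeps
  the deterministic covariate allocation exact along the search; any step
  can be forced.
* **Number of clusters**: same search over multiples of `J − 1`.
* **Minimal detectable HTE**: bisection on the interaction odds ratio,
  *re-deriving the design variance at every candidate* — `theta3` shifts
  the treated-minority cell mean, hence the information.  The crossing is
  rounded up to the requested resolution (default 0.01).

### Covariate allocation

Each cluster-period contains exactly `round(m * prevalence)` individuals
with `X = 1` (halves away from zero), placed deterministically; under
exchangeable correlation the positions are irrelevant (asserted numerically
by a permutation test).  Allocations leaving a covariate level empty are
rejected.  For non-grid sizes (e.g. `m = 79` at prevalence 1/3) the rounded
count makes predicted power very slightly non-monotone across adjacent
sizes; the default search grid avoids this by construction.

## Copula simulator

Binary outcomes with the exact marginal means and outcome correlation
`R(alpha, rho)` are generated by thresholding a latent Gaussian vector:
`Y = 1{Z <= Phi^{-1}(mu)}`, `Z ~ N(0, Xi)`.  Each latent pairwise
correlation solves `Phi2(Phi^{-1}(mu), Phi^{-1}(mu'); xi) = joint`, where
`joint = target * sqrt(v v') + mu mu'` must lie inside the
Fréchet–Hoeffding bounds (violations raise an explicit error).  The
bivariate normal CDF uses the Owen's-T closed form; the root is bracketed
on [−0.9999, 0.9999] with 1e-8 tolerance on the joint probability.  Only
distinct `(mu, mu', within/between)` combinations are solved (a handful per
design) and clusters sharing a crossover pattern share one factorization.

The assembled `Xi` need not be positive semi-definite.  Eigenvalues below a
floor of 1e-6 are raised to the floor, the matrix is rescaled to unit
diagonal, and the maximum entry adjustment is recorded on the
`LatentCorrelation` object (`repaired` flag).  The floor and rescaling rule
are this package's choices; the adjustment is tiny in practice (the
reference designs perturb entries by < 1e-3) and the simulator's marginal
and correlation fidelity is verified by Monte-Carlo tests at 10,000
replicates.

Randomness follows a substream contract: one root seed expands through
`numpy.random.SeedSequence.spawn` into an independent stream per replicate,
so results are reproducible and independent of execution order.

## GEE fitter

Fisher scoring on `theta` alternates with moment re-estimation of
`(alpha, rho)` from standardized Pearson-residual cross-products:
within-period ordered pair products average to `alpha`, cross-period
products to `alpha * rho` (for the simple working structure, all pairs
pooled).  Estimates are clipped into the positive-definite region.  The
update solves `B step = score` with the structured `R^{-1}`; steps are
capped at 5 in max-norm to prevent early overshoot; convergence is a
maximum coefficient change below 1e-6 within 100 iterations.  Replicates
with only one outcome level, separation (|linear predictor| > 30) or
non-convergence are flagged — never raised — and excluded from
operating-characteristic denominators with a reported count (the reference
study is silent on its handling; exclusion-with-reporting was chosen for
transparency, and exclusions are rare at the study's sizes).

After convergence the fitter reports naive, robust, KC and MD coefficient
covariances, the last two via the same rank-p identity applied to fitted
residuals.  The exact moment estimator used by the original R analysis is
unknown; agreement is validated at the level of operating characteristics
(type-I error, power), plus an exact oracle: with the working correlation
fixed at independence the fit reproduces pooled logistic-regression ML to
1e-6.

## Simulation harness and problem sizes

`run_operating_characteristics` composes simulator, fitter and test;
rejection proportions estimate the empirical type-I error `psi0` (null
generation) or simulated power `phi0`, alongside the SE bias
`mean(SE) − SD(estimates)`.  An `ote` mode generates and fits the reduced
model `logit(mu) = theta0 + gamma_j + theta1 W` to reproduce the
overall-treatment-effect diagnostics.  The reference study used 1,000
replicates per cell; the bundled acceptance checks run 300–1,000 replicates
depending on the cell (chosen so each check completes in seconds to a
couple of minutes on one core) and compare through binomial confidence
intervals at the matched count.  Default generator parameters are the
study's: 15% control-arm prevalence, secular trend (0, .1, .2, .3, .4),
covariate prevalence 30%/50%, ICC 0.1, CAC 1 or 0.8.

### What the simulator does and does not emulate

The generator reproduces exactly the factors the analytic predictions rest
on: marginal means from the logistic model, deterministic covariate counts,
and nested exchangeable outcome correlation.  It does not emulate features
of field data — unequal cluster sizes, covariate prevalence drift across
periods or clusters, missing outcomes, decaying between-period correlation,
or time-varying treatment effects — so passing operating-characteristic
checks validate internal consistency of the design calculations, not
robustness to those departures.

## Known limitations

* Cross-sectional designs only; closed-cohort and open-cohort SW-CRTs (with
  repeated measures per individual) need an extra correlation level.
* Equal cluster sizes and a balanced crossover schedule are assumed (the
  schedule matrix is constructed internally; alternative schedules would
  need a custom layout).
* Exponential-decay between-period correlation is not implemented.
* The KC/MD corrections inflate design-stage variance; published
  small-sample comparisons (and our simulations) show the model-based GEE
  power tracks naive-SE analyses well, while robust-SE analyses with few
  clusters reject more often than predicted.
* The minimal-detectable-effect search assumes power is monotone in the
  interaction odds ratio at fixed design, which holds throughout the
  supported parameter region.
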