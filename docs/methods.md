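# Methods

## Scientific setting

The package models longitudinal tumour-volume data from an orthotopic,
syngeneic mouse mammary cancer experiment: 4T1 cells implanted in the
mammary fat pad, animals enrolled and randomized to vehicle or one of two
P2X7-receptor antagonists (A438079, AZ10606120) once the tumour reaches
80 mm³, and caliper volumes (L·l²/2) recorded twice a week.  The analysis
questions are (i) how fast tumours grow and to what plateau, (ii) by how
much antagonist treatment slows growth, (iii) whether the two antagonists
differ, and (iv) whether treatment prolongs survival to a humane-endpoint
volume.

## Structural model

Tumour volume follows a generalized Gompertz law,

    dV/dt = k_eff(t) · V · [ln(V_max / V)]^γ,    V(0) = v0,

with `k_growth` (1/day) the growth-rate constant, `V_max` (mm³) the
plateau, and γ a dimensionless power.  γ = 1 recovers the classic Gompertz
model.  Treatment multiplies the rate: `k_eff = k_growth · (1 − EFF)`
while treatment is on, so `EFF = 0.52` means growth is slowed by a factor
`1/(1 − 0.52) ≈ 2`.  Two genuinely open structural choices were resolved
as package design decisions:

- **Placement of γ.**  γ powers the `ln(V_max/V)` term rather than `V`,
  because that form uses exactly the three named parameters and reduces to
  the classic model at γ = 1.
- **Action of EFF.**  EFF scales the rate multiplicatively as `(1 − EFF)`,
  because the reported effect size then reproduces the reported factor-two
  growth slowdown exactly.

Substituting `u = ln(V_max/V)` separates the ODE (`du/dt = −k_eff u^γ`),
which integrates in closed form, including the finite-time arrival at the
plateau for γ < 1.  The default predictor evaluates this exact solution;
`predict_volume(..., method="ode")` integrates the ODE with adaptive
Runge–Kutta (rtol = atol = 1e-8, treatment start forced as a segment
boundary) and is cross-checked against the analytic path in the tests.
The exact solution is also inverted analytically to obtain
humane-endpoint crossing times.

Treatment is modelled as continuously on from the start time; the
every-two-days dosing interval is design metadata only — no
pharmacokinetics is modelled.  The time origin is the treatment start, and
each animal's `v0` is fixed to its first observed volume rather than
estimated (it is the enrollment measurement; estimating it would add one
weakly identified parameter per animal).  Consequently the first
observation anchors the trajectory and is excluded from the residual
likelihood.

## Population model and estimation

Per-animal parameters are log-normal around population typical values:
`log k_i ~ N(log k_mean, ω_k²)`, similarly for `V_max` and (treated
animals only) `EFF`; γ is a fixed effect without a random effect.
Inter-individual percentages are read as the sd of the log-scale random
effect (39% → ω = 0.39); the alternative CV% reading
`sqrt(exp(ω²) − 1)` is numerically close at these magnitudes and not
recoverable from the source.  EFF is drawn log-normally and may exceed 1
(tumour shrinkage), which the trajectory code supports explicitly.
Covariates are multiplicative arm coefficients on the log scale with the
vehicle arm (or, for EFF, the first antagonist arm) as reference.

The residual model is combined, `sd(y|f) = σ_add + σ_prop · f`, with
defaults σ_add = 5 mm³ and σ_prop = 0.15 — the source analysis does not
state its residual model, and a pure proportional error would degenerate
at small volumes.

Estimation is SAEM, written from scratch (re-implementing the commercial
estimator is the point of the package):

- **S-step.**  A component-wise Metropolis random walk on each animal's
  log-scale parameters targets the conditional posterior under the current
  population law; proposal scales adapt toward ~30% acceptance during
  burn-in.  All animals are updated simultaneously with vectorized
  trajectory evaluations (the closed-form solution makes one cohort
  evaluation microseconds, which is what keeps the Monte-Carlo suites
  tractable).
- **SA/M-step.**  Sufficient statistics are smoothed with step 1 during
  `n_burnin` exploratory iterations and `(k)^(−0.8)` afterwards; means and
  covariate coefficients come from a least-squares projection of the
  smoothed statistics, omegas from the smoothed second moments, and the
  residual pair (σ_add, σ_prop) from a two-parameter Gaussian likelihood
  in the smoothed per-observation statistics.
- **γ profile step with a ridge move.**  γ is updated by maximizing the
  complete-data likelihood jointly with *global shifts* of the sampled
  log-k (and log-EFF) values, because γ and the rate scale are strongly
  correlated: coordinate-wise updates mix too slowly along that ridge and
  can freeze the run in a spurious basin.  The shift is applied to the
  sufficient statistics as well, so the population means follow.  The
  move is damped (factor 0.3) during burn-in and disabled for the first
  ten iterations, when the φ samples are still immature.
- **Simulated annealing.**  During burn-in, omegas and residual sds may
  not fall below a geometrically decaying floor (0.97 per iteration),
  keeping the kernels mobile early on.

Convergence is declared when the population means and γ in the last 20%
of SA iterations have a coefficient of variation below 2%; the full trace
is returned for inspection.  Vehicle animals contribute no information
about EFF; with no treated animals EFF is reported at its initial value,
unchanged.

**Initialization / two-stage oracle.**  `two_stage_fit` fits each animal
by weighted least squares — (rate, V_max) per animal, with γ profiled on
a grid and refined — and aggregates means/omegas from the per-animal
logs.  Because post-enrollment data identify only the product
`k·(1 − EFF)` within a treated animal, the two-stage estimate takes
`k_mean` from vehicle animals and derives EFF from the mean-log rate
difference between arms.  It initializes SAEM and serves as an
independent cross-check of the population means on rich data.

## Observed-data log-likelihood and LRT

The marginal likelihood integrates the random effects per animal by
importance sampling with a defensive mixture proposal: a Gaussian at the
conditional mode with Laplace covariance (inflated 1.3×), the population
prior, and a widened prior (3× sd, floored at 0.45) as a heavy tail.  The
mixture keeps the weights bounded when a conditional is wide or
non-Gaussian (e.g. EFF in animals that never plateau).  The Monte-Carlo
standard error is reported from the normalized weights.

Covariate tests are likelihood-ratio tests against the chi-square with
df = number of added coefficients (only fixed-effect covariates are
tested, so no boundary mixture correction applies).  A df = 1 likelihood
difference is smaller than the stochastic placement offset of two
independent SAEM runs, so `covariate_lrt` implements a robustified
protocol: (i) the null model is additionally refit warm-started from the
alternative's estimates and the better null is kept — nested runs can
land in different basins, and a stuck null would inflate the test while
a stuck alternative only makes it conservative; (ii) every finalist is
*polished* by directly maximizing the fixed-draw simulated likelihood
over the population means, covariate coefficients and omegas (analytic
gradients, L-BFGS-B, a ±0.25 log-scale trust region around the SAEM
estimate because the fixed draws only support the objective near the
proposal), with one shared draw seed for both models.  The polish removes
SAEM's placement noise in the mean/omega directions from the likelihood
difference; γ and the residual sds stay at their fitted values, and their
run-to-run variation is strongly correlated between the two fits of the
same data.  Negative statistics are clamped to zero, with a warning when
the deficit exceeds three Monte-Carlo standard errors.

## Synthetic cohorts: what they emulate and what they do not

`simulate_cohort` reproduces the statistical structure the estimator
assumes: enrollment at 80 mm³ (the baseline is the threshold perturbed by
one measurement error), twice-weekly observations over 28 days, log-normal
inter-individual variability at the published values (k 0.64/day, 39%;
V_max 1620 mm³, 64%; EFF 0.52, 82%; γ 0.17), combined residual error, a
1 mm³ observation floor, and survival defined by the noise-free trajectory
crossing 1500 mm³ (the humane-endpoint volume and group size of 10 per arm
are package choices; the source states neither).  Passing recovery tests
therefore show that the estimator inverts its own generating model at
realistic noise levels — they do not validate the Gompertz form against
real tumours, nor cover model misspecification, missed visits, dropout
before enrollment, or measurement error correlated within days, none of
which are simulated.

## Calibration studies and problem sizes

The test suite runs three kinds of Monte-Carlo calibration, sized to keep
the full suite within a routine CI run:

- **Recovery** (headline): 3 replicate studies of 3 arms × 20 animals at
  the published truths; the across-replicate mean of each population
  estimate must be within 15% of truth (γ within ±0.1).  Averaging over
  replicates makes the check a test of estimator bias; a single replicate
  at this sample size has sampling noise of the same order as the
  tolerance.
- **Type-I error of the LRT**: 100 null-true replicates of a scaled-down
  but densely observed design (3 arms × 6 animals, observations every 2
  days), testing shared-EFF against per-arm EFF (df = 1) — the package's
  version of the "difference between antagonists" question.  Dense
  per-animal sampling is deliberate: it is what makes the Laplace
  importance-sampling proposals accurate and the fits reproducible enough
  for a df = 1 test.  The rejection count at α = 0.05 must fall in the
  central 99% binomial range around 5% (1–11 of 100).
- **Prediction-interval coverage**: the 90% band simulated from the
  generating law (3000 virtual animals per arm) must cover fresh simulated
  observations 90% ± 3%.

A caveat found while building the calibration suite: a covariate LRT on
`V_max` in designs whose treated arm rarely reaches the plateau is
genuinely anticonservative (the parameter is then weakly identified and
the null distribution of the statistic is heavier than chi-square).  This
is a property of the test/design combination, not of the estimator; the
calibration suite therefore uses the well-identified EFF contrast.

## Numerical choices

- Trajectories: exact closed form; `w = u^(1−γ)` clamped at 0 (γ < 1
  plateau) or at 1e-300 (γ > 1 shrinkage blow-up); `u0 = 0` treated as an
  equilibrium.
- Individual parameters with `V_max ≤ v0` get log-likelihood −∞ (rejected
  by the sampler) rather than an exception.
- Omegas floored at 1e-3 during estimation; residual sds floored at
  (1e-3, 1e-4); Hill fit `top` bounded in (0, 1.5] because normalization
  pins the reference response near 1.
- Hill EC50 fit: deterministic multi-start (log-spaced EC50 in
  [0.1, 30] mM × slopes {0.5, 1, 1.5, 2, 3}), trust-region least squares
  on (log EC50, log n, top); the returned SSE is never worse than any
  start.
- Gehan–Breslow–Wilcoxon: weight = pooled number at risk, simultaneous
  risk-set reduction at ties, hypergeometric variance, chi-square(1)
  p-value; exact enumeration of group assignments when feasible
  (≤ 200 000), seeded Monte-Carlo permutation otherwise.  The three-arm
  survival display is handled as pairwise tests against vehicle without
  multiplicity correction.
- All stochastic operations take explicit seeds; identical config + seed
  reproduces outputs byte for byte.

## Known limitations

- Standard errors of the population estimates are not computed (no Fisher
  information matrix); replicate fits over seeds are the substitute.
- `k_growth` and EFF are confounded within a treated animal when no
  pre-treatment observations exist; they separate only at the population
  level through the vehicle arm.  Adding a `k_growth` covariate on a
  treated arm on top of EFF is therefore not identified in the default
  design.
- The reported doubling-time interpretation of `k_growth` in the source
  (0.64 day) does not follow from any standard Gompertz parameterization;
  the package treats `k_growth` strictly as the rate constant.
- The LRT relies on the asymptotic chi-square; for weakly identified
  covariates (see above) it can be anticonservative.
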