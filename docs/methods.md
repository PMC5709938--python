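# Methods

`popsse` implements a stochastic-simulation-and-estimation (SSE) study of
population-pharmacokinetic estimation methods under a small number of
subjects: simulate many replicate datasets from a known hierarchical model,
re-fit each with several estimators, and score the estimators by the
relative error of their estimates against the generating truth.

## Model

Structural model: one-compartment disposition with first-order oral
absorption and first-order elimination,

    dA_d/dt = -Ka A_d,      dA_c/dt = Ka A_d - (CL/V) A_c,

observed as concentration C(t) = A_c/V.  For a single oral bolus at t = 0
the solution is the closed-form Bateman curve; the implementation switches
to the L'Hopital limit form when |Ka - ke|/Ka < 1e-8 (ke = CL/V), which
keeps predictions continuous through the flip-flop tie and avoids
catastrophic cancellation.  An explicit Runge-Kutta integration of the
compartment system (`ode_concentration`, DOP853, rtol 1e-10) is shipped as
an independent verification oracle and is tested against the closed form
over 1000 random parameter sets.

Statistical model: fixed effects theta = (Ka, Vd/F, CL/F); lognormal
inter-individual variability (IIV) on Vd/F and CL/F,
P_i = theta_P exp(eta_P,i) with eta ~ N(0, omega2_P); proportional residual
error DV = C_pred (1 + eps), eps ~ N(0, sigma2).  IIV magnitude is
specified as a coefficient of variation and converted exactly by
CV% = 100 sqrt(exp(omega2) - 1).  The theophylline-style case-study
parameterization additionally carries an eta on Ka; all estimators accept
any subset of {Ka, Vd/F, CL/F} with IIV (the active set is whatever has
omega2 > 0 in the initial values).

## Study conditions (generator defaults)

- 6 subjects, 8 sampling times in (0, 24] h, 100 replicates per IIV level,
  IIV levels {5, 10, 20, 30, 50, 80}% CV with omega2_V = omega2_CL.
- Truth: Ka = 2 1/h, Vd/F = 40 L, CL/F = 10 L/h.
- Dose 320 mg (a standard single oral theophylline-scale dose), sampling
  times {0.25, 0.5, 1, 2, 4, 8, 12, 24} h (a conventional rich single-dose
  schedule: three absorption-phase points, peak region, elimination tail),
  and sigma2 = 0.01 (10% proportional CV, a typical assay + model residual
  magnitude).  These three values are design choices of this package —
  configurable, recorded in the dataset metadata, and fixed once.
- Simulated negative concentrations (possible under proportional normal
  error at late times) are retained: truncation would change the generative
  law the estimators assume.
- Case-study preset: CL/F = 2.88 L/h (25.69% CV), Vd/F = 33.01 L (13.48%
  CV), Ka = 1.46 1/h (65.39% CV), 6 subjects, 11 samples to 24.3 h.

What the generator does *not* emulate: covariates, inter-occasion
variability, censoring/BLQ, dropout, dose-timing deviations.  Passing tests
therefore speak to estimator behaviour under a clean, correctly-specified
hierarchical model — not to robustness against real-data artifacts.

## FOCE-I estimator

First-order conditional estimation with interaction, written from scratch:

1. **Inner problem.**  Per subject, the empirical-Bayes conditional mode
   minimizes g(eta) = sum_j [log(sigma2 f_j^2) + (y_j - f_j)^2/(sigma2
   f_j^2)] + eta' Omega^{-1} eta.  A damped Newton iteration runs over all
   subjects simultaneously (batched finite-difference gradients/Hessians,
   step 1e-4; eigenvalue-shifted Hessians; step-halving line search; trust
   cap 4).  A subject whose line search can no longer descend is at the
   finite-difference noise floor and is frozen — without this, sharp
   subjects cycle at the optimum.  Warm starts from the previous outer
   iterate speed convergence without changing the fixed point.
2. **Objective.**  The marginal -2 log-likelihood is approximated by
   linearizing f about the conditional modes: OFV = sum_i [log det C_i +
   r_i' C_i^{-1} r_i] with C_i = G_i Omega G_i' + diag(sigma2 f_i(eta_i)^2)
   and r_i = y_i - f_i(eta_i) + G_i eta_i; G_i by central differences with
   relative step 1e-5.  Evaluating the error variance at the mode (not at
   eta = 0) is the eta-eps interaction.  The additive n log 2pi constant is
   omitted, as is conventional for NLME objective values; the test-suite
   quadrature oracle adds it back before comparing.
3. **Outer problem.**  Minimization over log(theta, omega2, sigma2) — the
   log transform enforces positivity and makes step sizes relative.  The
   optimizer is a damped BFGS with plain Armijo step-halving rather than a
   Wolfe line search: the proportional-error OFV has near-vertical cliffs
   where predictions underflow (weighted squared residuals of 1e20+), and
   interpolation-based line searches stall against them, whereas geometric
   halving crosses a cliff in a few steps.  Steps are capped at norm 2 in
   log space and clipped to wide bounds (1e-8..1e8).
4. **Convergence and covariance bookkeeping.**  `minimization_success`
   requires the optimizer's own convergence (gradient below 3e-3, or no
   descent beyond noise) plus stability of every parameter to 3 significant
   digits across the final iterations (relative change < 0.5e-3, the
   SIG = 3 analogue).  The covariance step computes the central-difference
   Hessian of the OFV at the optimum (log scale) and succeeds when it is
   finite and positive definite.

Correctness is anchored to independent oracles, not to any external
implementation: conditional modes against exhaustive grid search, the OFV
against adaptive Gauss-Hermite quadrature (41 nodes/dimension) of the exact
marginal likelihood on small datasets, and the omega2 -> 0 limit against
the fixed-effects weighted least-squares deviance.

## Bayesian estimator (Metropolis-within-Gibbs)

Single-chain MCMC on the exact hierarchical posterior with a fixed scan:
(1) per-subject random-walk Metropolis on eta (all subjects in parallel;
they are conditionally independent given theta), proposal scales adapted
during burn-in toward 30% acceptance; (2) conjugate inverse-gamma draw of
each omega2 given the etas (skipped in the fixed-omega variant);
(3) component-wise random-walk Metropolis on log theta, followed by an
interweaving Gibbs shift along the theta/eta ridge — a common shift delta
moved from the etas into log theta leaves every individual parameter and
hence the likelihood unchanged, and its full conditional is
N(mean(eta), omega2/n); without this move the centered parameterization
makes theta mix at random-walk speed; (4) conjugate inverse-gamma draw of
sigma2 from the scaled residuals.  Priors: flat (improper) on log theta,
inverse-gamma(0.01, 0.01) on each variance — weakly informative and
conjugate where possible; they are this package's choices and are recorded
in the fit metadata.

Burn-in (cap 4000) ends early when a stationarity check passes: every 500
iterations, each monitored series (log posterior, thetas, omega2s, sigma2)
over the most recent half of the burn-in is tested for a linear trend.
The slope t-test runs on 20 non-overlapping batch means with an AR(1)
correction of the slope standard error (alpha = 0.01): a naive OLS test on
raw autocorrelated iterates flags a trend in almost any stationary chain.
Point estimates are posterior means over the stationary phase (10,000
iterations by default; medians are stored alongside); the burn-in
convergence flag doubles as `minimization_success`, and the covariance
flag is always true for MCMC since posterior spread is always available.

Variants: the fixed-omega variant holds the IIV variances at their initial
(true) values; the composite variant runs FOCE-I first and seeds the chain
with its estimates (falling back to the user initials, flagged, only if
FOCE-I returns non-finite values).

## SSE engine and metrics

For each (IIV level, replicate) one dataset is simulated and presented
bit-identically to every method; initials are the true values ("open true
values").  Per-fit RNG streams derive from SeedSequence keys
(master_seed, level, replicate, method), so any subset of the sweep
reproduces identical rows in isolation and results are independent of
execution order.  Numerical failures become rows with success flags set to
false; they never abort the sweep.

Metrics, per (parameter, method, level) over successful fits (count
reported as `n_used`):

- REE = 100 (P_est - P_true)/P_true, signed percent; median = bias,
  spread = precision.  Quantiles use the linear-interpolation (type-7)
  rule.
- rRMSE = sqrt(mean(((P_est - P_true)/P_true)^2)) — the conventional
  definition, used for all method comparisons.  A dimensionally
  inconsistent variant that divides the squared error by P_true and by n^2
  circulates in some reports; it is computed alongside as `rrmse_printed`
  for transparency, never used for comparisons.

## Small-sample bias of the IIV variances: a structural note

With n = 6 subjects, any maximum-likelihood estimate of a between-subject
variance behaves (in the informative-data limit) like
omega2-hat ~ omega2 chi2_{n-1}/n.  At n = 6 this distribution has **mean**
5/6 (mean REE exactly -16.7%) but **median** 0.725 (median REE -27.5%),
because it is right-skewed.  The package's FOCE-I tracks this floor (the
acceptance sweep's per-level omega2 medians land in the band this
distribution implies, with some additional negative bias for omega2_V,
whose information content under this design is weaker).  Any claim that
the *median* REE of
variance-scale estimates stays above about -27% at n = 6 is therefore
unattainable for a correctly behaving ML estimator; bounds around -15 to
-17% are consistent with the mean REE (-1/6) or with medians computed on
the standard-deviation scale (sqrt(0.725) - 1 = -14.8%).  The reporting
layer computes medians on the variance scale, per the study design
implemented here.

## Numerical choices and degenerate inputs

- Predictions are floored at 1e-10 mg/L inside variance terms so the
  objective stays finite when the outer search probes extreme parameters.
- Non-positive-definite linearized covariance matrices get one jitter
  retry, then the objective reports +inf (recorded, not raised).
- omega2 initials equal to zero mean "no random effect on this parameter"
  (structural), not "estimate from zero".
- Datasets must have exactly one EVID=1 dose record at t=0 per subject;
  unbalanced observation schedules are padded and masked internally.

## Scaled-down defaults used in the test suite

The shipped acceptance checks run the sweep at 50 replicates per level
(bias floor) and 30 replicates at levels {10, 50, 80}% with reduced chains
(burn-in cap 1000, 2000 stationary iterations) for the four-method
ordering; these sizes give stable medians/rRMSE orderings while keeping
the whole suite desk-scale.  The full 100-replicate, 10,000-iteration
configuration is the package default for study-scale runs.

## Known limitations

- Diagonal Omega only; no covariance between etas.
- No FO/Laplace variants, no SAEM/importance-sampling EM methods.
- Single-chain MCMC by design (matching the study layout); no multi-chain
  R-hat diagnostics.
- The covariance step is a positive-definiteness check, not a
  standard-error report.
- Estimator comparisons inherit the generator's idealizations listed above.
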