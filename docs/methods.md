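# Methods

## Data-generating mechanism

Each simulated trial draws, in a fixed order so that a `(config, seed)`
pair is bit-reproducible:

1. **Center sizes.** Balanced: `n_total` split as evenly as possible, the
   remainder going one subject each to the lowest-indexed centers. Skewed:
   one multinomial draw of `n_total` subjects into `J` equal-probability
   cells; cells drawn as zero are dropped, so the *realized* center count
   can fall below the target (with `n = 200` and `J = 100` the expected
   realized count is `100·(1 − 0.99²⁰⁰) = 86.6`). Equal cell probabilities
   are used because the skew they induce matches the spread of reported
   example allocations and the realized-center counts quoted for small
   trials; no further skewness parameter is exposed.
2. **Treatment.** 1:1 permuted blocks stratified by center, block size 4
   (configurable, even). A final incomplete block is a freshly permuted
   block truncated to the remaining count — the standard practice; any
   enrollment-order prefix within a center is imbalanced by at most
   `block_size/2`.
3. **Outcomes.** `Y*_ij = α + β_trt X_ij + u_j + ε_ij` with
   `u_j ~ N(0, σ²)`, `ε_ij` standard logistic, `Y_ij = 1{Y*_ij > 0}`;
   equivalently `P(Y=1|X,u) = expit(α + β_trt X + u)`. σ² is set from the
   latent-scale ICC via `σ² = ICC/(1−ICC)·π²/3`.

**Intercept calibration.** By default `α = logit(p0)`: the control event
probability is anchored at the median center (`u = 0`), because the model
is written on the conditional scale and the marginal/conditional gap at the
ICCs of interest (0.025–0.075) is under 2%. A `calibration="marginal"`
switch instead solves `E_u[expit(α+u)] = p0` by Brent root finding with
40-node Gauss–Hermite integration.

**Prescreening.** Simulated trials with no events, or with all events in
one arm, are unanalyzable by every method compared here and are excluded
before fitting. Excluded replicates are dropped, not replaced; summaries
report both the generated and the analyzable counts, so either convention
can be reconstructed.

## Estimators

All five return the treatment log odds ratio with a two-sided test and a
95% interval whose rejection/exclusion decisions agree by construction
(same reference distribution for test and interval).

- **Unadjusted logistic** (marginal estimand). With a single binary
  covariate the ML fit is saturated on the collapsed 2×2 table, so the
  closed forms `log OR = log(ad/bc)`, `SE = √(1/a+1/b+1/c+1/d)` are used
  directly; they agree with IRLS to machine precision (cross-checked
  against `statsmodels` GLM in the tests). Any zero cell puts the MLE on
  the boundary and flags non-convergence.
- **Random-intercept logistic** (conditional). Marginal likelihood
  maximized over `(α, β, log σ)` with L-BFGS-B; each center's integral is
  approximated by adaptive Gauss–Hermite quadrature (9 nodes by default):
  nodes are recentred at the center's posterior mode, found by damped
  Newton steps (≤50, tol 1e-10; the integrand is log-concave so Newton is
  safe), and rescaled by the curvature there. Within a center only the
  per-arm totals `(n0, y0, n1, y1)` matter, so centers sharing totals are
  grouped and weighted. SEs come from the inverse of a central-difference
  Hessian at the optimum; if `σ` sits at its floor (1e-6, imposed by
  optimizing `log σ` with a bound rather than constrained optimization) the
  model has degenerated to the unadjusted fit and the fixed-effect block of
  the information is used. Wald z inference; increasing the node count from
  9 to 25 moves well-behaved estimates by < 1e-4. The implementation agrees
  with `lme4::glmer` (nAGQ = 9) to ~1e-6 on a frozen fixture.
- **Mantel–Haenszel** (conditional). Pooled OR by the classical weighted
  formula; Robins–Breslow–Greenland SE for the log OR; p-value from the MH
  chi-square with continuity correction (a flag disables it) — the default
  pairing of standard software. No 0.5 constant is added to cells: the
  estimator handles zero cells natively, and adding one would distort the
  bias pattern under rare events. Strata with `a_j d_j = b_j c_j = 0`
  contribute nothing; the analyzed-subject count reports only informative
  strata. A fit is flagged non-converged when either pooled sum is zero
  (common OR undefined) **or any stratum has fewer than two subjects** —
  the stratum-size requirement of the standard stratified-test routine.
  The second clause matters: with 100 target centers and a few hundred
  subjects, the probability that *no* center receives exactly one subject
  is small (≈ e^{−100·P(cell count = 1)}), and this, not an undefined OR,
  is what collapses the MH convergence rate in skewed small-sample
  scenarios (≈0% at n = 200, ≈2–3% at n = 500, ≈96% at n = 1000).
- **GEE, exchangeable** (marginal). Fisher scoring for `(α, β)` alternates
  with moment re-estimation of the dispersion
  `φ = Σe²/(N−2)` and working correlation
  `ρ = Σ_{i,j<k} e_ij e_ik / ((Σ_i n_i(n_i−1)/2 − 2)·φ)` from Pearson
  residuals, until the coefficient step is < 1e-8 (≤100 iterations). The
  exchangeable inverse `R⁻¹ = [I − ρ/(1+(n−1)ρ)·J]/(1−ρ)` keeps every
  cluster operation O(n_i). Robust (sandwich) SEs with Wald z inference.
  Estimates and robust SEs match `statsmodels` GEE to ~1e-9 in the
  cross-check test.
- **GEE, Fay–Graubard corrected.** The coefficient is untouched; each
  cluster's score contribution is premultiplied by
  `H_i = diag{(1 − min(b, {D_i'V_i⁻¹D_iΩ}_jj))^{−1/2}}` with `b = 0.75`
  before the meat is assembled. Inference uses a t reference by default
  (`use_t=False` for z), with Satterthwaite degrees of freedom
  `df = (Σ w_i)²/Σ w_i²`, where `w_i = [Ω H_i (D_i'V_i⁻¹D_i) H_i Ω]_ββ`
  is cluster *i*'s working-model contribution to the corrected variance of
  the treatment coefficient; with 5 roughly equal clusters df ≈ 4.8. A
  plain z test on the corrected SE cannot hold the size near nominal with
  so few clusters, which is why the t pairing is the default.

  A note on a tempting "obvious" inequality: because every inflation
  factor is ≥ 1, each cluster's *meat* contribution grows elementwise on
  the diagonal, and on typical data the corrected variance of `β̂_trt`
  exceeds the robust one. After sandwiching with Ω, however, elementwise
  domination of the full covariance diagonal is **not** a theorem for the
  diagonal-matrix form of the correction (the form used by the
  correction's reference software): cross terms can locally deflate a
  diagonal entry. Empirically this affects well under 1% of fits in the
  scenarios studied; the tests assert the per-cluster inflation, which is
  the statement that is actually always true.

## Performance measures

Computed per scenario × method over **converged** fits only: rejection rate
(`p < 0.05`; type I error under the null, power otherwise), geometric-mean
OR (`exp` of the mean log OR), 95% CI coverage against the
estimand-appropriate truth (conditional truth for random-intercept and MH,
marginal truth — `β_c` divided by `√(1+c²σ²)`, `c = 16√3/(15π)`, giving
divisors 1.0145/1.0452 at ICC 0.025/0.075 — for the others), and the
convergence rate out of analyzable (post-prescreen) replicates. A fit
counts as a convergence failure when the fitter said so or when the OR or
SE exceeds 1000. Monte Carlo SEs: `√(p̂(1−p̂)/m)` for proportions; delta
method on the log scale for the mean OR. When fewer than 50 fits survive
(configurable), estimate-based measures are reported as NaN — a handful of
survivors characterizes the failure mechanism, not the estimator.

## Power calibration

`solve_or_for_power` bisects on the conditional OR against a
simulation-estimated power curve (default 2000 replicates per evaluation,
unadjusted test, bisection tolerance 0.01 on the OR scale — the precision
at which such targets are usually quoted). All evaluations share one set of
replicate seeds (common random numbers), which makes the estimated curve
monotone up to residual noise. The solver refuses targets at or below the
test's size at the null boundary and targets unreachable below OR = 100.

## Problem sizes and what the tests show

The acceptance-style tests re-run the key design cells at reduced replicate
counts chosen to keep the whole suite at a few minutes on one core while
leaving the Monte Carlo SE small relative to the effects being checked:
2000 replicates for the 5-center null cell, 1000 for the 100-center powered
cells at n = 200/500, 500 and 300 for the n = 5000 cells. Comparisons use
three binomial MCSEs at the reduced count (observed delta-method MCSEs for
mean ORs). Estimator-level correctness is checked independently of the
simulation study: brute-force integration for the AGHQ likelihood, dense
matrix algebra for both sandwiches, closed forms for the 2×2 and MH
estimators, and third-party fitters (statsmodels, lme4) where available.

The generator emulates the *design* features that drive the phenomena of
interest — stratified blocks, center-size skew, rare events, latent-scale
ICC — and deliberately omits features of real multicenter trials such as
covariates, secular trends, differential consent/missingness, non-normal
center effects and treatment-by-center interaction. Passing tests therefore
demonstrate correct behavior of the estimators under the stated mechanism,
not robustness to those complications.

## Known limitations

- Two-arm, 1:1 allocation only; multi-arm tables are analyzed pairwise
  against a reference arm.
- No covariate adjustment; the models contain only the treatment term.
- The FG degrees-of-freedom formula is one member of a family of
  Satterthwaite-style choices; alternatives differ slightly with very few
  clusters. The z/t choice is exposed as a flag.
- The Mantel–Haenszel "non-convergence" rule intentionally mirrors common
  software (minimum stratum size 2); analysts wanting the pure estimator
  can set `min_stratum_size=0`.
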