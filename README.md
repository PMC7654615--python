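# rarecenter

Simulation and estimation toolkit for **multicenter randomized trials with
binary outcomes and very low event rates**.

When randomization is stratified by center, the analysis should account for
center — but with rare events many centers end up with no events, or with
events in only one arm, and common center-adjusted estimators start to
misbehave: some silently drop participants, some fail to converge, and some
report standard errors that are too small. `rarecenter` lets trial
statisticians quantify these failure modes before writing a statistical
analysis plan. It provides:

- a **trial simulator**: latent-variable logistic outcomes
  `Y*_ij = α + β_trt X_ij + u_j + ε_ij`, `Y_ij = 1{Y*_ij > 0}`, with
  `u_j ~ N(0, σ²)` center effects set by a latent-scale ICC
  (`ICC = σ²/(σ² + π²/3)`), 1:1 permuted-block randomization stratified by
  center (block size 4), and balanced or skewed (multinomial) center sizes;
- **five estimators** of the treatment odds ratio, all returning a common
  `FitResult` (log OR, SE, two-sided p, 95% CI, convergence flag, estimand
  tag):
  1. center-unadjusted logistic regression (marginal),
  2. random-intercept logistic regression fitted by adaptive Gauss–Hermite
     quadrature, 9 nodes by default (conditional),
  3. Mantel–Haenszel common odds ratio
     `OR_MH = Σ_j (a_j d_j / n_j) / Σ_j (b_j c_j / n_j)` with the
     Robins–Breslow–Greenland interval and the continuity-corrected MH
     chi-square test (conditional),
  4. GEE with logit link, exchangeable working correlation and the
     Liang–Zeger robust sandwich variance (marginal),
  5. GEE with the Fay–Graubard small-sample correction (bound `b = 0.75`)
     and Satterthwaite-df t inference (marginal);
- **performance evaluation**: type I error / power, mean OR, 95% CI
  coverage and convergence rate per scenario and method, each with a Monte
  Carlo standard error, scoring conditional estimators against the
  conditional truth and marginal estimators against the attenuated marginal
  truth `β_m = β_c / √(1 + c²σ²)`, `c = 16√3/(15π)`;
- **calibration utilities**: conditional↔marginal odds-ratio conversion and
  a simulation-based solver for the conditional OR giving a target power;
- a **scenario-grid runner** and a thin CLI.

## Worked example

Simulate a 2000-participant trial across 50 centers of uneven size with a
2% control event rate and a true conditional OR of 2, then fit all five
estimators:

```bash
rarecenter simulate --n-total 2000 --n-centers 50 --icc 0.025 --p0 0.02 \
    --true-or 2.0 --skewed --seed 11 -o trial.csv
rarecenter analyze trial.csv
```

Abbreviated output (columns trimmed):

```
method            odds_ratio   ci_low    ci_high   p_value  n_analyzed
unadjusted          1.231     -0.362     0.778      0.475      2000
random_intercept    1.231     -0.362     0.778      0.475      2000
mantel_haenszel     1.217     -0.371     0.763      0.592      1387
gee                 1.234     -0.396     0.817      0.496      2000
gee_fg              1.234     -0.418     0.839      0.504      2000
```

With only ~45 events in 2000 participants, the Mantel–Haenszel analysis
silently drops 613 participants (30.7%) because 16 of the 50 centers
contribute no discordant pairs — the `n_analyzed` column makes the
exclusion visible. The random-intercept fit estimates `σ̂ ≈ 0` here, so its
estimate coincides with the unadjusted one; the Fay–Graubard correction
widens the GEE interval slightly (the confidence limits are on the log-OR
scale).

The same machinery runs whole scenario grids:

```python
from rarecenter import GridSpec, run_grid

spec = GridSpec(n_total=[200], n_centers=[5], icc=[0.025], p0=[0.10],
                size_distribution=["skewed"], replicates=2000, seed=1)
long, summary = run_grid(spec)
```

`summary` then contains, per method, the null rejection rate (e.g. ~0.15
for GEE with 5 centers versus ~0.04–0.05 for the corrected and likelihood
methods), the geometric-mean OR, coverage, and the convergence rate, each
with its Monte Carlo SE.

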