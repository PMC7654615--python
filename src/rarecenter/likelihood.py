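"""Likelihood-based fits: center-unadjusted logistic regression and the
random-intercept logistic model via adaptive Gauss–Hermite quadrature.

Both models contain only the treatment indicator. For the unadjusted model
this means the logistic ML fit is saturated on the collapsed 2x2 table, so
the estimate and Wald standard error have the familiar closed forms

    log OR = log(a d / (b c)),   SE = sqrt(1/a + 1/b + 1/c + 1/d),

which this module uses directly (they coincide with iteratively reweighted
least squares to machine precision and are cheap enough for large simulation
grids).

The random-intercept model maximizes the marginal likelihood

    sum_j log INT prod_i Bernoulli(y_ij; expit(alpha + beta x_ij + u))
                  N(u; 0, sigma^2) du

with each center's integral approximated by Gauss–Hermite quadrature after
recentring and rescaling at the center-specific posterior mode and curvature
(adaptive GHQ). Within a center, subjects in the same arm are exchangeable,
so the integrand depends on the center only through the per-arm totals
(n0, y0, n1, y1); centers sharing those totals are grouped and weighted,
which keeps the cost independent of center count for large balanced designs.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .results import FitResult, failed_fit, wald_result
from .simulate import TrialData

__all__ = ["fit_unadjusted", "fit_random_intercept", "collapse_by_center"]


def collapse_by_center(data: TrialData):
    """Per-center arm totals ``(n0, y0, n1, y1)``, centers sorted by id."""
    _, idx = np.unique(data.center_id, return_inverse=True)
    J = int(idx.max()) + 1
    ones = np.ones_like(data.arm)
    n1 = np.bincount(idx, weights=data.arm, minlength=J)
    n0 = np.bincount(idx, weights=ones - data.arm, minlength=J)
    y1 = np.bincount(idx, weights=data.arm * data.outcome, minlength=J)
    y0 = np.bincount(idx, weights=(1 - data.arm) * data.outcome, minlength=J)
    return n0, y0, n1, y1


def fit_unadjusted(data: TrialData) -> FitResult:
    """Logistic regression of outcome on treatment, ignoring center.

    Targets the marginal odds ratio. With any zero cell in the collapsed
    2x2 table the MLE lies on the boundary (the treatment coefficient
    diverges), and the fit is flagged as non-converged.
    """
    n0, y0, n1, y1 = collapse_by_center(data)
    a = float(y1.sum())               # treated, event
    b = float(n1.sum()) - a           # treated, no event
    c = float(y0.sum())               # control, event
    d = float(n0.sum()) - c           # control, no event
    n = data.n_subjects
    if min(a, b, c, d) <= 0:
        return failed_fit("unadjusted", n, {"table": (a, b, c, d)})
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return wald_result("unadjusted", log_or, se, n,
                       extras={"alpha": math.log(c / d)})


def _group_centers(n0, y0, n1, y1):
    stacked = np.column_stack([n0, y0, n1, y1]).astype(np.int64)
    groups, counts = np.unique(stacked, axis=0, return_counts=True)
    return (groups[:, 0].astype(float), groups[:, 1].astype(float),
            groups[:, 2].astype(float), groups[:, 3].astype(float),
            counts.astype(float))


_SIGMA_FLOOR = 1e-6
_LOG_SIGMA_BOUNDS = (math.log(_SIGMA_FLOOR), math.log(10.0))


def aghq_loglik(theta, n0, y0, n1, y1, weights, nodes, node_w,
                mode_cache=None, newton_iter=50, newton_tol=1e-10):
    """Marginal log-likelihood of the random-intercept model by adaptive GHQ.

    ``theta = (alpha, beta, log sigma)``; the remaining arrays describe
    grouped centers (per-arm totals plus group multiplicities ``weights``).
    The posterior mode of each center's random effect is located by damped
    Newton steps (the integrand is log-concave in u), then ``len(nodes)``
    Hermite nodes are centered at the mode and scaled by the curvature.
    """
    alpha, beta, log_sigma = theta
    sigma = max(math.exp(log_sigma), _SIGMA_FLOOR)
    s2 = sigma * sigma
    u = (np.zeros_like(n0) if mode_cache is None
         else mode_cache.copy())
    for _ in range(newton_iter):
        p0 = expit(alpha + u)
        p1 = expit(alpha + beta + u)
        grad = (y0 - n0 * p0) + (y1 - n1 * p1) - u / s2
        curv = n0 * p0 * (1 - p0) + n1 * p1 * (1 - p1) + 1.0 / s2
        step = np.clip(grad / curv, -4.0, 4.0)
        u += step
        if np.abs(step).max() < newton_tol:
            break
    p0 = expit(alpha + u)
    p1 = expit(alpha + beta + u)
    curv = n0 * p0 * (1 - p0) + n1 * p1 * (1 - p1) + 1.0 / s2
    scale = 1.0 / np.sqrt(curv)
    uk = u[:, None] + math.sqrt(2.0) * scale[:, None] * nodes[None, :]
    eta0 = alpha + uk
    eta1 = alpha + beta + uk
    # log f(y | u) + log phi(u) up to the N(0, s2) normalizing constant
    h = (y0[:, None] * eta0 - n0[:, None] * np.logaddexp(0.0, eta0)
         + y1[:, None] * eta1 - n1[:, None] * np.logaddexp(0.0, eta1)
         - uk * uk / (2.0 * s2))
    lse = logsumexp(np.log(node_w)[None, :] + nodes[None, :] ** 2 + h, axis=1)
    ll = lse + np.log(math.sqrt(2.0) * scale) - 0.5 * math.log(
        2.0 * math.pi * s2)
    return float(weights @ ll), u


def _numeric_hessian(f, x, rel_step=1e-4):
    """Central-difference Hessian of scalar f at x."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def _starting_values(n0, y0, n1, y1, weights):
    a = float(weights @ y1) + 0.5
    b = float(weights @ (n1 - y1)) + 0.5
    c = float(weights @ y0) + 0.5
    d = float(weights @ (n0 - y0)) + 0.5
    return np.array([math.log(c / d), math.log(a * d / (b * c)),
                     math.log(0.5)])


def fit_random_intercept(data: TrialData, n_quad: int = 9) -> FitResult:
    """ML fit of the random-intercept logistic model by adaptive GHQ.

    Returns the conditional (within-center) log odds ratio with a Wald z
    test and normal-theory 95% CI; the estimated random-effect SD is
    reported in ``extras["sigma"]``. The variance parameter is optimized on
    the log-sigma scale with a floor near zero; at the floor the model
    degenerates toward the unadjusted fit and standard errors are taken
    from the fixed-effect block of the information matrix.
    """
    n0, y0, n1, y1 = collapse_by_center(data)
    if n0.size < 2:
        raise ValueError("random-intercept fit requires >= 2 centers")
    gn0, gy0, gn1, gy1, gw = _group_centers(n0, y0, n1, y1)
    nodes, node_w = np.polynomial.hermite.hermgauss(n_quad)
    cache = {"modes": None}

    def nll(theta):
        ll, modes = aghq_loglik(theta, gn0, gy0, gn1, gy1, gw,
                                nodes, node_w, cache["modes"])
        cache["modes"] = modes
        return -ll

    x0 = _starting_values(gn0, gy0, gn1, gy1, gw)
    res = minimize(
        nll, x0, method="L-BFGS-B",
        bounds=[(-30, 30), (-30, 30), _LOG_SIGMA_BOUNDS],
        options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
    )
    n = data.n_subjects
    sigma = math.exp(res.x[2])
    extras = {"sigma": sigma, "sigma2": sigma**2, "alpha": res.x[0],
              "loglik": -res.fun, "n_quad": n_quad}
    if not np.all(np.isfinite(res.x)):
        return failed_fit("random_intercept", n, extras)
    at_floor = res.x[2] <= _LOG_SIGMA_BOUNDS[0] + 1e-8
    H = _numeric_hessian(nll, res.x)
    se = math.nan
    if not at_floor:
        try:
            cov = np.linalg.inv(H)
            if cov[1, 1] > 0:
                se = math.sqrt(cov[1, 1])
        except np.linalg.LinAlgError:
            pass
    if not math.isfinite(se):
        # boundary or ill-conditioned sigma block: use the fixed-effect block
        try:
            cov2 = np.linalg.inv(H[:2, :2])
            if cov2[1, 1] > 0:
                se = math.sqrt(cov2[1, 1])
        except np.linalg.LinAlgError:
            pass
    converged = bool(res.success) and math.isfinite(se)
    if not math.isfinite(se):
        return failed_fit("random_intercept", n, extras)
    return wald_result("random_intercept", float(res.x[1]), se, n,
                       converged=converged, extras=extras)
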