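"""Logistic GEE with exchangeable working correlation, the Liang–Zeger
robust (sandwich) variance, and the Fay–Graubard small-sample correction.

The mean model is ``logit(mu_ij) = alpha + beta_trt x_ij`` with clusters
defined by center. Coefficients solve the estimating equation

    sum_i D_i' V_i^{-1} (Y_i - mu_i) = 0,

with ``D_i = d mu_i / d beta'`` and working covariance
``V_i = phi A_i^{1/2} R(rho) A_i^{1/2}``, ``R`` exchangeable. Fisher scoring
for beta alternates with moment re-estimation of the dispersion ``phi`` and
the working correlation ``rho`` from Pearson residuals. Because ``R^{-1}``
has the closed form ``[I - rho/(1 + (n-1) rho) J] / (1 - rho)``, all
cluster-level quantities are computed in O(cluster size) without forming
any n x n matrix.

The robust variance is ``V = Omega M Omega`` with bread
``Omega = (sum_i D_i' V_i^{-1} D_i)^{-1}`` and meat
``M = sum_i g_i g_i'``, ``g_i = D_i' V_i^{-1} r_i``. The Fay–Graubard
correction inflates each cluster's meat contribution by the diagonal matrix
``H_i = diag{(1 - min(b, {D_i' V_i^{-1} D_i Omega}_jj))^{-1/2}}`` (bound
``b = 0.75`` by default) and pairs the corrected variance with a t
reference whose degrees of freedom come from a Satterthwaite approximation,
treating the per-cluster variance contributions as independent scaled
chi-square(1) terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .results import FitResult, failed_fit, wald_result
from .simulate import TrialData

__all__ = ["GeeState", "fit_gee_exchangeable", "fay_graubard_correct"]


@dataclass
class GeeState:
    """Converged GEE fit with the per-cluster blocks needed for corrections.

    ``bread_blocks[i]`` is ``D_i' V_i^{-1} D_i`` (2x2) and
    ``score_blocks[i]`` is ``g_i = D_i' V_i^{-1} r_i`` (length 2) at the
    returned coefficients; ``omega`` is the inverse of the summed bread.
    """

    beta: np.ndarray               # (alpha, beta_trt)
    rho: float
    scale: float
    omega: np.ndarray              # 2x2 model-based bread inverse
    bread_blocks: list[np.ndarray]
    score_blocks: list[np.ndarray]
    cluster_sizes: np.ndarray
    n_subjects: int
    converged: bool
    n_iter: int

    @property
    def robust_cov(self) -> np.ndarray:
        meat = sum(np.outer(g, g) for g in self.score_blocks)
        return self.omega @ meat @ self.omega


def _split_clusters(data: TrialData):
    order = np.argsort(data.center_id, kind="stable")
    cid = data.center_id[order]
    y = data.outcome[order].astype(float)
    x = data.arm[order].astype(float)
    _, starts = np.unique(cid, return_index=True)
    bounds = np.append(starts, cid.size)
    return [(y[s:e], x[s:e]) for s, e in zip(bounds[:-1], bounds[1:])]


def _cluster_blocks(clusters, beta, rho, scale):
    """Summed bread/score plus per-cluster blocks at given parameters."""
    bread_sum = np.zeros((2, 2))
    score_sum = np.zeros(2)
    bread_blocks, score_blocks = [], []
    for y, x in clusters:
        eta = beta[0] + beta[1] * x
        mu = expit(eta)
        v = mu * (1 - mu)
        sqrt_v = np.sqrt(v)
        X = np.column_stack([np.ones_like(x), x])
        M = sqrt_v[:, None] * X          # A^{1/2} X
        s = (y - mu) / sqrt_v            # A^{-1/2} r
        n = y.size
        r_eff = rho if n > 1 else 0.0
        shrink = r_eff / (1.0 + (n - 1) * r_eff)
        m1 = M.sum(axis=0)
        B = (M.T @ M - shrink * np.outer(m1, m1)) / ((1 - r_eff) * scale)
        g = (M.T @ s - shrink * m1 * s.sum()) / ((1 - r_eff) * scale)
        bread_blocks.append(B)
        score_blocks.append(g)
        bread_sum += B
        score_sum += g
    return bread_sum, score_sum, bread_blocks, score_blocks


def _moment_estimates(clusters, beta):
    """Dispersion and exchangeable correlation from Pearson residuals."""
    n_params = 2
    sq_sum = 0.0
    pair_sum = 0.0
    n_pairs = 0.0
    n_obs = 0
    for y, x in clusters:
        mu = expit(beta[0] + beta[1] * x)
        e = (y - mu) / np.sqrt(mu * (1 - mu))
        tot = e.sum()
        sq = float(e @ e)
        sq_sum += sq
        pair_sum += (tot * tot - sq) / 2.0
        n = y.size
        n_pairs += n * (n - 1) / 2.0
        n_obs += n
    scale = sq_sum / max(n_obs - n_params, 1)
    denom = (n_pairs - n_params) * scale
    rho = pair_sum / denom if denom > 0 else 0.0
    max_n = max(y.size for y, _ in clusters)
    lo = -0.95 / (max_n - 1) if max_n > 1 else 0.0
    return scale, float(np.clip(rho, lo, 0.999))


def _init_beta(clusters):
    y_all = np.concatenate([y for y, _ in clusters])
    x_all = np.concatenate([x for _, x in clusters])
    a = y_all[x_all == 1].sum() + 0.5
    b = (x_all == 1).sum() - y_all[x_all == 1].sum() + 0.5
    c = y_all[x_all == 0].sum() + 0.5
    d = (x_all == 0).sum() - y_all[x_all == 0].sum() + 0.5
    return np.array([math.log(c / d), math.log(a * d / (b * c))])


def fit_gee_exchangeable(
    data: TrialData,
    max_iter: int = 100,
    tol: float = 1e-8,
    return_state: bool = False,
) -> FitResult | tuple[FitResult, GeeState]:
    """Fit the exchangeable-correlation logistic GEE with robust SEs.

    The Wald test and 95% CI use a standard normal reference on the robust
    (sandwich) standard error; the working correlation and dispersion are
    reported in ``extras``. Requires at least two clusters.
    """
    clusters = _split_clusters(data)
    if len(clusters) < 2:
        raise ValueError("GEE requires >= 2 clusters (centers)")
    n = data.n_subjects
    beta = _init_beta(clusters)
    rho, scale = 0.0, 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        scale, rho = _moment_estimates(clusters, beta)
        bread_sum, score_sum, _, _ = _cluster_blocks(
            clusters, beta, rho, scale)
        try:
            step = np.linalg.solve(bread_sum, score_sum)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if not np.all(np.isfinite(beta)):
            break
        if np.abs(step).max() < tol:
            converged = True
            break
    state = None
    if np.all(np.isfinite(beta)):
        scale, rho = _moment_estimates(clusters, beta)
        bread_sum, _, bread_blocks, score_blocks = _cluster_blocks(
            clusters, beta, rho, scale)
        try:
            omega = np.linalg.inv(bread_sum)
            state = GeeState(
                beta=beta, rho=rho, scale=scale, omega=omega,
                bread_blocks=bread_blocks, score_blocks=score_blocks,
                cluster_sizes=np.array([y.size for y, _ in clusters]),
                n_subjects=n, converged=converged, n_iter=it)
        except np.linalg.LinAlgError:
            converged = False
    if state is None:
        result = failed_fit("gee", n)
        return (result, None) if return_state else result
    cov = state.robust_cov
    se = math.sqrt(cov[1, 1]) if cov[1, 1] > 0 else math.nan
    result = wald_result(
        "gee", float(beta[1]), se, n, converged=converged,
        extras={"rho": rho, "scale": scale, "alpha": float(beta[0]),
                "n_iter": it})
    if not math.isfinite(se):
        result = failed_fit("gee", n, result.extras)
    return (result, state) if return_state else result


def fay_graubard_correct(state: GeeState, b: float = 0.75,
                         use_t: bool = True) -> FitResult:
    """Bias-corrected sandwich variance with small-sample t inference.

    The coefficient estimate is unchanged; only the variance is inflated.
    ``b < 1`` bounds the per-cluster leverage used in the inflation factors,
    guarding against near-singular adjustments. With ``use_t`` (default) the
    p-value and CI use a t reference with Satterthwaite-type degrees of
    freedom (reported in ``extras["df"]``); otherwise a normal reference.
    """
    if state is None:
        return failed_fit("gee_fg", 0)
    if not 0 < b < 1:
        raise ValueError(f"bound b must lie in (0, 1), got {b!r}")
    omega = state.omega
    meat = np.zeros((2, 2))
    w = []  # per-cluster contribution to var(beta_trt), working model
    for B, g in zip(state.bread_blocks, state.score_blocks):
        lever = np.diag(B @ omega)
        adj = 1.0 / np.sqrt(1.0 - np.minimum(b, lever))
        ga = adj * g
        meat += np.outer(ga, ga)
        contrib = omega @ (adj[:, None] * B * adj[None, :]) @ omega
        w.append(contrib[1, 1])
    v_fg = omega @ meat @ omega
    w = np.asarray(w)
    df = float(w.sum() ** 2 / (w ** 2).sum()) if (w ** 2).sum() > 0 else (
        len(w) - 1.0)
    se = math.sqrt(v_fg[1, 1]) if v_fg[1, 1] > 0 else math.nan
    extras = {"df": df, "rho": state.rho, "scale": state.scale, "b": b}
    if not math.isfinite(se):
        return failed_fit("gee_fg", state.n_subjects, extras)
    return wald_result(
        "gee_fg", float(state.beta[1]), se, state.n_subjects,
        converged=state.converged, df=df if use_t else None, extras=extras)


def fay_graubard_cov(state: GeeState, b: float = 0.75) -> np.ndarray:
    """The corrected covariance matrix itself (for inspection and tests)."""
    omega = state.omega
    meat = np.zeros((2, 2))
    for B, g in zip(state.bread_blocks, state.score_blocks):
        adj = 1.0 / np.sqrt(1.0 - np.minimum(b, np.diag(B @ omega)))
        ga = adj * g
        meat += np.outer(ga, ga)
    return omega @ meat @ omega
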