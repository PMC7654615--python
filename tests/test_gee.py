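import math

import numpy as np
import pytest
from scipy.special import expit

from rarecenter import (ScenarioConfig, TrialData, fit_gee_exchangeable,
                        fit_unadjusted, generate_trial)
from rarecenter.gee import fay_graubard_correct, fay_graubard_cov


def oracle_blocks(trial, beta, rho, scale):
    """Literal dense-matrix evaluation of the per-cluster GEE quantities."""
    blocks = []
    for cid in np.unique(trial.center_id):
        mask = trial.center_id == cid
        x = trial.arm[mask].astype(float)
        y = trial.outcome[mask].astype(float)
        n = x.size
        mu = expit(beta[0] + beta[1] * x)
        A = np.diag(mu * (1 - mu))
        R = np.full((n, n), rho) + (1 - rho) * np.eye(n)
        V = scale * np.sqrt(A) @ R @ np.sqrt(A)
        D = A @ np.column_stack([np.ones(n), x])
        Vinv = np.linalg.inv(V)
        blocks.append((D.T @ Vinv @ D, D.T @ Vinv @ (y - mu)))
    return blocks


def oracle_sandwiches(trial, state, b=0.75):
    """Dense evaluation of the robust and Fay–Graubard covariances."""
    blocks = oracle_blocks(trial, state.beta, state.rho, state.scale)
    bread = sum(B for B, _ in blocks)
    omega = np.linalg.inv(bread)
    meat = sum(np.outer(g, g) for _, g in blocks)
    meat_fg = np.zeros((2, 2))
    for B, g in blocks:
        adj = np.diag(1.0 / np.sqrt(1.0 - np.minimum(b, np.diag(B @ omega))))
        meat_fg += adj @ np.outer(g, g) @ adj
    return omega @ meat @ omega, omega @ meat_fg @ omega


class TestExchangeableFit:
    def test_sandwich_matches_matrix_oracle(self, toy_trial):
        res, state = fit_gee_exchangeable(toy_trial, return_state=True)
        assert res.converged
        v_oracle, vfg_oracle = oracle_sandwiches(toy_trial, state)
        np.testing.assert_allclose(state.robust_cov, v_oracle, atol=1e-10)
        np.testing.assert_allclose(fay_graubard_cov(state), vfg_oracle,
                                   atol=1e-10)

    def test_estimating_equation_solved(self, toy_trial):
        _, state = fit_gee_exchangeable(toy_trial, return_state=True)
        blocks = oracle_blocks(toy_trial, state.beta, state.rho, state.scale)
        score = sum(g for _, g in blocks)
        assert np.linalg.norm(score) < 1e-6

    def test_singleton_clusters_reduce_to_unadjusted(self):
        rng = np.random.default_rng(15)
        n = 120
        arm = rng.integers(0, 2, n)
        outcome = (rng.random(n) < expit(-1.2 + 0.7 * arm)).astype(int)
        trial = TrialData(np.arange(1, n + 1), arm, outcome)
        res, state = fit_gee_exchangeable(trial, return_state=True)
        un = fit_unadjusted(trial)
        assert res.log_or == pytest.approx(un.log_or, abs=1e-8)
        # with clusters of size 1 the sandwich is the dense-matrix oracle
        # with rho irrelevant (no within-cluster pairs)
        v_oracle, _ = oracle_sandwiches(trial, state)
        np.testing.assert_allclose(state.robust_cov, v_oracle, atol=1e-12)

    def test_rho_consistent_under_independence(self):
        config = ScenarioConfig(n_total=4000, n_centers_target=50, icc=0.0,
                                p0=0.2, true_conditional_or=1.5)
        trial = generate_trial(config, np.random.default_rng(16))
        res = fit_gee_exchangeable(trial)
        assert abs(res.extras["rho"]) < 0.02

    def test_agrees_with_statsmodels(self, rng):
        import statsmodels.api as sm
        from statsmodels.genmod.cov_struct import Exchangeable

        config = ScenarioConfig(n_total=500, n_centers_target=10, icc=0.05,
                                p0=0.15, true_conditional_or=1.8,
                                size_distribution="skewed")
        trial = generate_trial(config, rng)
        res = fit_gee_exchangeable(trial)
        model = sm.GEE.from_formula(
            "outcome ~ arm", groups="center_id", data=trial.to_frame(),
            family=sm.families.Binomial(), cov_struct=Exchangeable())
        ref = model.fit()
        assert res.log_or == pytest.approx(ref.params["arm"], abs=1e-6)
        assert res.se == pytest.approx(ref.bse["arm"], rel=1e-6)

    def test_invariant_to_cluster_order_and_labels(self, rng):
        config = ScenarioConfig(n_total=300, n_centers_target=8, icc=0.05,
                                p0=0.2, true_conditional_or=1.4)
        trial = generate_trial(config, rng)
        res = fit_gee_exchangeable(trial)
        perm = np.random.default_rng(1).permutation(trial.n_subjects)
        relabeled = TrialData(trial.center_id[perm] * 13 + 5,
                              trial.arm[perm], trial.outcome[perm])
        res2 = fit_gee_exchangeable(relabeled)
        assert res2.log_or == pytest.approx(res.log_or, abs=1e-10)
        assert res2.se == pytest.approx(res.se, rel=1e-10)

    def test_requires_two_clusters(self):
        trial = TrialData([1, 1, 1, 1], [0, 0, 1, 1], [0, 1, 0, 1])
        with pytest.raises(ValueError):
            fit_gee_exchangeable(trial)


class TestFayGraubard:
    def test_meat_contributions_inflated_elementwise(self, rng):
        # the correction scales each cluster's score by factors >= 1, so
        # every per-cluster meat diagonal grows (the bread is untouched)
        for seed in range(5):
            config = ScenarioConfig(
                n_total=150, n_centers_target=5, icc=0.025, p0=0.15,
                true_conditional_or=1.0, size_distribution="skewed")
            trial = generate_trial(config, np.random.default_rng(seed))
            _, state = fit_gee_exchangeable(trial, return_state=True)
            if state is None:
                continue
            omega = state.omega
            for B, g in zip(state.bread_blocks, state.score_blocks):
                adj = 1.0 / np.sqrt(
                    1.0 - np.minimum(0.75, np.diag(B @ omega)))
                assert (adj >= 1.0 - 1e-12).all()
                assert ((adj * g)**2 >= g**2 - 1e-12).all()

    def test_point_estimate_unchanged(self, toy_trial):
        res, state = fit_gee_exchangeable(toy_trial, return_state=True)
        fg = fay_graubard_correct(state)
        assert fg.log_or == res.log_or
        assert fg.se > res.se

    def test_t_reference_widens_interval(self, toy_trial):
        _, state = fit_gee_exchangeable(toy_trial, return_state=True)
        fg_t = fay_graubard_correct(state, use_t=True)
        fg_z = fay_graubard_correct(state, use_t=False)
        assert fg_t.extras["df"] > 0
        assert (fg_t.ci_high - fg_t.ci_low) > (fg_z.ci_high - fg_z.ci_low)

    def test_bound_validation(self, toy_trial):
        _, state = fit_gee_exchangeable(toy_trial, return_state=True)
        with pytest.raises(ValueError):
            fay_graubard_correct(state, b=1.5)

    def test_corrected_rejects_less_than_robust_under_null(self):
        # few clusters: the robust z test is anticonservative, the
        # corrected t test is near nominal
        config = ScenarioConfig(n_total=200, n_centers_target=5, icc=0.025,
                                p0=0.10, true_conditional_or=1.0,
                                size_distribution="skewed")
        ss = np.random.SeedSequence(17)
        rej_gee, rej_fg = [], []
        for child in ss.spawn(300):
            trial = generate_trial(config, np.random.default_rng(child))
            res, state = fit_gee_exchangeable(trial, return_state=True)
            if state is None or not res.converged:
                continue
            fg = fay_graubard_correct(state)
            rej_gee.append(res.p_value < 0.05)
            rej_fg.append(fg.p_value < 0.05)
        assert np.mean(rej_fg) < np.mean(rej_gee)

    def test_matches_robust_with_many_clusters(self):
        config = ScenarioConfig(n_total=4000, n_centers_target=100,
                                icc=0.025, p0=0.10, true_conditional_or=1.0)
        trial = generate_trial(config, np.random.default_rng(18))
        res, state = fit_gee_exchangeable(trial, return_state=True)
        fg = fay_graubard_correct(state, use_t=False)
        assert fg.se == pytest.approx(res.se, rel=0.05)
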