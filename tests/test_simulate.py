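import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rarecenter import (ScenarioConfig, assign_center_sizes, generate_trial,
                        icc_to_sigma2, permuted_block_randomize,
                        prescreen_trial, sigma2_to_icc)
from rarecenter.simulate import LOGISTIC_VARIANCE, calibrate_intercept


class TestIccConversion:
    @pytest.mark.parametrize("icc, expected", [
        (0.0, 0.0),
        (0.5, math.pi**2 / 3),          # equal variance shares
        (0.025, 0.08436),               # 0.025/0.975 * pi^2/3
    ])
    def test_known_values(self, icc, expected):
        assert icc_to_sigma2(icc) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("bad", [-0.01, 1.0, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            icc_to_sigma2(bad)

    @given(st.floats(min_value=0.0, max_value=0.99))
    def test_roundtrip_identity(self, icc):
        assert sigma2_to_icc(icc_to_sigma2(icc)) == pytest.approx(
            icc, abs=1e-12)


class TestCenterSizes:
    def test_balanced_divisible(self, rng):
        sizes = assign_center_sizes(500, 5, "balanced", rng)
        assert list(sizes) == [100] * 5

    def test_balanced_remainder_goes_to_first_centers(self, rng):
        sizes = assign_center_sizes(503, 5, "balanced", rng)
        assert list(sizes) == [101, 101, 101, 100, 100]

    def test_skewed_conserves_total_and_drops_empty(self, rng):
        for _ in range(50):
            sizes = assign_center_sizes(200, 100, "skewed", rng)
            assert sizes.sum() == 200
            assert (sizes > 0).all()
            assert sizes.size <= 100

    def test_skewed_mean_realized_center_count(self, rng):
        # one equal-probability multinomial draw; empty cells vanish, so the
        # expected realized count is J * (1 - (1 - 1/J)^n)
        draws = 500
        counts = [assign_center_sizes(200, 100, "skewed", rng).size
                  for _ in range(draws)]
        expected = 100 * (1 - 0.99**200)
        mcse = np.std(counts, ddof=1) / math.sqrt(draws)
        assert abs(np.mean(counts) - expected) < 3 * mcse


class TestPermutedBlocks:
    def test_complete_blocks_balance_exactly(self, rng):
        arms = permuted_block_randomize(np.array([8]), 4, rng)
        assert arms.sum() == 4

    def test_truncated_final_block_bounds_imbalance(self, rng):
        treated = {int(permuted_block_randomize(np.array([6]), 4, rng).sum())
                   for _ in range(300)}
        assert treated <= {2, 3, 4}
        assert {2, 4} & treated  # truncation actually varies the count

    @given(st.lists(st.integers(min_value=1, max_value=25), min_size=1,
                    max_size=6), st.integers(min_value=0, max_value=2**31))
    def test_any_prefix_imbalance_bounded(self, sizes, seed):
        rng = np.random.default_rng(seed)
        arms = permuted_block_randomize(np.array(sizes), 4, rng)
        pos = 0
        for size in sizes:
            center = arms[pos:pos + size]
            pos += size
            running = np.cumsum(2 * center - 1)
            assert np.abs(running).max() <= 2

    def test_odd_block_size_rejected(self, rng):
        with pytest.raises(ValueError):
            permuted_block_randomize(np.array([4]), 3, rng)


class TestGenerateTrial:
    def test_null_control_rate_matches_p0(self):
        config = ScenarioConfig(n_total=100_000, n_centers_target=10,
                                icc=0.0, p0=0.10)
        trial = generate_trial(config, np.random.default_rng(5))
        control = trial.outcome[trial.arm == 0]
        tol = 3 * math.sqrt(0.1 * 0.9 / control.size)
        assert control.mean() == pytest.approx(0.10, abs=tol)

    def test_treated_rate_closed_form(self):
        # expit(logit(0.1) + log 3) = 0.25 when sigma = 0
        config = ScenarioConfig(n_total=100_000, n_centers_target=10,
                                icc=0.0, p0=0.10, true_conditional_or=3.0)
        trial = generate_trial(config, np.random.default_rng(6))
        treated = trial.outcome[trial.arm == 1]
        tol = 3 * math.sqrt(0.25 * 0.75 / treated.size)
        assert treated.mean() == pytest.approx(0.25, abs=tol)

    def test_bit_reproducibility(self):
        config = ScenarioConfig(n_total=500, n_centers_target=20, icc=0.05,
                                p0=0.05, size_distribution="skewed")
        t1 = generate_trial(config, np.random.default_rng(77))
        t2 = generate_trial(config, np.random.default_rng(77))
        assert np.array_equal(t1.center_id, t2.center_id)
        assert np.array_equal(t1.arm, t2.arm)
        assert np.array_equal(t1.outcome, t2.outcome)

    def test_marginal_calibration_hits_p0_on_average(self):
        config = ScenarioConfig(n_total=200_000, n_centers_target=400,
                                icc=0.3, p0=0.05, calibration="marginal")
        trial = generate_trial(config, np.random.default_rng(8))
        control = trial.outcome[trial.arm == 0]
        tol = 4 * math.sqrt(0.05 * 0.95 / control.size) + 0.005
        assert control.mean() == pytest.approx(0.05, abs=tol)

    def test_conditional_intercept_is_logit_p0(self):
        assert calibrate_intercept(0.1, 1.0, "conditional") == pytest.approx(
            math.log(0.1 / 0.9))

    def test_latent_variance_partition(self):
        # sigma^2 from the ICC plus logistic noise reproduces the ICC share
        sigma2 = icc_to_sigma2(0.075)
        assert sigma2 / (sigma2 + LOGISTIC_VARIANCE) == pytest.approx(0.075)


class TestPrescreen:
    def test_no_events(self, rng):
        config = ScenarioConfig(n_total=40, n_centers_target=2, icc=0.0,
                                p0=0.05)
        trial = generate_trial(config, rng)
        trial.outcome[:] = 0
        assert prescreen_trial(trial) == "exclude_no_events"

    def test_one_arm_only(self, rng):
        config = ScenarioConfig(n_total=40, n_centers_target=2, icc=0.0,
                                p0=0.05)
        trial = generate_trial(config, rng)
        trial.outcome[:] = 0
        trial.outcome[np.flatnonzero(trial.arm == 1)[:5]] = 1
        assert prescreen_trial(trial) == "exclude_one_arm_only"

    def test_retained(self, rng):
        config = ScenarioConfig(n_total=40, n_centers_target=2, icc=0.0,
                                p0=0.05)
        trial = generate_trial(config, rng)
        trial.outcome[np.flatnonzero(trial.arm == 1)[0]] = 1
        trial.outcome[np.flatnonzero(trial.arm == 0)[0]] = 1
        assert prescreen_trial(trial) == "retain"


def test_trial_csv_roundtrip(tmp_path, rng):
    config = ScenarioConfig(n_total=60, n_centers_target=3, icc=0.025,
                            p0=0.2, size_distribution="skewed")
    trial = generate_trial(config, rng)
    path = tmp_path / "trial.csv"
    trial.to_csv(path)
    assert path.read_text().splitlines()[0] == "center_id,arm,outcome"
    from rarecenter import TrialData

    back = TrialData.from_csv(path)
    assert np.array_equal(back.outcome, trial.outcome)
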