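"""Unit and property tests for the two-state Kalman learner."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motorlearn import (
    LearnerParams,
    PerturbationSchedule,
    asymptotic_compensation,
    generate_observations,
    kalman_step,
    run_step_protocol,
    simulate_learner,
    steady_state_solution,
)
from motorlearn.learner import StepProtocol

from conftest import seed_set


class TestParams:
    def test_defaults_validate(self, default_params):
        assert default_params.A[0, 0] == 0.998  # slow state retains more
        assert default_params.A[1, 1] == 0.75
        assert np.allclose(default_params.P0, default_params.Q)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(A=np.diag([1.2, 0.75])),      # retention > 1
            dict(A=np.array([[0.9, 0.1], [0.0, 0.7]])),  # non-diagonal
            dict(Q=np.diag([-1e-7, 1e-7])),
            dict(R=0.0),
            dict(P0=np.array([[1.0, 2.0], [0.5, 1.0]])),  # asymmetric
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LearnerParams(**kwargs)


class TestGenerateObservations:
    def test_noise_free_fixed_point(self):
        params = LearnerParams(Q=np.zeros((2, 2)), R=1e-300)
        z = generate_observations(params, 100, seed=0)
        assert np.allclose(z, 0.0, atol=1e-140)

    def test_seeded_determinism(self, default_params):
        z1 = generate_observations(default_params, 500, seed=42)
        z2 = generate_observations(default_params, 500, seed=42)
        assert np.array_equal(z1, z2)
        assert not np.array_equal(z1, generate_observations(default_params, 500, seed=43))

    def test_stationary_variance_matches_closed_form(self, default_params):
        # closed form: sum_i q_i/(1-a_i^2) + R for two independent AR(1) states
        a = np.diag(default_params.A)
        q = np.diag(default_params.Q)
        expected = float(np.sum(q / (1 - a**2)) + default_params.R)
        # ensemble estimate: the slow state decorrelates over ~1/(1-a²) ≈ 250
        # trials, so pool draws 2000 trials apart across independent seeds
        n, n_seeds = 10_000, 100
        picks = np.arange(1999, n, 2000)
        samples = np.concatenate(
            [
                generate_observations(default_params, n, seed=int(s))[picks]
                for s in seed_set(7, n_seeds)
            ]
        )
        est = samples.var(ddof=1)
        se = est * np.sqrt(2.0 / (len(samples) - 1))
        assert abs(est - expected) < 3 * se
        assert expected == pytest.approx(3.37e-4, rel=0.01)

    def test_nonpositive_n_trials_rejected(self, default_params):
        with pytest.raises(ValueError):
            generate_observations(default_params, 0, seed=0)


class TestKalmanStep:
    def test_zero_error_no_update(self, default_params):
        step = kalman_step(default_params, np.zeros(2), default_params.Q, z=0.0)
        assert step.innovation == 0.0
        assert np.allclose(step.posterior_x, 0.0)

    def test_scalar_equivalent_gain(self, default_params):
        # with P = diag(p, 0) and H = [1, 1] the gain reduces to [p/(p+R), 0]
        p, r = 1e-4, 3e-4
        step = kalman_step(default_params, np.zeros(2), np.diag([p, 0.0]), z=0.5)
        assert step.gain[0] == pytest.approx(p / (p + r), rel=1e-12)
        assert step.gain[1] == 0.0
        assert step.gain[0] == pytest.approx(0.25, rel=1e-10)

    def test_infinite_noise_limit(self, default_params):
        params = LearnerParams(R=default_params.R * 1e6)
        step = kalman_step(params, np.zeros(2), np.diag([1e-4, 1e-4]), z=1.0)
        assert np.all(np.abs(step.gain) < 1e-3)

    def test_update_equations(self, default_params):
        # direct check of the matrix recursion against its definition
        rng = np.random.default_rng(3)
        prior_x = rng.normal(size=2)
        M = rng.normal(size=(2, 2))
        prior_P = M @ M.T
        z = 0.7
        step = kalman_step(default_params, prior_x, prior_P, z)
        H, R = default_params.H, default_params.R
        S = H @ prior_P @ H + R
        K = prior_P @ H / S
        y = z - H @ prior_x
        assert step.innovation == pytest.approx(y)
        assert step.innovation_variance == pytest.approx(S)
        assert np.allclose(step.gain, K)
        assert np.allclose(step.posterior_x, prior_x + K * y)
        assert np.allclose(step.posterior_P, (np.eye(2) - np.outer(K, H)) @ prior_P)
        assert np.allclose(step.next_prior_x, default_params.A @ step.posterior_x)


class TestSimulateLearner:
    def test_matches_kalman_step_chain(self, default_params):
        obs = generate_observations(default_params, 50, seed=9)
        trace = simulate_learner(default_params, obs)
        x = default_params.A @ default_params.x0
        P = default_params.A @ default_params.P0 @ default_params.A.T + default_params.Q
        for k in range(50):
            step = kalman_step(default_params, x, P, obs[k])
            assert trace.innovation[k] == pytest.approx(step.innovation, abs=1e-14)
            assert np.allclose(trace.gain[k], step.gain, atol=1e-15)
            assert np.allclose(trace.posterior_x[k], step.posterior_x, atol=1e-15)
            x, P = step.next_prior_x, step.next_prior_P

    def test_innovation_identity_and_variance_floor(self, default_params):
        obs = generate_observations(default_params, 2000, seed=1)
        trace = simulate_learner(
            default_params, obs, schedule=PerturbationSchedule(onset=500, magnitude=-0.3)
        )
        assert np.array_equal(trace.innovation, trace.observation - trace.prediction)
        assert np.all(trace.innovation_variance >= default_params.R)

    def test_posterior_covariance_psd(self, default_params):
        obs = generate_observations(default_params, 500, seed=5)
        trace = simulate_learner(default_params, obs)
        eig = np.linalg.eigvalsh(trace.prior_P)
        assert np.all(eig >= -1e-18)

    def test_unbiased_steady_state(self, default_params):
        obs = generate_observations(default_params, 10_000, seed=11)
        inn = simulate_learner(default_params, obs).innovation[1000:]
        se = inn.std(ddof=1) / np.sqrt(len(inn))
        assert abs(inn.mean()) < 3 * se

    def test_step_perturbation_jump_and_decay(self, default_params):
        # onset at trial 201: |error| jumps to ~|magnitude| then decays
        obs = generate_observations(default_params, 2000, seed=2)
        trace = simulate_learner(
            default_params, obs, schedule=PerturbationSchedule(onset=201, magnitude=-0.3)
        )
        base_sd = trace.innovation[:200].std(ddof=1)
        assert abs(trace.innovation[200]) > 5 * base_sd
        assert abs(trace.innovation[200]) == pytest.approx(0.3, abs=0.1)
        late = np.abs(trace.innovation[-200:]).mean()
        assert late < 0.3 * abs(trace.innovation[200])

    def test_scaled_gain_inflates_baseline_variance(self, default_params):
        wins = 0
        for s in seed_set(21, 20):
            obs = generate_observations(default_params, 5_000, seed=int(s))
            v1 = np.var(simulate_learner(default_params, obs, gain_scale=1.0).innovation[1000:])
            v4 = np.var(simulate_learner(default_params, obs, gain_scale=4.0).innovation[1000:])
            wins += v4 > v1
        assert wins == 20  # identical observations: strictly larger on every seed

    def test_gain_one_minimizes_variance_sign_test(self, default_params):
        # optimal gain beats every scaled gain on the same feedback sequences
        from scipy.stats import binomtest

        scales = (1 / 16, 1 / 8, 1 / 4, 4, 8, 16)
        seeds = seed_set(31, 20)
        for scale in scales:
            wins = 0
            for s in seeds:
                obs = generate_observations(default_params, 4_000, seed=int(s))
                v1 = np.var(simulate_learner(default_params, obs).innovation[1000:])
                vs = np.var(
                    simulate_learner(default_params, obs, gain_scale=scale).innovation[1000:]
                )
                wins += v1 <= vs
            assert binomtest(wins, 20, 0.5, alternative="greater").pvalue < 0.01

    def test_bit_reproducible(self, default_params):
        t1 = run_step_protocol(default_params, seed=8, protocol=StepProtocol(2000, 500, 500))
        t2 = run_step_protocol(default_params, seed=8, protocol=StepProtocol(2000, 500, 500))
        assert np.array_equal(t1.innovation, t2.innovation)
        assert np.array_equal(t1.gain, t2.gain)

    @pytest.mark.parametrize("bad_gain", [0.0, -1.0])
    def test_invalid_gain_scale(self, default_params, bad_gain):
        with pytest.raises(ValueError):
            simulate_learner(default_params, np.zeros(10), gain_scale=bad_gain)

    def test_invalid_onset(self):
        with pytest.raises(ValueError):
            PerturbationSchedule(onset=0)


@settings(max_examples=25, deadline=None)
@given(
    a_slow=st.floats(0.9, 1.0, exclude_min=True),
    a_fast=st.floats(0.3, 0.89),
    log_q=st.floats(-8, -4),
    log_r=st.floats(-5, -2),
    seed=st.integers(0, 2**20),
)
def test_innovation_identity_property(a_slow, a_fast, log_q, log_r, seed):
    """The error-signal identity holds to machine precision for any model."""
    params = LearnerParams(
        A=np.diag([a_slow, a_fast]), Q=np.diag([10**log_q] * 2), R=10**log_r
    )
    obs = generate_observations(params, 300, seed=seed)
    trace = simulate_learner(params, obs, schedule=PerturbationSchedule(onset=100, magnitude=0.2))
    assert np.array_equal(trace.innovation, trace.observation - trace.prediction)
    assert np.all(trace.innovation_variance >= params.R)


class TestSteadyState:
    def test_zero_process_noise_kills_learning(self):
        params = LearnerParams(Q=np.zeros((2, 2)), P0=np.zeros((2, 2)))
        P, K, S = steady_state_solution(params)
        assert np.allclose(P, 0.0, atol=1e-12)
        assert np.allclose(K, 0.0, atol=1e-9)

    def test_simulated_gain_converges_to_fixed_point(self, default_params):
        _, K_inf, _ = steady_state_solution(default_params)
        obs = generate_observations(default_params, 5_000, seed=4)
        trace = simulate_learner(default_params, obs)
        assert np.allclose(trace.gain[4_999], K_inf, atol=1e-6)

    def test_gain_monotone_decreasing_in_observation_noise(self, default_params):
        gains = np.array(
            [steady_state_solution(default_params.with_scaled(R=f))[1] for f in range(1, 11)]
        )
        assert np.all(np.diff(gains[:, 0]) < 0)
        assert np.all(np.diff(gains[:, 1]) < 0)


class TestAsymptoticCompensation:
    def test_matches_long_simulation(self, default_params):
        frac = asymptotic_compensation(default_params, -0.3)
        trace = run_step_protocol(
            default_params, seed=6, protocol=StepProtocol(10_000, 1_000, 5_000)
        )
        residual = np.abs(trace.innovation[-1_000:]).mean()
        assert frac == pytest.approx(1 - residual / 0.3, abs=0.02)

    def test_sign_invariance(self, default_params):
        assert asymptotic_compensation(default_params, 0.3) == pytest.approx(
            asymptotic_compensation(default_params, -0.3), rel=1e-12
        )

    def test_zero_magnitude_rejected(self, default_params):
        with pytest.raises(ValueError):
            asymptotic_compensation(default_params, 0.0)


def test_trace_csv_roundtrip(tmp_path, default_params):
    trace = run_step_protocol(default_params, seed=1, protocol=StepProtocol(1500, 500, 500))
    path = tmp_path / "trace.csv"
    trace.to_csv(path)
    import pandas as pd

    df = pd.read_csv(path)
    assert list(df.columns) == [
        "trial", "observation", "perturbation", "prediction", "innovation",
        "gain_slow", "gain_fast", "posterior_slow", "posterior_fast",
    ]
    assert df["trial"].iloc[0] == 1
    assert len(df) == 2000
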