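"""Unit and property tests for the four learning rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kalmantd import (
    KalmanFilter,
    KalmanTD,
    ModelParams,
    RescorlaWagner,
    TemporalDifference,
    batch_posterior_oracle,
    kalman_predict,
    kalman_step,
    kalman_td_step,
    parse_design,
    run_model,
    rw_update,
    td_step,
)


class TestRescorlaWagner:
    def test_single_cue_acquisition_step(self):
        tr = rw_update(np.zeros(1), np.ones(1), 1.0, alpha=0.3)
        assert tr.delta == 1.0 and tr.w.tolist() == [0.3]

    def test_overexpectation_decrement(self):
        tr = rw_update(np.ones(2), np.ones(2), 1.0, alpha=0.3)
        assert tr.delta == -1.0
        assert np.allclose(tr.w, [0.7, 0.7])

    def test_zero_error_is_fixed_point(self):
        w = np.array([0.25, 0.75])
        tr = rw_update(w, np.ones(2), 1.0, alpha=0.3)
        assert np.array_equal(tr.w, w)

    def test_one_over_n_schedule_averages(self):
        # with x=1 and alpha=1/n, the weight is the running mean of rewards
        est = RescorlaWagner(alpha=1.0, lr_schedule="one_over_n")
        rewards = np.array([1.0, 0.0, 1.0, 1.0, 0.0])
        est.fit(np.ones((5, 1)), rewards)
        assert np.isclose(est.w_[0], rewards.mean())


class TestKalmanFilter:
    def test_first_trial_gain(self, params):
        # prior variance 1 plus diffusion 0.01, reward noise 1 -> 1.01/2.01
        tr = kalman_step(np.zeros(1), np.eye(1), np.ones(1), 1.0,
                         sigma_r2=1.0, tau2=0.01)
        assert np.isclose(tr.gain[0], 1.01 / 2.01)

    def test_huge_reward_noise_freezes_learning(self):
        w = np.array([0.4])
        tr = kalman_step(w, np.eye(1), np.ones(1), 1.0, sigma_r2=1e12, tau2=0.01)
        assert abs(tr.gain[0]) < 1e-11
        assert np.allclose(tr.w, w)
        assert np.isclose(tr.Sigma[0, 0], 1.01, atol=1e-10)

    def test_compound_training_builds_negative_covariance(self, params):
        run = run_model(parse_design("AB→+"), model="KF", params=params)
        Sigma = run.estimator.Sigma_
        assert Sigma[0, 1] < 0

    def test_negative_covariance_magnitude_matches_batch_oracle(self):
        # at tau2=0 the sequential off-diagonal equals the conjugate posterior's
        X = np.tile([1.0, 1.0], (10, 1))
        r = np.ones(10)
        kf = KalmanFilter(tau2=0.0)
        for i in range(10):
            kf.partial_fit(X[i : i + 1], r[i : i + 1])
        _, Sigma = batch_posterior_oracle(X, r)
        assert np.allclose(kf.Sigma_, Sigma, atol=1e-8)

    def test_joseph_form_agrees(self, rng):
        X = rng.normal(size=(40, 3))
        r = rng.normal(size=40)
        plain = KalmanFilter().fit(X, r)
        joseph = KalmanFilter(joseph=True).fit(X, r)
        assert np.allclose(plain.w_, joseph.w_, atol=1e-10)
        assert np.allclose(plain.Sigma_, joseph.Sigma_, atol=1e-10)

    def test_non_finite_observation_rejected(self):
        with pytest.raises(ValueError):
            kalman_step(np.zeros(1), np.eye(1), np.array([np.nan]), 1.0)

    def test_gain_decreases_then_recovers_after_diffusion(self, params):
        """Pre-exposure shrinks the gain; an unobserved delay regrows it."""
        kf = KalmanFilter(sigma_w2=1.0, sigma_r2=1.0, tau2=0.01)
        x = np.ones((1, 1))
        gains = []
        for _ in range(10):
            kf.partial_fit(x, np.zeros(1))
            gains.append(kf.gain_history_[-1, 0])
        assert np.all(np.diff(gains) < 0)
        kf.diffuse(n_steps=200)  # a long retention interval
        kf.partial_fit(x, np.zeros(1))
        assert kf.gain_history_[-1, 0] > gains[-1]


class TestTemporalDifference:
    def test_gamma_zero_equals_rescorla_wagner(self, rng):
        X = rng.integers(0, 2, size=(30, 4)).astype(float)
        r = rng.normal(size=30)
        rw = RescorlaWagner(alpha=0.3).fit(X, r)
        td = TemporalDifference(alpha=0.3, gamma=0.0).fit(
            X, r, trial_ends=np.ones(30, dtype=bool)
        )
        assert np.array_equal(td.w_history_, rw.w_history_)

    def test_second_order_error_is_positive(self):
        # no reward, but the successor state has value: delta = gamma * v'
        tr = td_step(np.array([0.0, 1.0]), np.array([1.0, 0.0]),
                     np.array([0.0, 1.0]), 0.0, alpha=0.3, gamma=0.98)
        assert np.isclose(tr.delta, 0.98)
        assert np.allclose(tr.w, [0.294, 1.0])

    def test_value_propagates_backwards_within_trial(self, params):
        run = run_model(parse_design("Z→X→+"), model="TD", params=params)
        w = dict(zip(run.feature_names, run.estimator.w_))
        assert w["X/3"] > w["X/0"] > 0
        assert w["Z/0"] >= 0


class TestKalmanTD:
    def test_gamma_zero_single_step_trials_equal_kalman_filter(self, rng):
        X = rng.normal(size=(25, 3))
        r = rng.normal(size=25)
        kf, ktd = KalmanFilter(), KalmanTD(gamma=0.0)
        for i in range(25):
            kf.partial_fit(X[i : i + 1], r[i : i + 1])
            ktd.partial_fit(X[i : i + 1], r[i : i + 1])
        assert np.array_equal(kf.w_history_, ktd.w_history_)
        assert np.allclose(kf.Sigma_, ktd.Sigma_, atol=0)

    def test_serial_training_builds_positive_onset_covariance(self, params):
        run = run_model(parse_design("Z→X→+"), model="KTD", params=params)
        names = run.feature_names
        Sigma = run.estimator.Sigma_
        zi, xi = names.index("Z/0"), names.index("X/0")
        assert Sigma[zi, xi] > 0

    def test_absent_stimulus_gain_negative_during_partner_extinction(self, params):
        # overshadowing partner A is extinguished; X never appears in that
        # phase yet its gain is negative, so A's extinction inflates X
        run = run_model(
            parse_design("AX→+ / BY→+; A→-; Z→X; Z→?"), model="KTD", params=params
        )
        xi = run.feature_names.index("X/0")
        phase2_onset_gains = run.estimator.gain_history_[80:120:4, xi]
        assert np.all(phase2_onset_gains < 0)

    def test_flipped_derivative_sign_flips_weights(self, params):
        run = run_model(parse_design("A→+"), model="KTD", params=params)
        est2 = KalmanTD(derivative_sign="flipped")
        from kalmantd import CscLayout, encode_csc

        layout = CscLayout(alphabet=("A",), bins_per_stimulus=4)
        tl = encode_csc(parse_design("A→+").phases[0].trial_types[0], layout)
        for _ in range(10):
            est2.partial_fit(tl.X, tl.r, trial_ends=tl.trial_ends)
        assert np.allclose(est2.w_, -run.estimator.w_)


class TestBatchPosteriorOracle:
    def test_single_observation_closed_form(self):
        mu, Sigma = batch_posterior_oracle(np.array([[1.0]]), np.array([1.0]))
        assert np.isclose(mu[0], 0.5) and np.isclose(Sigma[0, 0], 0.5)

    def test_no_observations_returns_prior(self):
        mu, Sigma = batch_posterior_oracle(np.zeros((0, 3)), np.zeros(0),
                                           sigma_w2=2.0)
        assert np.allclose(mu, 0) and np.allclose(Sigma, 2.0 * np.eye(3))

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            batch_posterior_oracle(np.ones((1, 1)), np.ones(1), sigma_w2=0.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 8), st.integers(1, 40))
    def test_sequential_kalman_equals_batch_posterior(self, seed, D, N):
        """With τ²=0 the recursive filter is exact conjugate inference."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(N, D))
        r = rng.normal(size=N)
        kf = KalmanFilter(tau2=0.0).fit(X, r)
        mu, Sigma = batch_posterior_oracle(X, r)
        assert np.allclose(kf.w_, mu, atol=1e-8)
        assert np.allclose(kf.Sigma_, Sigma, atol=1e-8)


class TestStateInvariants:
    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_covariance_symmetric_psd_every_step(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, size=(30, 4)).astype(float)
        r = rng.integers(0, 2, size=30).astype(float)
        for est in (KalmanFilter(), KalmanTD()):
            for i in range(len(X)):
                est.partial_fit(X[i : i + 1], r[i : i + 1])
                S = est.Sigma_
                assert np.array_equal(S, S.T)
                assert np.linalg.eigvalsh(S).min() >= -1e-8

    def test_runs_are_bit_reproducible(self, params):
        d = parse_design("A→+ / AB→-; A→-; B→?")
        a = run_model(d, model="KF", params=params, schedule="shuffled", seed=11)
        b = run_model(d, model="KF", params=params, schedule="shuffled", seed=11)
        assert a.responses == b.responses
        assert np.array_equal(a.estimator.w_history_, b.estimator.w_history_)
        assert a.trace.equals(b.trace)


class TestRunModel:
    def test_latent_inhibition_kf_vs_rw(self, params):
        pre = parse_design("A→-; A→+; A→?")
        no_pre = parse_design("A→+; A→?")
        kf_pre = run_model(pre, "KF", params).responses["A→?"]
        kf_no = run_model(no_pre, "KF", params).responses["A→?"]
        assert kf_pre < kf_no
        # RW sees zero prediction error during pre-exposure: no effect
        rw_pre = run_model(pre, "RW", params).responses["A→?"]
        rw_no = run_model(no_pre, "RW", params).responses["A→?"]
        assert rw_pre == rw_no

    def test_trial_level_model_rejects_serial_design(self, params):
        with pytest.raises(ValueError, match="serial"):
            run_model(parse_design("Z→X→+"), model="KF", params=params)

    def test_empty_design_gives_zero_responses(self, params):
        from kalmantd import Design

        run = run_model(Design(phases=()), model="KF", params=params)
        assert run.responses == {}
        assert len(run.estimator.w_history_) == 0

    def test_probes_do_not_update_state(self, params):
        with_probe = run_model(parse_design("A→+; A→?"), "KF", params)
        without = run_model(parse_design("A→+"), "KF", params)
        assert np.array_equal(with_probe.estimator.w_, without.estimator.w_)

    def test_trace_is_tidy_per_feature(self, params):
        run = run_model(parse_design("AB→+; B→?"), "KF", params)
        df = run.trace
        assert set(df["feature"]) == {"A", "B"}
        assert len(df) == 10 * 2  # 10 trials x 2 features
        assert {"phase", "trial", "step", "w_hat", "gain", "delta", "v", "r"} <= set(df.columns)

    def test_unknown_model_name(self, params):
        with pytest.raises(ValueError):
            run_model(parse_design("A→+"), model="QL", params=params)


def test_params_bounds_validated():
    with pytest.raises(ValueError):
        ModelParams(alpha=2.0)
    with pytest.raises(ValueError):
        ModelParams(sigma_r2=0.0)
    with pytest.raises(ValueError):
        ModelParams(tau2=-0.1)
    with pytest.raises(ValueError):
        ModelParams(lr_schedule="cosine")


def test_kalman_predict_grows_diagonal():
    S = kalman_predict(np.eye(2) * 0.3, tau2=0.01, n_steps=5)
    assert np.allclose(np.diag(S), 0.35)
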