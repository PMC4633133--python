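"""The four learning rules: Rescorla-Wagner, Kalman filter, TD, and Kalman TD.

All four estimate a weight vector w linking stimulus features to reward
(RW, KF) or to discounted cumulative future reward, i.e. value (TD, KTD).
The Bayesian pair (KF, KTD) additionally tracks a posterior covariance Σ
over the weights under a linear-Gaussian dynamical system:

    w_0 ~ N(0, σw²·I),   w_n ~ N(w_{n−1}, τ²·I),   r_n ~ N(w_n·x_n, σr²),

which turns the fixed learning rate α of the point-estimate pair into a
stimulus-specific, uncertainty-weighted Kalman gain.  Kalman TD is the
Kalman filter run on the discounted temporal derivative h_t of the CSC
features, so it is a Bayesian estimator of the value function.

Two interfaces are provided: pure single-step update functions
(:func:`rw_update`, :func:`kalman_step`, :func:`td_step`,
:func:`kalman_td_step`) and scikit-learn style estimators
(:class:`RescorlaWagner`, :class:`KalmanFilter`,
:class:`TemporalDifference`, :class:`KalmanTD`) that run them over a
sequence of observations and keep full per-step traces.
:func:`run_model` drives an estimator over a parsed design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .design import Design, expand_phase
from .encoding import CscLayout, Timeline, discounted_derivative, encode_csc, encode_trial_level

__all__ = [
    "ModelParams",
    "UpdateTrace",
    "rw_update",
    "kalman_step",
    "kalman_predict",
    "td_step",
    "kalman_td_step",
    "batch_posterior_oracle",
    "RescorlaWagner",
    "KalmanFilter",
    "TemporalDifference",
    "KalmanTD",
    "make_estimator",
    "run_model",
    "ModelRun",
    "MODEL_NAMES",
]

MODEL_NAMES = ("RW", "KF", "TD", "KTD")


@dataclass
class ModelParams:
    """Shared parameter bundle for all four models.

    alpha
        Learning rate (associability) of the point-estimate models, in [0, 1].
    gamma
        Discount factor of the real-time models, in [0, 1].
    sigma_w2
        Prior weight variance σw² (> 0): how strong associations are
        expected to be a priori.
    sigma_r2
        Reward noise variance σr² (> 0).
    tau2
        Diffusion variance τ² (≥ 0): how fast weights are assumed to
        drift between observations; higher τ² keeps the Kalman gain high.
    bins_per_stimulus
        CSC bins per stimulus for the real-time models.
    lr_schedule
        "constant" (α) or "one_over_n" (α/n, the Robbins-Monro schedule
        under which RW converges to the maximum-likelihood weights).
    """

    alpha: float = 0.3
    gamma: float = 0.98
    sigma_w2: float = 1.0
    sigma_r2: float = 1.0
    tau2: float = 0.01
    bins_per_stimulus: int = 4
    lr_schedule: str = "constant"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.sigma_w2 <= 0 or self.sigma_r2 <= 0:
            raise ValueError("sigma_w2 and sigma_r2 must be positive")
        if self.tau2 < 0:
            raise ValueError("tau2 must be nonnegative")
        if self.bins_per_stimulus < 1:
            raise ValueError("bins_per_stimulus must be >= 1")
        if self.lr_schedule not in ("constant", "one_over_n"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")

    def override(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class UpdateTrace:
    """Result of one learning step: error, prediction, gain and new state."""

    delta: float
    v: float
    w: np.ndarray
    gain: np.ndarray | None = None
    Sigma: np.ndarray | None = None


def rw_update(
    w: np.ndarray,
    x: np.ndarray,
    r: float,
    alpha: float = 0.3,
    lr_schedule: str = "constant",
    step_count: int = 1,
) -> UpdateTrace:
    """One Rescorla-Wagner step: w ← w + α_n·x·(r − w·x).

    With ``lr_schedule="one_over_n"`` the effective rate is α/n where n
    is ``step_count`` (1-based), the Robbins-Monro schedule.
    """
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    v = float(w @ x)
    delta = r - v
    a = alpha if lr_schedule == "constant" else alpha / max(step_count, 1)
    return UpdateTrace(delta=delta, v=v, w=w + a * x * delta)


def kalman_predict(Sigma: np.ndarray, tau2: float, n_steps: int = 1) -> np.ndarray:
    """Diffusion-only predict step(s): Σ ← Σ + n·τ²·I.

    Models the growth of uncertainty over unobserved time (e.g. a delay
    interposed between phases), which raises subsequent Kalman gains.
    """
    return Sigma + n_steps * tau2 * np.eye(Sigma.shape[0])


def kalman_step(
    w: np.ndarray,
    Sigma: np.ndarray,
    x: np.ndarray,
    r: float,
    sigma_r2: float = 1.0,
    tau2: float = 0.01,
    joseph: bool = False,
) -> UpdateTrace:
    """One Kalman filter predict+update step on observation (x, r).

    With S = Σ + τ²·I:

        k  = S·x / (xᵀ·S·x + σr²)        (Kalman gain)
        w' = w + k·(r − w·x)
        Σ' = S − k·xᵀ·S                   (re-symmetrized)

    ``joseph=True`` uses the Joseph-form covariance update
    (I − k·xᵀ)·S·(I − k·xᵀ)ᵀ + σr²·k·kᵀ, algebraically equal but more
    robust to round-off; provided for numerical comparison.
    """
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    if not (np.all(np.isfinite(x)) and np.isfinite(r)):
        raise ValueError("non-finite observation")
    S = Sigma + tau2 * np.eye(len(w))
    Sx = S @ x
    denom = float(x @ Sx) + sigma_r2
    k = Sx / denom
    v = float(w @ x)
    delta = r - v
    if joseph:
        A = np.eye(len(w)) - np.outer(k, x)
        Sigma_new = A @ S @ A.T + sigma_r2 * np.outer(k, k)
    else:
        Sigma_new = S - np.outer(k, Sx)
    Sigma_new = (Sigma_new + Sigma_new.T) / 2.0
    return UpdateTrace(delta=delta, v=v, w=w + k * delta, gain=k, Sigma=Sigma_new)


def td_step(
    w: np.ndarray,
    x_t: np.ndarray,
    x_next: np.ndarray,
    r: float,
    alpha: float = 0.3,
    gamma: float = 0.98,
) -> UpdateTrace:
    """One TD(0) step with linear values: δ = r + γ·w·x_{t+1} − w·x_t.

    ``x_next`` must be the zero vector at a trial's last step.  With
    γ = 0 this is exactly the Rescorla-Wagner update on (x_t, r).
    """
    w = np.asarray(w, dtype=float)
    x_t = np.asarray(x_t, dtype=float)
    v = float(w @ x_t)
    delta = r + gamma * float(w @ np.asarray(x_next, dtype=float)) - v
    return UpdateTrace(delta=delta, v=v, w=w + alpha * x_t * delta)


def kalman_td_step(
    w: np.ndarray,
    Sigma: np.ndarray,
    h_t: np.ndarray,
    r: float,
    sigma_r2: float = 1.0,
    tau2: float = 0.01,
    joseph: bool = False,
) -> UpdateTrace:
    """One Kalman TD step: a Kalman filter step on the discounted
    derivative feature h_t = x_t − γ·x_{t+1} instead of x_t."""
    return kalman_step(w, Sigma, h_t, r, sigma_r2=sigma_r2, tau2=tau2, joseph=joseph)


def batch_posterior_oracle(
    X: np.ndarray,
    r: np.ndarray,
    sigma_w2: float = 1.0,
    sigma_r2: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate Gaussian linear-regression posterior for static weights (τ² = 0).

    Σ = (I/σw² + XᵀX/σr²)⁻¹,  μ = Σ·Xᵀ·r/σr².  With τ² = 0 the sequential
    Kalman filter must reproduce this batch posterior exactly, which makes
    it an independent check on the recursive update.
    """
    if sigma_w2 <= 0 or sigma_r2 <= 0:
        raise ValueError("variances must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    r = np.asarray(r, dtype=float)
    D = X.shape[1]
    precision = np.eye(D) / sigma_w2 + X.T @ X / sigma_r2
    Sigma = np.linalg.inv(precision)
    Sigma = (Sigma + Sigma.T) / 2.0
    mu = Sigma @ X.T @ r / sigma_r2
    return mu, Sigma


# ---------------------------------------------------------------------------
# Estimators


class _AssociativeLearner(BaseEstimator):
    """Shared scaffolding: online fitting over (X, y) with per-step traces."""

    is_bayesian = False
    is_realtime = False

    def _init_state(self, n_features: int) -> None:
        raise NotImplementedError

    def _step(self, x, x_next, r, at_start: bool = True) -> UpdateTrace:
        raise NotImplementedError

    def _validate(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if len(X) != len(y):
            raise ValueError(f"X has {len(X)} rows but y has {len(y)} entries")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("X and y must be finite")
        return X, y

    def _ensure_initialized(self, n_features: int) -> None:
        if not hasattr(self, "w_"):
            self._init_state(n_features)
            self.n_features_in_ = n_features
            self._history = {k: [] for k in ("delta", "v", "r", "gain", "w", "Sigma_diag")}
            self._finalize_history()

    def partial_fit(self, X, y, trial_ends=None):
        """Consume further observations without resetting state.

        For real-time models ``trial_ends`` flags each trial's last step
        (default: only the final row ends a trial, i.e. X is one trial).
        Trial-level models ignore ``trial_ends``.
        """
        X, y = self._validate(X, y)
        self._ensure_initialized(X.shape[1])
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension changed: {X.shape[1]} != {self.n_features_in_}"
            )
        ends = self._resolve_ends(trial_ends, len(X))
        at_start = getattr(self, "_prev_trial_ended", True)
        for t in range(len(X)):
            if self.is_realtime and not ends[t] and t + 1 < len(X):
                x_next = X[t + 1]
            else:
                x_next = np.zeros(self.n_features_in_)
            tr = self._step(X[t], x_next, y[t], at_start=at_start)
            self._record(tr, y[t])
            at_start = bool(ends[t])
        self._prev_trial_ended = at_start
        self._finalize_history()
        return self

    def fit(self, X, y, trial_ends=None):
        """Reset state and learn from scratch on the observation sequence."""
        for attr in ("w_", "Sigma_", "n_features_in_", "step_count_"):
            if hasattr(self, attr):
                delattr(self, attr)
        return self.partial_fit(X, y, trial_ends=trial_ends)

    def _resolve_ends(self, trial_ends, n):
        if trial_ends is None:
            ends = np.zeros(n, dtype=bool)
            ends[-1] = True
            return ends
        ends = np.asarray(trial_ends, dtype=bool)
        if len(ends) != n:
            raise ValueError("trial_ends length mismatch")
        return ends

    def _record(self, tr: UpdateTrace, r: float) -> None:
        h = self._history
        h["delta"].append(tr.delta)
        h["v"].append(tr.v)
        h["r"].append(r)
        h["w"].append(tr.w.copy())
        self.w_ = tr.w
        if tr.gain is not None:
            h["gain"].append(tr.gain.copy())
        if tr.Sigma is not None:
            h["Sigma_diag"].append(np.diag(tr.Sigma).copy())
            self.Sigma_ = tr.Sigma

    def _finalize_history(self) -> None:
        h = self._history
        self.delta_history_ = np.array(h["delta"])
        self.value_history_ = np.array(h["v"])
        self.reward_history_ = np.array(h["r"])
        self.w_history_ = (
            np.array(h["w"]) if h["w"] else np.zeros((0, getattr(self, "n_features_in_", 0)))
        )
        if h["gain"]:
            self.gain_history_ = np.array(h["gain"])
            self.Sigma_diag_history_ = np.array(h["Sigma_diag"])

    def predict(self, X):
        """Reward expectation (or value) v = w·x for each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.w_


class RescorlaWagner(_AssociativeLearner):
    """Rescorla-Wagner: error-driven point estimation of immediate reward.

    w ← w + α·x·(r − w·x).  With ``lr_schedule="one_over_n"`` the learning
    rate decays as α/n and the estimate converges to the maximum-likelihood
    (least-squares) weights of a static linear-Gaussian generator.
    """

    def __init__(self, alpha: float = 0.3, lr_schedule: str = "constant"):
        self.alpha = alpha
        self.lr_schedule = lr_schedule

    def _init_state(self, n_features: int) -> None:
        ModelParams(alpha=self.alpha, lr_schedule=self.lr_schedule)  # bounds check
        self.w_ = np.zeros(n_features)
        self.step_count_ = 0

    def _step(self, x, x_next, r, at_start: bool = True) -> UpdateTrace:
        self.step_count_ += 1
        return rw_update(
            self.w_, x, r,
            alpha=self.alpha, lr_schedule=self.lr_schedule, step_count=self.step_count_,
        )


class KalmanFilter(_AssociativeLearner):
    """Kalman filter: Bayesian estimation of immediate-reward weights.

    Tracks a Gaussian posterior N(w_, Sigma_) under the linear-Gaussian
    dynamical system prior; the gain k replaces the fixed learning rate
    and shrinks as cue uncertainty (diagonal of Σ) shrinks, while negative
    off-diagonals of Σ couple cues trained in compound (the substrate of
    retrospective revaluation such as backward blocking).
    """

    is_bayesian = True

    def __init__(
        self,
        sigma_w2: float = 1.0,
        sigma_r2: float = 1.0,
        tau2: float = 0.01,
        joseph: bool = False,
    ):
        self.sigma_w2 = sigma_w2
        self.sigma_r2 = sigma_r2
        self.tau2 = tau2
        self.joseph = joseph

    def _init_state(self, n_features: int) -> None:
        ModelParams(sigma_w2=self.sigma_w2, sigma_r2=self.sigma_r2, tau2=self.tau2)
        self.w_ = np.zeros(n_features)
        self.Sigma_ = self.sigma_w2 * np.eye(n_features)

    def _step(self, x, x_next, r, at_start: bool = True) -> UpdateTrace:
        return kalman_step(
            self.w_, self.Sigma_, x, r,
            sigma_r2=self.sigma_r2, tau2=self.tau2, joseph=self.joseph,
        )

    def diffuse(self, n_steps: int = 1):
        """Let uncertainty grow over unobserved time: Σ ← Σ + n·τ²·I."""
        self.Sigma_ = kalman_predict(self.Sigma_, self.tau2, n_steps)
        return self


class TemporalDifference(_AssociativeLearner):
    """TD(0) with linear value approximation over CSC features.

    δ_t = r_t + γ·w·x_{t+1} − w·x_t;  w ← w + α·x_t·δ_t.  Learns the
    expected discounted future return; reduces to Rescorla-Wagner when
    γ = 0 or on single-step trials.
    """

    is_realtime = True

    def __init__(self, alpha: float = 0.3, gamma: float = 0.98):
        self.alpha = alpha
        self.gamma = gamma

    def _init_state(self, n_features: int) -> None:
        ModelParams(alpha=self.alpha, gamma=self.gamma)
        self.w_ = np.zeros(n_features)

    def _step(self, x, x_next, r, at_start: bool = True) -> UpdateTrace:
        return td_step(self.w_, x, x_next, r, alpha=self.alpha, gamma=self.gamma)


class KalmanTD(_AssociativeLearner):
    """Kalman TD: Bayesian estimation of the value function.

    Runs the Kalman filter on the discounted derivative features
    h_t = x_t − γ·x_{t+1}, unifying uncertainty tracking with long-term
    reward prediction.  ``derivative_sign="flipped"`` negates h for
    comparison with the opposite sign convention.

    ``diffusion="trial"`` (default) applies the τ²·I predict step once at
    each trial's first time step, mirroring the per-trial weight drift of
    the generative model; ``diffusion="step"`` applies it at every CSC
    time step instead (uncertainty then grows with trial length).
    """

    is_bayesian = True
    is_realtime = True

    def __init__(
        self,
        sigma_w2: float = 1.0,
        sigma_r2: float = 1.0,
        tau2: float = 0.01,
        gamma: float = 0.98,
        derivative_sign: str = "onset",
        diffusion: str = "trial",
        joseph: bool = False,
    ):
        self.sigma_w2 = sigma_w2
        self.sigma_r2 = sigma_r2
        self.tau2 = tau2
        self.gamma = gamma
        self.derivative_sign = derivative_sign
        self.diffusion = diffusion
        self.joseph = joseph

    def _init_state(self, n_features: int) -> None:
        ModelParams(sigma_w2=self.sigma_w2, sigma_r2=self.sigma_r2,
                    tau2=self.tau2, gamma=self.gamma)
        if self.diffusion not in ("trial", "step"):
            raise ValueError(f"unknown diffusion timing {self.diffusion!r}")
        self.w_ = np.zeros(n_features)
        self.Sigma_ = self.sigma_w2 * np.eye(n_features)

    def partial_fit(self, X, y, trial_ends=None):
        X, y = self._validate(X, y)
        ends = self._resolve_ends(trial_ends, len(X))
        timeline = Timeline(X=X, r=y, trial_ends=ends)
        H = discounted_derivative(timeline, self.gamma, sign=self.derivative_sign).X
        # the Kalman steps see h_t, never raw x_t, so run the base loop on H
        return super().partial_fit(H, y, trial_ends=ends)

    def _step(self, h, h_next, r, at_start: bool = True) -> UpdateTrace:
        if self.diffusion == "trial":
            if at_start:
                self.Sigma_ = kalman_predict(self.Sigma_, self.tau2)
            step_tau2 = 0.0
        else:
            step_tau2 = self.tau2
        return kalman_td_step(
            self.w_, self.Sigma_, h, r,
            sigma_r2=self.sigma_r2, tau2=step_tau2, joseph=self.joseph,
        )

    def diffuse(self, n_steps: int = 1):
        self.Sigma_ = kalman_predict(self.Sigma_, self.tau2, n_steps)
        return self


def make_estimator(model: str, params: ModelParams | None = None) -> _AssociativeLearner:
    """Build an estimator for a model name in {RW, KF, TD, KTD}."""
    p = params or ModelParams()
    if model == "RW":
        return RescorlaWagner(alpha=p.alpha, lr_schedule=p.lr_schedule)
    if model == "KF":
        return KalmanFilter(sigma_w2=p.sigma_w2, sigma_r2=p.sigma_r2, tau2=p.tau2)
    if model == "TD":
        return TemporalDifference(alpha=p.alpha, gamma=p.gamma)
    if model == "KTD":
        return KalmanTD(sigma_w2=p.sigma_w2, sigma_r2=p.sigma_r2,
                        tau2=p.tau2, gamma=p.gamma)
    raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")


@dataclass
class ModelRun:
    """A model executed over a design: probe responses plus full traces."""

    model: str
    design: Design
    estimator: _AssociativeLearner
    responses: dict[str, float]
    feature_names: list[str]
    trace: pd.DataFrame = field(repr=False, default=None)


def _trial_level_timeline(design, schedule, seed):
    rows, rewards, meta = [], [], []
    for pi, phase in enumerate(design.phases):
        for ti, trial in enumerate(expand_phase(phase, schedule, seed + pi)):
            if trial.is_test:
                continue
            x, r = encode_trial_level(trial, design.alphabet)
            rows.append(x)
            rewards.append(r)
            meta.append((pi, ti, trial.label))
    return rows, rewards, meta


def run_model(
    design: Design,
    model: str = "KF",
    params: ModelParams | None = None,
    schedule: str = "alternating",
    seed: int = 0,
    trace: bool = True,
) -> ModelRun:
    """Run a model over a design and read out every "?" test probe.

    Trial-level models (RW, KF) require single-event trial types; real-time
    models (TD, KTD) expand each trial into its CSC timeline.  Test probes
    never update the state: the response is the value of the probe's
    (onset) features under the final weights.
    """
    if params is None:
        params = ModelParams()
    est = make_estimator(model, params)
    probe_meta = []  # (phase, trial, step, label) per learning step

    if est.is_realtime:
        layout = CscLayout.from_design(design, params.bins_per_stimulus)
        feature_names = layout.feature_names
        for pi, phase in enumerate(design.phases):
            trials = [t for t in expand_phase(phase, schedule, seed + pi) if not t.is_test]
            for ti, trial in enumerate(trials):
                tl = encode_csc(trial, layout)
                est.partial_fit(tl.X, tl.r, trial_ends=tl.trial_ends)
                probe_meta.extend((pi, ti, si, trial.label) for si in range(len(tl)))
        est._ensure_initialized(layout.n_features)
        responses = {
            t.label: float(est.w_ @ layout.onset_vector(t)) for t in design.test_trials
        }
    else:
        if design.is_serial:
            raise ValueError(
                f"model {model} is trial-level but the design contains serial "
                "compounds; use TD or KTD"
            )
        feature_names = list(design.alphabet)
        rows, rewards, meta = _trial_level_timeline(design, schedule, seed)
        if rows:
            est.fit(np.array(rows), np.array(rewards))
        est._ensure_initialized(len(design.alphabet))
        probe_meta = [(pi, ti, 0, lbl) for pi, ti, lbl in meta]
        responses = {}
        for t in design.test_trials:
            x, _ = encode_trial_level(t, design.alphabet)
            responses[t.label] = float(est.w_ @ x)

    frame = _trace_frame(est, probe_meta, feature_names) if trace else None
    return ModelRun(model=model, design=design, estimator=est,
                    responses=responses, feature_names=feature_names, trace=frame)


def _trace_frame(est, meta, feature_names) -> pd.DataFrame:
    """Tidy per-step, per-feature trace table."""
    n_steps = len(est.delta_history_)
    if n_steps == 0:
        return pd.DataFrame(
            columns=["phase", "trial", "step", "trial_type", "feature",
                     "w_hat", "gain", "sigma_diag", "delta", "v", "r"]
        )
    D = len(feature_names)
    phase = np.repeat([m[0] for m in meta], D)
    trial = np.repeat([m[1] for m in meta], D)
    step = np.repeat([m[2] for m in meta], D)
    label = np.repeat([m[3] for m in meta], D)
    df = pd.DataFrame({
        "phase": phase,
        "trial": trial,
        "step": step,
        "trial_type": label,
        "feature": np.tile(feature_names, n_steps),
        "w_hat": est.w_history_.ravel(),
        "delta": np.repeat(est.delta_history_, D),
        "v": np.repeat(est.value_history_, D),
        "r": np.repeat(est.reward_history_, D),
    })
    if hasattr(est, "gain_history_"):
        df["gain"] = est.gain_history_.ravel()
        df["sigma_diag"] = est.Sigma_diag_history_.ravel()
    else:
        df["gain"] = np.nan
        df["sigma_diag"] = np.nan
    return df
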