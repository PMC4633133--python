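"""Stimulus representations: trial-level one-hots and the complete serial compound.

Trial-level models (Rescorla-Wagner, Kalman filter) see one feature vector
per trial with a 1 for every cue present.  Real-time models (TD, Kalman TD)
see a complete serial compound (CSC): each stimulus is split into
``bins_per_stimulus`` non-overlapping time bins and each (stimulus, bin)
pair is its own feature, active only at its time relative to stimulus
onset.  Kalman TD additionally replaces features by their discounted time
derivative h_t = x_t − γ·x_{t+1}, so that the one-step reward is linear in
h under the value consistency condition r_t = V(x_t) − γ·V(x_{t+1}).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import Design, TrialType

__all__ = [
    "Timeline",
    "CscLayout",
    "encode_trial_level",
    "encode_csc",
    "discounted_derivative",
]


@dataclass
class Timeline:
    """A per-time-step feature/reward sequence.

    ``X`` is (T, D), ``r`` is (T,), and ``trial_ends[t]`` is True at the
    final step of each trial.  Trial-level timelines have one step per
    trial (every step is a trial end).
    """

    X: np.ndarray
    r: np.ndarray
    trial_ends: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.r = np.asarray(self.r, dtype=float)
        self.trial_ends = np.asarray(self.trial_ends, dtype=bool)
        if not (len(self.X) == len(self.r) == len(self.trial_ends)):
            raise ValueError("X, r and trial_ends must have equal length")
        if not np.all(np.isfinite(self.r)):
            raise ValueError("rewards must be finite")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @staticmethod
    def concatenate(timelines: list["Timeline"]) -> "Timeline":
        return Timeline(
            X=np.vstack([t.X for t in timelines]),
            r=np.concatenate([t.r for t in timelines]),
            trial_ends=np.concatenate([t.trial_ends for t in timelines]),
        )

    def to_frame(self, feature_names: list[str] | None = None) -> pd.DataFrame:
        """Tidy export: one row per time step, one column per feature."""
        names = feature_names or [f"f{j}" for j in range(self.n_features)]
        trial = np.cumsum(np.concatenate([[False], self.trial_ends[:-1]]))
        df = pd.DataFrame(self.X, columns=names)
        df.insert(0, "trial", trial)
        df.insert(1, "step", np.arange(len(self)))
        df["reward"] = self.r
        return df


@dataclass(frozen=True)
class CscLayout:
    """Feature layout for the complete serial compound.

    Each stimulus owns ``bins_per_stimulus`` consecutive columns; the same
    stimulus reuses the same columns in every trial type and phase, so
    feature identity is per (stimulus, bin), not per serial position.
    """

    alphabet: tuple[str, ...]
    bins_per_stimulus: int = 4

    def __post_init__(self) -> None:
        if self.bins_per_stimulus < 1:
            raise ValueError("bins_per_stimulus must be >= 1")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("duplicate labels in alphabet")

    @property
    def n_features(self) -> int:
        return len(self.alphabet) * self.bins_per_stimulus

    def column(self, stimulus: str, bin_index: int) -> int:
        if stimulus not in self.alphabet:
            raise KeyError(f"unknown stimulus label {stimulus!r}")
        if not 0 <= bin_index < self.bins_per_stimulus:
            raise IndexError(f"bin {bin_index} out of range")
        return self.alphabet.index(stimulus) * self.bins_per_stimulus + bin_index

    @property
    def feature_names(self) -> list[str]:
        return [f"{s}/{b}" for s in self.alphabet for b in range(self.bins_per_stimulus)]

    def onset_vector(self, trial: TrialType) -> np.ndarray:
        """Features at stimulus onset (first bin of the trial's first event).

        This is the readout used for test probes: the value w·x at onset
        is the anticipatory-response proxy.
        """
        x = np.zeros(self.n_features)
        for stim in trial.events[0]:
            x[self.column(stim, 0)] = 1.0
        return x

    @classmethod
    def from_design(cls, design: Design, bins_per_stimulus: int = 4) -> "CscLayout":
        return cls(alphabet=design.alphabet, bins_per_stimulus=bins_per_stimulus)


def encode_trial_level(trial: TrialType, alphabet: tuple[str, ...]) -> tuple[np.ndarray, float]:
    """One-hot compound encoding for trial-level models.

    Returns (x, r) where x has a 1 at each present cue's index.  Serial
    compounds have no trial-level encoding and raise.
    """
    if trial.is_serial:
        raise ValueError(
            f"trial {trial.label!r} is a serial compound; use the CSC "
            "encoding (encode_csc) with a real-time model"
        )
    x = np.zeros(len(alphabet))
    for stim in trial.events[0]:
        try:
            x[alphabet.index(stim)] = 1.0
        except ValueError:
            raise KeyError(f"stimulus {stim!r} not in alphabet {alphabet}") from None
    r = 0.0 if trial.outcome is None else trial.outcome
    return x, r


def encode_csc(trial: TrialType, layout: CscLayout) -> Timeline:
    """Complete-serial-compound timeline for one trial.

    Each event occupies ``bins_per_stimulus`` consecutive steps; within a
    step exactly the current bin of each present stimulus is active.
    Serial events concatenate in order and the reward arrives at the final
    step (stimulus termination), 0 elsewhere.
    """
    nb = layout.bins_per_stimulus
    T = nb * len(trial.events)
    X = np.zeros((T, layout.n_features))
    for i, event in enumerate(trial.events):
        for b in range(nb):
            for stim in event:
                X[i * nb + b, layout.column(stim, b)] = 1.0
    r = np.zeros(T)
    r[-1] = 0.0 if trial.outcome is None else trial.outcome
    ends = np.zeros(T, dtype=bool)
    ends[-1] = True
    return Timeline(X=X, r=r, trial_ends=ends)


def discounted_derivative(timeline: Timeline, gamma: float, sign: str = "onset") -> Timeline:
    """Discounted temporal derivative of a timeline's features.

    Within a trial h_t = x_t − γ·x_{t+1}; at each trial's last step the
    successor is the zero vector, so h_T = x_T and nothing leaks across
    trial boundaries.  Rewards and boundaries pass through unchanged.

    ``sign="onset"`` (default) orients h so that reward-predictive cues
    acquire positive weights (r_t = w·h_t is then the TD fixed point
    δ_t = 0); ``sign="flipped"`` negates h, for comparison with the
    opposite convention.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    if sign not in ("onset", "flipped"):
        raise ValueError(f"unknown sign convention {sign!r}")
    X = timeline.X
    X_next = np.vstack([X[1:], np.zeros((1, X.shape[1]))])
    X_next[timeline.trial_ends] = 0.0
    H = X - gamma * X_next
    if sign == "flipped":
        H = -H
    return Timeline(X=H, r=timeline.r.copy(), trial_ends=timeline.trial_ends.copy())
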