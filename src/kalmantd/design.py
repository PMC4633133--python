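"""Textual notation for classical-conditioning designs.

Designs are written the way the animal-learning literature abbreviates
paradigms: uppercase letters are conditioned stimuli, letter runs are
simultaneous compounds (``AB``), arrows chain serial events and terminate
in an outcome (``Z→X→+``), ``+``/``-`` mark reward and no reward, ``?``
marks a test probe, ``/`` interleaves trial types within a phase and ``;``
separates phases.  Example: ``"A→+ / AB→-; A→-"`` is a conditioned
inhibition phase followed by extinction of the excitor.

ASCII ``->`` is accepted everywhere in place of ``→``.  An outcome may
also be a numeric magnitude (``"A→0.5"``).  A trial with no outcome token
(``"Z→X"``, a second-order pairing) means the trial ends without reward.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "DesignParseError",
    "TrialType",
    "Phase",
    "Design",
    "parse_design",
    "format_design",
    "expand_phase",
]

ARROW = "→"

_STIMSET_RE = re.compile(r"^[A-Z]+$")
_NUMBER_RE = re.compile(r"^\d+(\.\d+)?$")


class DesignParseError(ValueError):
    """Raised for malformed design notation; the message names the bad span."""


@dataclass(frozen=True)
class TrialType:
    """One trial type: a sequence of stimulus events and a terminal outcome.

    ``events`` holds one frozenset of stimulus labels per serial event; a
    simultaneous compound like AB is a single two-element set, while the
    serial compound A→B is two one-element sets.  ``outcome`` is the reward
    magnitude delivered at trial end, or ``None`` for a "?" test probe.
    """

    events: tuple[frozenset[str], ...]
    outcome: float | None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.events or any(not ev for ev in self.events):
            raise ValueError("trial type needs at least one nonempty event")
        if self.outcome is not None and self.outcome < 0:
            raise ValueError("reward magnitude must be nonnegative")
        if not self.label:
            object.__setattr__(self, "label", _format_trial(self))

    @property
    def is_test(self) -> bool:
        return self.outcome is None

    @property
    def is_serial(self) -> bool:
        return len(self.events) > 1

    @property
    def stimuli(self) -> frozenset[str]:
        return frozenset().union(*self.events)


@dataclass(frozen=True)
class Phase:
    """A block of interleaved trial types, each presented a fixed number of times."""

    trial_types: tuple[TrialType, ...]
    n_trials_per_type: int = 10

    def __post_init__(self) -> None:
        if not self.trial_types:
            raise ValueError("phase needs at least one trial type")
        if self.n_trials_per_type < 1:
            raise ValueError("n_trials_per_type must be >= 1")


@dataclass(frozen=True)
class Design:
    """An ordered sequence of phases plus the derived stimulus alphabet."""

    phases: tuple[Phase, ...]
    alphabet: tuple[str, ...] = field(default=())
    test_trials: tuple[TrialType, ...] = field(default=())

    def __post_init__(self) -> None:
        labels = sorted({s for p in self.phases for t in p.trial_types for s in t.stimuli})
        object.__setattr__(self, "alphabet", tuple(labels))
        probes = tuple(
            t for p in self.phases for t in p.trial_types if t.is_test
        )
        object.__setattr__(self, "test_trials", probes)

    @property
    def is_serial(self) -> bool:
        """True if any trial type has serial (multi-event) structure."""
        return any(t.is_serial for p in self.phases for t in p.trial_types)


def _parse_outcome(token: str):
    if token == "+":
        return 1.0
    if token == "-":
        return 0.0
    if token == "?":
        return None
    if _NUMBER_RE.match(token):
        return float(token)
    raise DesignParseError(f"cannot interpret outcome token {token!r}")


def _parse_trial(text: str) -> TrialType:
    raw = text.strip()
    if not raw:
        raise DesignParseError("empty trial type")
    parts = [p.strip() for p in raw.split(ARROW)]
    if any(p == "" for p in parts):
        raise DesignParseError(f"dangling arrow in {raw!r}")
    last = parts[-1]
    if _STIMSET_RE.match(last):
        event_parts, outcome = parts, 0.0  # pairing trial, ends without reward
    else:
        event_parts = parts[:-1]
        outcome = _parse_outcome(last)
        if not event_parts:
            raise DesignParseError(f"trial {raw!r} has an outcome but no stimuli")
    events = []
    for part in event_parts:
        if not _STIMSET_RE.match(part):
            raise DesignParseError(
                f"bad stimulus token {part!r} in {raw!r}: labels are single "
                "uppercase letters, compounds are letter runs"
            )
        if len(set(part)) != len(part):
            raise DesignParseError(f"repeated stimulus in compound {part!r}")
        events.append(frozenset(part))
    return TrialType(events=tuple(events), outcome=outcome)


def parse_design(text: str, n_trials_per_type: int = 10) -> Design:
    """Parse design notation into a :class:`Design`.

    Parameters
    ----------
    text:
        Notation string, e.g. ``"A→+; AB→+; A→-; B→?"``.  ``->`` is
        accepted for ``→``.
    n_trials_per_type:
        Presentations per trial type in every phase (the catalog default
        is 10 per phase).
    """
    if not text or not text.strip():
        raise DesignParseError("empty design")
    normalized = text.replace("->", ARROW)
    bad = re.sub(r"[A-Z0-9+\-?/;.\s→]", "", normalized)
    if bad:
        raise DesignParseError(f"unknown character(s) {bad!r} in design")
    phases = []
    for phase_text in normalized.split(";"):
        if not phase_text.strip():
            raise DesignParseError("empty phase (stray semicolon?)")
        trials = tuple(_parse_trial(t) for t in phase_text.split("/"))
        phases.append(Phase(trial_types=trials, n_trials_per_type=n_trials_per_type))
    return Design(phases=tuple(phases))


def _format_outcome(outcome: float | None) -> str:
    if outcome is None:
        return "?"
    if outcome == 1.0:
        return "+"
    if outcome == 0.0:
        return "-"
    return format(outcome, "g")


def _format_trial(trial: TrialType) -> str:
    events = [("".join(sorted(ev))) for ev in trial.events]
    return ARROW.join(events + [_format_outcome(trial.outcome)])


def format_design(design: Design) -> str:
    """Render a design in canonical notation; inverse of :func:`parse_design`.

    Canonical form sorts letters within a compound, always prints an
    explicit outcome token, and spaces separators as ``" / "`` and ``"; "``.
    """
    return "; ".join(
        " / ".join(_format_trial(t) for t in phase.trial_types)
        for phase in design.phases
    )


def expand_phase(phase: Phase, schedule: str = "alternating", seed: int = 0) -> list[TrialType]:
    """Expand a phase into a concrete ordered trial list.

    ``alternating`` round-robins the trial types (deterministic, the
    default); ``shuffled`` draws a seeded permutation with exactly
    ``n_trials_per_type`` instances of each type either way.
    """
    base = [t for _ in range(phase.n_trials_per_type) for t in phase.trial_types]
    if schedule == "alternating":
        return base
    if schedule == "shuffled":
        import numpy as np

        rng = np.random.default_rng(seed)
        return [base[i] for i in rng.permutation(len(base))]
    raise ValueError(f"unknown schedule {schedule!r}; use 'alternating' or 'shuffled'")
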