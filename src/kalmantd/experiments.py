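"""Named conditioning paradigms and their predicted response orderings.

The catalog covers the classic cue-competition and revaluation paradigms
at trial level under the Kalman filter (latent inhibition, overshadowing,
forward blocking, overexpectation, conditioned inhibition) and the
serial/second-order paradigms in real time under Kalman TD versus plain TD
(second-order conditioning after overshadowing, second-order extinction,
serial compound extinction, serial latent inhibition, recovery from
serial overshadowing).  Each experiment carries the directional
predictions the models make — e.g. that only the Bayesian learners show
retrospective revaluation, while TD responds identically across revalued
and control conditions — as machine-checkable ordering constraints.

Every phase runs 10 trials per trial type and parameters default to
σw² = 1, σr² = 1, τ² = 0.01, α = 0.3, γ = 0.98 with 4 CSC bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .design import Design, parse_design
from .models import ModelParams, ModelRun, run_model

__all__ = [
    "Constraint",
    "ExperimentSpec",
    "ExperimentResult",
    "catalog",
    "run_experiment",
    "ordering_report",
]

EQ_TOL = 1e-9


@dataclass(frozen=True)
class Constraint:
    """A directional prediction over probe responses.

    ``op`` is ">" (lhs strictly exceeds rhs), "=" (equal within
    tolerance) or "<=" (lhs at most rhs).  ``lhs`` is a (condition,
    model, probe-stimulus) triple; ``rhs`` is another triple or a number.
    """

    lhs: tuple[str, str, str]
    op: str
    rhs: tuple[str, str, str] | float
    note: str = ""


@dataclass(frozen=True)
class ExperimentSpec:
    """One catalog entry: named conditions, models to run, predictions."""

    name: str
    conditions: dict[str, str]  # condition name -> design notation
    models: tuple[str, ...]
    expected_ordering: tuple[Constraint, ...]
    n_trials_per_type: int = 10

    def design(self, condition: str, n_trials: int | None = None) -> Design:
        return parse_design(self.conditions[condition],
                            n_trials or self.n_trials_per_type)


@dataclass
class ExperimentResult:
    """Probe responses keyed by (condition, model, probe stimulus)."""

    spec: ExperimentSpec
    responses: dict[tuple[str, str, str], float]
    runs: dict[tuple[str, str], ModelRun] = field(repr=False, default=None)
    params: ModelParams = None


def _c(lhs, op, rhs, note=""):
    return Constraint(lhs=lhs, op=op, rhs=rhs, note=note)


def catalog() -> dict[str, ExperimentSpec]:
    """The simulation catalog: ten paradigms with their predicted orderings."""
    specs = [
        ExperimentSpec(
            name="latent_inhibition",
            conditions={"pre": "A→-; A→+; A→?", "no_pre": "A→+; A→?"},
            models=("KF",),
            expected_ordering=(
                _c(("no_pre", "KF", "A"), ">", ("pre", "KF", "A"),
                   "pre-exposure retards conditioning under the Kalman filter"),
            ),
        ),
        ExperimentSpec(
            name="overshadowing",
            conditions={
                "overshadowing": "AB→+; B→?",
                "unovershadowing": "AB→+; A→-; B→?",
                "element_control": "B→+; B→?",
            },
            models=("KF",),
            expected_ordering=(
                _c(("unovershadowing", "KF", "B"), ">", ("overshadowing", "KF", "B"),
                   "extinguishing A inflates B via negative covariance"),
                _c(("element_control", "KF", "B"), ">", ("overshadowing", "KF", "B"),
                   "compound training overshadows the element"),
            ),
        ),
        ExperimentSpec(
            name="forward_blocking",
            conditions={
                "blocking": "A→+; AB→+; B→?",
                "unblocking": "A→+; AB→+; A→-; B→?",
            },
            models=("KF",),
            expected_ordering=(
                _c(("unblocking", "KF", "B"), ">", ("blocking", "KF", "B"),
                   "extinction of the blocking stimulus recovers B"),
            ),
        ),
        ExperimentSpec(
            name="overexpectation",
            conditions={
                "overexpectation": "A→+ / B→+; AB→+; B→?",
                "unoverexpectation": "A→+ / B→+; AB→+; A→-; B→?",
            },
            models=("KF",),
            expected_ordering=(
                _c(("unoverexpectation", "KF", "B"), ">", ("overexpectation", "KF", "B"),
                   "extinction of one element recovers the other"),
            ),
        ),
        ExperimentSpec(
            name="conditioned_inhibition",
            conditions={
                "inhibition": "A→+ / AB→-; B→?",
                "uninhibition": "A→+ / AB→-; A→-; B→?",
            },
            models=("KF",),
            expected_ordering=(
                _c(("uninhibition", "KF", "B"), ">", ("inhibition", "KF", "B"),
                   "extinguishing the excitor weakens the inhibitor"),
                _c(("inhibition", "KF", "B"), "<=", 0.0, "B is a net inhibitor"),
                _c(("uninhibition", "KF", "B"), "<=", 0.0,
                   "recovery moves B toward, not past, zero"),
            ),
        ),
        ExperimentSpec(
            name="overshadowing_second_order",
            conditions={
                "ov_a": "AX→+ / BY→+; A→-; Z→X; Z→?",
                "ov_b": "AX→+ / BY→+; B→-; Z→X; Z→?",
            },
            models=("KTD", "TD"),
            expected_ordering=(
                _c(("ov_a", "KTD", "Z"), ">", ("ov_b", "KTD", "Z"),
                   "extinguishing X's overshadowing partner restores X as a "
                   "second-order reinforcer"),
                _c(("ov_a", "TD", "Z"), "=", ("ov_b", "TD", "Z"),
                   "TD cannot revalue the absent stimulus X"),
            ),
        ),
        ExperimentSpec(
            name="second_order_extinction",
            conditions={
                "extinction": "A→+; Z→A; A→-; Z→?",
                "control": "A→+; Z→A; Z→?",
            },
            models=("KTD", "TD"),
            expected_ordering=(
                _c(("control", "KTD", "Z"), ">", ("extinction", "KTD", "Z"),
                   "first-order extinction propagates to Z via positive covariance"),
                _c(("control", "TD", "Z"), "=", ("extinction", "TD", "Z"),
                   "TD leaves Z untouched by A's extinction"),
                _c(("control", "KTD", "Z"), ">", 0.0, "second-order acquisition"),
                _c(("control", "TD", "Z"), ">", 0.0, "second-order acquisition"),
            ),
        ),
        ExperimentSpec(
            name="serial_compound_extinction",
            conditions={
                "extinction": "Z→X→+; X→-; Z→?",
                "control": "Z→X→+; Z→?",
            },
            models=("KTD", "TD"),
            expected_ordering=(
                _c(("control", "KTD", "Z"), ">", ("extinction", "KTD", "Z"),
                   "extinguishing X lowers Z via positive Z-X covariance"),
                _c(("control", "TD", "Z"), "=", ("extinction", "TD", "Z"),
                   "TD value of Z is insensitive to X's extinction"),
            ),
        ),
        ExperimentSpec(
            name="serial_latent_inhibition",
            conditions={
                "pre": "X→-; Z→X→+; Z→?",
                "no_pre": "Z→X→+; Z→?",
            },
            models=("KTD", "TD"),
            expected_ordering=(
                _c(("no_pre", "KTD", "Z"), ">", ("pre", "KTD", "Z"),
                   "pre-exposing X shrinks its gain and retards the chain"),
                _c(("no_pre", "TD", "Z"), "=", ("pre", "TD", "Z"),
                   "TD learns nothing during zero-error pre-exposure"),
            ),
        ),
        ExperimentSpec(
            name="serial_recovery_from_overshadowing",
            conditions={"extinguish_z": "Z→X→+ / W→Y→+; Z→-; X→? / Y→?"},
            models=("KTD", "TD"),
            expected_ordering=(
                _c(("extinguish_z", "KTD", "X"), ">", ("extinguish_z", "KTD", "Y"),
                   "extinguishing the second-order stimulus recovers its "
                   "first-order partner from overshadowing"),
                _c(("extinguish_z", "TD", "X"), "=", ("extinguish_z", "TD", "Y"),
                   "TD predicts no recovery"),
            ),
        ),
    ]
    return {s.name: s for s in specs}


def _probe_stimulus(trial) -> str:
    # probes in the catalog are single stimuli; key responses by that letter
    return "".join(sorted(trial.events[0]))


def run_experiment(
    spec: ExperimentSpec,
    params: ModelParams | None = None,
    schedule: str = "alternating",
    seed: int = 0,
    n_trials_per_type: int | None = None,
) -> ExperimentResult:
    """Run every (condition, model) pairing of an experiment."""
    params = params or ModelParams()
    responses: dict[tuple[str, str, str], float] = {}
    runs: dict[tuple[str, str], ModelRun] = {}
    for cond in spec.conditions:
        design = spec.design(cond, n_trials_per_type)
        for model in spec.models:
            run = run_model(design, model=model, params=params,
                            schedule=schedule, seed=seed)
            runs[(cond, model)] = run
            for probe in design.test_trials:
                responses[(cond, model, _probe_stimulus(probe))] = run.responses[probe.label]
    return ExperimentResult(spec=spec, responses=responses, runs=runs, params=params)


def _resolve(result: ExperimentResult, ref):
    if isinstance(ref, tuple):
        return result.responses[ref], "/".join(ref)
    return float(ref), format(ref, "g")


def ordering_report(result: ExperimentResult, eq_tol: float = EQ_TOL) -> pd.DataFrame:
    """Check each predicted ordering; one row per constraint with its margin.

    Margin is lhs − rhs for ">" constraints, −|lhs − rhs| + eq_tol for
    "=", and rhs − lhs for "<=": positive margin means the prediction
    holds.
    """
    rows = []
    for c in result.spec.expected_ordering:
        refs = [r for r in (c.lhs, c.rhs) if isinstance(r, tuple)]
        if any(ref not in result.responses for ref in refs):
            continue  # constraint refers to a model/condition not run
        lhs, lhs_name = _resolve(result, c.lhs)
        rhs, rhs_name = _resolve(result, c.rhs)
        if c.op == ">":
            margin = lhs - rhs
            passed = margin > 0
        elif c.op == "=":
            margin = eq_tol - abs(lhs - rhs)
            passed = margin >= 0
        elif c.op == "<=":
            margin = rhs - lhs + eq_tol
            passed = margin >= 0
        else:
            raise ValueError(f"unknown constraint op {c.op!r}")
        rows.append({
            "experiment": result.spec.name,
            "lhs": lhs_name, "op": c.op, "rhs": rhs_name,
            "lhs_value": lhs, "rhs_value": rhs,
            "margin": margin, "passed": passed, "note": c.note,
        })
    return pd.DataFrame(rows)
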