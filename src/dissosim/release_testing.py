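"""Staged dissolution acceptance testing and real-time-release sampling plans.

Implements the compendial three-stage acceptance table for dissolution of
immediate-release products against a specification of Q percent dissolved at
a stated time:

    stage 1 (6 units):  pass if every unit >= Q + 5
    stage 2 (6 more, 12 total):  mean of 12 >= Q and no unit < Q - 15
    stage 3 (12 more, 24 total): mean of 24 >= Q, at most 2 units < Q - 15,
                                 and no unit < Q - 25

and the two real-time-release (RTRt) sampling modes: a pooled batch plan
(12 model predictions per batch, released on the predicted average meeting
Q + 5, otherwise routed to physical stage-3 testing) and a stratified plan
for continuous runs (12 evenly spaced segments, each held to the stage-2
criteria).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReleaseSpec",
    "StageResult",
    "usp711_evaluate",
    "rtrt_sampling_plan",
    "SamplingPlan",
    "evaluate_pooled_prediction",
]

STAGE_SIZES = (6, 6, 12)  # additional units drawn at S1, S2, S3


@dataclass
class ReleaseSpec:
    Q: float  # % label claim
    time_point_min: float

    def __post_init__(self) -> None:
        if not (0.0 < self.Q <= 100.0):
            raise ValueError("Q must lie in (0, 100]")


@dataclass
class StageResult:
    stage: str  # "S1" | "S2" | "S3"
    unit_values: list[float]
    verdict: str  # "pass" | "escalate" | "fail"


def usp711_evaluate(
    unit_values_by_stage: list[list[float]], spec: ReleaseSpec
) -> StageResult:
    """Evaluate staged dissolution acceptance.

    ``unit_values_by_stage`` holds the additional units drawn at each stage
    (6, then 6, then 12). Supplying fewer stages than needed yields an
    ``escalate`` verdict at the last supplied stage; a completed stage 3 that
    does not meet its criteria is a ``fail``.
    """
    q = spec.Q
    for vals, n_expected in zip(unit_values_by_stage, STAGE_SIZES):
        if len(vals) != n_expected:
            raise ValueError(
                f"stage unit counts must be {STAGE_SIZES}, got "
                f"{[len(v) for v in unit_values_by_stage]}"
            )
    if not (1 <= len(unit_values_by_stage) <= 3):
        raise ValueError("supply one to three stages of unit values")

    s1 = np.asarray(unit_values_by_stage[0], dtype=float)
    if np.all(s1 >= q + 5.0):
        return StageResult("S1", list(s1), "pass")
    if len(unit_values_by_stage) == 1:
        return StageResult("S1", list(s1), "escalate")

    s12 = np.concatenate([s1, unit_values_by_stage[1]])
    if s12.mean() >= q and np.all(s12 >= q - 15.0):
        return StageResult("S2", list(s12), "pass")
    if len(unit_values_by_stage) == 2:
        return StageResult("S2", list(s12), "escalate")

    s123 = np.concatenate([s12, unit_values_by_stage[2]])
    ok = (
        s123.mean() >= q
        and int(np.sum(s123 < q - 15.0)) <= 2
        and np.all(s123 >= q - 25.0)
    )
    return StageResult("S3", list(s123), "pass" if ok else "fail")


@dataclass
class SamplingPlan:
    mode: str  # "batch_pooled" | "continuous_stratified"
    n_slots: int
    slots: list[dict] = field(default_factory=list)
    acceptance: str = ""


def rtrt_sampling_plan(
    mode: str,
    batch_descriptor: dict,
    n_segments: int = 12,
) -> SamplingPlan:
    """Build an RTRt sampling plan.

    ``batch_descriptor`` supplies ``run_length_min`` (continuous) or
    ``n_units`` (batch). Batch-pooled plans carry 12 prediction slots and
    release on the predicted batch average meeting Q + 5; continuous plans
    partition the run into ``n_segments`` equal segments, each evaluated
    against the stage-2 criteria.
    """
    if mode == "batch_pooled":
        n_units = batch_descriptor.get("n_units")
        if n_units is not None and n_units < n_segments:
            raise ValueError("batch too small for the pooled prediction plan")
        slots = [{"slot": i + 1} for i in range(n_segments)]
        return SamplingPlan(
            mode=mode, n_slots=n_segments, slots=slots,
            acceptance="predicted batch average >= Q + 5; otherwise route to "
                       "physical stage-3 testing",
        )
    if mode == "continuous_stratified":
        run_len = batch_descriptor.get("run_length_min")
        if run_len is None or run_len <= 0:
            raise ValueError("continuous plan needs a positive run_length_min")
        if run_len < n_segments:
            raise ValueError("run too short to stratify into segments")
        edges = np.linspace(0.0, run_len, n_segments + 1)
        slots = [
            {"segment": i + 1, "start_min": float(a), "end_min": float(b)}
            for i, (a, b) in enumerate(zip(edges[:-1], edges[1:]))
        ]
        return SamplingPlan(
            mode=mode, n_slots=n_segments, slots=slots,
            acceptance="each segment evaluated against stage-2 criteria",
        )
    raise ValueError(f"unknown RTRt mode {mode!r}")


def evaluate_pooled_prediction(
    predicted_values: list[float], spec: ReleaseSpec
) -> str:
    """Release verdict for a pooled-prediction batch: ``release`` if the
    predicted average meets Q + 5, else ``physical_stage3_required``."""
    avg = float(np.mean(predicted_values))
    return "release" if avg >= spec.Q + 5.0 else "physical_stage3_required"
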