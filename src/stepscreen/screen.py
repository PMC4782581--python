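"""The stepped detection algorithm: gate questions, then the full instrument.

The three-step procedure this module evaluates:

1. ask a single heart-mind-problems question; stop (screen negative) on "no";
2. ask about functional impairment due to heart-mind problems; stop on "no";
3. administer the full nine-item instrument to the remaining patients and
   call positive those with total score at or above the terminal cutoff
   (default 10).

Relative to universal screening at the same cutoff the gates can only
remove screen positives, so the algorithm trades a bounded sensitivity loss
for a reduction in instrument workload and in false positives — the
quantities :func:`evaluate` reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .cohort import MAX_TOTAL, SubjectRecord
from .metrics import (
    ConfusionTable,
    MetricSet,
    Undefined,
    from_labels,
    point_metrics,
    round_half_up,
)

__all__ = [
    "ScreenOutcome",
    "ScreenReport",
    "ScreenSpec",
    "StageAttrition",
    "classify",
    "evaluate",
    "stage_attrition",
]

DEFAULT_GATES = ("heart_mind", "impairment")


@dataclass(frozen=True)
class ScreenSpec:
    """Ordered gate questions plus the terminal total-score cutoff."""

    gates: tuple[str, ...] = DEFAULT_GATES
    terminal_cutoff: int = 10

    def __post_init__(self) -> None:
        if len(set(self.gates)) != len(self.gates):
            raise ValueError("gate names must be distinct")
        if not 0 <= self.terminal_cutoff <= MAX_TOTAL + 1:
            raise ValueError(f"terminal_cutoff must lie in 0..{MAX_TOTAL + 1}")


@dataclass(frozen=True)
class ScreenOutcome:
    """Result of running one subject through the stepped procedure.

    ``stage`` is the 1-based stage at which screening terminated: a gate
    index for a gate "no", or ``len(gates) + 1`` for subjects who reached
    the full instrument (whether they screened positive or negative there).
    """

    positive: bool
    stage: int


def _gate_value(record: SubjectRecord, gate: str, missing_as_negative: bool) -> int:
    try:
        value = getattr(record, gate)
    except AttributeError:
        raise ValueError(f"record {record.id!r} has no gate field {gate!r}") from None
    if value is None:
        if missing_as_negative:
            return 0
        raise ValueError(f"record {record.id!r}: gate {gate!r} is missing")
    if value not in (0, 1):
        raise ValueError(f"record {record.id!r}: gate {gate!r} must be binary")
    return int(value)


def classify(
    record: SubjectRecord, spec: ScreenSpec, missing_as_negative: bool = False
) -> ScreenOutcome:
    """Run one subject through the gates and, if all pass, the instrument.

    Deterministic: negative at the first gate answered "no"; otherwise
    positive iff total ≥ terminal cutoff.  With an empty gate list this
    reduces to universal screening at the cutoff.  A missing (None) gate
    answer is an error unless ``missing_as_negative`` is set.
    """
    for k, gate in enumerate(spec.gates, start=1):
        if _gate_value(record, gate, missing_as_negative) == 0:
            return ScreenOutcome(positive=False, stage=k)
    final = len(spec.gates) + 1
    return ScreenOutcome(positive=record.total >= spec.terminal_cutoff, stage=final)


@dataclass(frozen=True)
class StageAttrition:
    """Attrition bookkeeping for one stage of the procedure."""

    stage: int
    name: str
    entrants: int
    passers: int
    positives_lost: int


def stage_attrition(
    records: Sequence[SubjectRecord],
    spec: ScreenSpec,
    missing_as_negative: bool = False,
) -> list[StageAttrition]:
    """Entrants, passers and reference-positive losses at every stage.

    Gate stages lose the reference positives who answer "no"; the final
    instrument stage loses the reference-positive entrants scoring below
    the terminal cutoff.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    current = list(records)
    out: list[StageAttrition] = []
    for k, gate in enumerate(spec.gates, start=1):
        passers = [r for r in current if _gate_value(r, gate, missing_as_negative) == 1]
        lost = sum(r.reference for r in current) - sum(r.reference for r in passers)
        out.append(
            StageAttrition(
                stage=k,
                name=gate,
                entrants=len(current),
                passers=len(passers),
                positives_lost=lost,
            )
        )
        current = passers
    positives_in = sum(r.reference for r in current)
    screen_pos = [r for r in current if r.total >= spec.terminal_cutoff]
    out.append(
        StageAttrition(
            stage=len(spec.gates) + 1,
            name=f"instrument>={spec.terminal_cutoff}",
            entrants=len(current),
            passers=len(screen_pos),
            positives_lost=positives_in - sum(r.reference for r in screen_pos),
        )
    )
    return out


@dataclass(frozen=True)
class ScreenReport:
    """Cumulative accuracy and workload of the stepped procedure.

    ``workload_fraction`` is the share of all subjects who must complete the
    full instrument (those passing every gate).  ``fp_universal`` is the
    false-positive count of universal screening at the same terminal cutoff;
    ``fp_reduction`` is the percent reduction achieved by the gates
    (undefined when universal screening produces no false positives).
    """

    table: ConfusionTable
    metrics: MetricSet
    stages: tuple[StageAttrition, ...]
    workload_fraction: float
    fp_universal: int
    fp_algorithm: int
    fp_reduction: float | Undefined

    def flow_summary(self) -> str:
        """Human-readable per-stage flow, percentages of all subjects screened."""
        n = self.stages[0].entrants
        lines = []
        for st in self.stages:
            pct = 100.0 * st.passers / n
            lines.append(
                f"Step {st.stage} ({st.name}): {st.entrants} entered, "
                f"{st.passers} passed ({pct:.0f}% of cohort), "
                f"{st.positives_lost} reference positive(s) lost"
            )
        lines.append(
            f"Instrument workload: {round_half_up(100 * self.workload_fraction, 1):.1f}% "
            f"of cohort completes the full questionnaire"
        )
        if isinstance(self.fp_reduction, Undefined):
            lines.append("False-positive reduction vs universal screening: n/a")
        else:
            lines.append(
                f"False positives: {self.fp_universal} universal vs "
                f"{self.fp_algorithm} stepped "
                f"({round_half_up(self.fp_reduction, 0):.0f}% reduction)"
            )
        return "\n".join(lines)


def evaluate(
    records: Sequence[SubjectRecord],
    spec: ScreenSpec = ScreenSpec(),
    level: float = 0.95,
    ci_method: str = "wilson",
    missing_as_negative: bool = False,
) -> ScreenReport:
    """Evaluate the stepped procedure on a cohort against the reference.

    Builds the algorithm-versus-reference confusion table from
    :func:`classify`, recomputes universal screening at the same terminal
    cutoff (no gates) for the false-positive comparison, and attaches the
    full statistic set with confidence intervals.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    outcomes = [classify(r, spec, missing_as_negative) for r in records]
    refs = [r.reference for r in records]
    table = from_labels([int(o.positive) for o in outcomes], refs)
    stages = stage_attrition(records, spec, missing_as_negative)
    workload = stages[-1].entrants / len(records)

    universal = from_labels(
        [int(r.total >= spec.terminal_cutoff) for r in records], refs
    )
    fp_u, fp_a = universal.fp, table.fp
    reduction: float | Undefined
    if fp_u > 0:
        reduction = 100.0 * (fp_u - fp_a) / fp_u
    else:
        reduction = Undefined("fp_universal=0")

    return ScreenReport(
        table=table,
        metrics=point_metrics(table, level, ci_method),
        stages=tuple(stages),
        workload_fraction=workload,
        fp_universal=fp_u,
        fp_algorithm=fp_a,
        fp_reduction=reduction,
    )
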