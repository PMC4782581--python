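"""Accuracy-by-cutoff tables and ROC/AUC for total-score screeners.

A subject screens positive when their total score is greater than or equal
to the cutoff (the convention of published accuracy tables, whose rows are
labelled "≥ k"); no strictly-greater variant is offered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MAX_TOTAL, SubjectRecord
from .metrics import (
    ConfusionTable,
    MetricSet,
    from_labels,
    is_defined,
    point_metrics,
    round_half_up,
)

__all__ = ["SweepRow", "SweepTable", "auc", "best_cutoff", "sweep"]


@dataclass(frozen=True)
class SweepRow:
    """One cutoff's confusion table and accuracy statistics."""

    cutoff: int
    table: ConfusionTable
    metrics: MetricSet


@dataclass(frozen=True)
class SweepTable:
    """Rows sorted by ascending cutoff over a fixed cohort."""

    rows: tuple[SweepRow, ...]
    n_positive: int
    n_negative: int

    def __iter__(self):
        return iter(self.rows)

    def row_at(self, cutoff: int) -> SweepRow:
        for row in self.rows:
            if row.cutoff == cutoff:
                return row
        raise KeyError(f"no row at cutoff {cutoff}")

    def to_frame(self) -> pd.DataFrame:
        """Full-precision numeric table (NaN where a statistic is undefined)."""
        recs = []
        for row in self.rows:
            m = row.metrics
            recs.append(
                {
                    "cutoff": row.cutoff,
                    "tp": row.table.tp,
                    "tn": row.table.tn,
                    **{
                        name: (getattr(m, name) if is_defined(getattr(m, name)) else np.nan)
                        for name in (
                            "sensitivity",
                            "specificity",
                            "ppv",
                            "npv",
                            "lr_pos",
                            "lr_neg",
                            "dor",
                            "youden_j",
                        )
                    },
                }
            )
        return pd.DataFrame.from_records(recs)

    def to_report_frame(self, digits: int = 2) -> pd.DataFrame:
        """Report table: statistics rounded to ``digits``, undefined as ``n/a``.

        Youden's J is derived from the *displayed* (rounded) sensitivity and
        specificity so that J = sens + spec − 1 holds at report precision —
        the convention of published accuracy tables.  Full-precision J stays
        available through :meth:`to_frame`.
        """
        recs = []
        for row in self.rows:
            m = row.metrics
            rendered = m.rendered(digits)
            if is_defined(m.sensitivity) and is_defined(m.specificity):
                j_disp = round_half_up(
                    round_half_up(m.sensitivity, digits)
                    + round_half_up(m.specificity, digits)
                    - 1.0,
                    digits,
                )
                rendered["youden_j"] = f"{j_disp:.{digits}f}"
            recs.append(
                {
                    "cutoff": f">= {row.cutoff}",
                    "tp": row.table.tp,
                    "tn": row.table.tn,
                    **{
                        name: rendered[name]
                        for name in (
                            "sensitivity",
                            "specificity",
                            "ppv",
                            "npv",
                            "lr_pos",
                            "lr_neg",
                            "dor",
                            "youden_j",
                        )
                    },
                }
            )
        return pd.DataFrame.from_records(recs)


def _totals_and_refs(records: Sequence[SubjectRecord]) -> tuple[np.ndarray, np.ndarray]:
    if len(records) == 0:
        raise ValueError("empty cohort")
    totals = np.array([r.total for r in records])
    refs = np.array([r.reference for r in records])
    if totals.min() < 0 or totals.max() > MAX_TOTAL:
        raise ValueError(f"totals must lie in 0..{MAX_TOTAL}")
    return totals, refs


def sweep(
    records: Sequence[SubjectRecord],
    cutoffs: Sequence[int],
    level: float = 0.95,
    ci_method: str = "wilson",
) -> SweepTable:
    """Accuracy statistics at every requested cutoff (positive iff total ≥ cutoff)."""
    totals, refs = _totals_and_refs(records)
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ValueError("no cutoffs requested")
    for c in cutoffs:
        if not 0 <= int(c) <= MAX_TOTAL + 1:
            raise ValueError(f"cutoff {c} outside 0..{MAX_TOTAL + 1}")
    rows = []
    for c in sorted(int(c) for c in cutoffs):
        table = from_labels((totals >= c).astype(int), refs)
        rows.append(
            SweepRow(cutoff=c, table=table, metrics=point_metrics(table, level, ci_method))
        )
    return SweepTable(
        rows=tuple(rows),
        n_positive=int(refs.sum()),
        n_negative=int(len(refs) - refs.sum()),
    )


def auc(scores: Sequence[int], labels: Sequence) -> float:
    """Area under the empirical ROC curve.

    Computed as the Mann–Whitney probability that a reference-positive
    subject outscores a reference-negative one, with tied pairs counted
    one-half; identical to the trapezoidal area under the empirical ROC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both reference groups must be non-empty")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u) / (pos.size * neg.size)


def best_cutoff(
    table: SweepTable, criterion: str = "youden", floor: float | None = None
) -> int:
    """The cutoff optimizing a selection criterion; ties go to the lower cutoff.

    ``youden``: maximize Youden's J.  ``dor``: maximize the diagnostic odds
    ratio (rows where it is undefined are excluded).  ``sensitivity_floor``:
    among rows with sensitivity ≥ ``floor``, maximize specificity.
    The lowest qualifying cutoff wins ties, favouring sensitivity — the
    screening-context preference.
    """
    if not table.rows:
        raise ValueError("empty sweep table")
    if criterion == "youden":
        candidates = [
            (row.metrics.youden_j, row.cutoff)
            for row in table.rows
            if is_defined(row.metrics.youden_j)
        ]
    elif criterion == "dor":
        candidates = [
            (row.metrics.dor, row.cutoff)
            for row in table.rows
            if is_defined(row.metrics.dor)
        ]
    elif criterion == "sensitivity_floor":
        if floor is None or not 0.0 <= floor <= 1.0:
            raise ValueError("criterion 'sensitivity_floor' needs floor in [0,1]")
        candidates = [
            (row.metrics.specificity, row.cutoff)
            for row in table.rows
            if is_defined(row.metrics.sensitivity)
            and is_defined(row.metrics.specificity)
            and row.metrics.sensitivity >= floor
        ]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    if not candidates:
        raise ValueError(f"no row has a defined value under criterion {criterion!r}")
    best_value = max(v for v, _ in candidates)
    return min(c for v, c in candidates if v == best_value)
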