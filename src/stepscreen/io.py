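"""Cohort file I/O: comma-separated, UTF-8, header required, 0/1 binaries.

Columns: ``id,item1..item9,total,heart_mind,brain_mind,impairment,reference``.
Validation errors name the offending data row (1-based, excluding the
header) and field.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .cohort import N_ITEMS, SubjectRecord

__all__ = ["COLUMNS", "CohortFormatError", "read_cohort", "write_cohort"]

COLUMNS = (
    ["id"]
    + [f"item{i}" for i in range(1, N_ITEMS + 1)]
    + ["total", "heart_mind", "brain_mind", "impairment", "reference"]
)


class CohortFormatError(ValueError):
    """A cohort file violates the documented schema."""


def write_cohort(records: Sequence[SubjectRecord], path) -> None:
    """Write records as the documented CSV schema."""
    rows = [
        {
            "id": r.id,
            **{f"item{i + 1}": r.items[i] for i in range(N_ITEMS)},
            "total": r.total,
            "heart_mind": r.heart_mind,
            "brain_mind": r.brain_mind,
            "impairment": r.impairment,
            "reference": r.reference,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)


def read_cohort(path) -> list[SubjectRecord]:
    """Read and validate a cohort CSV, returning subject records.

    Raises :class:`CohortFormatError` naming the row and field on any
    violation: missing column, non-integer or out-of-range item score,
    total not equal to the item sum, non-binary flag, or an impairment
    endorsement without heart-mind endorsement.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise CohortFormatError(f"{path}: empty cohort file") from None
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(frame) == 0:
        raise CohortFormatError(f"{path}: empty cohort")

    records = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=1):
        values = {}
        for col in COLUMNS[1:]:
            raw = getattr(row, col)
            try:
                values[col] = int(raw)
            except (TypeError, ValueError):
                raise CohortFormatError(
                    f"{path}: row {row_no}, field {col!r}: "
                    f"expected an integer, got {raw!r}"
                ) from None
        try:
            records.append(
                SubjectRecord(
                    id=str(row.id),
                    items=tuple(values[f"item{i}"] for i in range(1, N_ITEMS + 1)),
                    total=values["total"],
                    heart_mind=values["heart_mind"],
                    brain_mind=values["brain_mind"],
                    impairment=values["impairment"],
                    reference=values["reference"],
                )
            )
        except ValueError as exc:
            raise CohortFormatError(f"{path}: row {row_no}: {exc}") from None
    return records
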