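"""Scale reliability and item-level analyses of the nine-item instrument.

Operates on an item matrix (subjects × 9 ordinal scores in {0,1,2,3}) and an
aligned binary reference-status vector.  Provides Cronbach's alpha,
corrected item-total correlations, per-item group comparisons with a
Bonferroni-type correction (raw p multiplied by the number of items, capped
at 1), and per-item positive likelihood ratios for the dichotomized items.

Per-item undefined values (zero-variance item, zero endorsement among
reference negatives) are returned as NaN inside arrays/frames; report
renderers display them as ``n/a``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MAX_ITEM, N_ITEMS, SubjectRecord
from .metrics import Undefined

__all__ = [
    "ITEM_LABELS",
    "cronbach_alpha",
    "group_item_comparison",
    "item_lr_pos",
    "item_total_correlations",
    "items_from_records",
]

ITEM_LABELS = (
    "anhedonia",
    "depressed mood",
    "sleep difficulties",
    "fatigue",
    "appetite problems",
    "self-blame / damaged family status",
    "concentration difficulties",
    "psychomotor agitation or retardation",
    "suicidality",
)


def items_from_records(
    records: Sequence[SubjectRecord],
) -> tuple[np.ndarray, np.ndarray]:
    """Item matrix and reference vector from a record sequence."""
    items = np.array([r.items for r in records], dtype=int)
    refs = np.array([r.reference for r in records], dtype=int)
    return items, refs


def _validate_items(m, min_items: int = 2, min_subjects: int = 2) -> np.ndarray:
    arr = np.asarray(m)
    if arr.ndim != 2:
        raise ValueError("item matrix must be 2-dimensional (subjects x items)")
    n, k = arr.shape
    if k < min_items or n < min_subjects:
        raise ValueError(f"need at least {min_subjects} subjects and {min_items} items")
    if not np.isin(arr, range(MAX_ITEM + 1)).all():
        raise ValueError(f"item scores must lie in 0..{MAX_ITEM}")
    return arr.astype(float)


def cronbach_alpha(m) -> float | Undefined:
    """Internal-consistency reliability of the summed scale.

    ``alpha = k/(k-1) * (1 - sum of item variances / total-score variance)``
    with sample (n−1) variances.  Undefined when the total score has zero
    variance.
    """
    arr = _validate_items(m)
    k = arr.shape[1]
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return Undefined("zero total-score variance")
    item_var = arr.var(axis=0, ddof=1).sum()
    return k / (k - 1) * (1.0 - item_var / total_var)


def item_total_correlations(m) -> np.ndarray:
    """Corrected item-total correlations (item vs sum of the other items).

    Returns one Pearson correlation per item; NaN for a zero-variance item.
    """
    arr = _validate_items(m)
    total = arr.sum(axis=1)
    out = np.empty(arr.shape[1])
    for i in range(arr.shape[1]):
        rest = total - arr[:, i]
        if arr[:, i].std(ddof=1) == 0 or rest.std(ddof=1) == 0:
            out[i] = np.nan
        else:
            out[i] = np.corrcoef(arr[:, i], rest)[0, 1]
    return out


def item_lr_pos(m, reference, endorse_threshold: int = 1) -> np.ndarray:
    """Positive likelihood ratio of each dichotomized item.

    An item is "endorsed" when its score is at least ``endorse_threshold``
    (default 1, i.e. any endorsement beyond "not at all").  LR+ is the
    endorsement rate among reference positives over the rate among
    reference negatives; NaN when no reference negative endorses the item.
    """
    if endorse_threshold not in (1, 2, 3):
        raise ValueError(f"endorse_threshold must be 1, 2 or 3, got {endorse_threshold}")
    arr = _validate_items(m, min_subjects=1)
    refs = np.asarray(reference, dtype=int)
    if refs.shape[0] != arr.shape[0]:
        raise ValueError("reference vector must align with the item matrix rows")
    pos, neg = arr[refs == 1], arr[refs == 0]
    if pos.shape[0] == 0 or neg.shape[0] == 0:
        raise ValueError("both reference groups must be non-empty")
    p_pos = (pos >= endorse_threshold).mean(axis=0)
    p_neg = (neg >= endorse_threshold).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = np.where(p_neg > 0, p_pos / p_neg, np.nan)
    return lr


def group_item_comparison(
    m,
    reference,
    equal_var: bool = False,
    endorse_threshold: int = 1,
) -> pd.DataFrame:
    """Per-item comparison of reference-positive vs reference-negative groups.

    One row per item: group means and sample SDs, the two-sample t statistic
    (Welch by default, pooled-variance with ``equal_var=True``; sign is
    positive when the reference-positive mean is larger), the raw and
    Bonferroni-adjusted p-value (raw p × number of items, capped at 1), the
    corrected item-total correlation on the whole cohort, and the per-item
    positive likelihood ratio at ``endorse_threshold``.
    """
    arr = _validate_items(m)
    refs = np.asarray(reference, dtype=int)
    if refs.shape[0] != arr.shape[0]:
        raise ValueError("reference vector must align with the item matrix rows")
    pos, neg = arr[refs == 1], arr[refs == 0]
    if pos.shape[0] < 2 or neg.shape[0] < 2:
        raise ValueError("each reference group needs at least 2 subjects")

    k = arr.shape[1]
    t_res = stats.ttest_ind(pos, neg, axis=0, equal_var=equal_var)
    p_raw = np.asarray(t_res.pvalue)
    labels = list(ITEM_LABELS) if k == N_ITEMS else [f"item{i + 1}" for i in range(k)]
    return pd.DataFrame(
        {
            "item": np.arange(1, k + 1),
            "label": labels,
            "mean_neg": neg.mean(axis=0),
            "sd_neg": neg.std(axis=0, ddof=1),
            "mean_pos": pos.mean(axis=0),
            "sd_pos": pos.std(axis=0, ddof=1),
            "t": np.asarray(t_res.statistic),
            "p_raw": p_raw,
            "p_adj": np.minimum(1.0, k * p_raw),
            "item_total_r": item_total_correlations(arr),
            "lr_pos": item_lr_pos(arr, refs, endorse_threshold),
        }
    )
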