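"""Diagnostic-accuracy statistics and confidence intervals from 2x2 confusion tables.

A screening instrument is compared against a reference ("gold standard")
diagnosis by cross-tabulating screen result against reference status:

===============  ==================  ==================
                 reference positive  reference negative
===============  ==================  ==================
screen positive  tp                  fp
screen negative  fn                  tn
===============  ==================  ==================

From this table the module computes the nine standard accuracy statistics —
sensitivity, specificity, predictive values, likelihood ratios, diagnostic
odds ratio, Youden's J and prevalence — together with confidence intervals:
Wilson score or Clopper–Pearson for the proportions, the asymptotic log
method for likelihood ratios, and Woolf's log method for the odds ratio.

Statistics whose denominator is zero are reported as a typed
:class:`Undefined` marker rather than raised or coerced to NaN, so reports
can render them as ``n/a``.  A negative likelihood ratio of exactly zero
(no false negatives, positive specificity) is a defined value, 0.0.

All computation is at full floating precision; :func:`round_half_up` is the
single rounding rule used for display (round-half-up, the convention of
published accuracy tables, where ``round(0.125, 2) == 0.13``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from math import exp, log, sqrt
from typing import Mapping, Sequence, Union

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionTable",
    "Interval",
    "MetricSet",
    "Undefined",
    "dor_interval",
    "exact_interval",
    "from_counts",
    "from_labels",
    "is_defined",
    "lr_interval",
    "point_metrics",
    "render_value",
    "round_half_up",
    "wilson_interval",
]


@dataclass(frozen=True)
class Undefined:
    """Marker for a statistic or interval with a zero denominator.

    Carries a short machine-readable reason code (e.g. ``"fn=0"``).
    Renders as ``n/a`` in reports and is falsy.
    """

    reason: str = ""

    def __bool__(self) -> bool:  # pragma: no cover - trivial
        return False

    def __repr__(self) -> str:
        return f"Undefined({self.reason!r})"


MaybeFloat = Union[float, Undefined]


def is_defined(value: object) -> bool:
    """True unless *value* is an :class:`Undefined` marker."""
    return not isinstance(value, Undefined)


def round_half_up(x: float, digits: int = 2) -> float:
    """Round with ties away from zero (0.005 -> 0.01), the report convention."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def render_value(value: MaybeFloat, digits: int = 2) -> str:
    """Format a statistic for a report: fixed decimals, ``n/a`` if undefined."""
    if isinstance(value, Undefined):
        return "n/a"
    return f"{round_half_up(value, digits):.{digits}f}"


def _check_count(name: str, value: object) -> int:
    if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
        raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")
    return int(value)


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 cross-tabulation of screen result against reference diagnosis."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            object.__setattr__(self, name, _check_count(name, getattr(self, name)))
        if self.total == 0:
            raise ValueError("confusion table must contain at least one subject")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        """Number of reference-positive subjects (tp + fn)."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        """Number of reference-negative subjects (fp + tn)."""
        return self.fp + self.tn

    @property
    def n_screen_positive(self) -> int:
        return self.tp + self.fp

    @property
    def n_screen_negative(self) -> int:
        return self.fn + self.tn

    def scaled(self, k: int) -> "ConfusionTable":
        """Table with every cell multiplied by a positive integer k."""
        k = _check_count("k", k)
        if k == 0:
            raise ValueError("scale factor must be positive")
        return ConfusionTable(self.tp * k, self.fp * k, self.fn * k, self.tn * k)


def from_counts(tp: int, fp: int, fn: int, tn: int) -> ConfusionTable:
    """Build a validated :class:`ConfusionTable` from the four cell counts."""
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def _as_binary(name: str, values: Sequence) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if arr.dtype == bool:
        arr = arr.astype(int)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return arr.astype(int)


def from_labels(screen_flags: Sequence, reference_flags: Sequence) -> ConfusionTable:
    """Tally a confusion table from paired binary screen / reference labels."""
    screen = _as_binary("screen_flags", screen_flags)
    ref = _as_binary("reference_flags", reference_flags)
    if screen.shape != ref.shape:
        raise ValueError(
            f"length mismatch: {screen.size} screen flags vs {ref.size} reference flags"
        )
    return ConfusionTable(
        tp=int(np.sum((screen == 1) & (ref == 1))),
        fp=int(np.sum((screen == 1) & (ref == 0))),
        fn=int(np.sum((screen == 0) & (ref == 1))),
        tn=int(np.sum((screen == 0) & (ref == 0))),
    )


@dataclass(frozen=True)
class Interval:
    """A two-sided confidence interval."""

    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError(f"confidence level must be in (0,1), got {self.level}")
        if self.lower > self.upper + 1e-12:
            raise ValueError(f"lower {self.lower} exceeds upper {self.upper}")

    def contains(self, x: float) -> bool:
        return self.lower - 1e-12 <= x <= self.upper + 1e-12

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def render(self, digits: int = 2) -> str:
        lo = round_half_up(self.lower, digits)
        hi = round_half_up(self.upper, digits)
        return f"({lo:.{digits}f}—{hi:.{digits}f})"


MaybeInterval = Union[Interval, Undefined]


def _check_proportion_args(successes: int, n: int, level: float) -> tuple[int, int]:
    successes = _check_count("successes", successes)
    n = _check_count("n", n)
    if n < 1:
        raise ValueError("n must be at least 1")
    if successes > n:
        raise ValueError(f"successes ({successes}) exceed n ({n})")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    return successes, n


def wilson_interval(successes: int, n: int, level: float = 0.95) -> Interval:
    """Wilson score interval for a binomial proportion, clipped to [0, 1]."""
    successes, n = _check_proportion_args(successes, n, level)
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level, method="wilson")
    return Interval(lower=max(0.0, float(lo)), upper=min(1.0, float(hi)), level=level)


def exact_interval(successes: int, n: int, level: float = 0.95) -> Interval:
    """Clopper–Pearson (exact) interval via beta-distribution quantiles.

    Lower bound is exactly 0 when ``successes == 0``; upper bound is exactly 1
    when ``successes == n``.
    """
    successes, n = _check_proportion_args(successes, n, level)
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level, method="beta")
    lo = 0.0 if successes == 0 else float(lo)
    hi = 1.0 if successes == n else float(hi)
    return Interval(lower=max(0.0, lo), upper=min(1.0, hi), level=level)


def _z(level: float) -> float:
    return float(stats.norm.ppf((1.0 + level) / 2.0))


def lr_interval(
    ct: ConfusionTable, which: str = "positive", level: float = 0.95
) -> MaybeInterval:
    """Log-method interval for a likelihood ratio.

    ``exp(ln LR ± z·SE)`` with ``SE(ln LR+) = sqrt(1/tp − 1/(tp+fn) + 1/fp −
    1/(fp+tn))`` and the fn/tn analogue for LR−.  Returns an
    :class:`Undefined` marker naming the zero cell when the ratio or its
    standard error does not exist.
    """
    if which not in ("positive", "negative"):
        raise ValueError(f"which must be 'positive' or 'negative', got {which!r}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    if which == "positive":
        a, b = ct.tp, ct.fp
        names = ("tp", "fp")
    else:
        a, b = ct.fn, ct.tn
        names = ("fn", "tn")
    if a == 0:
        return Undefined(f"{names[0]}=0")
    if b == 0:
        return Undefined(f"{names[1]}=0")
    lr = (a / ct.n_positive) / (b / ct.n_negative)
    se = sqrt(1.0 / a - 1.0 / ct.n_positive + 1.0 / b - 1.0 / ct.n_negative)
    half = _z(level) * se
    ln_lr = log(lr)
    return Interval(lower=exp(ln_lr - half), upper=exp(ln_lr + half), level=level)


def dor_interval(ct: ConfusionTable, level: float = 0.95) -> MaybeInterval:
    """Woolf log-method interval for the diagnostic odds ratio.

    ``exp(ln DOR ± z·sqrt(1/tp + 1/fp + 1/fn + 1/tn))``; undefined if any
    cell is zero.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    for name in ("tp", "fp", "fn", "tn"):
        if getattr(ct, name) == 0:
            return Undefined(f"{name}=0")
    dor = (ct.tp * ct.tn) / (ct.fp * ct.fn)
    se = sqrt(1.0 / ct.tp + 1.0 / ct.fp + 1.0 / ct.fn + 1.0 / ct.tn)
    half = _z(level) * se
    return Interval(lower=exp(log(dor) - half), upper=exp(log(dor) + half), level=level)


@dataclass(frozen=True)
class MetricSet:
    """The nine accuracy statistics of a confusion table, with intervals.

    Ratio statistics with a zero denominator carry an :class:`Undefined`
    marker instead of a number.  ``intervals`` maps statistic names
    (``"sensitivity"`` ... ``"dor"``) to :class:`Interval` objects or
    :class:`Undefined` markers.
    """

    sensitivity: MaybeFloat
    specificity: MaybeFloat
    ppv: MaybeFloat
    npv: MaybeFloat
    lr_pos: MaybeFloat
    lr_neg: MaybeFloat
    dor: MaybeFloat
    youden_j: MaybeFloat
    prevalence: float
    intervals: Mapping[str, MaybeInterval] = field(default_factory=dict)

    def rendered(self, digits: int = 2) -> dict[str, str]:
        """Report-ready strings for the nine statistics (``n/a`` if undefined)."""
        return {
            name: render_value(getattr(self, name), digits)
            for name in (
                "sensitivity",
                "specificity",
                "ppv",
                "npv",
                "lr_pos",
                "lr_neg",
                "dor",
                "youden_j",
                "prevalence",
            )
        }


def _ratio(num: float, den: float, reason: str) -> MaybeFloat:
    if den == 0:
        return Undefined(reason)
    return num / den


def point_metrics(
    ct: ConfusionTable,
    level: float = 0.95,
    ci_method: str = "wilson",
    haldane: bool = False,
    with_intervals: bool = True,
) -> MetricSet:
    """All nine accuracy statistics of *ct* at full precision.

    Parameters
    ----------
    ct : ConfusionTable
    level : confidence level for the attached intervals.
    ci_method : ``"wilson"`` (score) or ``"exact"`` (Clopper–Pearson) for the
        four proportion statistics.  Likelihood-ratio intervals always use the
        log method and the odds ratio Woolf's method.
    haldane : apply the Haldane–Anscombe +0.5 cell correction to the ratio
        statistics (LR+, LR−, DOR) so zero cells yield finite values.  Off by
        default; undefined ratios are then reported as markers.
    with_intervals : attach confidence intervals (on by default).
    """
    if ci_method not in ("wilson", "exact"):
        raise ValueError(f"ci_method must be 'wilson' or 'exact', got {ci_method!r}")
    prop_ci = wilson_interval if ci_method == "wilson" else exact_interval

    sens = _ratio(ct.tp, ct.n_positive, "no reference positives")
    spec = _ratio(ct.tn, ct.n_negative, "no reference negatives")
    ppv = _ratio(ct.tp, ct.n_screen_positive, "no screen positives")
    npv = _ratio(ct.tn, ct.n_screen_negative, "no screen negatives")

    if haldane:
        tp, fp, fn, tn = (c + 0.5 for c in (ct.tp, ct.fp, ct.fn, ct.tn))
        h_sens = tp / (tp + fn)
        h_spec = tn / (fp + tn)
        lr_pos: MaybeFloat = h_sens / (1.0 - h_spec)
        lr_neg: MaybeFloat = (1.0 - h_sens) / h_spec
        dor: MaybeFloat = (tp * tn) / (fp * fn)
    else:
        if not is_defined(sens) or not is_defined(spec):
            lr_pos = Undefined("single-class table")
            lr_neg = Undefined("single-class table")
        else:
            lr_pos = sens / (1.0 - spec) if spec < 1.0 else Undefined("specificity=1")
            lr_neg = (1.0 - sens) / spec if spec > 0.0 else Undefined("specificity=0")
        if ct.fp == 0 or ct.fn == 0:
            dor = Undefined("fp=0" if ct.fp == 0 else "fn=0")
        else:
            dor = (ct.tp * ct.tn) / (ct.fp * ct.fn)

    if is_defined(sens) and is_defined(spec):
        youden: MaybeFloat = sens + spec - 1.0
    else:
        youden = Undefined("single-class table")

    intervals: dict[str, MaybeInterval] = {}
    if with_intervals:
        intervals["sensitivity"] = (
            prop_ci(ct.tp, ct.n_positive, level)
            if ct.n_positive
            else Undefined("no reference positives")
        )
        intervals["specificity"] = (
            prop_ci(ct.tn, ct.n_negative, level)
            if ct.n_negative
            else Undefined("no reference negatives")
        )
        intervals["ppv"] = (
            prop_ci(ct.tp, ct.n_screen_positive, level)
            if ct.n_screen_positive
            else Undefined("no screen positives")
        )
        intervals["npv"] = (
            prop_ci(ct.tn, ct.n_screen_negative, level)
            if ct.n_screen_negative
            else Undefined("no screen negatives")
        )
        intervals["lr_pos"] = lr_interval(ct, "positive", level)
        intervals["lr_neg"] = lr_interval(ct, "negative", level)
        intervals["dor"] = dor_interval(ct, level)

    return MetricSet(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        dor=dor,
        youden_j=youden,
        prevalence=ct.n_positive / ct.total,
        intervals=intervals,
    )
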