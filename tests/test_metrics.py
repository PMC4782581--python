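"""Confusion-table statistics, intervals, and their algebraic invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from stepscreen import (
    ConfusionTable,
    Interval,
    Undefined,
    dor_interval,
    exact_interval,
    from_counts,
    from_labels,
    is_defined,
    lr_interval,
    point_metrics,
    round_half_up,
    wilson_interval,
)

# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------


def test_from_counts_totals():
    ct = from_counts(16, 22, 1, 86)
    assert (ct.n_positive, ct.n_negative, ct.total) == (17, 108, 125)


@pytest.mark.parametrize(
    "cells",
    [(-1, 0, 0, 1), (1.5, 0, 0, 1), (0, 0, 0, 0), ("1", 0, 0, 1)],
)
def test_from_counts_rejects_invalid(cells):
    with pytest.raises(ValueError):
        from_counts(*cells)


def test_from_labels_enumeration():
    assert from_labels([1, 1, 0], [1, 0, 0]) == ConfusionTable(tp=1, fp=1, fn=0, tn=1)


def test_from_labels_matches_loop_oracle():
    rng = np.random.default_rng(42)
    screen = rng.integers(0, 2, 50)
    ref = rng.integers(0, 2, 50)
    tp = fp = fn = tn = 0
    for s, r in zip(screen, ref):  # independent pair-counting oracle
        if s and r:
            tp += 1
        elif s and not r:
            fp += 1
        elif not s and r:
            fn += 1
        else:
            tn += 1
    assert from_labels(screen, ref) == ConfusionTable(tp, fp, fn, tn)


def test_from_labels_rejects_mismatch_and_nonbinary():
    with pytest.raises(ValueError):
        from_labels([1, 0], [1])
    with pytest.raises(ValueError):
        from_labels([1, 2], [1, 0])


# ---------------------------------------------------------------------------
# point statistics
# ---------------------------------------------------------------------------


def test_headline_table_statistics():
    m = point_metrics(from_counts(16, 22, 1, 86))
    rendered = m.rendered()
    assert rendered["sensitivity"] == "0.94"
    assert rendered["specificity"] == "0.80"
    assert rendered["ppv"] == "0.42"
    assert rendered["npv"] == "0.99"
    assert rendered["lr_pos"] == "4.62"
    assert rendered["lr_neg"] == "0.07"
    assert rendered["dor"] == "62.55"
    assert rendered["youden_j"] == "0.74"
    assert m.prevalence == pytest.approx(17 / 125)


def test_zero_false_negatives_row():
    """LR− of exactly 0 is a defined value; DOR with fn=0 is not."""
    m = point_metrics(from_counts(17, 49, 0, 59))
    assert m.sensitivity == 1.0
    assert m.lr_neg == 0.0
    assert m.rendered()["lr_neg"] == "0.00"
    assert isinstance(m.dor, Undefined) and m.dor.reason == "fn=0"
    assert m.rendered()["dor"] == "n/a"


def test_perfect_separation_lr_pos_undefined():
    m = point_metrics(from_counts(1, 0, 0, 1))
    assert m.sensitivity == 1.0 and m.specificity == 1.0 and m.youden_j == 1.0
    assert isinstance(m.lr_pos, Undefined)


def test_haldane_correction_gives_finite_ratios():
    m = point_metrics(from_counts(17, 49, 0, 59), haldane=True)
    assert is_defined(m.dor) and m.dor > 0
    # proportions themselves stay uncorrected
    assert m.sensitivity == 1.0


@settings(max_examples=200, derandomize=True)
@given(st.tuples(*[st.integers(1, 400)] * 4))
def test_ratio_identities(cells):
    """DOR = LR+/LR− exactly; J = sens + spec − 1 in [−1, 1]."""
    m = point_metrics(from_counts(*cells), with_intervals=False)
    assert m.dor == pytest.approx(m.lr_pos / m.lr_neg, rel=1e-12)
    assert m.youden_j == pytest.approx(m.sensitivity + m.specificity - 1.0, abs=1e-15)
    assert -1.0 <= m.youden_j <= 1.0


@settings(max_examples=100, derandomize=True)
@given(st.tuples(*[st.integers(1, 50)] * 4), st.integers(2, 9))
def test_scale_invariance(cells, k):
    """Every ratio statistic and the prevalence are invariant under cell scaling."""
    base = point_metrics(from_counts(*cells), with_intervals=False)
    scaled = point_metrics(from_counts(*cells).scaled(k), with_intervals=False)
    for name in ("sensitivity", "specificity", "ppv", "npv", "lr_pos", "lr_neg",
                 "dor", "youden_j", "prevalence"):
        assert getattr(base, name) == pytest.approx(getattr(scaled, name), rel=1e-12)


# ---------------------------------------------------------------------------
# proportion intervals
# ---------------------------------------------------------------------------


def test_wilson_reproduces_published_intervals():
    assert wilson_interval(16, 17).render() == "(0.73—0.99)"
    assert wilson_interval(86, 108).render() == "(0.71—0.86)"


def test_wilson_zero_successes_lower_bound_exact():
    assert wilson_interval(0, 10).lower == 0.0


def test_exact_interval_beta_quantile_oracle():
    """Clopper–Pearson bounds equal the textbook beta-quantile expressions."""
    from scipy.stats import beta

    ci = exact_interval(16, 38)
    assert ci.lower == pytest.approx(beta.ppf(0.025, 16, 23), abs=1e-12)
    assert ci.upper == pytest.approx(beta.ppf(0.975, 17, 22), abs=1e-12)
    assert ci.render() == "(0.26—0.59)"


def test_exact_interval_saturated_bounds():
    assert exact_interval(10, 10).upper == 1.0
    assert exact_interval(0, 10).lower == 0.0


def test_exact_interval_matches_binomial_tail_grid_inversion():
    """CP bounds agree with brute-force inversion of binomial tails on a grid."""
    x, n = 5, 20
    grid = np.linspace(1e-6, 1 - 1e-6, 400_001)
    sf = 1.0 - binom.cdf(x - 1, n, grid)   # P(X >= x | p)
    cdf = binom.cdf(x, n, grid)            # P(X <= x | p)
    lower_oracle = grid[np.argmax(sf >= 0.025)]
    upper_oracle = grid[len(grid) - 1 - np.argmax(cdf[::-1] >= 0.025)]
    ci = exact_interval(x, n)
    assert ci.lower == pytest.approx(lower_oracle, abs=1e-4)
    assert ci.upper == pytest.approx(upper_oracle, abs=1e-4)


def test_interval_containment_and_width_ordering():
    """Both intervals contain p̂; Clopper–Pearson is never narrower than
    Wilson away from the boundary.  (At s = 0 or s = n the one-sided exact
    bound 1 − (α/2)^(1/n) genuinely undercuts Wilson's z²/(n+z²) for n ≳ 46,
    so the width ordering is asserted for interior counts only.)"""
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = int(rng.integers(1, 200))
        s = int(rng.integers(0, n + 1))
        w, e = wilson_interval(s, n), exact_interval(s, n)
        assert w.contains(s / n) and e.contains(s / n)
        if 0 < s < n:
            assert e.width >= w.width - 1e-12


@pytest.mark.parametrize("args", [(5, 3, 0.95), (-1, 3, 0.95), (2, 3, 1.2)])
def test_proportion_interval_validation(args):
    with pytest.raises(ValueError):
        wilson_interval(*args)
    with pytest.raises(ValueError):
        exact_interval(*args)


# ---------------------------------------------------------------------------
# likelihood-ratio and odds-ratio intervals
# ---------------------------------------------------------------------------


def test_lr_interval_published_values():
    assert lr_interval(from_counts(16, 22, 1, 86), "positive").render() == "(3.12—6.83)"
    ci = lr_interval(from_counts(15, 18, 2, 90), "positive")
    assert round_half_up(ci.lower) == 3.36
    assert round_half_up(ci.upper) == 8.35


def test_lr_interval_degenerate_cell():
    out = lr_interval(from_counts(17, 49, 0, 59), "negative")
    assert isinstance(out, Undefined) and out.reason == "fn=0"


def test_dor_interval_contains_point_estimate():
    for cells, dor in [((16, 22, 1, 86), 62.55), ((16, 79, 1, 29), 5.87)]:
        ci = dor_interval(from_counts(*cells))
        assert ci.contains(dor)


def test_dor_interval_woolf_formula_oracle():
    import math

    tp, fp, fn, tn = 16, 22, 1, 86
    se = math.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)
    z = 1.959963984540054
    dor = tp * tn / (fp * fn)
    ci = dor_interval(from_counts(tp, fp, fn, tn))
    assert ci.lower == pytest.approx(dor * math.exp(-z * se), rel=1e-9)
    assert ci.upper == pytest.approx(dor * math.exp(z * se), rel=1e-9)


def test_dor_interval_symmetric_about_one_on_log_scale():
    ci = dor_interval(from_counts(10, 10, 10, 10))
    assert np.log(ci.lower) == pytest.approx(-np.log(ci.upper), abs=1e-12)


def test_dor_interval_zero_cell_undefined():
    assert isinstance(dor_interval(from_counts(0, 5, 5, 5)), Undefined)


# ---------------------------------------------------------------------------
# rounding / rendering
# ---------------------------------------------------------------------------


def test_round_half_up_breaks_ties_upward():
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(0.735, 2) == 0.74
    assert round_half_up(62.545, 2) == 62.55


def test_interval_level_validation():
    with pytest.raises(ValueError):
        Interval(0.2, 0.1, 0.95)
    with pytest.raises(ValueError):
        Interval(0.1, 0.2, 1.5)
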