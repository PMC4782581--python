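"""Subject records, synthetic screening cohorts, and the deterministic fixture.

The package evaluates a nine-item depression screener (items scored 0–3,
total 0–27) against a structured diagnostic reference in a primary-care
cohort, together with two single-question idiom-of-distress gates:
"heart-mind problems" (common, non-stigmatized) and "brain-mind problems"
(stigmatized), plus a functional-impairment follow-up asked only of
heart-mind endorsers.

Two data sources are provided:

* :func:`generate` draws synthetic cohorts whose joint structure matches the
  validation study this package models: latent depression status at
  prevalence 17/125, group-conditional ordinal item distributions moment-
  matched to the published item means/SDs, idiom-gate endorsement
  probabilities from the published cross-tabulations, and a single shared
  latent factor per subject inducing the inter-item correlation that yields
  the published internal consistency (alpha ≈ 0.84).

* :func:`reconstruct_fixture` rebuilds, with no randomness, a 125-subject
  dataset exactly consistent with every published marginal count: the
  true-positive / true-negative columns of the accuracy-by-cutoff table at
  cutoffs 7–15, the idiom endorsement counts by reference group, the
  stepped-algorithm confusion table (15, 18, 2, 90) at cutoff 10, and the
  per-stage attrition (one reference-positive lost at each gate).  Score
  values inside bands the published table does not pin down (totals ≤6 and
  ≥15) are assigned by a fixed documented cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "CalibrationError",
    "calibrate_discretization",
    "calibrate_latent_correlation",
    "generate",
    "reconstruct_fixture",
    "study_preset",
]

N_ITEMS = 9
MAX_ITEM = 3
MAX_TOTAL = N_ITEMS * MAX_ITEM


class CalibrationError(ValueError):
    """Raised when a target mean/SD is unattainable on the 0–3 item scale."""


@dataclass(frozen=True)
class SubjectRecord:
    """One screened patient.

    ``items`` are the nine ordinal item scores (each 0–3); ``total`` is their
    sum (0–27).  ``heart_mind``, ``brain_mind`` and ``impairment`` are the
    binary idiom/gate answers; ``impairment`` can only be endorsed by
    heart-mind endorsers because the question is asked as impairment *due to*
    heart-mind problems.  ``reference`` is the structured diagnostic result
    (major depressive episode, 2-week frame).
    """

    id: str
    items: tuple[int, ...]
    total: int
    heart_mind: int
    brain_mind: int
    impairment: int
    reference: int

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise ValueError(f"{self.id}: expected {N_ITEMS} items, got {len(self.items)}")
        if any(not 0 <= int(v) <= MAX_ITEM for v in self.items):
            raise ValueError(f"{self.id}: item scores must lie in 0..{MAX_ITEM}")
        if self.total != sum(self.items):
            raise ValueError(
                f"{self.id}: total {self.total} != sum of items {sum(self.items)}"
            )
        for name in ("heart_mind", "brain_mind", "impairment", "reference"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{self.id}: {name} must be 0 or 1")
        if self.impairment and not self.heart_mind:
            raise ValueError(
                f"{self.id}: impairment endorsed without heart-mind problems"
            )


@dataclass(frozen=True)
class CohortConfig:
    """All generator parameters.

    ``item_means`` / ``item_sds`` hold one row of nine values per reference
    group, index 0 = reference-negative, index 1 = reference-positive.
    ``latent_correlation`` is the equicorrelation of the latent item
    variables within each group (one shared standard-normal factor per
    subject with loading ``sqrt(rho)``).  Gate probabilities are conditional
    on reference group; the impairment probabilities are additionally
    conditional on heart-mind endorsement.
    """

    n: int = 125
    prevalence: float = 17 / 125
    item_means: tuple[tuple[float, ...], tuple[float, ...]] = ((1.0,) * 9, (2.0,) * 9)
    item_sds: tuple[tuple[float, ...], tuple[float, ...]] = ((0.9,) * 9, (1.0,) * 9)
    latent_correlation: float = 0.0
    p_heartmind_neg: float = 0.5
    p_heartmind_pos: float = 0.9
    p_impair_given_hm_neg: float = 0.5
    p_impair_given_hm_pos: float = 0.9
    p_brainmind_neg: float = 0.05
    p_brainmind_pos: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size n must be at least 1")
        probs = (
            self.prevalence,
            self.p_heartmind_neg,
            self.p_heartmind_pos,
            self.p_impair_given_hm_neg,
            self.p_impair_given_hm_pos,
            self.p_brainmind_neg,
            self.p_brainmind_pos,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0,1]")
        if not 0.0 <= self.latent_correlation < 1.0:
            raise ValueError("latent_correlation must lie in [0,1)")
        for grp in (0, 1):
            if len(self.item_means[grp]) != N_ITEMS or len(self.item_sds[grp]) != N_ITEMS:
                raise ValueError("item_means/item_sds need 9 values per group")

    def with_n(self, n: int) -> "CohortConfig":
        return replace(self, n=n)


# Published item means/SDs by reference group (negative, positive), items 1-9:
# anhedonia, depressed mood, sleep difficulties, fatigue, appetite problems,
# self-blame / damaged family status, concentration difficulties,
# psychomotor agitation or retardation, suicidality.
_ITEM_MEANS_NEG = (1.00, 0.85, 0.72, 1.11, 0.73, 0.58, 0.66, 0.55, 0.32)
_ITEM_SDS_NEG = (0.96, 0.84, 0.77, 0.89, 0.87, 0.81, 0.71, 0.76, 0.59)
_ITEM_MEANS_POS = (2.06, 2.24, 1.53, 2.29, 1.53, 1.65, 2.12, 1.65, 1.53)
_ITEM_SDS_POS = (1.09, 0.97, 0.87, 0.92, 1.00, 1.17, 1.05, 0.99, 1.18)

# Equicorrelation of the latent item variables; found once by
# calibrate_latent_correlation(target_alpha=0.84) under the study preset and
# stored so the preset is a pure constant.  See docs/methods.md.
_LATENT_CORRELATION = 0.3054199218750


def study_preset(n: int = 125) -> CohortConfig:
    """Generator configuration matching the validation-study conditions.

    Prevalence 17/125; heart-mind endorsement 16/17 among reference
    positives and 79/108 among negatives; impairment-given-heart-mind
    15/16 and 44/79 (the latter derived from the 59 stage-two passers of
    whom 15 are reference positive); brain-mind endorsement 8/17 and 4/108;
    item moments from the published item-level table; latent equicorrelation
    calibrated so that the population internal consistency (Cronbach's
    alpha) is approximately 0.84.
    """
    return CohortConfig(
        n=n,
        prevalence=17 / 125,
        item_means=(_ITEM_MEANS_NEG, _ITEM_MEANS_POS),
        item_sds=(_ITEM_SDS_NEG, _ITEM_SDS_POS),
        latent_correlation=_LATENT_CORRELATION,
        p_heartmind_neg=79 / 108,
        p_heartmind_pos=16 / 17,
        p_impair_given_hm_neg=44 / 79,
        p_impair_given_hm_pos=15 / 16,
        p_brainmind_neg=4 / 108,
        p_brainmind_pos=8 / 17,
    )


# ---------------------------------------------------------------------------
# Moment-matched discretization of a standard-normal latent to {0,1,2,3}
# ---------------------------------------------------------------------------

_SUPPORT = np.arange(MAX_ITEM + 1, dtype=float)


def _maxent_probs(ab: np.ndarray) -> np.ndarray:
    logits = ab[0] * _SUPPORT + ab[1] * _SUPPORT**2
    logits -= logits.max()
    p = np.exp(logits)
    return p / p.sum()


def _feasible(mean: float, var: float) -> bool:
    if not 0.0 < mean < MAX_ITEM or var <= 0.0:
        return False
    # Interior of the moment set on {0..3}: below the two-point {0,3}
    # boundary and above the adjacent-integer minimum-variance boundary.
    var_max = MAX_ITEM * mean - mean**2
    frac = mean - np.floor(mean)
    var_min = frac * (1.0 - frac)
    return var_min + 1e-9 < var < var_max - 1e-9


def calibrate_discretization(
    target_mean: float, target_sd: float
) -> tuple[float, float, float]:
    """Latent-scale cut points reproducing a target item mean and SD.

    Among all distributions on {0,1,2,3} with the requested first two
    moments, the maximum-entropy one (``p_k ∝ exp(a·k + b·k²)``) is selected;
    its cumulative probabilities are mapped through the standard-normal
    quantile function to three increasing thresholds.  A latent N(0,1)
    variable cut at these thresholds then has the target mean and SD to
    within 1e-3.  For a symmetric target (mean 1.5 with the SD of the
    uniform law) the thresholds are the 25/50/75% normal quantiles.

    Raises :class:`CalibrationError` when no distribution on the 4-point
    scale can achieve the targets.
    """
    var = float(target_sd) ** 2
    mean = float(target_mean)
    if not _feasible(mean, var):
        raise CalibrationError(
            f"mean {target_mean}, sd {target_sd} unattainable on the 0-3 scale"
        )
    m2 = var + mean**2

    def moments_gap(ab: np.ndarray) -> np.ndarray:
        p = _maxent_probs(ab)
        return np.array([p @ _SUPPORT - mean, p @ _SUPPORT**2 - m2])

    sol = optimize.root(moments_gap, x0=np.zeros(2), method="hybr", tol=1e-12)
    p = _maxent_probs(sol.x)
    err = moments_gap(sol.x)
    if not sol.success or np.abs(err).max() > 1e-6:
        raise CalibrationError(
            f"moment matching failed for mean {target_mean}, sd {target_sd}"
        )
    cum = np.clip(np.cumsum(p)[:3], 1e-12, 1.0 - 1e-12)
    t1, t2, t3 = (float(stats.norm.ppf(c)) for c in cum)
    return (t1, t2, t3)


def _group_thresholds(config: CohortConfig) -> list[np.ndarray]:
    """Per-group (neg, pos) arrays of shape (9, 3) of latent cut points."""
    out = []
    for grp in (0, 1):
        thr = np.array(
            [
                calibrate_discretization(config.item_means[grp][i], config.item_sds[grp][i])
                for i in range(N_ITEMS)
            ]
        )
        out.append(thr)
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _generate_arrays(config: CohortConfig, seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    n = config.n
    ref = (rng.random(n) < config.prevalence).astype(int)

    rho = config.latent_correlation
    factor = rng.standard_normal(n)
    noise = rng.standard_normal((n, N_ITEMS))
    latent = np.sqrt(rho) * factor[:, None] + np.sqrt(1.0 - rho) * noise

    thresholds = _group_thresholds(config)
    items = np.empty((n, N_ITEMS), dtype=int)
    for grp in (0, 1):
        mask = ref == grp
        if not mask.any():
            continue
        for i in range(N_ITEMS):
            items[mask, i] = np.searchsorted(thresholds[grp][i], latent[mask, i])

    p_hm = np.where(ref == 1, config.p_heartmind_pos, config.p_heartmind_neg)
    heart_mind = (rng.random(n) < p_hm).astype(int)
    p_imp = np.where(ref == 1, config.p_impair_given_hm_pos, config.p_impair_given_hm_neg)
    impairment = ((rng.random(n) < p_imp) & (heart_mind == 1)).astype(int)
    p_bm = np.where(ref == 1, config.p_brainmind_pos, config.p_brainmind_neg)
    brain_mind = (rng.random(n) < p_bm).astype(int)

    return {
        "items": items,
        "total": items.sum(axis=1),
        "heart_mind": heart_mind,
        "brain_mind": brain_mind,
        "impairment": impairment,
        "reference": ref,
    }


def generate(config: CohortConfig, seed: int | None = None) -> list[SubjectRecord]:
    """Draw a synthetic cohort of ``config.n`` subjects.

    The reference diagnosis is Bernoulli(prevalence); items are produced by
    cutting correlated latent normals (one shared factor, equicorrelation
    ``config.latent_correlation``) at per-item, per-group thresholds moment-
    matched to the configured means/SDs; gate answers follow the conditional
    probabilities with impairment restricted to heart-mind endorsers.
    The same (config, seed) pair always yields the identical cohort.
    """
    if seed is None:
        seed = config.seed
    arrays = _generate_arrays(config, seed)
    width = max(6, len(str(config.n)))
    return [
        SubjectRecord(
            id=f"S{i:0{width}d}",
            items=tuple(int(v) for v in arrays["items"][i]),
            total=int(arrays["total"][i]),
            heart_mind=int(arrays["heart_mind"][i]),
            brain_mind=int(arrays["brain_mind"][i]),
            impairment=int(arrays["impairment"][i]),
            reference=int(arrays["reference"][i]),
        )
        for i in range(config.n)
    ]


def calibrate_latent_correlation(
    target_alpha: float = 0.84,
    n: int = 400_000,
    seed: int = 20260929,
    lo: float = 0.0,
    hi: float = 0.9,
    tol: float = 1e-3,
) -> float:
    """Bisect the equicorrelation so the generated-cohort alpha hits a target.

    Simulates one large cohort per candidate under :func:`study_preset` (all
    other parameters fixed) with a fixed seed, computes Cronbach's alpha on
    the whole cohort, and bisects on the monotone correlation→alpha map.
    Used once to produce the stored preset constant.
    """
    base = study_preset(n=n)

    def alpha_at(rho: float) -> float:
        cfg = replace(base, latent_correlation=rho)
        items = _generate_arrays(cfg, seed)["items"]
        k = items.shape[1]
        item_var = items.var(axis=0, ddof=1).sum()
        total_var = items.sum(axis=1).var(ddof=1)
        return k / (k - 1) * (1.0 - item_var / total_var)

    if not alpha_at(lo) <= target_alpha <= alpha_at(hi):
        raise CalibrationError("target alpha outside the achievable bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if alpha_at(mid) < target_alpha:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Deterministic 125-subject fixture
# ---------------------------------------------------------------------------

# Totals of the 17 reference positives, derived as first differences of the
# published true-positive column over cutoffs 7..15: one subject each at
# 8, 10 and 12, two at 13, two at 14, and the ten at >=15 spread one per
# score over 15..24.
_POS_TOTALS = (8, 10, 12, 13, 13, 14, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23, 24)

# Expected screen-positive tallies by cutoff implied by the published table
# (cutoff -> (tp, tn)); used by the construction self-check.
_EXPECTED_SWEEP = {
    7: (17, 59),
    8: (17, 67),
    9: (16, 75),
    10: (16, 86),
    11: (15, 90),
    12: (15, 94),
    13: (14, 97),
    14: (12, 98),
    15: (10, 103),
}


def _negative_totals() -> list[int]:
    # 59 subjects below the lowest tabulated cutoff, spread over scores 2-6
    # by a fixed cycle; per-score counts 7..14 are first differences of the
    # true-negative column; the 5 subjects >=15 take scores 15..19.
    low = [2 + i % 5 for i in range(59)]
    mid = [7] * 8 + [8] * 8 + [9] * 11 + [10] * 4 + [11] * 4 + [12] * 3 + [13] * 1 + [14] * 5
    high = [15, 16, 17, 18, 19]
    return low + mid + high


def _split_total(total: int) -> tuple[int, ...]:
    # Even spread of a total over the nine items: base score for all, +1 for
    # the first (total mod 9) items.  Keeps every item in 0..3 for totals 0..27.
    base, rem = divmod(total, N_ITEMS)
    return tuple(base + 1 if i < rem else base for i in range(N_ITEMS))


def reconstruct_fixture() -> list[SubjectRecord]:
    """Rebuild the 125-subject validation dataset from its published margins.

    Deterministic (no randomness).  Flag assignment rules, fixed once:

    * Reference positives (ids F001–F017, totals ascending): all endorse
      heart-mind except the lowest scorer at or above the terminal cutoff 10
      (the score-10 subject), who is the single case missed by heart-mind
      screening; the score-8 subject endorses heart-mind but not impairment
      (the single case missed by impairment screening); every other
      heart-mind endorser endorses impairment.  The first eight positives
      endorse brain-mind (8 of 17).
    * Reference negatives (ids F018–F125, totals per the fixed band rule):
      the 79 highest-scoring negatives endorse heart-mind; of these, score
      ranks 5–48 endorse impairment, so the four highest-scoring negatives
      endorse heart-mind without impairment and exactly 18 negatives at
      total ≥10 pass both gates.  The first four negatives in construction
      order endorse brain-mind (4 of 108).

    A self-check asserts every published marginal before returning.
    """
    records: list[SubjectRecord] = []

    for idx, total in enumerate(_POS_TOTALS):
        heart_mind = 0 if total == 10 else 1
        impairment = 0 if total in (8, 10) else 1
        records.append(
            SubjectRecord(
                id=f"F{idx + 1:03d}",
                items=_split_total(total),
                total=total,
                heart_mind=heart_mind,
                brain_mind=1 if idx < 8 else 0,
                impairment=impairment,
                reference=1,
            )
        )

    neg_totals = _negative_totals()
    order = sorted(range(len(neg_totals)), key=lambda i: (-neg_totals[i], i))
    hm_idx = set(order[:79])
    imp_idx = set(order[4:48])
    for idx, total in enumerate(neg_totals):
        records.append(
            SubjectRecord(
                id=f"F{idx + 18:03d}",
                items=_split_total(total),
                total=total,
                heart_mind=1 if idx in hm_idx else 0,
                brain_mind=1 if idx < 4 else 0,
                impairment=1 if idx in imp_idx else 0,
                reference=0,
            )
        )

    _self_check(records)
    return records


def _self_check(records: Sequence[SubjectRecord]) -> None:
    assert len(records) == 125
    pos = [r for r in records if r.reference]
    neg = [r for r in records if not r.reference]
    assert len(pos) == 17 and len(neg) == 108
    for cutoff, (tp, tn) in _EXPECTED_SWEEP.items():
        assert sum(r.total >= cutoff for r in pos) == tp, f"tp mismatch at {cutoff}"
        assert sum(r.total < cutoff for r in neg) == tn, f"tn mismatch at {cutoff}"
    assert sum(r.heart_mind for r in pos) == 16
    assert sum(r.heart_mind for r in neg) == 79
    assert sum(r.brain_mind for r in pos) == 8
    assert sum(r.brain_mind for r in neg) == 4
    # stage-two passers and the algorithm confusion table at cutoff 10
    pass2_pos = [r for r in pos if r.heart_mind and r.impairment]
    pass2_neg = [r for r in neg if r.heart_mind and r.impairment]
    assert len(pass2_pos) == 15 and len(pass2_neg) == 44
    alg_tp = sum(r.total >= 10 for r in pass2_pos)
    alg_fp = sum(r.total >= 10 for r in pass2_neg)
    assert (alg_tp, alg_fp) == (15, 18)
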