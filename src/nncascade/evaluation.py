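"""ROC analysis, paired AUROC comparison, PPV calibration and validation.

Conventions: the positive class is outcome 1 (dead); a sample is predicted
positive when its score is **at or above** the threshold.  AUROC is the
Mann–Whitney probability that a random positive outranks a random negative
(ties count 0.5), its standard error follows Hanley & McNeil, and paired
AUROC differences are tested with DeLong's method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ROCCurve",
    "GroupComparison",
    "auroc",
    "roc_curve",
    "compare_auroc_paired",
    "ppv_at_criterion",
    "poor_prognosis_probability",
    "group_ttest",
]


def _check_binary(outcome: np.ndarray) -> np.ndarray:
    outcome = np.asarray(outcome).astype(int)
    if set(np.unique(outcome)) - {0, 1}:
        raise ValueError("outcome labels must be 0/1")
    if outcome.min() == outcome.max():
        raise ValueError("single-class outcome: ROC analysis needs both classes")
    return outcome


def auroc(scores: np.ndarray, outcome: np.ndarray) -> float:
    """Mann–Whitney AUROC with tie correction."""
    outcome = _check_binary(outcome)
    scores = np.asarray(scores, dtype=float)
    r = stats.rankdata(scores)
    n1 = int(outcome.sum())
    n0 = len(outcome) - n1
    u = r[outcome == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def _hanley_mcneil_se(a: float, n1: int, n0: int) -> float:
    q1 = a / (2 - a)
    q2 = 2 * a**2 / (1 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a**2) + (n0 - 1) * (q2 - a**2)) / (n1 * n0)
    return float(np.sqrt(max(var, 0.0)))


@dataclass
class ROCCurve:
    """Full ROC with per-threshold sensitivity/specificity/PPV.

    ``thresholds`` holds every distinct score (descending) plus a sentinel
    above the maximum (nobody predicted positive).  The reference scores
    and labels are retained so PPV can be evaluated at arbitrary criteria.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    ppv: np.ndarray
    auroc: float
    auroc_se: float
    n_pos: int
    n_neg: int
    ref_scores: np.ndarray = field(repr=False, default=None)
    ref_outcome: np.ndarray = field(repr=False, default=None)


def roc_curve(scores: np.ndarray, outcome: np.ndarray) -> ROCCurve:
    """Build the ROC of ``scores`` against a 0/1 outcome.

    Thresholds are all distinct score values (descending) plus a sentinel
    above the maximum; prediction is positive when score ≥ threshold.
    """
    outcome = _check_binary(outcome)
    scores = np.asarray(scores, dtype=float)
    n1 = int(outcome.sum())
    n0 = len(outcome) - n1
    uniq = np.unique(scores)[::-1]
    sentinel = uniq[0] + max(1.0, abs(uniq[0]))
    thresholds = np.concatenate([[sentinel], uniq])
    sens = np.empty_like(thresholds)
    spec = np.empty_like(thresholds)
    ppv = np.full_like(thresholds, np.nan)
    for i, t in enumerate(thresholds):
        pred = scores >= t
        tp = int((pred & (outcome == 1)).sum())
        fp = int((pred & (outcome == 0)).sum())
        sens[i] = tp / n1
        spec[i] = (n0 - fp) / n0
        if tp + fp > 0:
            ppv[i] = tp / (tp + fp)
    a = auroc(scores, outcome)
    return ROCCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        auroc=a,
        auroc_se=_hanley_mcneil_se(a, n1, n0),
        n_pos=n1,
        n_neg=n0,
        ref_scores=scores.copy(),
        ref_outcome=outcome.copy(),
    )


# ---------------------------------------------------------------------------
# DeLong paired AUROC comparison
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_placements(scores: np.ndarray, outcome: np.ndarray):
    """Per-sample placement values V10 (positives) and V01 (negatives)."""
    pos = scores[outcome == 1]
    neg = scores[outcome == 0]
    m, n = len(pos), len(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    a = (tz[:m].sum() / m - (m + 1) / 2.0) / n
    return a, v10, v01


def compare_auroc_paired(
    scores_a: np.ndarray, scores_b: np.ndarray, outcome: np.ndarray
) -> tuple[float, float]:
    """DeLong test for two correlated AUROCs measured on the same samples.

    Returns ``(delta, p)`` where ``delta = AUROC_a − AUROC_b`` and ``p`` is
    the two-sided normal p-value.  Identical score vectors give (0, 1).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired comparison needs score vectors of equal length")
    outcome = _check_binary(outcome)
    a1, v10_1, v01_1 = _delong_placements(scores_a, outcome)
    a2, v10_2, v01_2 = _delong_placements(scores_b, outcome)
    delta = float(a1 - a2)
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.vstack([v10_1, v10_2]))
    s01 = np.cov(np.vstack([v01_1, v01_2]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0 or not np.isfinite(var):
        return delta, 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return delta, p


def delong_variance(scores: np.ndarray, outcome: np.ndarray) -> float:
    """DeLong variance estimate of a single AUROC (used as a cross-check)."""
    outcome = _check_binary(outcome)
    _, v10, v01 = _delong_placements(np.asarray(scores, dtype=float), outcome)
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


# ---------------------------------------------------------------------------
# PPV / poor-prognosis probability
# ---------------------------------------------------------------------------

def ppv_at_criterion(curve: ROCCurve, criterion: float) -> float:
    """Positive predictive value among samples scoring ≥ ``criterion``.

    A criterion below every reference score yields the prevalence; one
    above every score is undefined and returned as NaN.
    """
    pred = curve.ref_scores >= criterion
    if not pred.any():
        return float("nan")
    tp = int((pred & (curve.ref_outcome == 1)).sum())
    return tp / int(pred.sum())


def poor_prognosis_probability(curve: ROCCurve, new_scores) -> np.ndarray:
    """Probability of poor prognosis for new samples: the reference-cohort
    PPV at each sample's score, vectorized."""
    new_scores = np.atleast_1d(np.asarray(new_scores, dtype=float))
    return np.array([ppv_at_criterion(curve, s) for s in new_scores])


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    mean_alive: float
    sem_alive: float
    mean_dead: float
    sem_dead: float
    t_statistic: float
    p_value: float


def group_ttest(values: np.ndarray, outcome: np.ndarray, equal_var: bool = True) -> GroupComparison:
    """Two-sided two-sample t-test between the alive (0) and dead (1) groups."""
    values = np.asarray(values, dtype=float)
    outcome = np.asarray(outcome).astype(int)
    g0 = values[outcome == 0]
    g1 = values[outcome == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each survival group needs at least 2 samples for a t-test")
    t, p = stats.ttest_ind(g1, g0, equal_var=equal_var)
    if not np.isfinite(t):  # both groups constant
        t, p = (0.0, 1.0) if g0.mean() == g1.mean() else (np.inf, 0.0)
    return GroupComparison(
        mean_alive=float(g0.mean()),
        sem_alive=float(stats.sem(g0)),
        mean_dead=float(g1.mean()),
        sem_dead=float(stats.sem(g1)),
        t_statistic=float(t),
        p_value=float(p),
    )
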