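"""Per-feature score transformation and Spearman-based biomarker ranking.

Every feature's expression column is pushed through its own 1-H-1 RBF unit
trained against the outcome, yielding a *score* in [0, 1] that is — by
construction — approximately linearly related to outcome risk even when the
raw expression is not (U-shaped, step-like, …).  Features are then ranked by
the Spearman correlation of their score with the outcome and the top k kept
as the biomarker signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import NormalizedCohort
from .evaluation import auroc, compare_auroc_paired, group_ttest, GroupComparison
from .rbf import (
    DEFAULT_HIDDEN,
    DEFAULT_RIDGE,
    DEFAULT_WIDTH_SCALE,
    RBFUnit,
    score_unit,
    train_rbf_unit,
)

__all__ = [
    "FeatureScoreTable",
    "FeatureRanking",
    "SpearmanResult",
    "child_seed",
    "transform_all_features",
    "score_features",
    "spearman_vs_outcome",
    "rank_and_select",
    "expression_vs_score_report",
    "ExpressionScoreReport",
]

_SEED_MASK = 0x7FFFFFFF
_MIX = 0x9E3779B1  # odd multiplier; spreads consecutive indices over the seed space


def child_seed(seed: int, index: int) -> int:
    """Deterministic per-feature seed derived from the global seed and index."""
    return (int(seed) ^ ((index + 1) * _MIX)) & _SEED_MASK


@dataclass
class FeatureScoreTable:
    """Per-feature scores plus the 1-H-1 units that produced them."""

    sample_ids: list[str]
    feature_ids: list[str]
    scores: np.ndarray  # features × samples, all in [0, 1]
    units: dict[str, RBFUnit]
    flagged: list[str]  # constant features: no unit, scores fixed at 0.5
    hidden: int
    seed: int

    def unit_for(self, feature_id: str) -> RBFUnit:
        return self.units[feature_id]


@dataclass
class FeatureRanking:
    """Ranking table: per feature Spearman R, p, AUROC, rank, selection flag."""

    table: pd.DataFrame  # columns: feature, spearman_r, p_value, auroc, rank, selected

    @property
    def selected(self) -> list[str]:
        sel = self.table[self.table["selected"]].sort_values("rank")
        return sel["feature"].tolist()

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class SpearmanResult:
    r: float
    p: float
    no_variance: bool = False


def transform_all_features(
    train: NormalizedCohort,
    hidden: int = DEFAULT_HIDDEN,
    seed: int = 0,
    ridge: float = DEFAULT_RIDGE,
    width_scale: float = DEFAULT_WIDTH_SCALE,
) -> FeatureScoreTable:
    """Train one 1-H-1 unit per non-constant feature of the training cohort.

    Constant (flagged) features get no unit and a fixed score of 0.5.  Each
    feature's unit uses a child seed derived from the global seed and the
    feature index, so any feature subset reproduces identical units.
    """
    if train.outcome.min() == train.outcome.max():
        raise ValueError("training cohort has a single-class outcome")
    scores = np.empty_like(train.expression)
    units: dict[str, RBFUnit] = {}
    flagged: list[str] = []
    flags = train.constant_feature_flags
    for i, fid in enumerate(train.feature_ids):
        if flags[i]:
            flagged.append(fid)
            scores[i] = 0.5
            continue
        unit = train_rbf_unit(
            train.expression[i],
            train.outcome,
            hidden=hidden,
            ridge=ridge,
            width_scale=width_scale,
            seed=child_seed(seed, i),
        )
        units[fid] = unit
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate units score 0.5 silently here
            scores[i] = score_unit(unit, train.expression[i])
    return FeatureScoreTable(
        sample_ids=list(train.sample_ids),
        feature_ids=list(train.feature_ids),
        scores=scores,
        units=units,
        flagged=flagged,
        hidden=hidden,
        seed=seed,
    )


def score_features(table: FeatureScoreTable, cohort: NormalizedCohort) -> np.ndarray:
    """Apply the trained per-feature units to a (new) normalized cohort.

    Returns a features × samples score matrix aligned with
    ``table.feature_ids``; flagged features score 0.5.
    """
    out = np.full((len(table.feature_ids), cohort.n_samples), 0.5)
    for i, fid in enumerate(table.feature_ids):
        if fid in table.units:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[i] = score_unit(table.units[fid], cohort.feature_values(fid))
    return out


def spearman_vs_outcome(scores: np.ndarray, outcome: np.ndarray) -> SpearmanResult:
    """Tie-corrected Spearman rank correlation of scores vs the 0/1 outcome.

    Constant score vectors are reported as R = 0 with a no-variance flag and
    p = 1 rather than NaN.  The p-value uses the standard large-sample
    t approximation.
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome).astype(int)
    if len(scores) < 3:
        raise ValueError("Spearman correlation needs at least 3 samples")
    if outcome.min() == outcome.max():
        raise ValueError("outcome has a single class")
    if np.all(scores == scores[0]):
        return SpearmanResult(r=0.0, p=1.0, no_variance=True)
    r, p = stats.spearmanr(scores, outcome)
    return SpearmanResult(r=float(r), p=float(p))


def rank_and_select(
    table: FeatureScoreTable,
    outcome: np.ndarray,
    k: int,
    rank_abs: bool = False,
) -> FeatureRanking:
    """Rank non-flagged features by Spearman R of score vs outcome; keep top k.

    Sort key: R descending (|R| with ``rank_abs``), ties broken by higher
    AUROC, then lexicographic feature id.  Flagged (constant) features are
    excluded entirely.
    """
    rows = []
    for i, fid in enumerate(table.feature_ids):
        if fid in table.flagged:
            continue
        sp = spearman_vs_outcome(table.scores[i], outcome)
        rows.append(
            {
                "feature": fid,
                "spearman_r": sp.r,
                "p_value": sp.p,
                "auroc": auroc(table.scores[i], outcome),
            }
        )
    if k > len(rows):
        raise ValueError(f"cannot select top {k} from {len(rows)} rankable features")
    df = pd.DataFrame(rows)
    key = df["spearman_r"].abs() if rank_abs else df["spearman_r"]
    df["_key"] = key
    df = df.sort_values(
        by=["_key", "auroc", "feature"], ascending=[False, False, True]
    ).drop(columns="_key")
    df["rank"] = np.arange(1, len(df) + 1)
    df["selected"] = df["rank"] <= k
    return FeatureRanking(table=df.reset_index(drop=True))


@dataclass
class ExpressionScoreReport:
    """Raw expression vs score for one feature: group stats and AUROCs."""

    feature: str
    expression_groups: GroupComparison
    score_groups: GroupComparison
    expression_auroc: float
    score_auroc: float
    auroc_delta: float
    auroc_p: float


def expression_vs_score_report(
    train: NormalizedCohort, table: FeatureScoreTable, feature: str
) -> ExpressionScoreReport:
    """Contrast a feature's raw expression with its score as risk predictors.

    For a nonlinearly informative feature the raw-expression t-test can be
    null while the score separates the survival groups cleanly; the paired
    AUROC comparison quantifies the gain from the transformation.
    """
    if feature not in train.feature_ids:
        raise ValueError(f"unknown feature {feature!r}")
    i = train.feature_ids.index(feature)
    expr = train.expression[i]
    score = table.scores[table.feature_ids.index(feature)]
    y = train.outcome
    delta, p = compare_auroc_paired(score, expr, y)
    return ExpressionScoreReport(
        feature=feature,
        expression_groups=group_ttest(expr, y),
        score_groups=group_ttest(score, y),
        expression_auroc=auroc(expr, y),
        score_auroc=auroc(score, y),
        auroc_delta=delta,
        auroc_p=p,
    )
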