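"""Holdout validation and the input-perturbation (swap) experiment.

Internal validation follows the 2:1:1 holdout protocol: the training cohort
is split into training, verification and testing parts; units are fit on
the training part only; per-unit training/testing output–outcome
correlations (Tr / Te) measure generalization, and the model-level AUROC is
reported on the held-out testing part.  The verification part plays no role
in the closed-form fit and is carried in the report for protocol fidelity.

The swap experiment replaces one input feature's values — with another
feature's values or with uniform noise — at prediction time only, and
compares each model's AUROC before and after; a cascade confines the damage
to one input channel while a flat network lets it spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cascade import (
    CascadeModel,
    FlatModel,
    plan_cascade,
    predict_cascade,
    predict_flat,
    train_cascade,
    train_flat,
)
from .cohort import Cohort, NormalizedCohort, normalize_expression, split_cohort
from .evaluation import auroc, roc_curve
from .rbf import DEFAULT_HIDDEN, RBFUnit, score_unit
from .scoring import FeatureScoreTable, rank_and_select, score_features, transform_all_features

__all__ = [
    "ModelSpec",
    "FittedPipeline",
    "ValidationReport",
    "SwapResult",
    "fit_pipeline",
    "predict_model",
    "internal_validate",
    "swap_experiment",
    "youden_threshold",
]


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: cascade ('nnc') or flat ('unn'/'tnn'), and its size."""

    kind: str = "nnc"  # "nnc" | "unn" | "tnn"
    k: int = 9
    fan_in: int = 3
    hidden: int = DEFAULT_HIDDEN

    def __post_init__(self) -> None:
        if self.kind not in ("nnc", "unn", "tnn"):
            raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass
class FittedPipeline:
    """A trained model together with the scoring state that produced it."""

    spec: ModelSpec
    model: CascadeModel | FlatModel
    score_table: FeatureScoreTable
    ranking: object
    train: NormalizedCohort


def fit_pipeline(
    train: NormalizedCohort,
    spec: ModelSpec,
    seed: int = 0,
    score_table: FeatureScoreTable | None = None,
    rank_k: int | None = None,
) -> FittedPipeline:
    """Transform → rank → fit one model on an already-normalized cohort."""
    if score_table is None:
        score_table = transform_all_features(train, hidden=spec.hidden, seed=seed)
    k_rank = max(spec.k, rank_k or 0)
    ranking = rank_and_select(score_table, train.outcome, k=k_rank)
    if spec.kind == "nnc":
        plan = plan_cascade(spec.k, spec.fan_in)
        model = train_cascade(
            train, ranking, plan, hidden=spec.hidden, seed=seed, score_table=score_table
        )
    else:
        model = train_flat(
            train, ranking, spec.kind, k=spec.k, hidden=spec.hidden,
            seed=seed, score_table=score_table,
        )
    return FittedPipeline(
        spec=spec, model=model, score_table=score_table, ranking=ranking, train=train
    )


def predict_model(model: CascadeModel | FlatModel, cohort: NormalizedCohort) -> np.ndarray:
    if isinstance(model, CascadeModel):
        return predict_cascade(model, cohort)
    return predict_flat(model, cohort)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _unit_outputs(model: CascadeModel | FlatModel, cohort: NormalizedCohort) -> list[list[np.ndarray]]:
    """Normalized output of every unit, layer by layer, on a cohort."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if isinstance(model, CascadeModel):
            layers = []
            current = np.vstack(
                [
                    score_unit(u, cohort.feature_values(f))
                    for u, f in zip(model.layer0_units, model.feature_ids)
                ]
            )
            layers.append(list(current))
            for groups, layer_units in zip(model.plan.grouping, model.upper_units):
                current = np.vstack(
                    [
                        score_unit(unit, current[group].T)
                        for group, unit in zip(groups, layer_units)
                    ]
                )
                layers.append(list(current))
            return layers
        # flat model: per-feature units (TNN only), then the single wide unit
        layers = []
        if model.feature_units:
            layers.append(
                [
                    score_unit(model.feature_units[f], cohort.feature_values(f))
                    for f in model.feature_ids
                ]
            )
        layers.append([predict_flat(model, cohort)])
        return layers


def youden_threshold(scores: np.ndarray, outcome: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity − 1 (ties → lower
    threshold, keeping sensitivity)."""
    curve = roc_curve(scores, outcome)
    j = curve.sensitivity + curve.specificity - 1.0
    best = np.flatnonzero(j == j.max())[-1]
    return float(curve.thresholds[best])


@dataclass
class ValidationReport:
    """Per-unit Tr/Te correlations and model-level holdout performance."""

    unit_tr: list[list[float]]  # per layer, per unit: output–outcome r, training part
    unit_te: list[list[float]]  # same on the testing part
    auroc_train: float
    auroc_verify: float
    auroc_test: float
    accuracy_test: float
    threshold: float
    part_sizes: tuple[int, ...]
    seed: int

    @property
    def tr_te_gaps(self) -> list[float]:
        return [
            abs(tr - te)
            for ltr, lte in zip(self.unit_tr, self.unit_te)
            for tr, te in zip(ltr, lte)
        ]


def internal_validate(
    cohort: Cohort,
    spec: ModelSpec,
    ratio: tuple[int, ...] = (2, 1, 1),
    seed: int = 0,
    legacy_calibration: bool = False,
) -> ValidationReport:
    """2:1:1 holdout validation of one model on a raw cohort.

    Splits stratified by outcome, normalizes with training-part calibration
    (or whole-cohort calibration under ``legacy_calibration``), fits the model on
    the training part and reports per-unit Tr/Te correlations plus AUROC
    and Youden-threshold accuracy on the testing part.
    """
    parts = split_cohort(cohort, ratio, stratify=True, seed=seed)
    for i, p in enumerate(parts):
        if p.outcome.min() == p.outcome.max():
            raise ValueError(
                f"holdout part {i} holds a single class; use a larger cohort or "
                "fewer parts"
            )
    train_raw, verify_raw, test_raw = parts[0], parts[1], parts[-1]
    if legacy_calibration:
        whole = normalize_expression(cohort, "all")
        cal = whole.calibration
    else:
        cal = normalize_expression(train_raw, "all").calibration
    from .cohort import apply_calibration

    train = apply_calibration(cal, train_raw)
    verify = apply_calibration(cal, verify_raw)
    test = apply_calibration(cal, test_raw)

    fitted = fit_pipeline(train, spec, seed=seed)
    out_tr = _unit_outputs(fitted.model, train)
    out_te = _unit_outputs(fitted.model, test)
    unit_tr = [[_pearson(o, train.outcome) for o in layer] for layer in out_tr]
    unit_te = [[_pearson(o, test.outcome) for o in layer] for layer in out_te]

    s_train = predict_model(fitted.model, train)
    s_verify = predict_model(fitted.model, verify)
    s_test = predict_model(fitted.model, test)
    thr = youden_threshold(s_train, train.outcome)
    acc = float(np.mean((s_test >= thr).astype(int) == test.outcome))
    return ValidationReport(
        unit_tr=unit_tr,
        unit_te=unit_te,
        auroc_train=auroc(s_train, train.outcome),
        auroc_verify=auroc(s_verify, verify.outcome),
        auroc_test=auroc(s_test, test.outcome),
        accuracy_test=acc,
        threshold=thr,
        part_sizes=tuple(p.n_samples for p in parts),
        seed=seed,
    )


@dataclass
class SwapResult:
    """AUROC before/after a prediction-time input perturbation, per model."""

    target_feature: str
    source: str
    auroc_before: dict[str, float]
    auroc_after: dict[str, float]
    predictions_after: dict[str, np.ndarray] = field(repr=False, default=None)
    perturbed: NormalizedCohort = field(repr=False, default=None)

    def auroc_drop(self, name: str) -> float:
        return self.auroc_before[name] - self.auroc_after[name]


def swap_experiment(
    models: dict[str, CascadeModel | FlatModel],
    cohort: NormalizedCohort,
    target_feature: str,
    source: str = "uniform-noise",
    seed: int = 0,
) -> SwapResult:
    """Replace one feature's values at prediction time and re-evaluate.

    ``source`` is another feature id (column-wise value swap) or
    ``"uniform-noise"`` for i.i.d. uniform [0, 1] replacements.  No model is
    retrained; the same perturbed cohort is fed to every model.
    """
    if target_feature not in cohort.feature_ids:
        raise ValueError(f"unknown target feature {target_feature!r}")
    ti = cohort.feature_ids.index(target_feature)
    expr = cohort.expression.copy()
    if source == "uniform-noise":
        rng = np.random.default_rng(seed)
        expr[ti] = rng.uniform(0.0, 1.0, size=cohort.n_samples)
    else:
        if source not in cohort.feature_ids:
            raise ValueError(f"unknown source feature {source!r}")
        expr[ti] = cohort.expression[cohort.feature_ids.index(source)]
    perturbed = replace(cohort, expression=expr)

    before = {name: auroc(predict_model(m, cohort), cohort.outcome) for name, m in models.items()}
    preds = {name: predict_model(m, perturbed) for name, m in models.items()}
    after = {name: auroc(p, cohort.outcome) for name, p in preds.items()}
    return SwapResult(
        target_feature=target_feature,
        source=source,
        auroc_before=before,
        auroc_after=after,
        predictions_after=preds,
        perturbed=perturbed,
    )
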