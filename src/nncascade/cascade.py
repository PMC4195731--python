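"""Pyramid neural-network cascades and the flat UNN/TNN baselines.

A cascade stacks small RBF units into a pyramid: one 1-H-1 unit per selected
feature (the score transformers), then fan-in integration units on the
normalized outputs of the layer below, repeated until a single unit emits
the final risk score.  With the defaults (k = 9 features, fan-in 3) the plan
is 9 primary + 3 secondary + 1 tertiary = 13 units.

The flat baselines use one k-H-1 unit over the top-k features directly:
UNN on raw (normalized) expression, TNN on the per-feature scores.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import NormalizedCohort
from .rbf import (
    DEFAULT_HIDDEN,
    DEFAULT_RIDGE,
    DEFAULT_WIDTH_SCALE,
    RBFUnit,
    score_unit,
    train_rbf_unit,
)
from .scoring import FeatureRanking, FeatureScoreTable, child_seed

__all__ = [
    "CascadePlan",
    "CascadeModel",
    "FlatModel",
    "plan_cascade",
    "train_cascade",
    "predict_cascade",
    "train_flat",
    "predict_flat",
    "save_model",
    "load_model",
]


@dataclass
class CascadePlan:
    """Layer layout of a cascade: unit counts and index groupings per layer.

    ``grouping[l]`` lists, for each unit of layer l+1, the indices of the
    layer-l outputs it integrates.  A trailing singleton group is merged
    into its predecessor so no 1-input integration unit ever occurs.
    """

    k: int
    fan_in: int
    layer_sizes: list[int]
    grouping: list[list[list[int]]]

    @property
    def total_units(self) -> int:
        return sum(self.layer_sizes)

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes)


def plan_cascade(k: int, fan_in: int = 3, grouping: str = "rank-consecutive") -> CascadePlan:
    """Plan a pyramid over ``k`` inputs with the given fan-in.

    Inputs are grouped consecutively in rank order ({1..f}, {f+1..2f}, …) or
    round-robin; layers repeat until one unit remains.  plan_cascade(9, 3)
    yields layer sizes (9, 3, 1) and 13 units in total.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if fan_in < 2:
        raise ValueError("fan_in must be >= 2")
    if grouping not in ("rank-consecutive", "round-robin"):
        raise ValueError(f"unknown grouping {grouping!r}")
    layer_sizes = [k]
    groups_per_layer: list[list[list[int]]] = []
    cur = k
    while cur > 1:
        n_groups = math.ceil(cur / fan_in)
        if cur - (n_groups - 1) * fan_in == 1 and n_groups > 1:
            n_groups -= 1  # merge the trailing singleton into its predecessor
        if grouping == "rank-consecutive":
            bounds = [min(i * fan_in, cur) for i in range(n_groups)] + [cur]
            groups = [list(range(bounds[i], bounds[i + 1])) for i in range(n_groups)]
        else:
            groups = [list(range(j, cur, n_groups)) for j in range(n_groups)]
        groups_per_layer.append(groups)
        layer_sizes.append(n_groups)
        cur = n_groups
    return CascadePlan(k=k, fan_in=fan_in, layer_sizes=layer_sizes, grouping=groups_per_layer)


@dataclass
class CascadeModel:
    """A trained cascade: selected features in rank order plus all units."""

    plan: CascadePlan
    feature_ids: list[str]
    layer0_units: list[RBFUnit]
    upper_units: list[list[RBFUnit]]  # one list per integration layer
    hidden: int
    seed: int
    train_scores: np.ndarray = field(repr=False, default=None)

    @property
    def n_units(self) -> int:
        return len(self.layer0_units) + sum(len(layer) for layer in self.upper_units)

    def units_by_layer(self) -> list[list[RBFUnit]]:
        return [self.layer0_units, *self.upper_units]


def train_cascade(
    train: NormalizedCohort,
    ranking: FeatureRanking,
    plan: CascadePlan,
    hidden: int = DEFAULT_HIDDEN,
    seed: int = 0,
    score_table: FeatureScoreTable | None = None,
    ridge: float = DEFAULT_RIDGE,
    width_scale: float = DEFAULT_WIDTH_SCALE,
) -> CascadeModel:
    """Greedy layer-by-layer training of a cascade on a normalized cohort.

    Layer 0 re-uses the per-feature 1-H-1 units from ``score_table`` when
    given (they are identical to retrained ones by determinism), otherwise
    trains them.  Each integration unit is then fit on the frozen,
    normalized outputs of its group with the outcome as target.
    """
    selected = ranking.selected
    if len(selected) < plan.k:
        raise ValueError(
            f"plan expects {plan.k} features but ranking selected {len(selected)}"
        )
    feats = selected[: plan.k]
    y = train.outcome
    if y.min() == y.max():
        raise ValueError("training cohort has a single-class outcome")

    layer0: list[RBFUnit] = []
    for j, fid in enumerate(feats):
        if score_table is not None and fid in score_table.units:
            layer0.append(score_table.units[fid])
        else:
            layer0.append(
                train_rbf_unit(
                    train.feature_values(fid), y,
                    hidden=hidden, ridge=ridge, width_scale=width_scale,
                    seed=child_seed(seed, j),
                )
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        current = np.vstack(
            [score_unit(u, train.feature_values(f)) for u, f in zip(layer0, feats)]
        )
        upper: list[list[RBFUnit]] = []
        for li, groups in enumerate(plan.grouping):
            layer_units: list[RBFUnit] = []
            outputs = []
            for gi, group in enumerate(groups):
                X = current[group].T
                unit = train_rbf_unit(
                    X, y,
                    hidden=hidden, ridge=ridge, width_scale=width_scale,
                    seed=child_seed(seed, 100_000 * (li + 1) + gi),
                )
                layer_units.append(unit)
                outputs.append(score_unit(unit, X))
            upper.append(layer_units)
            current = np.vstack(outputs)
    return CascadeModel(
        plan=plan,
        feature_ids=feats,
        layer0_units=layer0,
        upper_units=upper,
        hidden=hidden,
        seed=seed,
        train_scores=current[0].copy(),
    )


def predict_cascade(model: CascadeModel, cohort: NormalizedCohort) -> np.ndarray:
    """Feed a normalized cohort through the cascade; returns risk in [0, 1]."""
    missing = [f for f in model.feature_ids if f not in cohort.feature_ids]
    if missing:
        raise ValueError(f"cohort lacks model feature(s): {missing}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        current = np.vstack(
            [
                score_unit(u, cohort.feature_values(f))
                for u, f in zip(model.layer0_units, model.feature_ids)
            ]
        )
        for groups, layer_units in zip(model.plan.grouping, model.upper_units):
            current = np.vstack(
                [
                    score_unit(unit, current[group].T)
                    for group, unit in zip(groups, layer_units)
                ]
            )
    return current[0]


# ---------------------------------------------------------------------------
# flat baselines
# ---------------------------------------------------------------------------

@dataclass
class FlatModel:
    """Single k-H-1 unit over the top-k features (UNN: raw, TNN: scores)."""

    mode: str  # "unn" | "tnn"
    unit: RBFUnit
    feature_ids: list[str]
    feature_units: dict[str, RBFUnit]  # empty for UNN
    hidden: int
    seed: int


def train_flat(
    train: NormalizedCohort,
    ranking: FeatureRanking,
    mode: str,
    k: int = 3,
    hidden: int = DEFAULT_HIDDEN,
    seed: int = 0,
    score_table: FeatureScoreTable | None = None,
    ridge: float = DEFAULT_RIDGE,
    width_scale: float = DEFAULT_WIDTH_SCALE,
) -> FlatModel:
    """Fit a flat baseline on the k best-ranked features.

    UNN feeds the normalized expression values straight into one k-H-1
    unit; TNN first applies the per-feature score transformation (units
    from ``score_table`` or retrained) and feeds the scores instead.
    """
    mode = mode.lower()
    if mode not in ("unn", "tnn"):
        raise ValueError(f"mode must be 'unn' or 'tnn', got {mode!r}")
    feats = ranking.selected[:k]
    if len(feats) < k:
        raise ValueError(f"ranking selected only {len(feats)} features, need {k}")
    y = train.outcome
    feature_units: dict[str, RBFUnit] = {}
    if mode == "tnn":
        for j, fid in enumerate(feats):
            if score_table is not None and fid in score_table.units:
                feature_units[fid] = score_table.units[fid]
            else:
                feature_units[fid] = train_rbf_unit(
                    train.feature_values(fid), y,
                    hidden=hidden, ridge=ridge, width_scale=width_scale,
                    seed=child_seed(seed, j),
                )
    X = _flat_inputs(feats, feature_units, mode, train)
    unit = train_rbf_unit(
        X, y, hidden=hidden, ridge=ridge, width_scale=width_scale,
        seed=child_seed(seed, 999_983),
    )
    return FlatModel(
        mode=mode, unit=unit, feature_ids=feats,
        feature_units=feature_units, hidden=hidden, seed=seed,
    )


def _flat_inputs(
    feats: list[str],
    feature_units: dict[str, RBFUnit],
    mode: str,
    cohort: NormalizedCohort,
) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if mode == "unn":
            rows = [cohort.feature_values(f) for f in feats]
        else:
            rows = [score_unit(feature_units[f], cohort.feature_values(f)) for f in feats]
    return np.vstack(rows).T


def predict_flat(model: FlatModel, cohort: NormalizedCohort) -> np.ndarray:
    """Apply a flat baseline to a normalized cohort; returns risk in [0, 1]."""
    missing = [f for f in model.feature_ids if f not in cohort.feature_ids]
    if missing:
        raise ValueError(f"cohort lacks model feature(s): {missing}")
    X = _flat_inputs(model.feature_ids, model.feature_units, model.mode, cohort)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return score_unit(model.unit, X)


# ---------------------------------------------------------------------------
# serialization (JSON manifest; unit schema from nncascade.rbf)
# ---------------------------------------------------------------------------

def save_model(model: CascadeModel | FlatModel, path: str) -> None:
    """Serialize a cascade or flat model to a JSON manifest."""
    if isinstance(model, CascadeModel):
        doc = {
            "kind": "cascade",
            "plan": {
                "k": model.plan.k,
                "fan_in": model.plan.fan_in,
                "layer_sizes": model.plan.layer_sizes,
                "grouping": model.plan.grouping,
            },
            "feature_ids": model.feature_ids,
            "hidden": model.hidden,
            "seed": model.seed,
            "layer0_units": [u.to_dict() for u in model.layer0_units],
            "upper_units": [[u.to_dict() for u in layer] for layer in model.upper_units],
        }
    elif isinstance(model, FlatModel):
        doc = {
            "kind": "flat",
            "mode": model.mode,
            "feature_ids": model.feature_ids,
            "hidden": model.hidden,
            "seed": model.seed,
            "unit": model.unit.to_dict(),
            "feature_units": {f: u.to_dict() for f, u in model.feature_units.items()},
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path: str) -> CascadeModel | FlatModel:
    """Load a model saved by :func:`save_model`; predictions round-trip
    bit-exactly."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc["kind"] == "cascade":
        plan = CascadePlan(
            k=doc["plan"]["k"],
            fan_in=doc["plan"]["fan_in"],
            layer_sizes=doc["plan"]["layer_sizes"],
            grouping=doc["plan"]["grouping"],
        )
        return CascadeModel(
            plan=plan,
            feature_ids=doc["feature_ids"],
            layer0_units=[RBFUnit.from_dict(d) for d in doc["layer0_units"]],
            upper_units=[[RBFUnit.from_dict(d) for d in layer] for layer in doc["upper_units"]],
            hidden=doc["hidden"],
            seed=doc["seed"],
        )
    if doc["kind"] == "flat":
        return FlatModel(
            mode=doc["mode"],
            unit=RBFUnit.from_dict(doc["unit"]),
            feature_ids=doc["feature_ids"],
            feature_units={f: RBFUnit.from_dict(d) for f, d in doc["feature_units"].items()},
            hidden=doc["hidden"],
            seed=doc["seed"],
        )
    raise ValueError(f"unknown model kind {doc['kind']!r}")
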