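"""Cohort containers and expression-table I/O.

A cohort is the universal input of the pipeline: a features × samples
real-valued expression matrix together with one binary outcome label per
sample (0 = alive, 1 = dead).  This module loads cohorts from delimited
text tables and from GEO Series Matrix text exports, min–max normalizes
expression per feature, and splits cohorts deterministically for
training / validation.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "FeatureCalibration",
    "NormalizedCohort",
    "CohortError",
    "load_expression_table",
    "load_geo_series_matrix",
    "write_cohort",
    "normalize_expression",
    "apply_calibration",
    "split_cohort",
    "largest_remainder_sizes",
]


class CohortError(ValueError):
    """Raised when a cohort violates its structural invariants."""


@dataclass
class Cohort:
    """Expression matrix (features × samples) with a binary outcome per sample.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per matrix column.
    feature_ids : list of str
        Unique feature identifiers (e.g. miRNA names), one per matrix row.
    expression : ndarray, shape (n_features, n_samples)
        Real-valued expression, arbitrary scale.
    outcome : ndarray of int, shape (n_samples,)
        0 (alive) or 1 (dead).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    expression: np.ndarray
    outcome: np.ndarray

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.outcome = np.asarray(self.outcome)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise CohortError(f"duplicate sample id: {dup!r}")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dup = _first_duplicate(self.feature_ids)
            raise CohortError(f"duplicate feature id: {dup!r}")
        if self.expression.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise CohortError(
                f"expression shape {self.expression.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if np.isnan(self.expression).any():
            i, j = np.argwhere(np.isnan(self.expression))[0]
            raise CohortError(
                f"missing expression value for feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r} (enable imputation or fix the input)"
            )
        bad = [
            sid
            for sid, v in zip(self.sample_ids, np.asarray(self.outcome))
            if v not in (0, 1)
        ]
        if bad:
            raise CohortError(f"non-binary outcome for sample(s) {bad}: labels must be 0 or 1")
        self.outcome = self.outcome.astype(int)

    # -- conveniences ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def feature_values(self, feature_id: str) -> np.ndarray:
        try:
            idx = self.feature_ids.index(feature_id)
        except ValueError:
            raise CohortError(f"unknown feature {feature_id!r}") from None
        return self.expression[idx]

    def subset_samples(self, indices: np.ndarray) -> "Cohort":
        indices = np.asarray(indices, dtype=int)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in indices],
            expression=self.expression[:, indices].copy(),
            outcome=self.outcome[indices].copy(),
        )

    def subset_features(self, feature_ids: list[str]) -> "Cohort":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return replace(
            self,
            feature_ids=list(feature_ids),
            expression=self.expression[idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Features-in-rows DataFrame view (no outcome)."""
        return pd.DataFrame(self.expression, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class FeatureCalibration:
    """Per-feature min–max records sufficient to normalize new samples."""

    feature_ids: list[str]
    min_value: np.ndarray
    max_value: np.ndarray
    constant_flags: np.ndarray

    def for_features(self, feature_ids: list[str]) -> "FeatureCalibration":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return FeatureCalibration(
            feature_ids=list(feature_ids),
            min_value=self.min_value[idx].copy(),
            max_value=self.max_value[idx].copy(),
            constant_flags=self.constant_flags[idx].copy(),
        )


@dataclass
class NormalizedCohort(Cohort):
    """Cohort whose expression was min–max scaled to [0, 1] per feature.

    ``calibration`` records the Min_Value / Max_Value used so new samples
    normalize identically; ``clipped_count`` counts values outside [0, 1]
    (possible when the calibration came from a different sample set) that
    were clipped.
    """

    calibration: FeatureCalibration = None
    clipped_count: int = 0

    @property
    def constant_feature_flags(self) -> np.ndarray:
        return self.calibration.constant_flags


def _first_duplicate(items: list[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


# ---------------------------------------------------------------------------
# delimited-table I/O
# ---------------------------------------------------------------------------

def _infer_sep(path: str) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def load_expression_table(
    path: str,
    orientation: str = "features_in_rows",
    outcome: str = "outcome",
    impute_missing: bool = False,
) -> Cohort:
    """Load a delimited expression table plus binary outcome into a Cohort.

    The table has a header row and a first column of identifiers.  With
    ``orientation="features_in_rows"`` rows are features and columns are
    samples; ``"samples_in_rows"`` is the transpose.  ``outcome`` names
    either a row/column of the table holding the 0/1 labels, or a path to
    a two-column table mapping sample id → label.

    Missing cells are rejected unless ``impute_missing`` is set, in which
    case they are filled with the per-feature median.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise CohortError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_infer_sep(path), index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)

    if orientation == "samples_in_rows":
        df = df.T

    # now features in rows, samples in columns
    outcome_series = None
    if os.path.isfile(str(outcome)) and str(outcome) != str(path):
        omap = pd.read_csv(outcome, sep=_infer_sep(outcome), index_col=0).iloc[:, 0]
        omap.index = omap.index.map(str)
        missing = [s for s in df.columns if s not in omap.index]
        if missing:
            raise CohortError(f"outcome file lacks sample(s) {missing}")
        outcome_series = omap.reindex(df.columns)
    elif outcome in df.index:
        outcome_series = df.loc[outcome]
        df = df.drop(index=outcome)
    else:
        raise CohortError(
            f"outcome locator {outcome!r} is neither a row of the table nor a file"
        )

    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        if not impute_missing:
            i, j = np.argwhere(np.isnan(values))[0]
            raise CohortError(
                f"missing value at feature {df.index[i]!r}, sample {df.columns[j]!r};"
                " pass impute_missing=True to median-impute"
            )
        med = np.nanmedian(values, axis=1, keepdims=True)
        values = np.where(np.isnan(values), med, values)

    return Cohort(
        sample_ids=list(df.columns),
        feature_ids=list(df.index),
        expression=values,
        outcome=outcome_series.to_numpy(),
    )


def write_cohort(cohort: Cohort, path: str, outcome_row: str = "outcome") -> None:
    """Write a features-in-rows delimited table with an appended outcome row.

    The written file round-trips bit-exactly through
    :func:`load_expression_table` (floats are serialized with full repr
    precision).
    """
    sep = _infer_sep(path)
    with open(path, "w") as fh:
        fh.write(sep.join(["id", *cohort.sample_ids]) + "\n")
        for fid, row in zip(cohort.feature_ids, cohort.expression):
            fh.write(sep.join([fid, *[repr(float(v)) for v in row]]) + "\n")
        fh.write(sep.join([outcome_row, *[str(int(v)) for v in cohort.outcome]]) + "\n")


# ---------------------------------------------------------------------------
# GEO Series Matrix reader
# ---------------------------------------------------------------------------

def load_geo_series_matrix(
    path: str,
    characteristic: str,
    value_map: dict[str, int],
) -> Cohort:
    """Read a GEO Series Matrix text file into a Cohort.

    Parses the ``!series_matrix_table_begin`` … ``!series_matrix_table_end``
    expression block and extracts the outcome from the
    ``!Sample_characteristics_ch1`` line whose entries start with
    ``"<characteristic>:"``.  Observed characteristic values are mapped to
    0/1 through ``value_map`` (e.g. ``{"alive": 0, "dead": 1}``).
    """
    char_lines: list[list[str]] = []
    table: list[list[str]] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table, saw_begin = True, True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table, saw_end = False, True
                continue
            if in_table:
                if line.strip():
                    table.append([_unquote(t) for t in line.split("\t")])
            elif line.startswith("!Sample_characteristics_ch1"):
                char_lines.append([_unquote(t) for t in line.split("\t")[1:]])
    if not (saw_begin and saw_end):
        raise CohortError(
            "not a Series Matrix file: missing !series_matrix_table_begin/_end delimiters"
        )
    if not table:
        raise CohortError("empty series matrix table")

    sample_ids = table[0][1:]
    feature_ids = [row[0] for row in table[1:]]
    values = np.array([[float(v) for v in row[1:]] for row in table[1:]], dtype=float)

    prefix = characteristic.rstrip(":").lower() + ":"
    values_per_sample: list[str] | None = None
    for entries in char_lines:
        if all(e.lower().startswith(prefix) for e in entries if e):
            values_per_sample = [e.split(":", 1)[1].strip() for e in entries]
            break
    if values_per_sample is None:
        raise CohortError(
            f"no !Sample_characteristics_ch1 line with prefix {characteristic!r}"
        )
    if len(values_per_sample) != len(sample_ids):
        raise CohortError(
            f"characteristics count {len(values_per_sample)} != sample count {len(sample_ids)}"
        )
    unmapped = sorted({v for v in values_per_sample if v not in value_map})
    if unmapped:
        raise CohortError(
            f"unmapped characteristic value(s) {unmapped}; observed values: "
            f"{sorted(set(values_per_sample))}"
        )
    outcome = np.array([value_map[v] for v in values_per_sample])
    return Cohort(sample_ids, feature_ids, values, outcome)


def _unquote(token: str) -> str:
    return re.sub(r'^"(.*)"$', r"\1", token.strip())


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_expression(
    cohort: Cohort,
    calibration_samples: str | np.ndarray = "all",
) -> NormalizedCohort:
    """Min–max scale every feature to [0, 1].

    For each feature, ``value' = (value − Min_Value) / (Max_Value − Min_Value)``
    where Min_Value / Max_Value are that feature's extremes over the
    calibration samples ("all", or an index array — e.g. the training
    subset, to avoid calibration leakage into validation data).  Values of
    non-calibration samples may fall outside [0, 1]; they are clipped and
    counted.  Constant features are set to 0.5 and flagged.
    """
    if cohort.n_samples == 0 or cohort.n_features == 0:
        raise CohortError("cannot normalize an empty cohort")
    if isinstance(calibration_samples, str):
        if calibration_samples != "all":
            raise CohortError(f"unknown calibration subset {calibration_samples!r}")
        cal_idx = np.arange(cohort.n_samples)
    else:
        cal_idx = np.asarray(calibration_samples, dtype=int)
        if cal_idx.size == 0:
            raise CohortError("calibration subset is empty")
    cal = cohort.expression[:, cal_idx]
    mn = cal.min(axis=1)
    mx = cal.max(axis=1)
    constant = mx - mn <= 0
    calibration = FeatureCalibration(
        feature_ids=list(cohort.feature_ids),
        min_value=mn,
        max_value=mx,
        constant_flags=constant,
    )
    return apply_calibration(calibration, cohort)


def apply_calibration(calibration: FeatureCalibration, cohort: Cohort) -> NormalizedCohort:
    """Normalize a cohort with previously computed per-feature min/max records."""
    if calibration.feature_ids != cohort.feature_ids:
        cal = calibration.for_features(cohort.feature_ids)
    else:
        cal = calibration
    mn = cal.min_value[:, None]
    rng = (cal.max_value - cal.min_value)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (cohort.expression - mn) / rng
    scaled[cal.constant_flags] = 0.5
    clipped = int(((scaled < 0) | (scaled > 1)).sum())
    scaled = np.clip(scaled, 0.0, 1.0)
    return NormalizedCohort(
        sample_ids=list(cohort.sample_ids),
        feature_ids=list(cohort.feature_ids),
        expression=scaled,
        outcome=cohort.outcome.copy(),
        calibration=cal,
        clipped_count=clipped,
    )


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def largest_remainder_sizes(n: int, ratio: tuple[int, ...]) -> list[int]:
    """Integer part sizes proportional to ``ratio`` summing to ``n``.

    Largest-remainder apportionment; remainder ties go to earlier parts, so
    (312, (2, 1)) → [208, 104] and (208, (2, 1, 1)) → [104, 52, 52].
    """
    if any(r <= 0 for r in ratio):
        raise CohortError(f"ratio entries must be positive, got {ratio}")
    total = sum(ratio)
    quotas = [n * r / total for r in ratio]
    sizes = [int(q) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    # distribute leftovers to the largest remainders, earlier parts first on ties
    order = sorted(range(len(ratio)), key=lambda i: (-remainders[i], i))
    for i in order[: n - sum(sizes)]:
        sizes[i] += 1
    return sizes


def split_cohort(
    cohort: Cohort,
    ratio: tuple[int, ...],
    stratify: bool = True,
    seed: int = 0,
) -> list[Cohort]:
    """Randomly partition a cohort into parts with exact integer sizes.

    Part sizes follow :func:`largest_remainder_sizes`.  With ``stratify``
    (default) the positive labels are themselves apportioned by largest
    remainder so each part's class balance matches the cohort's up to
    integer rounding.  The partition is exhaustive, disjoint, and a
    deterministic function of ``seed``.
    """
    n = cohort.n_samples
    if len(ratio) > n:
        raise CohortError(f"cannot split {n} samples into {len(ratio)} parts")
    sizes = largest_remainder_sizes(n, ratio)
    rng = np.random.default_rng(seed)
    if stratify:
        pos = np.flatnonzero(cohort.outcome == 1)
        neg = np.flatnonzero(cohort.outcome == 0)
        pos_sizes = largest_remainder_sizes(len(pos), ratio)
        neg_sizes = [s - p for s, p in zip(sizes, pos_sizes)]
        if any(s < 0 for s in neg_sizes):
            raise CohortError("stratified split infeasible: a part would need negative negatives")
        rng.shuffle(pos)
        rng.shuffle(neg)
        parts: list[np.ndarray] = []
        p0 = n0 = 0
        for ps, ns in zip(pos_sizes, neg_sizes):
            idx = np.sort(np.concatenate([pos[p0 : p0 + ps], neg[n0 : n0 + ns]]))
            parts.append(idx)
            p0 += ps
            n0 += ns
    else:
        perm = rng.permutation(n)
        parts = []
        start = 0
        for s in sizes:
            parts.append(np.sort(perm[start : start + s]))
            start += s
    return [cohort.subset_samples(idx) for idx in parts]
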