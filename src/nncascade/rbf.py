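"""Radial basis function network units.

One unit is a d-H-1 network: ``output(x) = bias + Σ_h w_h · exp(−‖x − c_h‖² / (2 σ_h²))``.
Units are the atomic building block of every model in this package — the
per-feature 1-H-1 score transformers and the wider integration units of a
cascade.  Training is deterministic and closed-form: k-means centers, widths
from nearest-center spacing, and a ridge-regularized least-squares output
layer fit against the 0/1 outcome.

The raw output range observed on the training rows is stored in the unit
(``out_min`` / ``out_max``) so that :func:`score_unit` can map any input to a
normalized score in [0, 1], with out-of-range raw outputs clipped.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

__all__ = [
    "RBFUnit",
    "RBFTrainingError",
    "train_rbf_unit",
    "predict_unit",
    "score_unit",
    "DEFAULT_HIDDEN",
    "DEFAULT_RIDGE",
    "DEFAULT_WIDTH_SCALE",
]

#: default hidden-unit count, mirroring the 1-11-1 / 3-11-1 architectures
DEFAULT_HIDDEN = 11
#: default ridge penalty on the output layer; shrinks the fit enough that
#: pure-noise inputs are not memorized at cohort-scale n (see docs/methods.md)
DEFAULT_RIDGE = 10.0
#: widths are nearest-center spacing times this smoothing factor
DEFAULT_WIDTH_SCALE = 3.0

_MIN_WIDTH = 1e-6


class RBFTrainingError(ValueError):
    """Raised for degenerate training inputs (empty or single-class targets)."""


@dataclass
class RBFUnit:
    """A trained d-H-1 RBF network with its output calibration.

    Attributes
    ----------
    centers : ndarray (H, d)
    widths : ndarray (H,)
        Gaussian σ per hidden unit, all positive.
    weights : ndarray (H,)
        Output-layer weights.
    bias : float
    out_min, out_max : float
        Raw-output range on the training rows; the min→0, max→1 map behind
        normalized scores.
    degenerate : bool
        True when the training outputs had no spread; such a unit scores a
        constant 0.5.
    train_r : float
        Pearson correlation of raw output vs target on the training rows.
    """

    input_dim: int
    hidden_count: int
    centers: np.ndarray
    widths: np.ndarray
    weights: np.ndarray
    bias: float
    out_min: float
    out_max: float
    seed: int
    ridge: float
    width_scale: float
    degenerate: bool = False
    train_r: float = 0.0

    @property
    def architecture(self) -> str:
        return f"{self.input_dim}-{self.hidden_count}-1"

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["architecture"] = self.architecture
        for key in ("centers", "widths", "weights"):
            d[key] = np.asarray(d[key]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RBFUnit":
        d = dict(d)
        d.pop("architecture", None)
        d["centers"] = np.asarray(d["centers"], dtype=float).reshape(-1, d["input_dim"])
        d["widths"] = np.asarray(d["widths"], dtype=float)
        d["weights"] = np.asarray(d["weights"], dtype=float)
        return cls(**d)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "RBFUnit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _as_2d(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def train_rbf_unit(
    X: np.ndarray,
    y: np.ndarray,
    hidden: int = DEFAULT_HIDDEN,
    ridge: float = DEFAULT_RIDGE,
    width_scale: float = DEFAULT_WIDTH_SCALE,
    seed: int = 0,
) -> RBFUnit:
    """Fit one RBF unit on (X, y) with a deterministic closed-form recipe.

    Centers come from k-means (k = ``hidden``, 10 restarts, seeded); the
    width of each hidden unit is its distance to the nearest other center
    (floored at 1e-6) times ``width_scale``; the output layer solves
    ridge-regularized least squares against the 0/1 targets, with the bias
    unpenalized.  ``hidden`` is lowered to n when n < hidden.

    Identical (X, y, hidden, ridge, width_scale, seed) give a bit-identical
    unit.
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if n == 0:
        raise RBFTrainingError("cannot train on an empty sample set")
    if len(y) != n:
        raise RBFTrainingError(f"X has {n} rows but y has {len(y)}")
    classes = np.unique(y)
    if classes.size < 2:
        raise RBFTrainingError(f"degenerate target: only class {classes.tolist()} present")

    H = int(hidden)
    if H < 1:
        raise RBFTrainingError(f"hidden count must be positive, got {hidden}")
    if H > n:
        warnings.warn(f"hidden count {H} exceeds n={n}; lowering to {n}", stacklevel=2)
        H = n

    if H == n:
        centers = X.copy()
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # duplicate points may collapse clusters
            km = KMeans(n_clusters=H, n_init=10, random_state=int(seed) % (2**31))
            km.fit(X)
        centers = km.cluster_centers_.astype(float)

    widths = _nearest_center_widths(centers, X) * float(width_scale)
    Phi = _design(X, centers, widths)
    A = np.hstack([Phi, np.ones((n, 1))])
    penalty = float(ridge) * np.eye(H + 1)
    penalty[-1, -1] = 0.0  # bias unpenalized
    gram = A.T @ A + penalty
    try:
        coef = np.linalg.solve(gram, A.T @ y)
    except np.linalg.LinAlgError:
        coef = np.linalg.lstsq(A, y, rcond=None)[0]

    # evaluate through the same expression predict_unit uses, so the stored
    # calibration is bit-consistent with later predictions
    raw = Phi @ coef[:-1] + coef[-1]
    out_min, out_max = float(raw.min()), float(raw.max())
    degenerate = not (out_max - out_min > 1e-12)
    if np.std(raw) > 0 and np.std(y) > 0:
        train_r = float(np.corrcoef(raw, y)[0, 1])
    else:
        train_r = 0.0

    return RBFUnit(
        input_dim=d,
        hidden_count=H,
        centers=centers,
        widths=widths,
        weights=coef[:-1],
        bias=float(coef[-1]),
        out_min=out_min,
        out_max=out_max,
        seed=int(seed),
        ridge=float(ridge),
        width_scale=float(width_scale),
        degenerate=degenerate,
        train_r=train_r,
    )


def _nearest_center_widths(centers: np.ndarray, X: np.ndarray) -> np.ndarray:
    H = centers.shape[0]
    if H == 1:
        # single bump: spread over the data extent
        span = float(cdist(X, centers).max()) if len(X) else 1.0
        return np.array([max(span, _MIN_WIDTH)])
    D = cdist(centers, centers)
    np.fill_diagonal(D, np.inf)
    return np.maximum(D.min(axis=1), _MIN_WIDTH)


def _design(X: np.ndarray, centers: np.ndarray, widths: np.ndarray) -> np.ndarray:
    sq = cdist(X, centers, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * widths**2))


def predict_unit(unit: RBFUnit, X: np.ndarray) -> np.ndarray:
    """Raw network output ``bias + Σ_h w_h exp(−‖x − c_h‖²/(2σ_h²))`` per row."""
    X = _as_2d(X)
    if X.shape[1] != unit.input_dim:
        raise ValueError(
            f"input has {X.shape[1]} dims but unit expects {unit.input_dim}"
        )
    return _design(X, unit.centers, unit.widths) @ unit.weights + unit.bias


def score_unit(unit: RBFUnit, X: np.ndarray) -> np.ndarray:
    """Normalized score in [0, 1]: raw output mapped by the unit's stored
    training-output range (min→0, max→1) and clipped."""
    if unit.degenerate:
        warnings.warn("degenerate unit: returning constant 0.5 scores", stacklevel=2)
        return np.full(_as_2d(X).shape[0], 0.5)
    raw = predict_unit(unit, X)
    return np.clip((raw - unit.out_min) / (unit.out_max - unit.out_min), 0.0, 1.0)
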