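"""Origin discrimination: Fisher LDA with LOO-CV, wrapped in SA subset search.

The discriminant model is classical Fisher LDA with equal class priors and a
pooled within-class covariance; when that covariance is singular it is
ridge-regularized by ``1e-8 * trace(S)/p * I``.  Prediction assigns each
sample to the nearest class mean in the discriminant space.

Model selection follows the wrapper strategy: simulated annealing searches
over small sensor-feature subsets, scoring each candidate by its
leave-one-out cross-validated confusion summary.  The annealing energy is

    E = 1 - (overall_sensitivity + overall_specificity) / 2 + eps * |subset|

so ties in classification performance break toward fewer features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._anneal import SAParams, anneal_subset
from .features import FeatureTable

__all__ = [
    "ConfusionSummary",
    "LDAModel",
    "SubsetModel",
    "SAParams",
    "fit_lda",
    "classify",
    "loocv_evaluate",
    "sa_select_features",
]

_RIDGE = 1e-8


@dataclass
class ConfusionSummary:
    """2x2 confusion counts (true class x predicted class) and derived rates.

    ``overall_sensitivity`` is the total fraction of correctly classified
    samples; ``overall_specificity`` is the class-size-weighted mean of the
    per-class specificities (for two classes, the specificity of one class
    is the recall of the other).
    """

    classes: tuple[str, str]
    confusion: np.ndarray
    fold_errors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=float)
        if self.confusion.shape != (2, 2) or np.any(self.confusion < 0):
            raise ValueError("confusion must be a non-negative 2x2 matrix")

    @property
    def class_sizes(self) -> np.ndarray:
        return self.confusion.sum(axis=1)

    @property
    def per_class_sensitivity(self) -> np.ndarray:
        sizes = self.class_sizes
        with np.errstate(invalid="ignore"):
            return np.where(sizes > 0, np.diag(self.confusion) / sizes, np.nan)

    @property
    def per_class_specificity(self) -> np.ndarray:
        # for 2 classes: specificity of class i = recall of the other class
        return self.per_class_sensitivity[::-1]

    @property
    def overall_sensitivity(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    @property
    def overall_specificity(self) -> float:
        sizes = self.class_sizes
        return float(np.sum(sizes * self.per_class_specificity) / sizes.sum())


@dataclass
class LDAModel:
    """Fitted Fisher discriminant for two classes."""

    classes: tuple[str, str]
    features: tuple[str, ...]
    direction: np.ndarray          # p-vector, the single discriminant axis
    class_means: np.ndarray        # 2 x p
    threshold: float               # midpoint of projected class means

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return X @ self.direction - self.threshold


def _design(table: FeatureTable, features: Sequence[str]) -> np.ndarray:
    missing = [f for f in features if f not in table.features.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")
    return table.features[list(features)].to_numpy(dtype=float)


def _fit_arrays(
    X: np.ndarray, y: np.ndarray, classes: tuple[str, str], features: tuple[str, ...]
) -> LDAModel:
    n, p = X.shape
    if p > n - 2:
        raise ValueError("subset too large: more features than samples - 2")
    means = np.empty((2, p))
    scatter = np.zeros((p, p))
    for k, cls in enumerate(classes):
        Xk = X[y == cls]
        if len(Xk) < 2:
            raise ValueError(f"class {cls!r} needs >= 2 samples")
        means[k] = Xk.mean(axis=0)
        centered = Xk - means[k]
        scatter += centered.T @ centered
    within = scatter / (n - 2)  # pooled covariance
    # a feature constant over the whole table carries no information at all;
    # zero within-class spread with distinct means is fine (ridge handles it)
    flat = (X.max(axis=0) - X.min(axis=0)) == 0
    if np.any(flat):
        bad = features[int(np.argmax(flat))]
        raise ValueError(f"feature {bad!r} is constant within both classes")
    try:
        direction = np.linalg.solve(within, means[0] - means[1])
        if not np.all(np.isfinite(direction)):
            raise np.linalg.LinAlgError("non-finite solution")
    except np.linalg.LinAlgError:
        trace = np.trace(within)
        ridge = _RIDGE * (trace / p if trace > 0 else 1.0)
        direction = np.linalg.solve(
            within + ridge * np.eye(p), means[0] - means[1]
        )
    threshold = float(direction @ (means[0] + means[1]) / 2.0)
    return LDAModel(
        classes=classes,
        features=features,
        direction=direction,
        class_means=means,
        threshold=threshold,
    )


def _class_labels(labels: pd.Series) -> tuple[str, str]:
    classes = tuple(pd.unique(labels))
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required; got {classes}")
    return classes  # order of first appearance


def fit_lda(table: FeatureTable, features: Sequence[str]) -> LDAModel:
    """Fit the equal-priors Fisher discriminant on the named feature subset."""
    features = tuple(features)
    if not features:
        raise ValueError("feature subset must be non-empty")
    X = _design(table, features)
    y = table.labels.to_numpy()
    return _fit_arrays(X, y, _class_labels(table.labels), features)


def classify(model: LDAModel, table: FeatureTable | pd.DataFrame) -> pd.Series:
    """Predict region labels for every sample in ``table`` (resubstitution
    when applied to the training table — not a cross-validated estimate)."""
    frame = table.features if isinstance(table, FeatureTable) else table
    missing = [f for f in model.features if f not in frame.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")
    X = frame[list(model.features)].to_numpy(dtype=float)
    d = X @ model.direction - model.threshold
    labels = np.where(d >= 0, model.classes[0], model.classes[1])
    return pd.Series(labels, index=frame.index, name="predicted")


def loocv_evaluate(
    table: FeatureTable, features: Sequence[str]
) -> ConfusionSummary:
    """Leave-one-out confusion summary for one feature subset.

    Each sample is predicted by a discriminant fitted on the remaining
    n - 1 samples.  A fold whose fit fails (e.g. a class reduced below two
    members) is recorded in ``fold_errors`` rather than silently skipped.
    """
    features = tuple(features)
    X = _design(table, features)
    y = table.labels.to_numpy()
    ids = table.sample_ids
    classes = _class_labels(table.labels)
    cls_index = {c: k for k, c in enumerate(classes)}
    confusion = np.zeros((2, 2))
    errors: list[str] = []
    n = len(y)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            model = _fit_arrays(X[mask], y[mask], classes, features)
        except (ValueError, np.linalg.LinAlgError) as exc:
            errors.append(f"{ids[i]}: {exc}")
            mask[i] = True
            continue
        d = X[i] @ model.direction - model.threshold
        pred = model.classes[0] if d >= 0 else model.classes[1]
        confusion[cls_index[y[i]], cls_index[pred]] += 1
        mask[i] = True
    return ConfusionSummary(classes=classes, confusion=confusion, fold_errors=errors)


@dataclass
class SubsetModel:
    """SA-selected feature subset with its fitted discriminant and LOO-CV
    performance."""

    selected_features: tuple[str, ...]
    model: LDAModel
    loocv_summary: ConfusionSummary
    energy: float


def classification_energy(summary: ConfusionSummary) -> float:
    """Raw SA energy: one minus the balanced mean of the overall rates."""
    if summary.fold_errors:
        return np.inf
    return 1.0 - (summary.overall_sensitivity + summary.overall_specificity) / 2.0


def sa_select_features(
    table: FeatureTable,
    params: SAParams | None = None,
    candidates: Sequence[str] | None = None,
) -> SubsetModel:
    """Search feature subsets by simulated annealing on the LOO-CV energy.

    Deterministic given ``params.seed``; the best-ever subset over all
    restarts is refitted on the full table and returned.
    """
    params = params or SAParams()
    if candidates is None:
        candidates = table.columns
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate feature set")
    n = len(table.sample_ids)
    cap = min(params.max_subset_size, max(1, n - 3))

    def energy(subset: tuple[str, ...]) -> float:
        if len(subset) > cap:
            return np.inf
        return classification_energy(loocv_evaluate(table, subset))

    best, best_e = anneal_subset(candidates, energy, params)
    summary = loocv_evaluate(table, best)
    return SubsetModel(
        selected_features=best,
        model=fit_lda(table, best),
        loocv_summary=summary,
        energy=best_e,
    )
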