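"""Quantitation of volatile-class contents by multiple linear regression.

Ordinary least squares with intercept maps selected sensor features to a
volatile-class content (mg/kg oil).  Performance is summarized by
leave-one-out cross-validation:

* ``loocv_RMSE`` — root mean squared LOO prediction error (mg/kg);
* ``loocv_R2``  — squared Pearson correlation between LOO predictions and
  the observed contents (bounded in [0, 1]).

LOO predictions use the exact hat-matrix identity for OLS,
``y_i - e_i / (1 - h_ii)``, which equals refitting on every fold but is
cheap enough to sit inside the simulated-annealing subset search.  The SA
wrapper minimizes LOO RMSE with a parsimony tie-break, mirroring the
classification wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._anneal import SAParams, anneal_subset
from .features import FeatureTable

__all__ = [
    "LinearModel",
    "RegressionModel",
    "fit_mlr",
    "predict_mlr",
    "loocv_regression",
    "sa_select_regression",
]

TARGETS = ("alcohols", "aldehydes", "total")

_RANK_TOL = 1e-10


@dataclass
class LinearModel:
    """OLS fit: ``y = intercept + X @ coefficients``."""

    features: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in frame.columns]
        if missing:
            raise ValueError(f"missing feature column(s): {missing}")
        X = frame[list(self.features)].to_numpy(dtype=float)
        return self.intercept + X @ self.coefficients


@dataclass
class RegressionModel:
    """SA-selected quantitation model for one (region, target) pair."""

    target: str
    region: str | None
    selected_features: tuple[str, ...]
    model: LinearModel
    loocv_R2: float
    loocv_RMSE: float
    loo_predictions: np.ndarray
    energy: float


def _design(table: FeatureTable, features: Sequence[str]) -> np.ndarray:
    missing = [f for f in features if f not in table.features.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")
    return table.features[list(features)].to_numpy(dtype=float)


def _augmented(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def _check_rank(Z: np.ndarray, features: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(Z, tol=_RANK_TOL * max(Z.shape))
    if rank < Z.shape[1]:
        # identify offending columns by greedy QR growth
        collinear = []
        kept: list[int] = [0]  # intercept
        for j in range(1, Z.shape[1]):
            trial = Z[:, kept + [j]]
            if np.linalg.matrix_rank(trial, tol=_RANK_TOL * max(Z.shape)) <= len(kept):
                collinear.append(features[j - 1])
            else:
                kept.append(j)
        raise ValueError(f"rank-deficient design; collinear column(s): {collinear}")


def fit_mlr(
    table: FeatureTable, y: np.ndarray | pd.Series, features: Sequence[str]
) -> LinearModel:
    """Ordinary least squares of ``y`` on the named features, with intercept."""
    features = tuple(features)
    if not features:
        raise ValueError("feature subset must be non-empty")
    X = _design(table, features)
    yv = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 samples (n={n}, p={p})")
    Z = _augmented(X)
    _check_rank(Z, features)
    beta, *_ = np.linalg.lstsq(Z, yv, rcond=None)
    return LinearModel(
        features=features, coefficients=beta[1:], intercept=float(beta[0])
    )


def predict_mlr(model: LinearModel, table: FeatureTable | pd.DataFrame) -> np.ndarray:
    frame = table.features if isinstance(table, FeatureTable) else table
    return model.predict(frame)


def loocv_regression(
    table: FeatureTable, y: np.ndarray | pd.Series, features: Sequence[str]
) -> tuple[float, float, np.ndarray]:
    """LOO-CV R^2, RMSE and per-sample LOO predictions for one subset.

    Uses the exact leverage identity; equivalent to n explicit refits.
    A fold that would be rank-deficient (leverage ~ 1 or singular design)
    raises.
    """
    features = tuple(features)
    X = _design(table, features)
    yv = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError(
            f"need n > p + 2 samples for LOO (n={n}, p={p})"
        )
    Z = _augmented(X)
    _check_rank(Z, features)
    # hat diagonal via economy QR: h_i = ||q_i||^2
    Q, _ = np.linalg.qr(Z)
    h = np.sum(Q**2, axis=1)
    if np.any(h >= 1.0 - 1e-10):
        bad = int(np.argmax(h))
        raise ValueError(
            f"LOO fold for sample index {bad} is rank-deficient (leverage ~ 1)"
        )
    beta, *_ = np.linalg.lstsq(Z, yv, rcond=None)
    residuals = yv - Z @ beta
    loo_residuals = residuals / (1.0 - h)
    loo_pred = yv - loo_residuals
    rmse = float(np.sqrt(np.mean(loo_residuals**2)))
    if np.std(loo_pred) == 0 or np.std(yv) == 0:
        r2 = 0.0 if rmse > 0 else 1.0
    else:
        r2 = float(np.corrcoef(loo_pred, yv)[0, 1] ** 2)
    return r2, rmse, loo_pred


def sa_select_regression(
    table: FeatureTable,
    y: np.ndarray | pd.Series,
    params: SAParams | None = None,
    target: str = "",
    region: str | None = None,
    candidates: Sequence[str] | None = None,
) -> RegressionModel:
    """Simulated-annealing subset search minimizing LOO-CV RMSE.

    The candidate pool defaults to every column of ``table`` (all 63
    sensor-method features in a full table).  Deterministic given
    ``params.seed``.
    """
    params = params or SAParams(max_subset_size=29)
    if candidates is None:
        candidates = table.columns
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate feature set")
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    cap = min(params.max_subset_size, max(1, n - 3))

    def energy(subset: tuple[str, ...]) -> float:
        if len(subset) > cap:
            return np.inf
        try:
            _, rmse, _ = loocv_regression(table, yv, subset)
        except ValueError:
            return np.inf
        return rmse

    best, best_e = anneal_subset(candidates, energy, params)
    r2, rmse, loo_pred = loocv_regression(table, yv, best)
    return RegressionModel(
        target=target,
        region=region,
        selected_features=best,
        model=fit_mlr(table, yv, best),
        loocv_R2=r2,
        loocv_RMSE=rmse,
        loo_predictions=loo_pred,
        energy=best_e,
    )
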