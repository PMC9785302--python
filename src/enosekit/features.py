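"""Scalar feature extraction from sensor resistance curves.

Seven descriptors are computed per sensor and sample:

====== ==========================================================
LP     last response point (final resistance reading), ohm
INT    trapezoidal integral of the curve over time, ohm*s
MAX    maximum reading over the acquisition window, ohm
MIN    minimum reading, ohm
SUM    sum of the readings, ohm
MEAN   arithmetic mean of the readings, ohm
SD     sample standard deviation (n-1 denominator), ohm
====== ==========================================================

A full table carries 9 sensors x 7 methods = 63 columns named
``S{i}_{METHOD}``, ordered sensor-major, method-minor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import SENSOR_IDS, SensorCurve

__all__ = ["METHODS", "FeatureTable", "extract_features", "select_method_view"]

#: the seven extraction methods, canonical order
METHODS = ("LP", "INT", "MAX", "MIN", "SUM", "MEAN", "SD")


@dataclass
class FeatureTable:
    """Samples x features matrix with region labels.

    ``features`` is a DataFrame indexed by sample_id whose columns follow the
    ``S{i}_{METHOD}`` naming convention; ``labels`` is a parallel region
    Series with the same index.
    """

    features: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            raise ValueError("features and labels must share one sample index")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def columns(self) -> list[str]:
        return list(self.features.columns)

    def to_frame(self) -> pd.DataFrame:
        """Single DataFrame with sample_id, region and feature columns."""
        frame = self.features.copy()
        frame.insert(0, "region", self.labels)
        frame.index.name = "sample_id"
        return frame.reset_index()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        frame = frame.set_index("sample_id")
        return cls(features=frame.drop(columns=["region"]), labels=frame["region"])


def _feature_values(curve: SensorCurve, method: str) -> np.ndarray:
    r = curve.resistances
    if method == "LP":
        return r[-1, :]
    if method == "MAX":
        return r.max(axis=0)
    if method == "MIN":
        return r.min(axis=0)
    if method == "SUM":
        return r.sum(axis=0)
    if method == "MEAN":
        return r.mean(axis=0)
    if method == "SD":
        return r.std(axis=0, ddof=1)
    if method == "INT":
        return np.trapezoid(r, curve.times, axis=0)
    raise ValueError(f"unknown feature method {method!r}")


def extract_features(
    curves: Iterable[SensorCurve], methods: Sequence[str] = METHODS
) -> FeatureTable:
    """Compute the selected descriptors for every curve.

    Curves must have at least two time points on a uniform grid (the
    container enforces uniformity; the length is re-checked here because the
    trapezoidal integral and the sample SD are undefined for a single point).
    """
    methods = tuple(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown feature method(s): {sorted(unknown)}")
    # canonical order regardless of the order requested
    methods = tuple(m for m in METHODS if m in methods)
    rows, ids, regions = [], [], []
    for curve in curves:
        if curve.n_timepoints < 2:
            raise ValueError(
                f"sample {curve.sample_id!r}: need >= 2 time points"
            )
        row = {}
        per_method = {m: _feature_values(curve, m) for m in methods}
        for j, sensor in enumerate(SENSOR_IDS):
            for m in methods:
                row[f"{sensor}_{m}"] = per_method[m][j]
        rows.append(row)
        ids.append(curve.sample_id)
        regions.append(curve.region)
    index = pd.Index(ids, name="sample_id")
    columns = [f"{s}_{m}" for s in SENSOR_IDS for m in methods]
    features = pd.DataFrame(rows, index=index, columns=columns)
    labels = pd.Series(regions, index=index, name="region")
    return FeatureTable(features=features, labels=labels)


def select_method_view(table: FeatureTable, method: str) -> FeatureTable:
    """Nine-column sub-table for one extraction method (labels preserved)."""
    if method not in METHODS:
        raise ValueError(f"unknown feature method {method!r}")
    wanted = [f"{s}_{method}" for s in SENSOR_IDS]
    missing = [c for c in wanted if c not in table.features.columns]
    if missing:
        raise ValueError(f"table lacks columns {missing}")
    return FeatureTable(features=table.features[wanted].copy(), labels=table.labels)
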