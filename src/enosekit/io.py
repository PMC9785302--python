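"""CSV schemas and domain containers for e-nose sensor curves and volatile profiles.

All on-disk exchange is plain CSV (comma separator, ``.`` decimal, UTF-8,
mandatory header).  Three schemas are defined:

``sensor_curves.csv``
    long format, one row per time point:
    ``sample_id,region,time_s,S1,...,S9`` (resistances in ohm).
``volatiles.csv``
    one row per sample: ``sample_id,<eight class columns>[,total]`` (mg/kg oil).
``labels.csv``
    ``sample_id,region``.

Region labels are stored without diacritics (``Coa``/``Douro``) for
portability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "SENSOR_IDS",
    "VOLATILE_CLASSES",
    "SchemaError",
    "ValidationError",
    "SensorCurve",
    "VolatileProfile",
    "read_sensor_curves",
    "write_sensor_curves",
    "read_volatile_profiles",
    "write_volatile_profiles",
    "read_labels",
    "write_labels",
]

#: canonical region labels (ASCII, no diacritics)
REGIONS = ("Coa", "Douro")

#: the nine MOS sensors, fixed order
SENSOR_IDS = tuple(f"S{i}" for i in range(1, 10))

#: the eight volatile chemical classes quantified per sample (mg/kg oil)
VOLATILE_CLASSES = (
    "alcohols",
    "aldehydes",
    "alkanes",
    "alkenes",
    "esters",
    "ethers",
    "ketones",
    "terpenes",
)

#: half the printed precision of the reference tables (mg/kg)
TOTAL_TOLERANCE = 0.05


class SchemaError(ValueError):
    """A file does not match the expected column layout."""


class ValidationError(ValueError):
    """File contents violate a domain invariant."""


def _check_region(region: str) -> str:
    if region not in REGIONS:
        raise ValidationError(
            f"unknown region {region!r}; expected one of {REGIONS}"
        )
    return region


@dataclass
class SensorCurve:
    """One sample's resistance-versus-time trace for the nine-sensor array.

    Attributes
    ----------
    sample_id : str
    region : str
        ``"Coa"`` or ``"Douro"``.
    times : ndarray, shape (n_timepoints,)
        Seconds from exposure start; uniform grid starting at 0.
    resistances : ndarray, shape (n_timepoints, 9)
        Electrical resistance in ohm, strictly positive.
    """

    sample_id: str
    region: str
    times: np.ndarray
    resistances: np.ndarray
    sensor_ids: Sequence[str] = field(default=SENSOR_IDS)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.resistances = np.asarray(self.resistances, dtype=float)
        _check_region(self.region)
        if tuple(self.sensor_ids) != SENSOR_IDS:
            raise ValidationError(
                f"sensor columns must be exactly {SENSOR_IDS} in order"
            )
        if self.resistances.ndim != 2 or self.resistances.shape[1] != len(SENSOR_IDS):
            raise ValidationError(
                f"resistances must have shape (n_timepoints, 9); "
                f"got {self.resistances.shape}"
            )
        if self.times.shape[0] != self.resistances.shape[0]:
            raise ValidationError("times and resistances length mismatch")
        if np.any(self.resistances <= 0):
            bad = int(np.argwhere(self.resistances <= 0)[0][0])
            raise ValidationError(
                f"non-positive resistance in sample {self.sample_id!r} at row {bad}"
            )
        if self.times.size and self.times[0] != 0.0:
            raise ValidationError(
                f"sample {self.sample_id!r}: time grid must start at 0"
            )
        self._check_uniform_grid()

    def _check_uniform_grid(self) -> None:
        if self.times.size < 2:
            return
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValidationError(
                f"sample {self.sample_id!r}: times must be strictly increasing"
            )
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
            raise ValidationError(
                f"sample {self.sample_id!r}: non-uniform time grid"
            )

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return float(self.times[1] - self.times[0])

    @property
    def n_timepoints(self) -> int:
        return int(self.times.shape[0])


@dataclass
class VolatileProfile:
    """Per-sample contents of the eight volatile chemical classes (mg/kg oil)."""

    sample_id: str
    contents: dict[str, float]
    total: float | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.contents) - set(VOLATILE_CLASSES)
        if unknown:
            raise SchemaError(f"unknown volatile class column(s): {sorted(unknown)}")
        missing = set(VOLATILE_CLASSES) - set(self.contents)
        if missing:
            raise SchemaError(f"missing volatile class column(s): {sorted(missing)}")
        for name, value in self.contents.items():
            if value < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: negative content for {name}"
                )
        class_sum = float(sum(self.contents[c] for c in VOLATILE_CLASSES))
        if self.total is None:
            self.total = class_sum
        elif abs(self.total - class_sum) > TOTAL_TOLERANCE:
            raise ValidationError(
                f"sample {self.sample_id!r}: total {self.total} inconsistent with "
                f"class sum {class_sum:.6g} (tolerance {TOTAL_TOLERANCE} mg/kg)"
            )
        if self.region is not None:
            _check_region(self.region)

    def as_array(self) -> np.ndarray:
        """Class contents as a length-8 vector in canonical order."""
        return np.array([self.contents[c] for c in VOLATILE_CLASSES], dtype=float)


# ---------------------------------------------------------------------------
# sensor_curves.csv

_CURVE_COLUMNS = ["sample_id", "region", "time_s", *SENSOR_IDS]


def _require_columns(frame: pd.DataFrame, required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_sensor_curves(path: str | Path) -> list[SensorCurve]:
    """Read a long-format sensor-curve CSV into one :class:`SensorCurve` per sample.

    Samples keep their order of first appearance; rows within a sample are
    sorted by time.  All container invariants (positive resistances, uniform
    grid from 0, nine sensors) are enforced.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    _require_columns(frame, _CURVE_COLUMNS, path)
    curves: list[SensorCurve] = []
    for sample_id, block in frame.groupby("sample_id", sort=False):
        block = block.sort_values("time_s")
        regions = block["region"].unique()
        if len(regions) != 1:
            raise ValidationError(
                f"{path}: sample {sample_id!r} has conflicting region labels"
            )
        curves.append(
            SensorCurve(
                sample_id=str(sample_id),
                region=str(regions[0]),
                times=block["time_s"].to_numpy(dtype=float),
                resistances=block[list(SENSOR_IDS)].to_numpy(dtype=float),
            )
        )
    return curves


def write_sensor_curves(curves: Iterable[SensorCurve], path: str | Path) -> None:
    """Write curves to the long-format CSV schema (full float precision)."""
    rows = []
    for curve in curves:
        for i, t in enumerate(curve.times):
            rows.append(
                {
                    "sample_id": curve.sample_id,
                    "region": curve.region,
                    "time_s": t,
                    **{s: curve.resistances[i, j] for j, s in enumerate(SENSOR_IDS)},
                }
            )
    pd.DataFrame(rows, columns=_CURVE_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# volatiles.csv

def read_volatile_profiles(path: str | Path) -> list[VolatileProfile]:
    """Read per-sample volatile-class contents.

    The ``total`` column is optional; when absent it is recomputed as the
    class sum, and when present it must agree with the class sum to within
    0.05 mg/kg.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    _require_columns(frame, ["sample_id", *VOLATILE_CLASSES], path)
    extra = set(frame.columns) - {"sample_id", "region", "total", *VOLATILE_CLASSES}
    if extra:
        raise SchemaError(f"{path}: unknown class column(s) {sorted(extra)}")
    profiles = []
    for _, row in frame.iterrows():
        profiles.append(
            VolatileProfile(
                sample_id=str(row["sample_id"]),
                contents={c: float(row[c]) for c in VOLATILE_CLASSES},
                total=float(row["total"]) if "total" in frame.columns else None,
                region=str(row["region"]) if "region" in frame.columns else None,
            )
        )
    return profiles


def write_volatile_profiles(
    profiles: Iterable[VolatileProfile], path: str | Path
) -> None:
    rows = []
    include_region = False
    for p in profiles:
        row = {"sample_id": p.sample_id}
        if p.region is not None:
            row["region"] = p.region
            include_region = True
        row.update({c: p.contents[c] for c in VOLATILE_CLASSES})
        row["total"] = p.total
        rows.append(row)
    columns = ["sample_id"] + (["region"] if include_region else [])
    columns += [*VOLATILE_CLASSES, "total"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# labels.csv

def read_labels(path: str | Path) -> pd.Series:
    """Read ``labels.csv`` into a region Series indexed by sample_id."""
    path = Path(path)
    frame = pd.read_csv(path)
    _require_columns(frame, ["sample_id", "region"], path)
    for value in frame["region"]:
        _check_region(str(value))
    return pd.Series(
        frame["region"].to_numpy(), index=frame["sample_id"].astype(str), name="region"
    )


def write_labels(labels: pd.Series, path: str | Path) -> None:
    frame = pd.DataFrame(
        {"sample_id": labels.index.astype(str), "region": labels.to_numpy()}
    )
    frame.to_csv(path, index=False)
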