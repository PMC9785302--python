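"""Synthetic two-region e-nose cohorts.

Emulates the study design the analysis modules assume: two groups of olive
oils (36 from the Côa valley, 31 from the Douro valley) whose volatile-class
contents follow region-specific truncated normal distributions, transduced
into nine MOS sensor resistance curves by a first-order adsorption model

    R_s(t) = B_s - A_s * (1 - exp(-t / tau_s)) + eps,   eps ~ N(0, sigma)

with response amplitude ``A_s = sum_k M[s, k] * c_k`` linear in the class
contents ``c`` (ohm decrease per mg/kg).  Resistance is floored at 1 ohm.

Default class means/SDs are the published per-region summaries of the
reference cohort; truncation ranges bracket the published concentration
ranges (and zero).  The sensitivity matrix is random but fixed, and is the
same for both regions, so any class separation in the generated curves
arises from concentration differences alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import REGIONS, SENSOR_IDS, VOLATILE_CLASSES, SensorCurve, VolatileProfile

__all__ = [
    "GeneratorConfig",
    "CLASS_MEANS",
    "CLASS_SDS",
    "TRUNCATION_RANGES",
    "default_sensitivity_matrix",
    "sample_volatile_profiles",
    "transduce_to_curves",
    "generate_cohort",
    "truncated_normal_moments",
]


class ConfigurationError(ValueError):
    """A generator configuration violates a physical constraint."""


# Published per-region mean volatile-class contents, mg/kg oil.
CLASS_MEANS = {
    "Coa": {
        "alcohols": 1.2, "aldehydes": 9.8, "alkanes": 1.1, "alkenes": 0.4,
        "esters": 0.2, "ethers": 0.2, "ketones": 0.2, "terpenes": 1.4,
    },
    "Douro": {
        "alcohols": 5.1, "aldehydes": 27.7, "alkanes": 2.9, "alkenes": 2.2,
        "esters": 0.6, "ethers": 1.1, "ketones": 0.7, "terpenes": 1.4,
    },
}

# Matching standard deviations, mg/kg oil.
CLASS_SDS = {
    "Coa": {
        "alcohols": 3.4, "aldehydes": 9.9, "alkanes": 0.7, "alkenes": 0.4,
        "esters": 0.2, "ethers": 0.3, "ketones": 0.2, "terpenes": 0.8,
    },
    "Douro": {
        "alcohols": 4.9, "aldehydes": 18.0, "alkanes": 1.7, "alkenes": 0.9,
        "esters": 0.7, "ethers": 0.6, "ketones": 0.7, "terpenes": 0.9,
    },
}

# Per-class truncation bounds, mg/kg.  Alcohols/aldehydes bracket the
# published concentration ranges (union over the two regions); the remaining
# classes, for which no range is published, use [0, max regional mean + 4 SD].
TRUNCATION_RANGES = {
    "alcohols": (0.17, 22.1),
    "aldehydes": (0.41, 83.9),
    "alkanes": (0.0, 10.0),
    "alkenes": (0.0, 6.0),
    "esters": (0.0, 3.5),
    "ethers": (0.0, 3.5),
    "ketones": (0.0, 3.5),
    "terpenes": (0.0, 5.0),
}

#: seed of the fixed default sensitivity matrix (independent of cohort seed)
_SENSITIVITY_SEED = 973_101


def default_sensitivity_matrix() -> np.ndarray:
    """Fixed random 9x8 sensitivity matrix, entries in [0.5, 2.0] ohm.kg/mg.

    Seeded once and shared by all cohorts, mimicking a single physical
    sensor array with partially selective but region-independent responses.
    """
    rng = np.random.default_rng(_SENSITIVITY_SEED)
    return rng.uniform(0.5, 2.0, size=(len(SENSOR_IDS), len(VOLATILE_CLASSES)))


def _default_class_stats(which: str) -> dict[str, dict[str, float]]:
    source = CLASS_MEANS if which == "mean" else CLASS_SDS
    return {r: dict(source[r]) for r in REGIONS}


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the reference study's structure: cohort sizes 36/31,
    published class means and SDs, 38 time points every 4 s (t = 0..148 s).
    ``noise_sd_curve`` is the per-reading resistance noise in ohm.
    """

    n_coa: int = 36
    n_douro: int = 31
    class_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: _default_class_stats("mean")
    )
    class_sds: dict[str, dict[str, float]] = field(
        default_factory=lambda: _default_class_stats("sd")
    )
    truncation_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(TRUNCATION_RANGES)
    )
    sensitivity_matrix: np.ndarray = field(
        default_factory=default_sensitivity_matrix
    )
    baseline_resistances: np.ndarray = field(
        default_factory=lambda: np.array(
            [2600.0, 3100.0, 2300.0, 2900.0, 3400.0, 2500.0, 3000.0, 3600.0, 2700.0]
        )
    )
    tau: np.ndarray = field(
        default_factory=lambda: np.array(
            [30.0, 35.0, 40.0, 45.0, 50.0, 32.0, 38.0, 44.0, 48.0]
        )
    )
    noise_sd_curve: float = 5.0
    n_timepoints: int = 38
    dt: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.sensitivity_matrix = np.asarray(self.sensitivity_matrix, dtype=float)
        self.baseline_resistances = np.asarray(self.baseline_resistances, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.validate()

    def validate(self) -> None:
        n_s, n_c = len(SENSOR_IDS), len(VOLATILE_CLASSES)
        if self.sensitivity_matrix.shape != (n_s, n_c):
            raise ConfigurationError(
                f"sensitivity_matrix must be {n_s}x{n_c}; "
                f"got {self.sensitivity_matrix.shape}"
            )
        if np.any(self.sensitivity_matrix < 0):
            raise ConfigurationError("sensitivity_matrix entries must be >= 0")
        if self.baseline_resistances.shape != (n_s,) or self.tau.shape != (n_s,):
            raise ConfigurationError("baseline_resistances and tau must have length 9")
        if np.any(self.tau <= 0):
            raise ConfigurationError("tau must be positive")
        if self.noise_sd_curve < 0:
            raise ConfigurationError("noise_sd_curve must be >= 0")
        if self.n_timepoints < 2 or self.dt <= 0:
            raise ConfigurationError("need n_timepoints >= 2 and dt > 0")
        if self.n_coa < 0 or self.n_douro < 0:
            raise ConfigurationError("cohort sizes must be >= 0")
        for region in REGIONS:
            for cls in VOLATILE_CLASSES:
                if cls not in self.class_means[region] or cls not in self.class_sds[region]:
                    raise ConfigurationError(f"missing class stats for {cls!r}")
                if self.class_sds[region][cls] < 0:
                    raise ConfigurationError(f"negative SD for {region}/{cls}")
        for cls in VOLATILE_CLASSES:
            lo, hi = self.truncation_ranges[cls]
            if not lo < hi:
                raise ConfigurationError(f"truncation bounds for {cls!r} not ordered")
        # worst-case response amplitude must stay below every baseline so
        # that the positivity floor never engages systematically
        upper = np.array([self.truncation_ranges[c][1] for c in VOLATILE_CLASSES])
        max_drop = self.sensitivity_matrix @ upper
        if np.any(max_drop >= self.baseline_resistances):
            bad = SENSOR_IDS[int(np.argmax(max_drop - self.baseline_resistances))]
            raise ConfigurationError(
                f"maximum response amplitude exceeds baseline for sensor {bad}"
            )

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints, dtype=float) * self.dt


def _truncation_bounds(config: GeneratorConfig, cls: str) -> tuple[float, float]:
    lo, hi = config.truncation_ranges[cls]
    return max(lo, 0.0), hi


def truncated_normal_moments(
    mean: float, sd: float, lo: float, hi: float, n_grid: int = 200_001
) -> tuple[float, float]:
    """Mean and SD of N(mean, sd) truncated to [lo, hi], by numeric integration.

    Deliberately avoids the closed-form truncated-normal formulas so it can
    serve as an independent oracle for the sampling routine.
    """
    x = np.linspace(lo, hi, n_grid)
    w = np.exp(-0.5 * ((x - mean) / sd) ** 2)
    z = np.trapezoid(w, x)
    m1 = np.trapezoid(x * w, x) / z
    m2 = np.trapezoid(x**2 * w, x) / z
    return float(m1), float(np.sqrt(m2 - m1**2))


def sample_volatile_profiles(
    config: GeneratorConfig,
    region: str,
    n: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[VolatileProfile]:
    """Draw volatile-class profiles for one region.

    Each class content is drawn from a normal with the configured regional
    mean/SD, truncated to the configured range intersected with [0, inf).
    A zero SD degenerates to the mean exactly.  Totals are the class sums.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    if n is None:
        n = config.n_coa if region == "Coa" else config.n_douro
    if rng is None:
        rng = np.random.default_rng(config.seed)
    draws = np.empty((n, len(VOLATILE_CLASSES)))
    for j, cls in enumerate(VOLATILE_CLASSES):
        mean = config.class_means[region][cls]
        sd = config.class_sds[region][cls]
        lo, hi = _truncation_bounds(config, cls)
        if sd == 0:
            draws[:, j] = mean
        else:
            a, b = (lo - mean) / sd, (hi - mean) / sd
            draws[:, j] = stats.truncnorm.rvs(
                a, b, loc=mean, scale=sd, size=n, random_state=rng
            )
    return [
        VolatileProfile(
            sample_id=f"{region}-{i + 1:03d}",
            contents={c: float(draws[i, j]) for j, c in enumerate(VOLATILE_CLASSES)},
            region=region,
        )
        for i in range(n)
    ]


def transduce_to_curves(
    profiles: Iterable[VolatileProfile],
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> list[SensorCurve]:
    """Map volatile profiles to noisy sensor resistance curves.

    Implements the first-order adsorption response described in the module
    docstring; sample ids and region labels carry through.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = config.times
    # (n_timepoints, 9) fractional approach to steady state per sensor
    approach = 1.0 - np.exp(-t[:, None] / config.tau[None, :])
    curves = []
    for profile in profiles:
        amplitude = config.sensitivity_matrix @ profile.as_array()  # (9,)
        if config.noise_sd_curve == 0 and np.any(
            amplitude >= config.baseline_resistances
        ):
            raise ConfigurationError(
                f"sample {profile.sample_id!r}: response amplitude exceeds baseline "
                "(would systematically clip resistance at the positivity floor)"
            )
        clean = config.baseline_resistances[None, :] - amplitude[None, :] * approach
        noisy = clean + rng.normal(0.0, config.noise_sd_curve, size=clean.shape)
        curves.append(
            SensorCurve(
                sample_id=profile.sample_id,
                region=profile.region or "Coa",
                times=t.copy(),
                resistances=np.maximum(noisy, 1.0),
            )
        )
    return curves


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[SensorCurve], list[VolatileProfile], pd.Series]:
    """Generate the full two-region cohort (curves, profiles, labels).

    A single RNG seeded from ``config.seed`` drives every draw, so identical
    configurations give bitwise-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    profiles = sample_volatile_profiles(config, "Coa", config.n_coa, rng)
    profiles += sample_volatile_profiles(config, "Douro", config.n_douro, rng)
    curves = transduce_to_curves(profiles, config, rng)
    labels = pd.Series(
        [p.region for p in profiles],
        index=pd.Index([p.sample_id for p in profiles], name="sample_id"),
        name="region",
    )
    return curves, profiles, labels


def with_noise(config: GeneratorConfig, noise_sd_curve: float) -> GeneratorConfig:
    """Copy of ``config`` at a different curve-noise level."""
    return replace(config, noise_sd_curve=noise_sd_curve)
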