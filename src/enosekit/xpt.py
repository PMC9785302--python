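"""Method-agreement validation by the slope/intercept confidence-interval test.

Following the accuracy-assessment logic of the French XPT 90-210 standard,
an alternative method's predictions are regressed on the reference method's
values (reference on the x-axis).  The alternative method is accepted when,
at level alpha, the two-sided confidence interval of the slope contains 1
and that of the intercept contains 0 — i.e. the fit is statistically
indistinguishable from the identity line.

The two intervals are tested separately (no joint ellipse), matching the
common reporting convention; note that the joint verdict therefore has a
type-I error rate somewhat above alpha for a truly unbiased method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureTable
from .io import VolatileProfile
from .mlr import RegressionModel, loocv_regression

__all__ = ["ValidationReport", "validate_against_reference", "validate_models"]


@dataclass
class ValidationReport:
    """Slope/intercept estimates, 95% CIs and the pass/fail verdict."""

    n: int
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    ci_slope: tuple[float, float]
    ci_intercept: tuple[float, float]
    slope_ok: bool
    intercept_ok: bool
    alpha: float
    target: str | None = None
    region: str | None = None

    @property
    def verdict(self) -> bool:
        """Pass iff both theoretical values lie inside their intervals."""
        return self.slope_ok and self.intercept_ok


def validate_against_reference(
    predicted: np.ndarray | Sequence[float],
    reference: np.ndarray | Sequence[float],
    alpha: float = 0.05,
    target: str | None = None,
    region: str | None = None,
) -> ValidationReport:
    """OLS of predicted on reference with slope=1 / intercept=0 CI tests.

    Closed-form simple linear regression: ``CI = estimate +/-
    t(1 - alpha/2, n - 2) * SE``.  Requires n >= 3 and a non-constant
    reference.
    """
    yp = np.asarray(predicted, dtype=float)
    xr = np.asarray(reference, dtype=float)
    if yp.shape != xr.shape or yp.ndim != 1:
        raise ValueError("predicted and reference must be 1-d vectors of equal length")
    n = len(yp)
    if n < 3:
        raise ValueError("need n >= 3 points")
    sxx = float(np.sum((xr - xr.mean()) ** 2))
    if sxx == 0:
        raise ValueError("reference values are constant")
    sxy = float(np.sum((xr - xr.mean()) * (yp - yp.mean())))
    slope = sxy / sxx
    intercept = float(yp.mean() - slope * xr.mean())
    fitted = intercept + slope * xr
    sse = float(np.sum((yp - fitted) ** 2))
    s2 = sse / (n - 2)
    se_slope = float(np.sqrt(s2 / sxx))
    se_intercept = float(np.sqrt(s2 * (1.0 / n + xr.mean() ** 2 / sxx)))
    tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, n - 2))
    ci_slope = (slope - tcrit * se_slope, slope + tcrit * se_slope)
    ci_intercept = (intercept - tcrit * se_intercept, intercept + tcrit * se_intercept)
    return ValidationReport(
        n=n,
        slope=float(slope),
        intercept=intercept,
        se_slope=se_slope,
        se_intercept=se_intercept,
        ci_slope=ci_slope,
        ci_intercept=ci_intercept,
        slope_ok=ci_slope[0] <= 1.0 <= ci_slope[1],
        intercept_ok=ci_intercept[0] <= 0.0 <= ci_intercept[1],
        alpha=alpha,
        target=target,
        region=region,
    )


def validate_models(
    models: Iterable[RegressionModel],
    table: FeatureTable,
    volatiles: Sequence[VolatileProfile],
    alpha: float = 0.05,
) -> list[ValidationReport]:
    """One slope/intercept report per quantitation model, on LOO predictions.

    For each model the region's samples are pulled from ``table``, the LOO
    predictions recomputed for the model's selected subset, and regressed on
    the reference contents from ``volatiles``.  Sample ids must align.
    """
    by_id = {p.sample_id: p for p in volatiles}
    missing = [sid for sid in table.sample_ids if sid not in by_id]
    if missing:
        raise ValueError(f"sample id(s) missing from reference profiles: {missing}")
    reports = []
    for model in models:
        if model.region is not None:
            mask = table.labels == model.region
            sub = FeatureTable(
                features=table.features.loc[mask], labels=table.labels.loc[mask]
            )
        else:
            sub = table
        reference = np.array(
            [
                by_id[sid].total if model.target == "total"
                else by_id[sid].contents[model.target]
                for sid in sub.sample_ids
            ]
        )
        _, _, loo_pred = loocv_regression(sub, reference, model.selected_features)
        reports.append(
            validate_against_reference(
                loo_pred, reference, alpha=alpha,
                target=model.target, region=model.region,
            )
        )
    return reports
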