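"""Two-group univariate comparisons: F-test gated Student/Welch t-tests.

The battery applied to every per-sample variable is the classical one from
food-authentication tables: first an F-test on the two sample variances at
the 5% level; if the variances can be assumed equal, a pooled-variance
Student t-test, otherwise Welch's t-test with Satterthwaite degrees of
freedom.  Two-sided p-values throughout; no multiple-testing correction.

Display convention: when a comparison is significant at 5% the group with
the larger mean is lettered "a" and the other "b"; otherwise both get "a".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TwoGroupResult",
    "f_test_variances",
    "two_group_test",
    "two_group_test_from_summary",
    "compare_table",
]

ALPHA_VARIANCE = 0.05


@dataclass
class TwoGroupResult:
    """Outcome of one variable's two-group comparison."""

    variable: str
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    F_stat: float
    F_pvalue: float
    variance_equal: bool
    t_stat: float
    df: float
    p_value: float
    test_used: str  # "student" | "welch"
    letters: tuple[str, str] | None = None
    error: str | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _summary(x: np.ndarray) -> tuple[float, float, int]:
    return float(np.mean(x)), float(np.std(x, ddof=1)), int(len(x))


def f_test_variances(
    x: np.ndarray | None = None,
    y: np.ndarray | None = None,
    *,
    summaries: tuple[float, int, float, int] | None = None,
) -> tuple[float, float, bool]:
    """F-test for equality of two sample variances.

    F puts the larger sample variance in the numerator; the two-sided
    p-value is ``2 * min(P(F <= f), P(F >= f))`` (capped at 1).  Returns
    ``(F, p, variance_equal)`` with ``variance_equal = (p >= 0.05)``.

    Either raw vectors or ``summaries = (sd1, n1, sd2, n2)`` may be given.
    """
    if summaries is not None:
        sd1, n1, sd2, n2 = summaries
    else:
        x, y = np.asarray(x, float), np.asarray(y, float)
        if len(x) < 2 or len(y) < 2:
            raise ValueError("each group needs >= 2 observations")
        _, sd1, n1 = _summary(x)
        _, sd2, n2 = _summary(y)
    if sd1 == 0 or sd2 == 0:
        which = "first" if sd1 == 0 else "second"
        raise ValueError(f"zero variance in the {which} group")
    v1, v2 = sd1**2, sd2**2
    if v1 >= v2:
        f, dfn, dfd = v1 / v2, n1 - 1, n2 - 1
    else:
        f, dfn, dfd = v2 / v1, n2 - 1, n1 - 1
    p = min(1.0, 2.0 * float(stats.f.sf(f, dfn, dfd)))
    return float(f), p, p >= ALPHA_VARIANCE


def _welch_df(v1: float, n1: int, v2: float, n2: int) -> float:
    a, b = v1 / n1, v2 / n2
    return (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))


def two_group_test_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variable: str = "",
) -> TwoGroupResult:
    """Full F-gated t-test battery driven by sufficient statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("summary SDs must be positive")
    F, Fp, equal = f_test_variances(summaries=(sd1, n1, sd2, n2))
    if equal:
        t, p = stats.ttest_ind_from_stats(
            mean1, sd1, n1, mean2, sd2, n2, equal_var=True
        )
        df = float(n1 + n2 - 2)
        used = "student"
    else:
        t, p = stats.ttest_ind_from_stats(
            mean1, sd1, n1, mean2, sd2, n2, equal_var=False
        )
        df = _welch_df(sd1**2, n1, sd2**2, n2)
        used = "welch"
    result = TwoGroupResult(
        variable=variable,
        mean1=mean1, sd1=sd1, n1=n1,
        mean2=mean2, sd2=sd2, n2=n2,
        F_stat=F, F_pvalue=Fp, variance_equal=equal,
        t_stat=float(t), df=df, p_value=float(p), test_used=used,
    )
    result.letters = _assign_letters(result)
    return result


def two_group_test(
    x: np.ndarray, y: np.ndarray, variable: str = ""
) -> TwoGroupResult:
    """F-gated Student/Welch t-test on two raw sample vectors."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    m1, s1, n1 = _summary(x)
    m2, s2, n2 = _summary(y)
    if s1 == 0 or s2 == 0:
        which = "first" if s1 == 0 else "second"
        raise ValueError(f"zero variance in the {which} group")
    return two_group_test_from_summary(m1, s1, n1, m2, s2, n2, variable=variable)


def _assign_letters(result: TwoGroupResult) -> tuple[str, str]:
    if result.p_value < 0.05:
        return ("a", "b") if result.mean1 >= result.mean2 else ("b", "a")
    return ("a", "a")


def compare_table(
    table: pd.DataFrame, labels: pd.Series
) -> list[TwoGroupResult]:
    """Apply the two-group battery to every column of a variable table.

    ``labels`` must take exactly two values.  A variable that cannot be
    tested (e.g. zero variance within a group) yields a result whose
    ``error`` field carries the message; other variables are unaffected.
    """
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(
            f"two groups required; labels contain {len(groups)} distinct value(s)"
        )
    g1, g2 = groups
    results: list[TwoGroupResult] = []
    for col in table.columns:
        x = table.loc[labels == g1, col].to_numpy(float)
        y = table.loc[labels == g2, col].to_numpy(float)
        try:
            results.append(two_group_test(x, y, variable=str(col)))
        except ValueError as exc:
            results.append(
                TwoGroupResult(
                    variable=str(col),
                    mean1=float(np.mean(x)), sd1=float(np.std(x, ddof=1)), n1=len(x),
                    mean2=float(np.mean(y)), sd2=float(np.std(y, ddof=1)), n2=len(y),
                    F_stat=np.nan, F_pvalue=np.nan, variance_equal=False,
                    t_stat=np.nan, df=np.nan, p_value=np.nan,
                    test_used="none", error=str(exc),
                )
            )
    return results


def results_frame(results: list[TwoGroupResult]) -> pd.DataFrame:
    """Tabular summary of ``compare_table`` output."""
    rows = []
    for r in results:
        rows.append(
            {
                "variable": r.variable,
                "mean1": r.mean1, "sd1": r.sd1, "n1": r.n1,
                "mean2": r.mean2, "sd2": r.sd2, "n2": r.n2,
                "F": r.F_stat, "F_p": r.F_pvalue,
                "test": r.test_used, "t": r.t_stat, "df": r.df, "p": r.p_value,
                "letter1": r.letters[0] if r.letters else "",
                "letter2": r.letters[1] if r.letters else "",
                "error": r.error or "",
            }
        )
    return pd.DataFrame(rows)
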