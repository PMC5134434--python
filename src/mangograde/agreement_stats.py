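"""Method-agreement statistics: paired t-test, Bland–Altman limits, R².

These are the tools used to validate an indirect measurement method (image
sizing, disk-method volume) against a reference method (caliper, water
displacement): the paired t-test asks whether the mean difference is zero,
the Bland–Altman limits d̄ ± 1.96·s bracket where ~95% of individual
differences fall, and R² summarises how tightly one method tracks the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AgreementSummary", "paired_t", "bland_altman", "r_squared"]


@dataclass(frozen=True)
class AgreementSummary:
    """Bland–Altman summary of paired differences x − y."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    t_statistic: float
    df: int
    p_value: float
    ci95: tuple[float, float]


def paired_t(x, y) -> tuple[float, int, float, tuple[float, float]]:
    """Classical paired t-test; returns (t, df, two-sided p, 95% CI of d̄)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("differences have zero variance; t is undefined")
    res = stats.ttest_rel(x, y)
    df = n - 1
    se = sd / np.sqrt(n)
    tq = stats.t.ppf(0.975, df)
    mean = float(d.mean())
    return float(res.statistic), df, float(res.pvalue), (mean - tq * se, mean + tq * se)


def bland_altman(x, y) -> AgreementSummary:
    """Bland–Altman limits of agreement for the differences x − y.

    Uses the normal quantile 1.96 for the limits (the conventional form).
    The embedded t-test fields are NaN when the differences are constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd > 0:
        t, df, p, ci = paired_t(x, y)
    else:
        t, df, p, ci = float("nan"), len(x) - 1, float("nan"), (mean, mean)
    return AgreementSummary(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        t_statistic=t,
        df=df,
        p_value=p,
        ci95=ci,
    )


def r_squared(x, y) -> float:
    """Squared Pearson correlation between two measurement series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise np.linalg.LinAlgError("constant input; correlation undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
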