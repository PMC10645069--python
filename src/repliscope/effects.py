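"""Conversion of reported key statistics to a common effect-size currency.

Every study's reported statistic (per-condition means and SDs, a t or
1-df F value, a 2x2 proportion table, or a beta with standard error) is
converted to an :class:`EffectEstimate`: a signed point estimate with a
standard error on a named scale, plus a recomputed two-sided p-value.
p-values are always recomputed from the statistics rather than taken from
text.

Standardized mean differences use Cohen's d without the Hedges small-sample
correction; within-participants statistics use change-score standardization
(d_z), which is computable from t and n alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .dataset import StatisticsReport
from .errors import DomainError, UnsupportedStatisticError

SCALE_SMD = "smd"
SCALE_LOG_ODDS = "log_odds"
SCALE_NATIVE = "native"


@dataclass(frozen=True)
class EffectEstimate:
    """Point estimate + standard error on a named scale.

    The sign convention is that a positive estimate points in the same
    direction as the original study's reported effect.
    """

    estimate: float
    se: float
    scale: str
    p_value: float
    n_total: int
    source: str

    def __post_init__(self):
        if self.se <= 0:
            raise DomainError(f"se must be > 0 (got {self.se})")
        if not (0.0 < self.p_value <= 1.0):
            raise DomainError(f"p_value must be in (0, 1] (got {self.p_value})")


def _smd_se(d: float, n1: int, n2: int) -> float:
    n = n1 + n2
    return math.sqrt((n1 + n2) / (n1 * n2) + d * d / (2 * n))


_P_FLOOR = 1e-300  # keep p in (0, 1] even when the tail underflows


def _two_sided_t_p(t: float, df: float) -> float:
    return min(1.0, max(_P_FLOOR, float(2.0 * stats.t.sf(abs(t), df))))


def _two_sided_z_p(z: float) -> float:
    return min(1.0, max(_P_FLOOR, float(2.0 * stats.norm.sf(abs(z)))))


def smd_from_means(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> EffectEstimate:
    """Cohen's d from per-condition means and SDs of a between design.

    d = (m1 - m2) / s_pooled with the (n-1)-weighted pooled SD; the p-value
    comes from the two-sided t test on n1 + n2 - 2 degrees of freedom.
    """
    if s1 <= 0 or s2 <= 0:
        raise DomainError("per-condition SDs must be > 0")
    if n1 < 2 or n2 < 2:
        raise DomainError("per-condition n must be >= 2")
    s_pooled = math.sqrt(((n1 - 1) * s1 * s1 + (n2 - 1) * s2 * s2) / (n1 + n2 - 2))
    if s_pooled == 0:
        raise DomainError("pooled SD is zero")
    d = (m1 - m2) / s_pooled
    t = d / math.sqrt(1.0 / n1 + 1.0 / n2)
    return EffectEstimate(
        estimate=d,
        se=_smd_se(d, n1, n2),
        scale=SCALE_SMD,
        p_value=_two_sided_t_p(t, n1 + n2 - 2),
        n_total=n1 + n2,
        source="means_between",
    )


def smd_from_t_between(t: float, n1: int, n2: int) -> EffectEstimate:
    """Cohen's d from a between-participants t statistic."""
    if n1 < 2 or n2 < 2:
        raise DomainError("per-group n must be >= 2")
    d = t * math.sqrt(1.0 / n1 + 1.0 / n2)
    return EffectEstimate(
        estimate=d,
        se=_smd_se(d, n1, n2),
        scale=SCALE_SMD,
        p_value=_two_sided_t_p(t, n1 + n2 - 2),
        n_total=n1 + n2,
        source="t_between",
    )


def smd_from_t_within(t: float, n: int) -> EffectEstimate:
    """d_z (change-score standardized) from a paired t statistic."""
    if n < 2:
        raise DomainError("n must be >= 2")
    d = t / math.sqrt(n)
    se = math.sqrt(1.0 / n + d * d / (2 * n))
    return EffectEstimate(
        estimate=d,
        se=se,
        scale=SCALE_SMD,
        p_value=_two_sided_t_p(t, n - 1),
        n_total=n,
        source="t_within",
    )


def smd_from_means_within(m_diff: float, s_diff: float, n: int) -> EffectEstimate:
    """d_z from the mean and SD of paired difference scores."""
    if s_diff <= 0:
        raise DomainError("difference-score SD must be > 0")
    if n < 2:
        raise DomainError("n must be >= 2")
    t = m_diff / s_diff * math.sqrt(n)
    est = smd_from_t_within(t, n)
    return EffectEstimate(
        estimate=est.estimate,
        se=est.se,
        scale=SCALE_SMD,
        p_value=est.p_value,
        n_total=n,
        source="means_within",
    )


def smd_from_f(
    f_value: float,
    df2: float,
    n1: int,
    n2: int | None,
    direction_positive: bool,
    df1: float = 1.0,
) -> EffectEstimate:
    """Cohen's d from a 1-df F statistic.

    F statistics carry no direction, so the sign is supplied separately
    (from the independently coded direction flag).  Delegates to the
    between- or within-participants t conversion depending on whether a
    second group size is present.

    Raises
    ------
    UnsupportedStatisticError
        For omnibus F tests with numerator df > 1, which have no single
        standardized-difference equivalent.
    """
    if df1 != 1:
        raise UnsupportedStatisticError(
            f"F test with numerator df {df1} cannot be converted to an SMD"
        )
    if f_value < 0:
        raise DomainError("F value must be >= 0")
    t = math.sqrt(f_value)
    if not direction_positive:
        t = -t
    if n2 is not None:
        est = smd_from_t_between(t, n1, n2)
    else:
        est = smd_from_t_within(t, n1)
    return EffectEstimate(
        estimate=est.estimate,
        se=est.se,
        scale=SCALE_SMD,
        p_value=est.p_value,
        n_total=est.n_total,
        source="f_test",
    )


def estimate_from_proportions(
    success1: int, total1: int, success2: int, total2: int
) -> EffectEstimate:
    """Log odds ratio from a 2x2 table, with 0.5 continuity correction
    applied to every cell whenever any cell is zero."""
    if total1 < 1 or total2 < 1:
        raise DomainError("totals must be >= 1")
    if success1 > total1 or success2 > total2:
        raise DomainError("successes exceed totals")
    cells = [
        float(success1),
        float(total1 - success1),
        float(success2),
        float(total2 - success2),
    ]
    if all(c == 0 for c in cells[:2]) or all(c == 0 for c in cells[2:]):
        raise DomainError("a group has zero total after correction")
    if any(c == 0 for c in cells):
        cells = [c + 0.5 for c in cells]
    a, b, c, d = cells
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(
        estimate=log_or,
        se=se,
        scale=SCALE_LOG_ODDS,
        p_value=_two_sided_z_p(log_or / se),
        n_total=total1 + total2,
        source="proportions",
    )


def estimate_from_beta(beta: float, se: float, n_total: int = 0) -> EffectEstimate:
    """Pass a reported regression coefficient through on its native scale."""
    if se <= 0:
        raise DomainError("se must be > 0")
    return EffectEstimate(
        estimate=beta,
        se=se,
        scale=SCALE_NATIVE,
        p_value=_two_sided_z_p(beta / se),
        n_total=max(n_total, 1),
        source="beta_se",
    )


def derive_effect(
    report: StatisticsReport, direction_positive: bool = True
) -> EffectEstimate | None:
    """Dispatch a :class:`StatisticsReport` to the right conversion.

    Returns ``None`` when the report carries no convertible statistic
    (``test_type == "none"``); raises :class:`UnsupportedStatisticError`
    for statistics that exist but cannot be converted (multi-df F).
    ``direction_positive`` is only consulted for F tests, which carry no
    sign of their own.
    """
    tt = report.test_type
    if tt == "none":
        return None
    if tt == "means_between":
        return smd_from_means(
            report.m1, report.s1, report.n1, report.m2, report.s2, report.n2
        )
    if tt == "means_within":
        return smd_from_means_within(report.m1, report.s1, report.n1)
    if tt == "t_between":
        return smd_from_t_between(report.statistic, report.n1, report.n2)
    if tt == "t_within":
        return smd_from_t_within(report.statistic, report.n1)
    if tt == "f_test":
        return smd_from_f(
            report.statistic,
            report.df2,
            report.n1,
            report.n2,
            direction_positive,
            df1=report.df1 if report.df1 is not None else 1.0,
        )
    if tt == "proportions":
        return estimate_from_proportions(
            report.success1, report.total1, report.success2, report.total2
        )
    if tt == "beta_se":
        return estimate_from_beta(report.beta, report.se)
    raise DomainError(f"unknown test_type {tt!r}")
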