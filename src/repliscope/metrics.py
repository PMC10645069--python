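"""Per-pair replication outcomes: prediction interval, p-original, and the
heterogeneity-adjusted consistency classification.

``p_orig`` tests the null that the original and replication point estimates
are draws from one underlying effect; the 95% prediction interval is the
equivalent interval-membership view of the same z statistic, so with
``tau = 0`` and ``level = 0.95`` the two are exactly dual
(``in_interval  <=>  p_orig >= 0.05``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .dataset import StudyPair
from .design import original_effect, replication_effect
from .effects import SCALE_SMD, EffectEstimate
from .errors import DomainError, ScaleMismatchError

#: between-implementation heterogeneity assumed for the consistency
#: classification, in SMD units (average multi-site heterogeneity estimate)
DEFAULT_TAU = 0.21


@dataclass
class ReplicationMetrics:
    """Statistical replication outcomes for one pair."""

    pair_id: str
    ordinal_score: int
    available: bool
    scale: str | None = None
    pi_lower: float | None = None
    pi_upper: float | None = None
    in_interval: bool | None = None
    p_orig: float | None = None
    tau: float | None = None
    consistent_at_tau: bool | None = None


def score_to_ordinal(score: float) -> int:
    """Remap the subjective score grid {0, .25, .5, .75, 1} to levels 1-5."""
    grid = {0.0: 1, 0.25: 2, 0.5: 3, 0.75: 4, 1.0: 5}
    for value, level in grid.items():
        if math.isclose(score, value):
            return level
    raise DomainError(
        f"subjective score {score} not on the five-level grid {sorted(grid)}"
    )


def prediction_interval(
    original: EffectEstimate, replication_se: float, level: float = 0.95
) -> tuple[float, float]:
    """Normal-theory prediction interval for the replication estimate.

    The half-width combines both studies' sampling error:
    ``z * sqrt(se_o^2 + se_r^2)``.
    """
    if not (0.0 < level < 1.0):
        raise DomainError(f"level must be in (0, 1) (got {level})")
    if replication_se < 0:
        raise DomainError("replication_se must be >= 0")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(original.se**2 + replication_se**2)
    return original.estimate - half, original.estimate + half


def p_orig(
    original: EffectEstimate, replication: EffectEstimate, tau: float = 0.0
) -> float:
    """Two-sided p-value that both estimates share one underlying effect,
    allowing heterogeneity ``tau`` between implementations."""
    if original.scale != replication.scale:
        raise ScaleMismatchError(
            f"original on {original.scale!r}, replication on {replication.scale!r}"
        )
    if tau < 0:
        raise DomainError("tau must be >= 0")
    if tau > 0 and original.scale != SCALE_SMD:
        raise ScaleMismatchError("nonzero tau is defined in SMD units only")
    denom = math.sqrt(tau**2 + original.se**2 + replication.se**2)
    z = abs(replication.estimate - original.estimate) / denom
    return min(1.0, max(1e-300, float(2.0 * stats.norm.sf(z))))


def consistency_at_tau(
    original: EffectEstimate,
    replication: EffectEstimate,
    tau: float = DEFAULT_TAU,
    alpha: float = 0.05,
) -> bool:
    """Distributional consistency: ``p_orig(tau) >= alpha``."""
    return p_orig(original, replication, tau) >= alpha


def compute_pair_metrics(
    pair: StudyPair, tau: float = DEFAULT_TAU, level: float = 0.95
) -> ReplicationMetrics:
    """All statistical outcomes for one pair.

    Pairs without derivable estimates on a shared scale get
    ``available=False`` (they remain usable in the subjective-score
    analyses); the tau-consistency flag is additionally restricted to
    SMD-scale pairs.
    """
    ordinal = score_to_ordinal(pair.subjective_score)
    orig = original_effect(pair)
    rep = replication_effect(pair)
    if orig is None or rep is None or orig.scale != rep.scale:
        return ReplicationMetrics(
            pair_id=pair.pair_id, ordinal_score=ordinal, available=False
        )
    lo, hi = prediction_interval(orig, rep.se, level)
    p0 = p_orig(orig, rep, 0.0)
    out = ReplicationMetrics(
        pair_id=pair.pair_id,
        ordinal_score=ordinal,
        available=True,
        scale=orig.scale,
        pi_lower=lo,
        pi_upper=hi,
        in_interval=bool(lo <= rep.estimate <= hi),
        p_orig=p0,
    )
    if orig.scale == SCALE_SMD:
        out.tau = tau
        out.consistent_at_tau = consistency_at_tau(orig, rep, tau)
    return out


def attach_metric_outcomes(matrix, metrics: Sequence[ReplicationMetrics]) -> None:
    """Attach ``in_interval`` and ``p_orig`` outcome arrays to a design
    matrix, for the logistic and linear models.

    Every row of the matrix must have computable metrics (build the matrix
    from the metric-available subset first).
    """
    by_id = {m.pair_id: m for m in metrics}
    missing = [pid for pid in matrix.pair_ids
               if pid not in by_id or not by_id[pid].available]
    if missing:
        raise DomainError(
            f"metrics unavailable for pairs {missing[:5]}"
            + (" ..." if len(missing) > 5 else "")
        )
    matrix.outcomes["in_interval"] = np.array(
        [int(by_id[pid].in_interval) for pid in matrix.pair_ids]
    )
    matrix.outcomes["p_orig"] = np.array(
        [by_id[pid].p_orig for pid in matrix.pair_ids]
    )


def cohort_summary(
    metrics: Sequence[ReplicationMetrics], tau: float = DEFAULT_TAU
) -> dict:
    """Aggregate outcomes over a cohort of pairs.

    Reports the subjective-score mean, the prediction-interval membership
    rate over the pairs where the interval is computable, the median p_orig,
    and the tau-consistency fraction over the SMD-scale subset.
    """
    available = [m for m in metrics if m.available]
    smd = [m for m in available if m.consistent_at_tau is not None]
    out = {
        "n_total": len(metrics),
        "n_with_metrics": len(available),
        "n_smd": len(smd),
        "mean_ordinal_score": float(np.mean([m.ordinal_score for m in metrics])),
        "tau": tau,
    }
    if available:
        out["n_in_interval"] = int(sum(m.in_interval for m in available))
        out["rate_in_interval"] = out["n_in_interval"] / len(available)
        out["median_p_orig"] = float(np.median([m.p_orig for m in available]))
    if smd:
        out["n_consistent_at_tau"] = int(sum(m.consistent_at_tau for m in smd))
        out["rate_consistent_at_tau"] = out["n_consistent_at_tau"] / len(smd)
    return out
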