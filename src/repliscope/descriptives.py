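"""Descriptive layer: dataset summaries, bivariate correlations with the
subjective score, predictor inter-correlations, and effect-size shift
summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import StudyPair
from .design import (
    DesignMatrix,
    original_effect,
    replication_effect,
    switched_to_online,
)
from .effects import SCALE_SMD
from .errors import DomainError


@dataclass
class CorrelationRow:
    predictor: str
    r: float | None
    p: float | None
    n_used: int


@dataclass
class CorrelationTable:
    rows: list[CorrelationRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.predictor, r.r, r.p, r.n_used) for r in self.rows],
            columns=["predictor", "r", "p", "n"],
        )


@dataclass
class ShiftSummary:
    """Median and IQR of original, replication, and per-pair shifted SMDs."""

    subset: str
    n: int
    original: tuple[float, float, float]  # (q25, median, q75)
    replication: tuple[float, float, float]
    difference: tuple[float, float, float]  # original minus replication, per pair


def _median_iqr(x: np.ndarray, method: str = "linear") -> tuple[float, float, float]:
    q25, med, q75 = np.quantile(x, [0.25, 0.5, 0.75], method=method)
    return float(q25), float(med), float(q75)


def summarize_dataset(pairs: Sequence[StudyPair], quantile_method: str = "linear") -> pd.DataFrame:
    """Counts/percentages for categorical features and median/IQR for
    continuous ones, with statistics-dependent rows computed on (and
    labelled with) the available subset."""
    if not pairs:
        raise DomainError("no pairs supplied")
    n = len(pairs)
    rows: list[tuple[str, str, int]] = []

    def cat(label: str, flag: Callable[[StudyPair], bool]):
        c = sum(bool(flag(p)) for p in pairs)
        pct = 100.0 * c / n
        rows.append((label, f"{c} ({pct:.0f}%)", n))

    def cont(label: str, values: np.ndarray, n_used: int, fmt: str = "{:.2f}"):
        q25, med, q75 = _median_iqr(values, quantile_method)
        rows.append(
            (label, f"{fmt.format(med)} ({fmt.format(q25)}, {fmt.format(q75)})", n_used)
        )

    for level in ("cognitive", "social", "other_psych", "non_psych"):
        cat(f"subfield: {level}", lambda p, lv=level: p.subfield == lv)
    cat("open data", lambda p: p.open_data)
    cat("open materials", lambda p: p.open_materials)
    cat("switch from in-person to online", switched_to_online)
    cat("original authors at Stanford", lambda p: p.stanford_affiliation)
    cat("within participants design", lambda p: p.within_participants)
    cat("single vignette", lambda p: p.single_vignette)
    cont("number of trials", np.array([p.n_trials for p in pairs]), n, "{:.0f}")
    cont("publication year", np.array([p.publication_year for p in pairs]), n, "{:.0f}")
    cont("original sample size", np.array([p.n_original for p in pairs]), n, "{:.0f}")
    cont("replication sample size", np.array([p.n_replication for p in pairs]), n, "{:.0f}")
    cont(
        "ratio of replication/original sample sizes",
        np.array([p.n_replication / p.n_original for p in pairs]),
        n,
    )
    smd, logp = [], []
    for p in pairs:
        est = original_effect(p)
        if est is not None and est.scale == SCALE_SMD:
            smd.append(est.estimate)
            logp.append(est.p_value)
    if smd:
        cont("original effect size (SMD)", np.array(smd), len(smd))
        cont("original p-value", np.array(logp), len(logp), "{:.4f}")
    return pd.DataFrame(rows, columns=["feature", "summary", "n"])


def bivariate_correlations(
    matrix: DesignMatrix, outcome: np.ndarray | None = None
) -> CorrelationTable:
    """Unadjusted Pearson r of each predictor with the subjective score
    (0-1 scale), two-sided p, sorted by descending r.  Binary predictors
    enter as their 0/1 coding (point-biserial).  Zero-variance predictors
    are reported with r = None rather than dropped."""
    y = matrix.outcomes["subjective_score"] if outcome is None else np.asarray(outcome)
    rows: list[CorrelationRow] = []
    for name in matrix.column_names:
        x = matrix.column(name)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append(CorrelationRow(name, None, None, len(x)))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append(CorrelationRow(name, float(r), float(p), len(x)))
    rows.sort(key=lambda row: -np.inf if row.r is None else row.r, reverse=True)
    return CorrelationTable(rows)


def predictor_correlation_matrix(matrix: DesignMatrix) -> pd.DataFrame:
    """Symmetric Pearson-r matrix between predictors (unit diagonal;
    NaN rows/columns for zero-variance predictors)."""
    if len(matrix.column_names) < 2:
        raise DomainError("need at least 2 predictors")
    df = pd.DataFrame(matrix.X, columns=list(matrix.column_names))
    corr = df.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def effect_size_shift(
    pairs: Sequence[StudyPair],
    subset_rule: str = "all",
    quantile_method: str = "linear",
) -> ShiftSummary:
    """Medians/IQRs of original SMD, replication SMD, and the per-pair
    original-minus-replication difference.

    ``subset_rule`` is ``"all"`` (every pair with SMD estimates on both
    sides) or ``"score_1"`` (additionally subjective_score == 1).  The
    difference is computed pair-wise first, then summarized.
    """
    orig_vals, rep_vals = [], []
    for p in pairs:
        if subset_rule == "score_1" and p.subjective_score != 1.0:
            continue
        elif subset_rule not in ("all", "score_1"):
            raise DomainError(f"unknown subset_rule {subset_rule!r}")
        o, r = original_effect(p), replication_effect(p)
        if (
            o is not None
            and r is not None
            and o.scale == SCALE_SMD
            and r.scale == SCALE_SMD
        ):
            orig_vals.append(o.estimate)
            rep_vals.append(r.estimate)
    if not orig_vals:
        raise DomainError(f"no SMD-comparable pairs in subset {subset_rule!r}")
    orig = np.array(orig_vals)
    rep = np.array(rep_vals)
    return ShiftSummary(
        subset=subset_rule,
        n=len(orig),
        original=_median_iqr(orig, quantile_method),
        replication=_median_iqr(rep, quantile_method),
        difference=_median_iqr(orig - rep, quantile_method),
    )


def outcome_intercorrelations(scores, in_interval, p_orig_values) -> dict[str, float]:
    """Pearson correlations among the three outcome measures."""
    s = np.asarray(scores, dtype=float)
    pi = np.asarray(in_interval, dtype=float)
    po = np.asarray(p_orig_values, dtype=float)
    return {
        "score_vs_pi": float(stats.pearsonr(s, pi)[0]),
        "score_vs_p_orig": float(stats.pearsonr(s, po)[0]),
        "pi_vs_p_orig": float(stats.pearsonr(pi, po)[0]),
    }
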