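"""Predictor transformations and the model design matrix.

Builds the numeric predictor matrix used by the correlation tables and the
Bayesian models: subfield dummies (cognitive psychology as the reference
level), 0/1 flags for the binary design properties, natural-log transforms
for counts, and — when requested — the original study's standardized effect
size and log p-value.  Continuous columns are z-scored after the other
transforms; dummy columns stay 0/1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import effects
from .dataset import StudyPair
from .errors import DomainError

#: predictor columns in presentation order
BASE_COLUMNS = (
    "subfield_social",
    "subfield_other_psych",
    "subfield_non_psych",
    "open_data",
    "open_materials",
    "switched_to_online",
    "stanford_affiliation",
    "within_participants",
    "single_vignette",
    "log_n_trials",
    "publication_year",
    "log_n_original",
    "log_n_ratio",
)
STATISTIC_COLUMNS = ("original_smd", "log_original_p")
CONTINUOUS_COLUMNS = frozenset(
    {
        "log_n_trials",
        "publication_year",
        "log_n_original",
        "log_n_ratio",
        "original_smd",
        "log_original_p",
    }
)


@dataclass
class DesignMatrix:
    """Numeric predictors for a set of pairs, plus attached outcomes."""

    X: np.ndarray  # (n_pairs, n_columns), z-scored continuous columns
    column_names: tuple[str, ...]
    scaling: dict[str, tuple[float, float]]  # column -> (mean, sd) used
    pair_ids: tuple[str, ...]
    group: np.ndarray  # class_year per row (random-slope grouping)
    outcomes: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.column_names.index(name)]

    def raw_column(self, name: str) -> np.ndarray:
        """Column on its pre-z-scoring scale."""
        x = self.column(name)
        if name in self.scaling:
            mean, sd = self.scaling[name]
            return x * sd + mean
        return x


def switched_to_online(pair: StudyPair) -> bool:
    """True only for in-person originals replicated online; originally-online
    studies and the few in-person replications count as 'no change'."""
    return (not pair.original_online) and pair.replication_online


def original_effect(pair: StudyPair) -> effects.EffectEstimate | None:
    """The original study's effect estimate, or None if not derivable."""
    try:
        return effects.derive_effect(pair.original_stats, direction_positive=True)
    except effects.UnsupportedStatisticError:
        return None


def replication_effect(pair: StudyPair) -> effects.EffectEstimate | None:
    """The replication's effect estimate, sign-aligned to the original."""
    try:
        return effects.derive_effect(
            pair.replication_stats, direction_positive=pair.same_direction
        )
    except effects.UnsupportedStatisticError:
        return None


def _raw_row(pair: StudyPair) -> list[float]:
    return [
        1.0 if pair.subfield == "social" else 0.0,
        1.0 if pair.subfield == "other_psych" else 0.0,
        1.0 if pair.subfield == "non_psych" else 0.0,
        float(pair.open_data),
        float(pair.open_materials),
        float(switched_to_online(pair)),
        float(pair.stanford_affiliation),
        float(pair.within_participants),
        float(pair.single_vignette),
        math.log(pair.n_trials),
        float(pair.publication_year),
        math.log(pair.n_original),
        math.log(pair.n_replication / pair.n_original),
    ]


def transform_predictors(
    pairs: Sequence[StudyPair], include_statistics: bool = False
) -> DesignMatrix:
    """Build the design matrix from validated pairs.

    With ``include_statistics=True`` the original study's SMD and log
    p-value are appended as predictors; pairs for which those are not
    derivable make the call fail with the offending pair ids.
    """
    if not pairs:
        raise DomainError("no pairs supplied")
    columns = BASE_COLUMNS + (STATISTIC_COLUMNS if include_statistics else ())
    rows = []
    if include_statistics:
        missing = []
        for pair in pairs:
            est = original_effect(pair)
            if est is None or est.scale != effects.SCALE_SMD:
                missing.append(pair.pair_id)
        if missing:
            raise DomainError(
                "include_statistics requires an SMD-scale original effect; "
                f"missing for pairs: {missing}"
            )
    for pair in pairs:
        row = _raw_row(pair)
        if include_statistics:
            est = original_effect(pair)
            row.extend([est.estimate, math.log(est.p_value)])
        rows.append(row)
    X = np.asarray(rows, dtype=float)

    scaling: dict[str, tuple[float, float]] = {}
    for j, name in enumerate(columns):
        if name in CONTINUOUS_COLUMNS:
            mean = float(np.mean(X[:, j]))
            sd = float(np.std(X[:, j], ddof=1)) if X.shape[0] > 1 else 0.0
            if sd == 0.0:
                sd = 1.0  # constant column: centre only
            X[:, j] = (X[:, j] - mean) / sd
            scaling[name] = (mean, sd)

    from .metrics import score_to_ordinal  # local import avoids a cycle

    outcomes = {
        "subjective_score": np.array([p.subjective_score for p in pairs]),
        "ordinal_score": np.array([score_to_ordinal(p.subjective_score) for p in pairs]),
    }
    return DesignMatrix(
        X=X,
        column_names=tuple(columns),
        scaling=scaling,
        pair_ids=tuple(p.pair_id for p in pairs),
        group=np.array([p.class_year for p in pairs]),
        outcomes=outcomes,
    )
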