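"""Model configuration, fitting front-ends, and posterior summaries.

Three regularized regressions share one prior structure (horseshoe fixed
effects, cohort-nested random intercept + slopes with LKJ-correlated
covariance): a cumulative-logit model of the 1-5 ordinal score, a logistic
model of prediction-interval membership, and a linear model of p-original.
Summaries report odds ratios for the logit links and raw slopes for the
linear model, with split-R-hat / bulk-ESS diagnostics from ``arviz``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd

from ..design import DesignMatrix
from ..errors import ConvergenceError, DomainError
from .hmc import run_chain
from .posterior import HorseshoePosterior

OUTCOMES = ("ordinal_score", "in_interval", "p_orig")
_LINKS = {"ordinal_score": "ordinal", "in_interval": "bernoulli", "p_orig": "gaussian"}


@dataclass(frozen=True)
class ModelConfig:
    outcome: str = "ordinal_score"
    predictors: tuple[str, ...] | None = None  # None = all matrix columns
    horseshoe_df: float = 3.0
    global_scale: float = 1.0
    slab_width: float | None = None  # set to use the regularized horseshoe
    random_slope_sd_prior: float = 0.5
    lkj_shape: float = 1.0
    random_effects: str = "intercept_slopes"  # or "intercept", "none"
    chains: int = 2
    draws: int = 750
    warmup: int = 750
    seed: int = 0
    target_accept: float = 0.8
    max_leapfrog: int = 48
    rhat_max: float = 1.01
    ess_min: float = 400.0
    retries: int = 1
    prior_only: bool = False

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise DomainError(f"outcome must be one of {OUTCOMES}")


@dataclass
class PosteriorSummary:
    """Tidy per-predictor posterior summary plus diagnostics."""

    outcome: str
    link: str
    table: pd.DataFrame  # predictor, median, lower, upper, (or_*), rhat, ess
    divergences: int
    n_obs: int
    notes: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def coefficient(self, name: str) -> dict:
        """Posterior median and 95% CrI on the linear-predictor scale."""
        row = self.table.loc[self.table.predictor == name]
        if row.empty:
            raise KeyError(name)
        r = row.iloc[0]
        return {"median": r["median"], "lower": r["lower"], "upper": r["upper"]}

    def odds_ratio(self, name: str) -> dict:
        if self.link == "identity":
            raise DomainError("linear model reports raw slopes, not odds ratios")
        row = self.table.loc[self.table.predictor == name].iloc[0]
        return {
            "median": row["or_median"],
            "lower": row["or_lower"],
            "upper": row["or_upper"],
        }


def _summaries(draws_3d: np.ndarray, names: list[str], link: str) -> pd.DataFrame:
    """draws_3d: (chains, draws, p) on the coefficient scale."""
    flat = draws_3d.reshape(-1, draws_3d.shape[-1])
    med = np.median(flat, axis=0)
    lo, hi = np.quantile(flat, [0.025, 0.975], axis=0)
    data = {"predictor": names, "median": med, "lower": lo, "upper": hi}
    if link == "logit":
        data["or_median"] = np.exp(med)
        data["or_lower"] = np.exp(lo)
        data["or_upper"] = np.exp(hi)
    ds = az.convert_to_dataset(draws_3d, group="posterior")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(ds)["x"].values
        ess = az.ess(ds)["x"].values
    data["rhat"] = rhat
    data["ess"] = ess
    return pd.DataFrame(data)


def _fit(matrix: DesignMatrix, config: ModelConfig, y: np.ndarray) -> PosteriorSummary:
    names = list(config.predictors) if config.predictors else list(matrix.column_names)
    cols = [matrix.column_names.index(n) for n in names]
    X = matrix.X[:, cols]
    likelihood = _LINKS[config.outcome]
    group_codes = pd.factorize(matrix.group)[0]

    if likelihood == "ordinal":
        y = np.asarray(y, dtype=int)
        if y.min() < 1 or y.max() > 5:
            raise DomainError("ordinal outcome levels must lie in 1..5")
    elif likelihood == "bernoulli":
        y = np.asarray(y, dtype=int)
        if not set(np.unique(y)) <= {0, 1}:
            raise DomainError("logistic outcome must be 0/1")
    else:
        y = np.asarray(y, dtype=float)

    warmup, draws = config.warmup, config.draws
    last_diag = ""
    for attempt in range(config.retries + 1):
        post = HorseshoePosterior(
            X=X,
            y=y,
            group_idx=group_codes,
            likelihood=likelihood,
            horseshoe_df=config.horseshoe_df,
            global_scale=config.global_scale,
            slab_width=config.slab_width,
            random_slope_sd=config.random_slope_sd_prior,
            random_effects=config.random_effects,
            lkj_eta=config.lkj_shape,
            prior_only=config.prior_only,
        )
        chains = []
        for c in range(config.chains):
            rng = np.random.default_rng(
                [config.seed, attempt, c]
            )
            chains.append(
                run_chain(
                    post,
                    rng,
                    warmup=warmup,
                    draws=draws,
                    target_accept=config.target_accept,
                    max_leapfrog=config.max_leapfrog,
                )
            )
        # map unconstrained draws to coefficient draws
        beta_draws = np.stack(
            [
                np.stack([post.beta(row) for row in ch.draws])
                for ch in chains
            ]
        )  # (chains, draws, p)
        table = _summaries(
            beta_draws, names, "logit" if likelihood != "gaussian" else "identity"
        )
        divergences = sum(ch.divergences for ch in chains)
        bad_rhat = table["rhat"].max() > config.rhat_max
        bad_ess = table["ess"].min() < config.ess_min
        last_diag = (
            f"max R-hat {table['rhat'].max():.4f} (limit {config.rhat_max}), "
            f"min ESS {table['ess'].min():.0f} (floor {config.ess_min}), "
            f"{divergences} divergences"
        )
        if not (bad_rhat or bad_ess):
            break
        warmup, draws = warmup * 2, draws * 2
    else:
        raise ConvergenceError(
            f"{config.outcome} model failed convergence policy after "
            f"{config.retries + 1} attempts: {last_diag}"
        )

    link = "logit" if likelihood != "gaussian" else "identity"
    summary = PosteriorSummary(
        outcome=config.outcome,
        link=link,
        table=table,
        divergences=divergences,
        n_obs=matrix.n,
    )
    summary.extras["accept_rate"] = float(np.mean([c.accept_rate for c in chains]))
    summary.extras["sigma_u_median"] = (
        np.median(
            np.exp(
                np.concatenate([c.draws[:, post.layout.log_sigma_u] for c in chains])
            ),
            axis=0,
        ).tolist()
        if post.q
        else []
    )
    if likelihood == "gaussian" and matrix.n:
        # flag (never clamp) fitted values outside the (0,1) outcome scale
        theta_med = np.median(
            np.concatenate([c.draws for c in chains], axis=0), axis=0
        )
        post.set_cpc(np.median(np.concatenate([c.cpc_draws for c in chains]), axis=0)
                     if post.n_cpc else np.zeros(0))
        fitted = theta_med[post.layout.extra][0] + post.linear_predictor(theta_med)
        n_out = int(np.sum((fitted < 0) | (fitted > 1)))
        summary.extras["n_fitted_outside_unit_interval"] = n_out
        if n_out:
            summary.notes.append(
                f"{n_out}/{matrix.n} fitted values fall outside (0,1); the "
                "Gaussian likelihood on raw p_orig is a documented misfit"
            )
    return summary


def fit_ordinal(matrix: DesignMatrix, config: ModelConfig, y: np.ndarray | None = None) -> PosteriorSummary:
    """Cumulative-logit model of the remapped 1-5 subjective score."""
    cfg = replace(config, outcome="ordinal_score")
    return _fit(matrix, cfg, matrix.outcomes["ordinal_score"] if y is None else y)


def fit_logistic(matrix: DesignMatrix, config: ModelConfig, y: np.ndarray | None = None) -> PosteriorSummary:
    """Logistic model of prediction-interval membership."""
    cfg = replace(config, outcome="in_interval")
    return _fit(matrix, cfg, matrix.outcomes["in_interval"] if y is None else y)


def fit_linear(matrix: DesignMatrix, config: ModelConfig, y: np.ndarray | None = None) -> PosteriorSummary:
    """Gaussian model of the raw p_orig values (identity link)."""
    cfg = replace(config, outcome="p_orig")
    return _fit(matrix, cfg, matrix.outcomes["p_orig"] if y is None else y)
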