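"""Synthetic original/replication pair generator with full ground truth.

Emits datasets with the statistical structure the downstream analysis
assumes: design-cell-dependent true effects, publication selection of the
originals (only significant originals enter, producing winner's-curse
inflation), between-implementation heterogeneity tau, sampling error scaled
by the study sizes, and a subjective score drawn from an ordered-logit model
over the design features plus the observed replication evidence.

Every emitted dataset passes :func:`repliscope.dataset.validate_record`
with zero issues, and identical (config, seed) inputs reproduce the dataset
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import StudyPair, StatisticsReport
from .errors import DomainError


@dataclass(frozen=True)
class GeneratorConfig:
    n_pairs: int = 176
    # predictor mix (defaults mirror the coded dataset's marginals)
    p_within: float = 0.45
    subfield_probs: tuple[float, float, float, float] = (0.35, 0.40, 0.14, 0.11)
    single_vignette_rate: float = 0.44
    open_data_rate: float = 0.30
    open_materials_rate: float = 0.47
    original_in_person_rate: float = 0.53
    replication_online_rate: float = 0.97
    stanford_rate: float = 0.091
    sensitivity_include_rate: float = 0.75
    closeness_probs: tuple[float, float, float, float] = (0.19, 0.29, 0.44, 0.08)
    # sample sizes
    median_n_original: float = 100.0
    sd_log_n_original: float = 0.75
    median_n_ratio: float = 0.86
    sd_log_n_ratio: float = 0.55
    median_n_trials: float = 6.0
    sd_log_n_trials: float = 1.6
    # true-effect model: location can differ by design cell
    effect_location: float = 0.35
    effect_scale: float = 0.25
    effect_within_shift: float = 0.25
    effect_social_shift: float = -0.1
    # heterogeneity between implementations (SMD units)
    tau: float = 0.0
    # publication selection on the original's two-sided p
    selection_p_threshold: float | None = 0.05
    max_tries: int = 5000
    # reporting style of the emitted key statistic
    report_means_rate: float = 0.4
    report_f_rate: float = 0.15
    # subjective-score model: ordered logit over design features + evidence
    score_coefficients: dict = field(
        default_factory=lambda: {
            "within_participants": 0.8,
            "single_vignette": -0.6,
            "subfield_social": -0.7,
            "open_data": 0.4,
        }
    )
    score_evidence_coefficient: float = 1.5
    # "consistency": coder weighs PI-style agreement with the original plus
    # the replication's own significance; "significance": significance in the
    # original's direction only; "d": the raw replication effect size
    score_evidence_form: str = "consistency"
    score_cutpoints: tuple[float, float, float, float] = (-1.5, -0.5, 0.5, 1.5)

    def __post_init__(self):
        if self.n_pairs < 1:
            raise DomainError("n_pairs must be >= 1")
        for name in (
            "p_within",
            "single_vignette_rate",
            "open_data_rate",
            "open_materials_rate",
            "original_in_person_rate",
            "replication_online_rate",
            "stanford_rate",
            "sensitivity_include_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name} must be a probability (got {v})")


@dataclass
class SyntheticTruth:
    """Ground truth behind an emitted dataset."""

    table: pd.DataFrame  # pair_id, theta_original, theta_replication, tries
    score_coefficients: dict
    score_evidence_coefficient: float
    tau: float
    seed: int


def _observed_two_group(rng, theta: float, n1: int, n2: int):
    """Exact joint draw of two-group summary stats with unit SDs and a
    standardized mean separation theta."""
    m1 = rng.normal(theta, 1.0 / math.sqrt(n1))
    m2 = rng.normal(0.0, 1.0 / math.sqrt(n2))
    s1 = math.sqrt(rng.chisquare(n1 - 1) / (n1 - 1))
    s2 = math.sqrt(rng.chisquare(n2 - 1) / (n2 - 1))
    return m1, s1, m2, s2


def _observed_paired(rng, theta: float, n: int):
    """Mean/SD of paired difference scores with true d_z = theta."""
    m = rng.normal(theta, 1.0 / math.sqrt(n))
    s = math.sqrt(rng.chisquare(n - 1) / (n - 1))
    return m, s


def _two_group_t(m1, s1, n1, m2, s2, n2) -> float:
    sp = math.sqrt(((n1 - 1) * s1 * s1 + (n2 - 1) * s2 * s2) / (n1 + n2 - 2))
    return (m1 - m2) / (sp * math.sqrt(1.0 / n1 + 1.0 / n2))


def _paired_t(m, s, n) -> float:
    return m / s * math.sqrt(n)


def _t_p_value(t: float, df: int) -> float:
    from scipy import stats as st

    return float(2.0 * st.t.sf(abs(t), df))


def _make_report(rng, cfg: GeneratorConfig, within: bool, stats: dict) -> StatisticsReport:
    """Package observed summary statistics in one of the reporting styles."""
    u = rng.random()
    if within:
        m, s, n, t = stats["m"], stats["s"], stats["n"], stats["t"]
        if u < cfg.report_means_rate:
            return StatisticsReport(test_type="means_within", m1=m, s1=s, n1=n)
        if u < cfg.report_means_rate + cfg.report_f_rate:
            return StatisticsReport(
                test_type="f_test", statistic=t * t, df1=1, df2=n - 1, n1=n
            )
        return StatisticsReport(test_type="t_within", statistic=t, n1=n)
    m1, s1, n1, m2, s2, n2, t = (
        stats["m1"],
        stats["s1"],
        stats["n1"],
        stats["m2"],
        stats["s2"],
        stats["n2"],
        stats["t"],
    )
    if u < cfg.report_means_rate:
        return StatisticsReport(
            test_type="means_between", m1=m1, s1=s1, n1=n1, m2=m2, s2=s2, n2=n2
        )
    if u < cfg.report_means_rate + cfg.report_f_rate:
        return StatisticsReport(
            test_type="f_test", statistic=t * t, df1=1, df2=n1 + n2 - 2, n1=n1, n2=n2
        )
    return StatisticsReport(test_type="t_between", statistic=t, n1=n1, n2=n2)


def _simulate_study(rng, theta: float, n_total: int, within: bool) -> dict:
    """Observed summary statistics for one study arm of a pair."""
    if within:
        n = max(4, n_total)
        m, s = _observed_paired(rng, theta, n)
        t = _paired_t(m, s, n)
        return {"within": True, "m": m, "s": s, "n": n, "t": t, "d": t / math.sqrt(n),
                "p": _t_p_value(t, n - 1), "n_total": n}
    n1 = max(2, n_total // 2)
    n2 = max(2, n_total - n1)
    m1, s1, m2, s2 = _observed_two_group(rng, theta, n1, n2)
    t = _two_group_t(m1, s1, n1, m2, s2, n2)
    d = t * math.sqrt(1.0 / n1 + 1.0 / n2)
    return {"within": False, "m1": m1, "s1": s1, "n1": n1, "m2": m2, "s2": s2,
            "n2": n2, "t": t, "d": d, "p": _t_p_value(t, n1 + n2 - 2),
            "n_total": n1 + n2}


def _flip_study(stats: dict) -> dict:
    out = dict(stats)
    if stats["within"]:
        out["m"] = -stats["m"]
    else:
        out["m1"], out["m2"] = stats["m2"], stats["m1"]
    out["t"] = -stats["t"]
    out["d"] = -stats["d"]
    return out


def simulate_pairs(
    config: GeneratorConfig, seed: int
) -> tuple[list[StudyPair], SyntheticTruth]:
    """Generate a coded dataset with known ground truth.

    Originals are redrawn (bounded by ``config.max_tries``) until they pass
    the selection rule; the replication is then simulated once from the
    heterogeneity-shifted true effect.  After selection, both studies are
    re-oriented so the original's observed effect is positive, matching the
    coding convention of the real data.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    pairs: list[StudyPair] = []
    truth_rows = []
    subfield_levels = ("cognitive", "social", "other_psych", "non_psych")
    closeness_levels = ("exact", "very_close", "close", "far")

    for i in range(cfg.n_pairs):
        within = rng.random() < cfg.p_within
        subfield = subfield_levels[rng.choice(4, p=cfg.subfield_probs)]
        single_vignette = rng.random() < cfg.single_vignette_rate
        open_data = rng.random() < cfg.open_data_rate
        open_materials = rng.random() < max(cfg.open_materials_rate, float(open_data))
        original_online = rng.random() >= cfg.original_in_person_rate
        replication_online = rng.random() < cfg.replication_online_rate
        stanford = rng.random() < cfg.stanford_rate
        class_year = int(rng.integers(2011, 2023))
        publication_year = class_year - int(1 + rng.poisson(4.0))
        n_trials = max(1, int(round(float(rng.lognormal(
            math.log(cfg.median_n_trials), cfg.sd_log_n_trials)))))
        n_original = max(6, int(round(float(rng.lognormal(
            math.log(cfg.median_n_original), cfg.sd_log_n_original)))))
        ratio = float(rng.lognormal(math.log(cfg.median_n_ratio), cfg.sd_log_n_ratio))
        n_replication = max(4, int(round(n_original * ratio)))
        closeness = closeness_levels[rng.choice(4, p=cfg.closeness_probs)]
        sensitivity_include = rng.random() < cfg.sensitivity_include_rate

        loc = (
            cfg.effect_location
            + (cfg.effect_within_shift if within else 0.0)
            + (cfg.effect_social_shift if subfield == "social" else 0.0)
        )
        theta_o = float(rng.normal(loc, cfg.effect_scale))

        tries = 0
        while True:
            tries += 1
            if tries > cfg.max_tries:
                raise DomainError(
                    f"pair {i}: selection rule not satisfied after "
                    f"{cfg.max_tries} tries (effects too small for threshold "
                    f"{cfg.selection_p_threshold})"
                )
            orig = _simulate_study(rng, theta_o, n_original, within)
            if (
                cfg.selection_p_threshold is None
                or orig["p"] < cfg.selection_p_threshold
            ):
                break

        theta_r = theta_o + float(rng.normal(0.0, cfg.tau)) if cfg.tau > 0 else theta_o
        rep = _simulate_study(rng, theta_r, n_replication, within)

        # orient so the original's observed effect is positive
        if orig["d"] < 0:
            orig, rep = _flip_study(orig), _flip_study(rep)
            theta_o, theta_r = -theta_o, -theta_r
        same_direction = rep["d"] >= 0

        # subjective score from an ordered-logit over design features + evidence
        eta = 0.0
        feats = {
            "within_participants": float(within),
            "single_vignette": float(single_vignette),
            "subfield_social": float(subfield == "social"),
            "subfield_other_psych": float(subfield == "other_psych"),
            "subfield_non_psych": float(subfield == "non_psych"),
            "open_data": float(open_data),
            "open_materials": float(open_materials),
            "switched_to_online": float((not original_online) and replication_online),
            "stanford_affiliation": float(stanford),
        }
        for name, beta in cfg.score_coefficients.items():
            eta += beta * feats.get(name, 0.0)
        significant = 1.0 if (rep["p"] < 0.05 and rep["d"] > 0) else 0.0
        if cfg.score_evidence_form == "significance":
            evidence = significant - 0.5
        elif cfg.score_evidence_form == "consistency":
            # coder weighs agreement with the original (PI membership) and
            # the replication's own significance
            def _se(study):
                if study["within"]:
                    return math.sqrt(1.0 / study["n"] + study["d"] ** 2 / (2 * study["n"]))
                n1s, n2s = study["n1"], study["n2"]
                return math.sqrt(
                    (n1s + n2s) / (n1s * n2s) + study["d"] ** 2 / (2 * (n1s + n2s))
                )

            in_pi = 1.0 if (
                abs(rep["d"] - orig["d"])
                < 1.96 * math.sqrt(_se(orig) ** 2 + _se(rep) ** 2)
            ) else 0.0
            evidence = in_pi + 0.5 * significant - 0.75
        elif cfg.score_evidence_form == "d":
            evidence = rep["d"] - 0.3
        else:
            raise DomainError(
                f"unknown score_evidence_form {cfg.score_evidence_form!r}"
            )
        eta += cfg.score_evidence_coefficient * evidence
        latent = eta + float(rng.logistic(0.0, 1.0))
        level = int(np.searchsorted(np.asarray(cfg.score_cutpoints), latent))
        score = (0.0, 0.25, 0.5, 0.75, 1.0)[level]

        pair = StudyPair(
            pair_id=f"synth-{i:04d}",
            class_year=class_year,
            subfield=subfield,
            open_data=open_data,
            open_materials=open_materials,
            original_online=original_online,
            replication_online=replication_online,
            stanford_affiliation=stanford,
            within_participants=within,
            single_vignette=single_vignette,
            n_trials=n_trials,
            publication_year=publication_year,
            n_original=orig["n_total"],
            n_replication=rep["n_total"],
            closeness=closeness,
            subjective_score=score,
            same_direction=same_direction,
            sensitivity_include=sensitivity_include,
            original_stats=_make_report(rng, cfg, within, orig),
            replication_stats=_make_report(rng, cfg, within, rep),
        )
        pairs.append(pair)
        truth_rows.append(
            {
                "pair_id": pair.pair_id,
                "theta_original": theta_o,
                "theta_replication": theta_r,
                "observed_d_original": orig["d"],
                "observed_d_replication": rep["d"],
                "tries": tries,
            }
        )

    truth = SyntheticTruth(
        table=pd.DataFrame(truth_rows),
        score_coefficients=dict(cfg.score_coefficients),
        score_evidence_coefficient=cfg.score_evidence_coefficient,
        tau=cfg.tau,
        seed=seed,
    )
    return pairs, truth


def coverage_experiment(
    n_pairs: int,
    tau: float,
    seed: int,
    metric_tau: float = 0.0,
    level: float = 0.95,
    n_per_study: int = 100,
) -> dict:
    """Calibration run: pairs share one true effect per pair (plus optional
    heterogeneity shift for the replication); report 95%-PI coverage and the
    p_orig distribution.

    With ``tau == metric_tau == 0`` the expected coverage is the nominal
    level and p_orig is uniform on (0, 1).
    """
    from .effects import smd_from_t_between
    from .metrics import p_orig as p_orig_fn, prediction_interval

    rng = np.random.default_rng(seed)
    inside = 0
    p_values = np.empty(n_pairs)
    n1 = n2 = n_per_study

    def observed(theta: float):
        m1, s1, m2, s2 = _observed_two_group(rng, theta, n1, n2)
        return smd_from_t_between(_two_group_t(m1, s1, n1, m2, s2, n2), n1, n2)

    for i in range(n_pairs):
        theta = float(rng.normal(0.5, 0.3))
        theta_r = theta + (float(rng.normal(0.0, tau)) if tau > 0 else 0.0)
        o = observed(theta)
        r = observed(theta_r)
        lo, hi = prediction_interval(o, r.se, level)
        inside += lo <= r.estimate <= hi
        p_values[i] = p_orig_fn(o, r, metric_tau)
    return {
        "n_pairs": n_pairs,
        "coverage": inside / n_pairs,
        "p_orig": p_values,
    }


def simulate_design(
    n: int,
    coefficients: np.ndarray,
    outcome: str,
    seed: int,
    n_binary: int | None = None,
    n_groups: int = 8,
    group_sd: float = 0.0,
    sigma: float = 0.2,
    cutpoints: tuple = (-1.5, -0.5, 0.5, 1.5),
):
    """Design matrix + outcome drawn from the exact model each regression
    assumes, for parameter-recovery and CrI-calibration experiments.

    Half the predictors (or ``n_binary``) are 0/1 flags, the rest standard
    normal; the outcome is an ordered-logit draw (``"ordinal_score"``), a
    Bernoulli-logit draw (``"in_interval"``) or Gaussian (``"p_orig"``,
    residual scale ``sigma``).  Optional group-level intercept noise with SD
    ``group_sd`` exercises the random-effect structure.
    Returns a :class:`repliscope.design.DesignMatrix` with the outcome
    attached.
    """
    from .design import DesignMatrix

    rng = np.random.default_rng(seed)
    coefficients = np.asarray(coefficients, dtype=float)
    p = len(coefficients)
    nb = p // 2 if n_binary is None else n_binary
    X = np.empty((n, p))
    for j in range(p):
        X[:, j] = (
            (rng.random(n) < 0.5).astype(float)
            if j < nb
            else rng.normal(size=n)
        )
    group = rng.integers(2011, 2011 + n_groups, n)
    eta = X @ coefficients
    if group_sd > 0:
        offsets = rng.normal(0.0, group_sd, n_groups)
        eta = eta + offsets[group - 2011]
    if outcome == "ordinal_score":
        latent = eta + rng.logistic(0.0, 1.0, n)
        y = np.searchsorted(np.asarray(cutpoints), latent) + 1
    elif outcome == "in_interval":
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    elif outcome == "p_orig":
        y = 0.5 + eta + rng.normal(0.0, sigma, n)
    else:
        raise DomainError(f"unknown outcome {outcome!r}")
    names = tuple(f"x{j}" for j in range(p))
    return DesignMatrix(
        X=X,
        column_names=names,
        scaling={},
        pair_ids=tuple(str(i) for i in range(n)),
        group=group,
        outcomes={outcome: y},
    )


def recovery_experiment(
    config: GeneratorConfig,
    n_datasets: int,
    seed: int,
    model_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Fit the ordinal model on replicated synthetic datasets and report
    per-coefficient sign recovery and 95%-CrI coverage of zero/non-zero
    planted values.  Datasets failing the convergence policy are reported
    with ``converged = False`` rather than skipped."""
    from . import bayes
    from .design import transform_predictors

    rows = []
    model_kwargs = model_kwargs or {}
    for k in range(n_datasets):
        pairs, truth = simulate_pairs(config, seed + k)
        matrix = transform_predictors(pairs, include_statistics=False)
        cfg = bayes.ModelConfig(outcome="ordinal_score", seed=seed + 1000 + k, **model_kwargs)
        converged = True
        try:
            summary = bayes.fit_ordinal(matrix, cfg)
        except bayes.ConvergenceError:
            converged = False
            summary = None
        for name in matrix.column_names:
            planted = truth.score_coefficients.get(name, 0.0)
            row = {"dataset": k, "predictor": name, "planted": planted,
                   "converged": converged}
            if summary is not None:
                coef = summary.coefficient(name)
                row.update(
                    median=coef["median"],
                    lower=coef["lower"],
                    upper=coef["upper"],
                    covered=bool(coef["lower"] <= planted <= coef["upper"]),
                    sign_recovered=bool(
                        planted == 0.0 or math.copysign(1, coef["median"]) == math.copysign(1, planted)
                    ),
                )
            rows.append(row)
    return pd.DataFrame(rows)
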