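"""Staged pipeline with a run manifest and digest-based caching.

Stages (``simulate → derive-effects → metrics → describe → model → report``)
are pure functions of their declared input files, the config, and the seed;
each run writes ``manifest.json`` recording the config hash and
SHA-256 digests of every stage's inputs and outputs.  A rerun with an
unchanged config reuses cached stage outputs whose input digests still
match, and a corrupted intermediate file is reported as a digest mismatch
naming the stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, bayes, descriptives, metrics as metrics_mod
from .dataset import read_coded_dataset, write_coded_dataset
from .design import original_effect, replication_effect, transform_predictors
from .errors import PipelineError
from .synth import GeneratorConfig, simulate_pairs

STAGES = ("simulate", "derive-effects", "metrics", "describe", "model", "report")

#: input/output files per stage, relative to the output directory
_STAGE_IO = {
    "simulate": ((), ("dataset.csv", "truth.csv")),
    "derive-effects": (("dataset.csv",), ("effects.csv",)),
    "metrics": (("dataset.csv",), ("metrics.csv", "cohort_summary.json")),
    "describe": (("dataset.csv",), ("table1.csv", "table2.csv", "predictor_corr.csv")),
    "model": (("dataset.csv", "metrics.csv"), ("posteriors.csv",)),
    "report": (("cohort_summary.json",), ("report.json",)),
}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: dict) -> str:
    canon = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)  # name -> {inputs, outputs, time, cached}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _load_pairs(out_dir: Path):
    result = read_coded_dataset(out_dir / "dataset.csv")
    if result.issues:
        raise PipelineError(
            f"dataset.csv contains invalid rows: {result.issues[:3]}"
        )
    return result.pairs


def _stage_simulate(out_dir: Path, config: dict, seed: int) -> None:
    gen_cfg = GeneratorConfig(**config.get("simulate", {}))
    pairs, truth = simulate_pairs(gen_cfg, seed)
    write_coded_dataset(pairs, out_dir / "dataset.csv")
    truth.table.to_csv(out_dir / "truth.csv", index=False)


def _stage_derive_effects(out_dir: Path, config: dict, seed: int) -> None:
    pairs = _load_pairs(out_dir)
    rows = []
    for pair in pairs:
        for side, est in (
            ("original", original_effect(pair)),
            ("replication", replication_effect(pair)),
        ):
            rows.append(
                {
                    "pair_id": pair.pair_id,
                    "side": side,
                    "estimate": None if est is None else est.estimate,
                    "se": None if est is None else est.se,
                    "scale": None if est is None else est.scale,
                    "p_value": None if est is None else est.p_value,
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "effects.csv", index=False)


def _stage_metrics(out_dir: Path, config: dict, seed: int) -> None:
    pairs = _load_pairs(out_dir)
    tau = config.get("tau", metrics_mod.DEFAULT_TAU)
    per_pair = [metrics_mod.compute_pair_metrics(p, tau=tau) for p in pairs]
    pd.DataFrame([dataclasses.asdict(m) for m in per_pair]).to_csv(
        out_dir / "metrics.csv", index=False
    )
    summary = metrics_mod.cohort_summary(per_pair, tau=tau)
    tau_grid = config.get("tau_grid", [0.0, tau])
    summary["consistency_by_tau"] = {}
    for t in tau_grid:
        grid_metrics = [metrics_mod.compute_pair_metrics(p, tau=t) for p in pairs]
        smd = [m for m in grid_metrics if m.consistent_at_tau is not None]
        if smd:
            summary["consistency_by_tau"][str(t)] = float(
                np.mean([m.consistent_at_tau for m in smd])
            )
    (out_dir / "cohort_summary.json").write_text(json.dumps(summary, indent=2))


def _stage_describe(out_dir: Path, config: dict, seed: int) -> None:
    pairs = _load_pairs(out_dir)
    descriptives.summarize_dataset(pairs).to_csv(out_dir / "table1.csv", index=False)
    matrix = transform_predictors(pairs, include_statistics=False)
    descriptives.bivariate_correlations(matrix).to_frame().to_csv(
        out_dir / "table2.csv", index=False
    )
    descriptives.predictor_correlation_matrix(matrix).to_csv(
        out_dir / "predictor_corr.csv"
    )


def _stage_model(out_dir: Path, config: dict, seed: int) -> None:
    pairs = _load_pairs(out_dir)
    model_cfg = dict(config.get("model", {}))
    outcomes = model_cfg.pop("outcomes", ["ordinal_score"])
    include_statistics = model_cfg.pop("include_statistics", False)
    tau = config.get("tau", metrics_mod.DEFAULT_TAU)
    tables = []
    for outcome in outcomes:
        subset = pairs
        per_pair = [metrics_mod.compute_pair_metrics(p, tau=tau) for p in pairs]
        if outcome != "ordinal_score" or include_statistics:
            available = {m.pair_id for m in per_pair if m.available}
            subset = [p for p in pairs if p.pair_id in available]
        matrix = transform_predictors(subset, include_statistics=include_statistics)
        if outcome != "ordinal_score":
            metrics_mod.attach_metric_outcomes(
                matrix, [m for m in per_pair if m.available]
            )
        cfg = bayes.ModelConfig(outcome=outcome, seed=seed, **model_cfg)
        fit = {
            "ordinal_score": bayes.fit_ordinal,
            "in_interval": bayes.fit_logistic,
            "p_orig": bayes.fit_linear,
        }[outcome]
        table = fit(matrix, cfg).table.copy()
        table.insert(0, "outcome", outcome)
        tables.append(table)
    pd.concat(tables, ignore_index=True).to_csv(out_dir / "posteriors.csv", index=False)


def _stage_report(out_dir: Path, config: dict, seed: int) -> None:
    report = {
        "version": __version__,
        "cohort_summary": json.loads((out_dir / "cohort_summary.json").read_text()),
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))


_STAGE_FN = {
    "simulate": _stage_simulate,
    "derive-effects": _stage_derive_effects,
    "metrics": _stage_metrics,
    "describe": _stage_describe,
    "model": _stage_model,
    "report": _stage_report,
}


def run_pipeline(config_path: str | Path) -> RunManifest:
    """Execute the stages requested in a YAML config, with caching.

    The config needs ``output_dir`` and may set ``stages`` (default: all
    stages whose inputs exist), ``seed``, and per-stage sections
    (``simulate``, ``model``, ``tau``, ``tau_grid``).
    """
    config_path = Path(config_path)
    config = yaml.safe_load(config_path.read_text()) or {}
    out_dir = Path(config.get("output_dir", config_path.parent / "out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", ["simulate", "derive-effects", "metrics", "describe"])
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stages {unknown}; valid: {STAGES}")

    cfg_hash = _config_hash(config)
    manifest_path = out_dir / "manifest.json"
    previous = {}
    if manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            previous = {}
    prev_stages = previous.get("stages", {}) if previous.get("config_hash") == cfg_hash else {}

    manifest = RunManifest(config_hash=cfg_hash, seed=seed, version=__version__)
    for stage in stages:
        inputs, outputs = _STAGE_IO[stage]
        for name in inputs:
            if not (out_dir / name).exists():
                raise PipelineError(
                    f"stage {stage!r}: required input {name} missing; "
                    "run its producing stage first"
                )
        in_digests = {name: _digest(out_dir / name) for name in inputs}
        cached = prev_stages.get(stage)
        if (
            cached
            and cached.get("inputs") == in_digests
            and all((out_dir / name).exists() for name in outputs)
        ):
            out_digests = {name: _digest(out_dir / name) for name in outputs}
            if out_digests != cached.get("outputs"):
                raise PipelineError(
                    f"stage {stage!r}: cached output digest mismatch "
                    f"(an intermediate file was modified); delete {out_dir} to rerun"
                )
            manifest.stages[stage] = {**cached, "cached": True}
            continue
        t0 = time.time()
        try:
            _STAGE_FN[stage](out_dir, config, seed)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest.stages[stage] = {
            "inputs": in_digests,
            "outputs": {name: _digest(out_dir / name) for name in outputs},
            "seconds": round(time.time() - t0, 3),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "cached": False,
        }
    manifest_path.write_text(manifest.to_json())
    return manifest
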