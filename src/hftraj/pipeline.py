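"""End-to-end orchestration: simulate → split → train → thresholds →
evaluate → rollout, with a YAML run configuration.

Every random operation derives its seed deterministically from the single
global seed, so a run is reproducible bit-for-bit from its config file on
the same platform with single-threaded execution.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import read_cohort, write_cohort
from .metrics import (
    compute_thresholds,
    evaluate_next_step,
    evaluate_trajectory,
    pooled_next_step_scores,
)
from .networks import ModelSpec, save_checkpoint
from .rollout import batch_rollout
from .simulate import SimConfig, simulate_cohort
from .training import LossConfig, TrainConfig, split_cohort, train

logger = logging.getLogger("hftraj")

CONFIG_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A run configuration carries unknown keys or invalid values."""


@dataclass
class EvalOptions:
    observed_years: float = 15.0
    horizon_years: float = 10.0
    start_age: float = 40.0
    threshold: str = "conservative"
    n_years: int = 10
    cumulative: bool = False


@dataclass
class RunConfig:
    """Full pipeline configuration; component seeds derive from ``seed``."""

    seed: int = 0
    out_dir: str = "hftraj_run"
    cohort_path: str | None = None  # when set, load instead of simulating
    schema_version: int = CONFIG_SCHEMA_VERSION
    sim: SimConfig = field(default_factory=SimConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    evaluation: EvalOptions = field(default_factory=EvalOptions)


_NESTED = {
    "sim": SimConfig,
    "model": ModelSpec,
    "loss": LossConfig,
    "train": TrainConfig,
    "evaluation": EvalOptions,
}


def _build(cls, data: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")
    coerced = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    return cls(**coerced)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw)
    parts = {}
    for key, cls in _NESTED.items():
        if key in raw:
            parts[key] = _build(cls, raw.pop(key) or {}, key)
    cfg = _build(RunConfig, raw, "run config")
    for key, value in parts.items():
        setattr(cfg, key, value)
    if cfg.schema_version != CONFIG_SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported schema_version {cfg.schema_version}"
        )
    # deterministic component seeds from the global seed
    cfg.sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
    cfg.train = dataclasses.replace(cfg.train, seed=cfg.seed + 1)
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


def forecasts_to_frame(forecasts) -> pd.DataFrame:
    rows = []
    for fc in forecasts:
        for j in range(fc.horizon):
            row = {
                "patient_id": fc.patient_id,
                "future_step": fc.observed_steps + j,
                "hf_prob": fc.hf_probs[j],
            }
            if fc.cm_probs is not None:
                for k, name in enumerate(("acute_mi", "endocarditis", "sepsis")):
                    row[f"cm_prob_{name}"] = fc.cm_probs[j, k]
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full chain; returns a map of artifact names to paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    artifacts = {"log": str(log_path)}
    try:
        logger.info("resolved config: %s", json.dumps(dataclasses.asdict(cfg), default=str))

        stage = "simulate"
        if cfg.cohort_path:
            cohort = read_cohort(cfg.cohort_path)
            logger.info("loaded cohort from %s: %d patients", cfg.cohort_path, len(cohort))
        else:
            cohort = simulate_cohort(cfg.sim)
            logger.info("simulated cohort: %d patients x %d steps",
                        cfg.sim.n_patients, cfg.sim.n_steps)
        cohort_path = out / "cohort.csv"
        write_cohort(cohort, cohort_path)
        artifacts["cohort"] = str(cohort_path)

        stage = "split"
        cohort = split_cohort(cohort, cfg.train.split_fractions, seed=cfg.seed + 2)

        stage = "train"
        model, history = train(cfg.model, cohort, cfg.loss, cfg.train)
        ckpt_path = out / "model.npz"
        save_checkpoint(model, ckpt_path)
        history_path = out / "training_log.csv"
        history.to_csv(history_path, index=False)
        artifacts["checkpoint"] = str(ckpt_path)
        artifacts["training_log"] = str(history_path)
        logger.info("trained %s: final total loss %.6f",
                    cfg.model.variant, history["total_loss"].iloc[-1])

        stage = "thresholds"
        tr_labels, tr_scores = pooled_next_step_scores(model, cohort, "train")
        va_labels, va_scores = pooled_next_step_scores(model, cohort, "validation")
        thresholds = compute_thresholds(tr_scores, tr_labels, va_scores, va_labels)
        logger.info("thresholds: %s", thresholds)

        stage = "evaluate_next_step"
        next_report = evaluate_next_step(model, cohort, "test")

        stage = "rollout"
        test_cohort = cohort.subset("test")
        forecasts, skipped = batch_rollout(
            model,
            test_cohort,
            observed_years=cfg.evaluation.observed_years,
            horizon_years=cfg.evaluation.horizon_years,
            start_age=cfg.evaluation.start_age,
        )
        forecasts_path = out / "forecasts.csv"
        forecasts_to_frame(forecasts).to_csv(forecasts_path, index=False)
        artifacts["forecasts"] = str(forecasts_path)
        logger.info("rollout: %d forecasts, %d skipped", len(forecasts), len(skipped))

        stage = "evaluate_trajectory"
        trajectory_report = None
        if forecasts:
            trajectory_report = evaluate_trajectory(
                forecasts,
                test_cohort,
                thresholds,
                cfg.evaluation.threshold,
                n_years=cfg.evaluation.n_years,
                cumulative=cfg.evaluation.cumulative,
            )

        stage = "report"
        report = {
            "config": dataclasses.asdict(cfg),
            "thresholds": {
                "frequency": thresholds.frequency,
                "conservative": thresholds.conservative,
                "balanced": thresholds.balanced,
                "optimized": thresholds.optimized,
                "provenance": thresholds.provenance,
            },
            "next_step": next_report.to_dict(),
            "trajectory": None if trajectory_report is None else trajectory_report.to_dict(),
            "rollout_skipped": skipped,
            "final_training_loss": float(history["total_loss"].iloc[-1]),
        }
        report_path = out / "report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
        artifacts["report"] = str(report_path)
        config_path = out / "resolved_config.yaml"
        save_config(cfg, config_path)
        artifacts["config"] = str(config_path)
        return artifacts
    except Exception as exc:
        digest = hash(json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed (config digest {digest}): {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return str(obj)
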