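"""Batch pipeline wiring the stages into reproducible, file-based runs.

Each stage reads and writes plain-text artifacts (CSV/JSON) in an output
directory, plus the resolved run configuration beside them, so that a
rerun with an identical config is byte-identical.  Model artifacts are
stored with joblib.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import yaml

from roachloop import arena_metrics, report as report_mod
from roachloop.closed_loop import ExperimentDesign, StimulationPolicy, run_experiment
from roachloop.config import SAMPLE_RATE_HZ, TRIAL_MINUTES, ArenaConfig
from roachloop.imu_features import build_feature_table
from roachloop.motion_classification import (
    cross_validate,
    default_specs,
    select_best,
    train_classifier,
)
from roachloop.synthetic_data import (
    TEST_PROFILE_NAMES,
    TRAIN_PROFILE_NAMES,
    BehaviorTrace,
    ImuSeries,
    behavior_profile,
    imu_profile_for,
    make_labeled_dataset,
    simulate_behavior,
    synthesize_imu,
)

logger = logging.getLogger("roachloop")

STAGES = ("simulate", "features", "train", "evaluate", "closed-loop",
          "metrics", "track", "report")


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run (YAML round-trippable)."""

    out_dir: str = "runs/default"
    seed: int = 42
    profile: str = "intermediate"
    duration_s: float = TRIAL_MINUTES * 60.0
    policy: str = "none"            # {none, oracle, svm}
    n_per_class: int = 500
    folds: int = 10
    classifier: str = "svm_linear"
    train_profiles: tuple = TRAIN_PROFILE_NAMES
    test_profiles: tuple = TEST_PROFILE_NAMES
    trials_per_condition: int = 3
    trial_min: float = TRIAL_MINUTES
    confirm_delay_s: float = 1.0
    decision_stride_s: float = 0.5
    burst_s: float = 0.5
    grid_resolution: int = 100
    sample_rate: float = SAMPLE_RATE_HZ

    def to_yaml(self, path: Path) -> None:
        d = dataclasses.asdict(self)
        d["train_profiles"] = list(self.train_profiles)
        d["test_profiles"] = list(self.test_profiles)
        path.write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["train_profiles"] = tuple(d.get("train_profiles", TRAIN_PROFILE_NAMES))
        d["test_profiles"] = tuple(d.get("test_profiles", TEST_PROFILE_NAMES))
        return cls(**d)


def _out(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    return out


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the '{producing_stage}' stage first")
    return path


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def stage_simulate(config: RunConfig) -> dict:
    out = _out(config)
    params = behavior_profile(config.profile)
    imu_prof = imu_profile_for(config.profile)
    policy = None
    if config.policy == "oracle":
        policy = StimulationPolicy(confirm_delay_s=config.confirm_delay_s,
                                   decision_stride_s=config.decision_stride_s,
                                   burst_s=config.burst_s)
    elif config.policy == "svm":
        model = joblib.load(_require(out / "model.joblib", "train"))
        policy = StimulationPolicy(confirm_delay_s=config.confirm_delay_s,
                                   decision_stride_s=config.decision_stride_s,
                                   burst_s=config.burst_s,
                                   recognizer=None, imu_profile=imu_prof)
        from roachloop.closed_loop import ModelRecognizer
        policy.recognizer = ModelRecognizer(model)
    elif config.policy != "none":
        raise ValueError(f"unknown policy {config.policy!r}")
    trace = simulate_behavior(ArenaConfig(), params, config.duration_s,
                              config.seed, policy=policy,
                              imu_profile=imu_prof if policy else None)
    imu = synthesize_imu(trace, imu_prof, config.seed + 1)
    trace.write_csv(out / "trace.csv")
    imu.write_csv(out / "imu.csv")
    return {"trace": str(out / "trace.csv"), "imu": str(out / "imu.csv")}


def stage_features(config: RunConfig) -> dict:
    out = _out(config)
    trace = BehaviorTrace.read_csv(_require(out / "trace.csv", "simulate"))
    imu = ImuSeries.read_csv(_require(out / "imu.csv", "simulate"))
    table = build_feature_table(imu, trace, animal_id=config.profile)
    table.to_csv(out / "features.csv", index=False)
    return {"features": str(out / "features.csv"), "rows": len(table)}


def stage_train(config: RunConfig) -> dict:
    out = _out(config)
    table = make_labeled_dataset(config.n_per_class,
                                 profiles=config.train_profiles,
                                 seed=config.seed)
    spec = default_specs()[config.classifier]
    model = train_classifier(table, spec, seed=config.seed)
    joblib.dump(model, out / "model.joblib")
    _json_dump({"classifier": config.classifier,
                "n_train": model.n_train,
                "training_animals": list(model.training_animals)},
               out / "model_meta.json")
    return {"model": str(out / "model.joblib")}


def stage_evaluate(config: RunConfig) -> dict:
    out = _out(config)
    table = make_labeled_dataset(config.n_per_class,
                                 profiles=config.train_profiles,
                                 seed=config.seed)
    reports = [cross_validate(table, spec, k_folds=config.folds,
                              seed=config.seed)
               for spec in default_specs().values()]
    best = select_best(reports)
    payload = {"reports": [r.to_dict() for r in reports],
               "best": best.name,
               "n_rows": len(table)}
    _json_dump(payload, out / "benchmark.json")
    return {"benchmark": str(out / "benchmark.json"), "best": best.name}


def stage_closed_loop(config: RunConfig) -> dict:
    out = _out(config)
    model = joblib.load(_require(out / "model.joblib", "train"))
    design = ExperimentDesign(n_animals=len(config.test_profiles),
                              trials_per_condition=config.trials_per_condition,
                              trial_min=config.trial_min)
    policy = StimulationPolicy(confirm_delay_s=config.confirm_delay_s,
                               decision_stride_s=config.decision_stride_s,
                               burst_s=config.burst_s)
    free, stim, improvement, trials = run_experiment(
        design, list(config.test_profiles), model, policy, config.seed)
    free.to_csv(out / "summary_free.csv")
    stim.to_csv(out / "summary_stimulated.csv")
    trials.to_csv(out / "trials.csv", index=False)
    _json_dump({"mean_change_pct": improvement["mean_change_pct"],
                "pooled_change_pct": improvement["pooled_change_pct"],
                "headline": improvement["headline"]},
               out / "improvement.json")
    return {"improvement": improvement["headline"]}


def stage_metrics(config: RunConfig) -> dict:
    out = _out(config)
    trace = BehaviorTrace.read_csv(_require(out / "trace.csv", "simulate"))
    grid = arena_metrics.generate_grid(config.grid_resolution)
    m = arena_metrics.compute_metrics(trace, grid,
                                      t_exp_min=config.duration_s / 60.0)
    _json_dump(m.as_dict(), out / "metrics.json")
    return m.as_dict()


def stage_track(config: RunConfig) -> dict:
    from roachloop.synthetic_data import render_frames
    from roachloop.video_tracking import TrackerConfig, track_sequence
    out = _out(config)
    trace = BehaviorTrace.read_csv(_require(out / "trace.csv", "simulate"))
    positions = trace.positions[:: int(config.sample_rate)]  # 1 frame/s
    frames, truth, calib = render_frames(positions, noise_sd=2.0,
                                         seed=config.seed)
    tconf = TrackerConfig(center_px=calib["center_px"],
                          radius_px=calib["radius_px"])
    traj, n_invalid = track_sequence(frames, tconf, frame_rate=1.0)
    traj.to_csv(out / "tracked_trajectory.csv", index=False)
    truth.to_csv(out / "tracked_truth.csv", index=False)
    return {"frames": len(frames), "invalid": n_invalid,
            "trajectory": str(out / "tracked_trajectory.csv")}


def stage_report(config: RunConfig) -> dict:
    out = _out(config)
    payload = report_mod.fixture_report()
    _json_dump(payload, out / "report.json")
    return payload["improvement"]["headline"]


_DISPATCH = {
    "simulate": stage_simulate,
    "features": stage_features,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "closed-loop": stage_closed_loop,
    "metrics": stage_metrics,
    "track": stage_track,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, stage: str) -> dict:
    """Run one stage; artifacts land in ``config.out_dir``."""
    if stage not in _DISPATCH:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    t0 = time.time()
    logger.info("stage %s starting (seed=%d, out=%s)", stage, config.seed,
                config.out_dir)
    result = _DISPATCH[stage](config)
    logger.info("stage %s finished in %.1f s", stage, time.time() - t0)
    return result
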