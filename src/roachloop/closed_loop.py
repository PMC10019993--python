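"""Stimulate-on-stop feedback policy coupled to a trained recognizer.

Every decision stride (0.5 s) the recognizer classifies the trailing
1.5-s IMU window as stop or move.  When the decisions have read *stop*
continuously for the confirm delay (1 s) and no burst is active, a
stimulation burst (0.5 s) is emitted; a stopped animal responds to a
burst by walking with probability ``p_respond_stim``.  The experiment
stage runs the paired free-vs-stimulated design — three animals, three
7-minute trials per condition, identical seeds across conditions — and
summarizes both conditions with the arena metrics plus improvement
statistics.  The stimulus waveform itself (50-Hz PWM, 50% duty) is
metadata: only its timing is modeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from roachloop.config import SAMPLE_RATE_HZ, TRIAL_MINUTES, ArenaConfig
from roachloop import arena_metrics
from roachloop.imu_features import FilterSpec, extract_features
from roachloop.motion_classification import TrainedModel
from roachloop.synthetic_data import (
    TEST_PROFILE_NAMES,
    BehaviorParams,
    ImuProfile,
    behavior_profile,
    imu_profile_for,
    simulate_behavior,
)

__all__ = [
    "StimulationPolicy",
    "ExperimentDesign",
    "ModelRecognizer",
    "online_recognizer",
    "stimulation_policy_step",
    "run_experiment",
]


class ModelRecognizer:
    """Adapter classifying one raw (L, 6) IMU window with a trained model."""

    def __init__(self, model: TrainedModel,
                 filter_spec: FilterSpec | None = FilterSpec()):
        self.model = model
        self.filter_spec = filter_spec

    def classify(self, window: np.ndarray) -> int:
        feats = extract_features(window, self.filter_spec)
        return int(self.model.predict(feats[None, :])[0])


@dataclass
class StimulationPolicy:
    """Timing of the stimulate-on-stop loop.

    ``recognizer`` is either None (oracle: the majority of true states
    over the trailing window, ties read as stop) or an object with a
    ``classify(window) -> {0, 1}`` method; a model-based recognizer
    additionally needs ``imu_profile`` to synthesize its input stream.
    """

    confirm_delay_s: float = 1.0
    decision_stride_s: float = 0.5
    burst_s: float = 0.5
    window_s: float = 1.5
    recognizer: object | None = None
    imu_profile: ImuProfile | None = None
    stimulus_descriptor: str = "50-Hz PWM, 50% duty cycle"

    def __post_init__(self) -> None:
        if not self.confirm_delay_s >= self.decision_stride_s > 0:
            raise ValueError("require confirm_delay_s >= decision_stride_s > 0")
        if self.burst_s <= 0:
            raise ValueError("burst_s must be positive")


@dataclass(frozen=True)
class ExperimentDesign:
    """Paired free-vs-stimulated open-field design."""

    n_animals: int = 3
    trials_per_condition: int = 3
    trial_min: float = TRIAL_MINUTES
    conditions: tuple[str, str] = ("free", "stimulated")

    def __post_init__(self) -> None:
        if self.trials_per_condition < 1 or self.n_animals < 1:
            raise ValueError("need at least one animal and one trial")


def online_recognizer(model: TrainedModel, imu, *,
                      window_s: float = 1.5, stride_s: float = 0.5,
                      filter_spec: FilterSpec | None = FilterSpec()
                      ) -> pd.DataFrame:
    """Classify a complete IMU record the way the online loop would.

    Returns a DataFrame of (t, decision): one decision per stride over
    the trailing window, timestamped at the window's trailing edge, the
    first at t = window_s.  A stream shorter than one window yields no
    decisions (with a warning).
    """
    data = imu.data if hasattr(imu, "data") else np.asarray(imu, float)
    rate = getattr(imu, "sample_rate", SAMPLE_RATE_HZ)
    L = int(round(window_s * rate))
    stride = max(1, int(round(stride_s * rate)))
    if data.shape[0] < L:
        warnings.warn("stream shorter than one window; no decisions",
                      stacklevel=2)
        return pd.DataFrame({"t": [], "decision": []})
    rec = ModelRecognizer(model, filter_spec)
    starts = np.arange(0, data.shape[0] - L + 1, stride)
    times = (starts + L) / rate
    decisions = [rec.classify(data[s:s + L]) for s in starts]
    return pd.DataFrame({"t": times, "decision": np.asarray(decisions, int)})


def stimulation_policy_step(decisions: pd.DataFrame | list,
                            policy: StimulationPolicy, t_now: float,
                            burst_active: bool = False) -> bool:
    """Should a burst start now, given the timestamped decisions so far?

    True iff no burst is active and the decisions spanning the last
    ``confirm_delay_s`` are all stop — i.e. stop has been read
    continuously for the confirm delay.
    """
    if burst_active:
        return False
    if isinstance(decisions, pd.DataFrame):
        pairs = list(zip(decisions["t"], decisions["decision"]))
    else:
        pairs = list(decisions)
    recent = [(t, int(d)) for t, d in pairs
              if t >= t_now - policy.confirm_delay_s - 1e-9]
    if len(recent) < 2:
        return False
    if any(d == 1 for _, d in recent):
        return False
    return min(t for t, _ in recent) <= t_now - policy.confirm_delay_s + 1e-9


def _resolve_test_profiles(profiles) -> list[tuple[BehaviorParams, ImuProfile, str]]:
    resolved = []
    for p in profiles:
        if isinstance(p, str):
            resolved.append((behavior_profile(p), imu_profile_for(p), p))
        else:
            resolved.append(tuple(p))
    return resolved


def run_experiment(design: ExperimentDesign, profiles, model: TrainedModel,
                   policy: StimulationPolicy, master_seed: int, *,
                   arena: ArenaConfig | None = None):
    """Run the paired free-vs-stimulated experiment on the test animals.

    ``profiles`` lists the test animals (names or (BehaviorParams,
    ImuProfile, id) triples); they must be disjoint from the animals the
    model was trained on.  Each (animal, trial) pair shares one seed
    across the two conditions to reduce Monte-Carlo variance in the
    improvement estimates.  Returns ``(free_summary, stim_summary,
    improvement, trials_df)``.
    """
    arena = arena or ArenaConfig()
    resolved = _resolve_test_profiles(profiles)[: design.n_animals]
    if model is not None:
        overlap = {name for _, _, name in resolved} & set(model.training_animals)
        if overlap:
            raise ValueError(
                f"test animals {sorted(overlap)} overlap the model's "
                f"training animals; use held-out animals")
    grid = arena_metrics.generate_grid(arena.grid_resolution)
    duration_s = design.trial_min * 60.0
    ss = np.random.SeedSequence(master_seed)
    rows = []
    for params, imu_prof, name in resolved:
        for trial in range(1, design.trials_per_condition + 1):
            seed = int(ss.spawn(1)[0].generate_state(1, dtype=np.uint32)[0]
                       ) & 0x7FFFFFFF
            trial_policy = StimulationPolicy(
                confirm_delay_s=policy.confirm_delay_s,
                decision_stride_s=policy.decision_stride_s,
                burst_s=policy.burst_s, window_s=policy.window_s,
                recognizer=(ModelRecognizer(model) if model is not None
                            else policy.recognizer),
                imu_profile=imu_prof)
            free = simulate_behavior(arena, params, duration_s, seed)
            stim = simulate_behavior(arena, params, duration_s, seed,
                                     policy=trial_policy)
            for condition, trace in (("free", free), ("stimulated", stim)):
                m = arena_metrics.compute_metrics(
                    trace, grid, boundary=arena.zone_boundary,
                    threshold=arena.d_min_cut, t_exp_min=design.trial_min)
                rows.append({"animal": name, "trial": trial,
                             "condition": condition, "seed": seed,
                             **m.as_dict()})
    trials = pd.DataFrame(rows)
    free_summary = arena_metrics.summarize_trials(
        trials[trials["condition"] == "free"])
    stim_summary = arena_metrics.summarize_trials(
        trials[trials["condition"] == "stimulated"])
    free_for_imp = free_summary
    if (free_summary["stimulation_time"] == 0).all():
        # no bursts in the free condition: the ratio is undefined, not zero
        free_for_imp = free_summary.drop(columns=["stimulation_time"])
    improvement = arena_metrics.improvement_stats(free_for_imp, stim_summary)
    return free_summary, stim_summary, improvement, trials


def default_test_profiles() -> list[str]:
    """The three held-out test animals, ordered by increasing activity."""
    return list(TEST_PROFILE_NAMES)
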