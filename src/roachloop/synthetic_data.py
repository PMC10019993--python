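"""Synthetic insect locomotion, IMU signatures, datasets and video frames.

The generator emulates the study conditions of a 7-minute open-field
trial in a circular arena: a two-state (stop/move) Markov walker that
performs a diffusive random walk in the central zone and wall following
(thigmotaxis) in the peripheral annulus, with occasional exits back
toward the center; per-animal activity profiles (inactive, intermediate,
active) differ in their spontaneous stop→move rate.  The IMU model adds
a per-animal attitude-dependent accelerometer/gyroscope bias, Gaussian
noise whose amplitude is state dependent (larger while moving), a gait
oscillation in the move state and an extra transient while stimulated —
the qualitative signature that makes simple thresholding unreliable and
motivates a learned stop/move classifier.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; every operation is pure given its inputs
and seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from roachloop.config import SAMPLE_RATE_HZ, ArenaConfig

__all__ = [
    "BehaviorParams",
    "BehaviorTrace",
    "ImuProfile",
    "ImuSeries",
    "behavior_profile",
    "imu_profile_for",
    "TEST_PROFILE_NAMES",
    "TRAIN_PROFILE_NAMES",
    "simulate_behavior",
    "synthesize_imu",
    "make_labeled_dataset",
    "render_frames",
]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class BehaviorParams:
    """Per-animal locomotion parameters (rates per second of real time).

    ``p_start_per_s`` is the spontaneous stop→move rate and is the main
    activity dial separating the inactive/intermediate/active profiles;
    ``p_respond_stim`` is the probability that one stimulation burst
    converts a stopped animal to walking.
    """

    profile_id: str = "custom"
    p_stop_per_s: float = 0.05
    p_start_per_s: float = 0.02
    p_exit_per_s: float = 0.05
    mean_speed: float = 0.1           # normalized radius units / s (4 cm/s)
    heading_diffusion: float = 1.0    # rad^2 / s, central-zone random walk
    wall_follow_direction_persistence: float = 0.99  # per step
    p_respond_stim: float = 0.9

    def __post_init__(self) -> None:
        for name in ("p_stop_per_s", "p_start_per_s", "p_exit_per_s",
                     "wall_follow_direction_persistence", "p_respond_stim"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mean_speed <= 0:
            raise ValueError("mean_speed must be positive")
        if self.heading_diffusion < 0:
            raise ValueError("heading_diffusion must be >= 0")


#: Activity ordering of the three simulated test animals.
TEST_PROFILE_NAMES = ("inactive", "intermediate", "active")
#: Distinct animals used only for classifier training.
TRAIN_PROFILE_NAMES = ("train_low", "train_high")

_P_START = {"inactive": 0.005, "intermediate": 0.02, "active": 0.08,
            "train_low": 0.01, "train_high": 0.06}


def behavior_profile(name: str) -> BehaviorParams:
    """Named default locomotion profile (see TEST/TRAIN_PROFILE_NAMES)."""
    if name not in _P_START:
        raise KeyError(f"unknown profile {name!r}; known: {sorted(_P_START)}")
    return BehaviorParams(profile_id=name, p_start_per_s=_P_START[name])


@dataclass(frozen=True)
class ImuProfile:
    """Per-animal IMU signature: bias, state-dependent noise, oscillations.

    Accelerations in m/s², angular rates in deg/s.  The accelerometer
    bias depends on the animal's backpack attitude and is drawn once per
    animal; move-state noise strictly exceeds stop-state noise on every
    channel.
    """

    accel_bias: np.ndarray
    gyro_bias: np.ndarray
    noise_sd_stop: np.ndarray = field(
        default_factory=lambda: np.array([0.05, 0.05, 0.05, 0.5, 0.5, 0.5]))
    noise_sd_move: np.ndarray = field(
        default_factory=lambda: np.array([0.4, 0.4, 0.4, 8.0, 8.0, 8.0]))
    gait_amp: np.ndarray = field(
        default_factory=lambda: np.array([0.8, 0.8, 0.4, 15.0, 15.0, 10.0]))
    gait_freq_hz: float = 4.0
    gait_phase: np.ndarray = field(default_factory=lambda: np.zeros(6))
    stim_amp: np.ndarray = field(
        default_factory=lambda: np.array([1.2, 1.2, 0.6, 20.0, 20.0, 15.0]))
    stim_freq_hz: float = 6.0

    def __post_init__(self) -> None:
        for name in ("accel_bias", "gyro_bias", "noise_sd_stop",
                     "noise_sd_move", "gait_amp", "gait_phase", "stim_amp"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if self.accel_bias.shape != (3,) or self.gyro_bias.shape != (3,):
            raise ValueError("biases must be 3-vectors")
        noiseless = (self.noise_sd_move == 0) & (self.noise_sd_stop == 0)
        if not np.all((self.noise_sd_move > self.noise_sd_stop) | noiseless):
            raise ValueError("move-state noise must exceed stop-state noise "
                             "on every noisy channel")
        nyquist = SAMPLE_RATE_HZ / 2.0
        if not (0 < self.gait_freq_hz < nyquist and 0 < self.stim_freq_hz < nyquist):
            raise ValueError(f"oscillation frequencies must lie below the "
                             f"{nyquist:g}-Hz Nyquist limit")

    @property
    def bias(self) -> np.ndarray:
        return np.concatenate([self.accel_bias, self.gyro_bias])

    @classmethod
    def from_seed(cls, seed: int) -> "ImuProfile":
        """Draw a per-animal attitude bias (±2 m/s², ±5 deg/s) and phases."""
        rng = np.random.default_rng(seed)
        return cls(
            accel_bias=rng.uniform(-2.0, 2.0, 3),
            gyro_bias=rng.uniform(-5.0, 5.0, 3),
            gait_phase=rng.uniform(0.0, _TWO_PI, 6),
        )


def imu_profile_for(name: str) -> ImuProfile:
    """Deterministic per-animal IMU profile keyed by the profile name."""
    return ImuProfile.from_seed(zlib.crc32(name.encode()) % (2 ** 31))


@dataclass(frozen=True)
class BehaviorTrace:
    """Simulator ground truth at the IMU rate.

    ``states``: 1 = move, 0 = stop; ``stim_flags``: 1 while a
    stimulation burst is applied; ``zones``: 'peripheral' iff the sample
    radius is >= the arena zone boundary.
    """

    sample_rate: float
    times: np.ndarray
    states: np.ndarray
    stim_flags: np.ndarray
    positions: np.ndarray
    zones: np.ndarray
    profile_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("states", "stim_flags", "zones"):
            if len(getattr(self, name)) != n:
                raise ValueError("trace series must share one length")
        if self.positions.shape != (n, 2):
            raise ValueError("positions must be (n, 2)")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration_min(self) -> float:
        return len(self) / self.sample_rate / 60.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.times, "state": self.states, "stim": self.stim_flags,
            "x": self.positions[:, 0], "y": self.positions[:, 1],
            "zone": self.zones,
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, sample_rate: float = SAMPLE_RATE_HZ) -> "BehaviorTrace":
        df = pd.read_csv(path)
        return cls(sample_rate=sample_rate, times=df["t"].to_numpy(float),
                   states=df["state"].to_numpy(int),
                   stim_flags=df["stim"].to_numpy(int),
                   positions=df[["x", "y"]].to_numpy(float),
                   zones=df["zone"].to_numpy(str))


@dataclass(frozen=True)
class ImuSeries:
    """Uniformly sampled 6-channel inertial record, columns a_x..g_z."""

    sample_rate: float
    data: np.ndarray  # (n, 6)

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != 6:
            raise ValueError("data must be (n, 6)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("IMU data must be finite")

    def __len__(self) -> int:
        return len(self.data)

    def to_frame(self) -> pd.DataFrame:
        from roachloop.imu_features import CHANNELS
        df = pd.DataFrame(self.data, columns=CHANNELS)
        df.insert(0, "t", np.arange(len(self)) / self.sample_rate)
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ImuSeries":
        from roachloop.imu_features import CHANNELS
        df = pd.read_csv(path)
        t = df["t"].to_numpy(float)
        rate = 1.0 / np.median(np.diff(t)) if len(t) > 1 else SAMPLE_RATE_HZ
        return cls(sample_rate=float(round(rate, 6)),
                   data=df[CHANNELS].to_numpy(float))


def _per_step(p_per_s: float, dt: float) -> float:
    """Convert a per-second event probability to the per-step probability."""
    return 1.0 - (1.0 - p_per_s) ** dt


def _imu_sample(profile: ImuProfile, unit_noise_row: np.ndarray,
                state: int, stim: int, t: float) -> np.ndarray:
    sd = profile.noise_sd_move if state == 1 else profile.noise_sd_stop
    val = profile.bias + unit_noise_row * sd
    if state == 1:
        val = val + profile.gait_amp * np.sin(
            _TWO_PI * profile.gait_freq_hz * t + profile.gait_phase)
    if stim:
        val = val + profile.stim_amp * np.sin(
            _TWO_PI * profile.stim_freq_hz * t + profile.gait_phase)
    return val


def simulate_behavior(arena: ArenaConfig, params: BehaviorParams,
                      duration_s: float, seed: int, policy=None, *,
                      initial_state: int = 1,
                      imu_profile: ImuProfile | None = None,
                      return_imu: bool = False):
    """Simulate one open-field trial as a discrete-time state machine.

    The walker starts at the arena center.  In the central zone a moving
    animal performs a heading-diffusion random walk; in the peripheral
    annulus it follows the wall tangentially with persistent handedness
    and leaves it through exit events.  Stops freeze the position.

    When ``policy`` is given (see :mod:`roachloop.closed_loop`) the
    stimulate-on-stop feedback loop runs inside the simulation: a
    recognizer classifies the trailing window every decision stride, and
    a burst triggered after a sustained run of stop decisions converts a
    stopped animal to walking with probability ``p_respond_stim``.  A
    model-based recognizer reads an IMU stream synthesized sample by
    sample from ``policy.imu_profile`` (or ``imu_profile``).

    Returns the :class:`BehaviorTrace`; with ``return_imu=True`` a
    ``(trace, ImuSeries)`` pair (requires an IMU profile).
    """
    if not np.isfinite(duration_s) or duration_s <= 0:
        raise ValueError("duration_s must be finite and positive")
    if initial_state not in (0, 1):
        raise ValueError("initial_state must be 0 (stop) or 1 (move)")

    rate = SAMPLE_RATE_HZ
    dt = 1.0 / rate
    n = int(round(duration_s * rate))
    boundary = arena.zone_boundary

    ss = np.random.SeedSequence(seed)
    beh_rng, imu_rng, resp_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    p_stop = _per_step(params.p_stop_per_s, dt)
    p_start = _per_step(params.p_start_per_s, dt)
    p_exit = _per_step(params.p_exit_per_s, dt)
    step_len = params.mean_speed * dt
    diff_sd = np.sqrt(params.heading_diffusion * dt)
    r_max = 0.995  # wall standoff keeps positions strictly inside the disk

    recognizer = getattr(policy, "recognizer", None) if policy is not None else None
    prof = imu_profile or (getattr(policy, "imu_profile", None)
                           if policy is not None else None)
    need_imu = return_imu or recognizer is not None
    if need_imu and prof is None:
        raise ValueError("an ImuProfile is required to synthesize IMU samples")
    unit_noise = imu_rng.standard_normal((n, 6)) if need_imu else None
    imu = np.empty((n, 6)) if need_imu else None

    if policy is not None:
        win_smp = int(round(getattr(policy, "window_s", 1.5) * rate))
        stride_smp = max(1, int(round(policy.decision_stride_s * rate)))
        burst_smp = max(1, int(round(policy.burst_s * rate)))
        confirm = policy.confirm_delay_s
        decisions: list[tuple[float, int]] = []
    burst_until = -1

    states = np.empty(n, dtype=np.int8)
    stim = np.zeros(n, dtype=np.int8)
    pos = np.empty((n, 2))

    x = y = 0.0
    heading = beh_rng.uniform(0.0, _TWO_PI)
    state = int(initial_state)
    handedness = 1 if beh_rng.random() < 0.5 else -1
    exiting = False
    was_wall = False

    for i in range(n):
        t = i * dt
        if policy is not None and i >= win_smp and (i - win_smp) % stride_smp == 0:
            if recognizer is None:  # oracle: majority of true states, tie -> stop
                label = 1 if states[i - win_smp:i].mean() > 0.5 else 0
            else:
                label = int(recognizer.classify(imu[i - win_smp:i]))
            # decisions made while stimulating do not count toward the
            # next confirmation: stop must be re-read for a full confirm
            # delay after each burst before another one may fire
            if i >= burst_until:
                decisions.append((t, label))
                while decisions and decisions[0][0] < t - confirm - 1e-9:
                    decisions.pop(0)
                if _confirmed_stop(decisions, t, confirm):
                    burst_until = i + burst_smp
                    decisions.clear()
                    if state == 0 and resp_rng.random() < params.p_respond_stim:
                        state = 1
                        heading = resp_rng.uniform(0.0, _TWO_PI)
        stim_i = 1 if i < burst_until else 0

        states[i] = state
        stim[i] = stim_i
        pos[i, 0], pos[i, 1] = x, y
        if need_imu:
            imu[i] = _imu_sample(prof, unit_noise[i], state, stim_i, t)

        # --- advance position over [t, t+dt) using the current state ---
        r = np.hypot(x, y)
        if state == 1:
            if r >= boundary and not exiting:
                theta = np.arctan2(y, x)
                if not was_wall:
                    cross = x * np.sin(heading) - y * np.cos(heading)
                    handedness = 1 if cross >= 0 else -1
                was_wall = True
                if beh_rng.random() > params.wall_follow_direction_persistence:
                    handedness = -handedness
                if beh_rng.random() < p_exit:
                    exiting = True
                    heading = theta + np.pi + beh_rng.normal(0.0, 0.3)
                else:
                    theta += handedness * step_len / max(r, boundary)
                    r_new = np.clip(r + beh_rng.normal(0.0, 0.02) * np.sqrt(dt),
                                    boundary + 0.005, r_max)
                    x, y = r_new * np.cos(theta), r_new * np.sin(theta)
                    heading = theta + handedness * np.pi / 2.0
            else:
                was_wall = False
                heading += beh_rng.normal(0.0, diff_sd)
                x += step_len * np.cos(heading)
                y += step_len * np.sin(heading)
                r = np.hypot(x, y)
                if r > r_max:  # reflect at the wall standoff
                    x, y = x * r_max / r, y * r_max / r
                if exiting and r < boundary:
                    exiting = False
        # --- state transition for the next sample ---
        u = beh_rng.random()
        if state == 1 and u < p_stop:
            state = 0
        elif state == 0 and u < p_start:
            state = 1

    r_all = np.hypot(pos[:, 0], pos[:, 1])
    zones = np.where(r_all >= boundary, "peripheral", "central")
    trace = BehaviorTrace(sample_rate=rate, times=np.arange(n) * dt,
                          states=states, stim_flags=stim, positions=pos,
                          zones=zones, profile_id=params.profile_id)
    if return_imu:
        return trace, ImuSeries(sample_rate=rate, data=imu)
    return trace


def _confirmed_stop(decisions: list[tuple[float, int]], t_now: float,
                    confirm_s: float) -> bool:
    """True iff decisions cover the last confirm_s and are all 'stop'."""
    recent = [(td, lab) for td, lab in decisions if td >= t_now - confirm_s - 1e-9]
    if len(recent) < 2:
        return False
    if any(lab == 1 for _, lab in recent):
        return False
    return min(td for td, _ in recent) <= t_now - confirm_s + 1e-9


def synthesize_imu(trace: BehaviorTrace, profile: ImuProfile,
                   seed: int) -> ImuSeries:
    """IMU record of a completed behavior trace.

    Per sample: channel = bias + Gaussian noise with state-dependent
    standard deviation + gait oscillation while moving + an extra
    transient while stimulated.  Deterministic given (trace, profile,
    seed).
    """
    n = len(trace)
    rng = np.random.default_rng(seed)
    unit = rng.standard_normal((n, 6))
    state = trace.states.astype(bool)[:, None]
    stim = trace.stim_flags.astype(bool)[:, None]
    t = trace.times[:, None]
    sd = np.where(state, profile.noise_sd_move, profile.noise_sd_stop)
    data = profile.bias + unit * sd
    data += state * profile.gait_amp * np.sin(
        _TWO_PI * profile.gait_freq_hz * t + profile.gait_phase)
    data += stim * profile.stim_amp * np.sin(
        _TWO_PI * profile.stim_freq_hz * t + profile.gait_phase)
    return ImuSeries(sample_rate=trace.sample_rate, data=data)


def make_labeled_dataset(n_windows_per_class: int,
                         profiles=TRAIN_PROFILE_NAMES, seed: int = 0, *,
                         arena: ArenaConfig | None = None,
                         trial_s: float = 420.0,
                         max_rounds: int = 50) -> pd.DataFrame:
    """Balanced labeled feature windows drawn from >= 2 distinct animals.

    Repeatedly simulates 7-minute trials for each profile (behavior +
    IMU + windowed features, non-overlapping windows) until both classes
    hold ``n_windows_per_class`` rows, then truncates each class to
    exactly that count in deterministic order.
    """
    from roachloop.imu_features import build_feature_table

    if n_windows_per_class < 10:
        raise ValueError("need at least 10 windows per class")
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least 2 distinct animal profiles")
    arena = arena or ArenaConfig()
    resolved = []
    for p in profiles:
        if isinstance(p, str):
            resolved.append((behavior_profile(p), imu_profile_for(p), p))
        else:
            resolved.append(p)

    ss = np.random.SeedSequence(seed)
    parts: list[pd.DataFrame] = []
    counts = {0: 0, 1: 0}
    for _ in range(max_rounds):
        for params, prof, name in resolved:
            s_beh, s_imu = (int(c.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF
                            for c in ss.spawn(2))
            trace = simulate_behavior(arena, params, trial_s, s_beh)
            imu = synthesize_imu(trace, prof, s_imu)
            tab = build_feature_table(imu, trace, animal_id=name)
            parts.append(tab)
            for lab in (0, 1):
                counts[lab] += int((tab["label"] == lab).sum())
        if counts[0] >= n_windows_per_class and counts[1] >= n_windows_per_class:
            break
    else:
        raise RuntimeError("could not accumulate enough windows per class")
    full = pd.concat(parts, ignore_index=True)
    kept = pd.concat([full[full["label"] == lab].head(n_windows_per_class)
                      for lab in (0, 1)], ignore_index=True)
    return kept


def render_frames(trace_or_positions, image_size_px: int = 200,
                  body_axes_px: tuple[float, float] = (12.0, 6.0),
                  noise_sd: float = 0.0, seed: int = 0):
    """Grayscale frames of a bright body ellipse moving over the arena.

    The ellipse's major axis aligns with the direction of motion.
    Returns ``(frames, truth, calibration)``: an (m, H, W) uint8 stack,
    a DataFrame of ground-truth pixel centers (frame, cx_px, cy_px), and
    the pixel→normalized calibration dict (center_px, radius_px).
    """
    from skimage.draw import ellipse as draw_ellipse

    xy = (trace_or_positions.positions
          if hasattr(trace_or_positions, "positions")
          else np.asarray(trace_or_positions, dtype=float))
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("positions must be (m, 2)")
    a, b = body_axes_px
    margin = max(a, b) + 2.0
    radius_px = image_size_px / 2.0 - margin
    if radius_px <= 0:
        raise ValueError("body does not fit inside the image")
    cx0 = cy0 = image_size_px / 2.0
    px = cx0 + xy[:, 0] * radius_px
    py = cy0 - xy[:, 1] * radius_px  # image y grows downward
    lim = max(a, b)
    if np.any(px - lim < 0) or np.any(px + lim >= image_size_px) \
            or np.any(py - lim < 0) or np.any(py + lim >= image_size_px):
        raise ValueError("ellipse would cross the image border")

    steps = np.diff(xy, axis=0)
    angles = np.zeros(len(xy))
    moved = np.hypot(steps[:, 0], steps[:, 1]) > 0
    ang_step = np.arctan2(-steps[:, 1], steps[:, 0])  # image coordinates
    last = 0.0
    for i in range(len(xy)):
        if i > 0 and moved[i - 1]:
            last = ang_step[i - 1]
        angles[i] = last

    rng = np.random.default_rng(seed)
    frames = np.empty((len(xy), image_size_px, image_size_px), dtype=np.uint8)
    for i in range(len(xy)):
        img = np.zeros((image_size_px, image_size_px), dtype=float)
        rr, cc = draw_ellipse(py[i], px[i], b, a, shape=img.shape,
                              rotation=angles[i])
        img[rr, cc] = 255.0
        if noise_sd > 0:
            img += rng.normal(0.0, noise_sd, img.shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)
    truth = pd.DataFrame({"frame": np.arange(len(xy)),
                          "cx_px": px, "cy_px": py})
    calibration = {"center_px": (cx0, cy0), "radius_px": radius_px}
    return frames, truth, calibration
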