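"""Windowed time-domain features of 6-channel IMU records.

Each 1.5-s window (30 samples at 20 Hz) of the three accelerometer and
three gyroscope channels is reduced to 45 features: seven order/moment
statistics per channel (mean, variance, skewness, kurtosis, range, mean
absolute deviation, interquartile range; 42 values) plus the mean
squared angular rate ("gyro energy") of each gyroscope axis (3 values).
Accelerometer channels are smoothed with a first-order low-pass filter
(unit steady-state gain, time constant 0.1 s) before the statistics are
taken; gyroscope channels are used raw.

Formula conventions, fixed so results are reproducible:

* variance, skewness and kurtosis all normalize by ``L - 1`` and use the
  sample standard deviation ``s`` (``skew = Σ(x-x̄)³ / ((L-1)s³)``,
  ``kurt = Σ(x-x̄)⁴ / ((L-1)s⁴)``, non-excess — no −3 correction);
* a zero-variance window has skewness and kurtosis 0 by convention;
* MAD is the mean absolute deviation about the mean;
* quartiles use linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from roachloop.config import SAMPLE_RATE_HZ

__all__ = [
    "FilterSpec",
    "WindowSpec",
    "CHANNELS",
    "ACCEL_CHANNELS",
    "GYRO_CHANNELS",
    "FEATURE_COLUMNS",
    "lowpass_filter",
    "segment_windows",
    "extract_features",
    "build_feature_table",
]

CHANNELS = ["a_x", "a_y", "a_z", "g_x", "g_y", "g_z"]
ACCEL_CHANNELS = CHANNELS[:3]
GYRO_CHANNELS = CHANNELS[3:]
_STATS = ["mean", "var", "skew", "kurt", "range", "mad", "iqr"]

#: Fixed, versioned feature order: 7 statistics × 6 channels, then 3 energies.
FEATURE_COLUMNS = [f"{stat}_{ch}" for ch in CHANNELS for stat in _STATS] + [
    "ge_x", "ge_y", "ge_z"]


@dataclass(frozen=True)
class FilterSpec:
    """First-order low-pass: H(s) = K / (τ s + 1)."""

    gain: float = 1.0
    time_constant_s: float = 0.1

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.time_constant_s <= 0:
            raise ValueError("gain and time constant must be positive")


@dataclass(frozen=True)
class WindowSpec:
    """Analysis window: 1.5 s (30 samples at 20 Hz), configurable stride."""

    window_s: float = 1.5
    stride_samples: int = 30
    sample_rate: float = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        if self.stride_samples < 1:
            raise ValueError("stride must be >= 1")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.sample_rate))


def lowpass_filter(series: np.ndarray, spec: FilterSpec = FilterSpec(),
                   sample_rate: float = SAMPLE_RATE_HZ) -> np.ndarray:
    """Discrete exponential smoothing of one channel.

    ``y_i = K·α·x_i + (1−α)·y_{i−1}`` with ``α = Δt / (τ + Δt)`` and the
    startup-transient-free initial condition ``y_0 = K·x_0``.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    dt = 1.0 / sample_rate
    alpha = dt / (spec.time_constant_s + dt)
    # IIR form: y[i] - (1-alpha) y[i-1] = K alpha x[i]; zi seeds y_0 = K x_0
    b = [spec.gain * alpha]
    a = [1.0, -(1.0 - alpha)]
    zi = np.array([(1.0 - alpha) * spec.gain * x[0]])
    y, _ = lfilter(b, a, x, zi=zi)
    return y


def segment_windows(data: np.ndarray, labels: np.ndarray | None,
                    spec: WindowSpec = WindowSpec()):
    """Cut an (n, n_channels) array into fixed-length windows.

    Returns ``(windows, window_labels, start_indices)``.  A window's
    label is the majority per-sample state; exact ties resolve to stop
    (0) — the conservative choice for a stimulate-on-stop system.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < data.shape[1]:
        pass  # caller is trusted on orientation; (n, ch) expected
    L = spec.window_samples
    n = data.shape[0]
    if n < L:
        raise ValueError(f"series of {n} samples is shorter than one "
                         f"window of {L}")
    starts = np.arange(0, n - L + 1, spec.stride_samples)
    windows = np.stack([data[s:s + L] for s in starts])
    if labels is None:
        return windows, None, starts
    labels = np.asarray(labels)
    if len(labels) != n:
        raise ValueError("labels length must match series length")
    wl = np.array([1 if labels[s:s + L].mean() > 0.5 else 0 for s in starts],
                  dtype=int)
    return windows, wl, starts


def _stats_1d(x: np.ndarray) -> dict[str, float]:
    L = x.size
    mean = x.mean()
    dev = x - mean
    var = float(dev @ dev) / (L - 1)
    s = np.sqrt(var)
    if s > 0:
        skew = float((dev ** 3).sum()) / ((L - 1) * s ** 3)
        kurt = float((dev ** 4).sum()) / ((L - 1) * s ** 4)
    else:
        skew = 0.0
        kurt = 0.0
    q1, q3 = np.percentile(x, [25, 75])  # linear interpolation
    return {
        "mean": float(mean),
        "var": var,
        "skew": skew,
        "kurt": kurt,
        "range": float(x.max() - x.min()),
        "mad": float(np.abs(dev).mean()),
        "iqr": float(q3 - q1),
    }


def extract_features(window: np.ndarray,
                     filter_spec: FilterSpec | None = FilterSpec(),
                     sample_rate: float = SAMPLE_RATE_HZ) -> np.ndarray:
    """45-dimensional feature vector of one (L, 6) window.

    The low-pass filter is applied to the three accelerometer channels
    only; gyro energy is the mean squared *raw* angular rate per axis.
    Requires L >= 4 so that kurtosis is defined.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2 or w.shape[1] != len(CHANNELS):
        raise ValueError("window must be (L, 6)")
    if w.shape[0] < 4:
        raise ValueError("window must hold at least 4 samples")
    out: list[float] = []
    for ci, ch in enumerate(CHANNELS):
        x = w[:, ci]
        if filter_spec is not None and ch in ACCEL_CHANNELS:
            x = lowpass_filter(x, filter_spec, sample_rate)
        st = _stats_1d(x)
        out.extend(st[name] for name in _STATS)
    for ci in range(3, 6):
        g = w[:, ci]
        out.append(float((g ** 2).mean()))
    return np.asarray(out)


def build_feature_table(imu, trace=None, *,
                        window_spec: WindowSpec = WindowSpec(),
                        filter_spec: FilterSpec | None = FilterSpec(),
                        animal_id: str | None = None) -> pd.DataFrame:
    """Windowed features of a full record, with labels when a trace is given.

    ``imu`` is an ImuSeries (or an (n, 6) array); ``trace`` supplies the
    per-sample stop/move states used as window labels.  Returns a
    DataFrame with the 45 ``FEATURE_COLUMNS`` plus ``label`` and
    ``animal_id`` columns, rows in window order.
    """
    data = imu.data if hasattr(imu, "data") else np.asarray(imu, dtype=float)
    rate = getattr(imu, "sample_rate", window_spec.sample_rate)
    labels = None
    if trace is not None:
        labels = np.asarray(trace.states if hasattr(trace, "states") else trace)
        if len(labels) != data.shape[0]:
            raise ValueError("trace and IMU series lengths differ")
    windows, wl, starts = segment_windows(data, labels, window_spec)
    feats = np.stack([extract_features(w, filter_spec, rate) for w in windows])
    df = pd.DataFrame(feats, columns=FEATURE_COLUMNS)
    if wl is not None:
        df["label"] = wl
    df["animal_id"] = animal_id if animal_id is not None else ""
    df["window_start"] = starts
    return df
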