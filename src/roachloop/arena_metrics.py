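"""Movement-performance metrics for a circular bounded arena.

A trial is scored by six quantities: the search rate ``ε`` (fraction of a
regular lattice of interior grid points passed within a virtual-sensor
reach of the route), the central and peripheral occupancy rates ``c_r``
and ``p_r``, the normalized path length ``d_t``, the stop time ``t_s``
and the stimulation time ``t_st``.  The grid is the square lattice of
step 1/resolution spanning [-1, 1]²; a point belongs to the arena
interior when its radius is strictly below 1, and a grid point counts as
*searched* when its minimum distance to the route is strictly below the
sensor reach (0.1 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Grid",
    "MovementMetrics",
    "generate_grid",
    "min_distance_field",
    "searched_grid_count",
    "search_rate",
    "central_peripheral_rates",
    "path_length",
    "stop_time",
    "stimulation_time",
    "compute_metrics",
    "summarize_trials",
    "improvement_stats",
]

#: Metric columns of a tidy trial table, in report order.
METRIC_COLUMNS = [
    "search_rate",
    "distance",
    "central_rate",
    "peripheral_rate",
    "stop_time",
    "stimulation_time",
]


@dataclass(frozen=True)
class Grid:
    """Normalized square lattice over the arena with its interior mask."""

    resolution: int
    points: np.ndarray        # (n_lattice, 2) normalized coordinates
    interior: np.ndarray      # boolean mask over points, radius strictly < 1
    grid_area: int            # number of interior lattice points

    @property
    def interior_points(self) -> np.ndarray:
        return self.points[self.interior]


@dataclass(frozen=True)
class MovementMetrics:
    """One trial's scores; all on the normalized-arena scale."""

    search_rate: float
    distance: float
    central_rate: float
    peripheral_rate: float
    stop_time: float
    stimulation_time: float
    trial_minutes: float

    def as_dict(self) -> dict[str, float]:
        return {
            "search_rate": self.search_rate,
            "distance": self.distance,
            "central_rate": self.central_rate,
            "peripheral_rate": self.peripheral_rate,
            "stop_time": self.stop_time,
            "stimulation_time": self.stimulation_time,
        }


def generate_grid(resolution: int = 100) -> Grid:
    """Lattice (j/res, k/res) for j, k in [-res, res], interior radius < 1.

    At the default resolution of 100 the interior holds 31,397 points.
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    ax = np.arange(-resolution, resolution + 1, dtype=float) / resolution
    jj, kk = np.meshgrid(ax, ax, indexing="ij")
    pts = np.column_stack([jj.ravel(), kk.ravel()])
    interior = (pts[:, 0] ** 2 + pts[:, 1] ** 2) < 1.0
    return Grid(resolution=resolution, points=pts, interior=interior,
                grid_area=int(interior.sum()))


def _as_xy(traj) -> np.ndarray:
    """Accept an (m, 2) array or a DataFrame with x/y columns."""
    if isinstance(traj, pd.DataFrame):
        xy = traj[["x", "y"]].to_numpy(dtype=float)
    else:
        xy = np.asarray(traj, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("trajectory must be an (m, 2) array of x, y")
    if not np.all(np.isfinite(xy)):
        raise ValueError("trajectory contains non-finite coordinates")
    return xy


def min_distance_field(traj, grid: Grid) -> np.ndarray:
    """Exact minimum Euclidean distance from each interior grid point to the route."""
    xy = _as_xy(traj)
    if len(xy) == 0:
        raise ValueError("empty trajectory")
    tree = cKDTree(xy)
    d, _ = tree.query(grid.interior_points, k=1)
    return np.asarray(d, dtype=float)


def searched_grid_count(field: np.ndarray, threshold: float = 0.1) -> int:
    """Number of interior grid points with d_min strictly below the sensor reach."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    field = np.asarray(field, dtype=float)
    return int((field < threshold).sum())


def search_rate(count: int, grid: Grid) -> float:
    """ε = searched grid points / interior grid points."""
    if not 0 <= count <= grid.grid_area:
        raise ValueError("count outside [0, grid_area]")
    return count / grid.grid_area


def central_peripheral_rates(traj, boundary: float = 0.9) -> tuple[float, float]:
    """Fractions of samples inside (r < boundary) / outside the central zone."""
    xy = _as_xy(traj)
    if len(xy) == 0:
        raise ValueError("empty trajectory")
    r = np.hypot(xy[:, 0], xy[:, 1])
    c_r = float(np.mean(r < boundary))
    return c_r, 1.0 - c_r


def path_length(traj) -> float:
    """Normalized distance travelled: sum of Euclidean step lengths."""
    xy = _as_xy(traj)
    if len(xy) < 2:
        warnings.warn("trajectory has fewer than two points; distance is 0",
                      stacklevel=2)
        return 0.0
    steps = np.diff(xy, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def _binary(series, name: str) -> np.ndarray:
    s = np.asarray(series)
    if s.size == 0:
        raise ValueError(f"empty {name} series")
    if not np.isin(s, (0, 1)).all():
        raise ValueError(f"{name} series must be binary 0/1")
    return s.astype(float)


def stop_time(states, t_exp_min: float) -> float:
    """Seconds spent stopped: (1 - mean state) × trial duration.

    ``states`` is the per-sample indicator, 1 = move, 0 = stop.
    """
    if t_exp_min <= 0:
        raise ValueError("t_exp_min must be positive")
    s = _binary(states, "state")
    return float((1.0 - s.mean()) * t_exp_min * 60.0)


def stimulation_time(stim_flags, t_exp_min: float) -> float:
    """Seconds of applied stimulation: mean flag × trial duration."""
    if t_exp_min <= 0:
        raise ValueError("t_exp_min must be positive")
    s = _binary(stim_flags, "stim")
    return float(s.mean() * t_exp_min * 60.0)


def compute_metrics(trace, grid: Grid | None = None, *,
                    boundary: float = 0.9, threshold: float = 0.1,
                    t_exp_min: float | None = None) -> MovementMetrics:
    """Score a simulated or tracked trial (a BehaviorTrace-like object).

    ``trace`` needs ``positions`` (m × 2), ``states``, ``stim_flags`` and
    ``duration_min`` attributes, or is a DataFrame with t/x/y/state/stim.
    """
    if isinstance(trace, pd.DataFrame):
        xy = trace[["x", "y"]].to_numpy(float)
        states = trace["state"].to_numpy()
        stim = trace["stim"].to_numpy() if "stim" in trace else np.zeros(len(trace))
        if t_exp_min is None:
            t = trace["t"].to_numpy(float)
            t_exp_min = (t[-1] - t[0] + (t[1] - t[0] if len(t) > 1 else 0)) / 60.0
    else:
        xy = trace.positions
        states = trace.states
        stim = trace.stim_flags
        if t_exp_min is None:
            t_exp_min = trace.duration_min
    grid = grid or generate_grid()
    field = min_distance_field(xy, grid)
    count = searched_grid_count(field, threshold)
    c_r, p_r = central_peripheral_rates(xy, boundary)
    return MovementMetrics(
        search_rate=search_rate(count, grid),
        distance=path_length(xy),
        central_rate=c_r,
        peripheral_rate=p_r,
        stop_time=stop_time(states, t_exp_min),
        stimulation_time=stimulation_time(stim, t_exp_min),
        trial_minutes=float(t_exp_min),
    )


def trials_frame(per_trial: Iterable[tuple[str, int, MovementMetrics]]) -> pd.DataFrame:
    """Tidy table (animal, trial, metrics...) from labelled MovementMetrics."""
    rows = []
    for animal, trial, m in per_trial:
        rows.append({"animal": animal, "trial": trial, **m.as_dict()})
    return pd.DataFrame(rows)


def summarize_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-animal means of each metric, plus an ``overall`` row.

    The overall row is the mean across animals of the per-animal means,
    which weights every animal equally regardless of trial count.
    """
    if len(trials) == 0:
        raise ValueError("no trials to summarize")
    metrics = [c for c in METRIC_COLUMNS if c in trials.columns]
    per_animal = trials.groupby("animal")[metrics].mean()
    overall = per_animal.mean(axis=0).to_frame().T
    overall.index = pd.Index(["overall"], name="animal")
    return pd.concat([per_animal, overall])


def improvement_stats(free_summary: pd.DataFrame,
                      stim_summary: pd.DataFrame) -> dict:
    """Percentage change of each metric between matched conditions.

    Per-animal percent changes are computed from the per-animal means and
    averaged across animals; a pooled reading (percent change of the
    cross-animal means) is reported alongside.  Stop-time is additionally
    expressed as a positive *reduction*.  Animals with a zero
    free-condition mean for a metric are excluded from that metric with a
    warning.
    """
    free = free_summary.drop(index="overall", errors="ignore")
    stim = stim_summary.drop(index="overall", errors="ignore")
    animals = [a for a in free.index if a in stim.index]
    if not animals:
        raise ValueError("no matched animals between conditions")
    metrics = [c for c in METRIC_COLUMNS
               if c in free.columns and c in stim.columns]
    out: dict = {"per_animal_change_pct": {}, "mean_change_pct": {},
                 "pooled_change_pct": {}}
    for metric in metrics:
        per_animal: dict[str, float] = {}
        for a in animals:
            f = free.loc[a, metric]
            if f == 0:
                warnings.warn(
                    f"animal {a!r} excluded from {metric}: zero free-condition mean",
                    stacklevel=2)
                continue
            per_animal[a] = (stim.loc[a, metric] - f) / f * 100.0
        out["per_animal_change_pct"][metric] = per_animal
        if per_animal:
            out["mean_change_pct"][metric] = float(np.mean(list(per_animal.values())))
        f_pool = free[metric].mean()
        if f_pool != 0:
            out["pooled_change_pct"][metric] = float(
                (stim[metric].mean() - f_pool) / f_pool * 100.0)
    headline = {}
    if "search_rate" in out["mean_change_pct"]:
        headline["search_rate_increase_pct"] = round(out["mean_change_pct"]["search_rate"])
    if "distance" in out["mean_change_pct"]:
        headline["distance_increase_pct"] = round(out["mean_change_pct"]["distance"])
    if "stop_time" in out["mean_change_pct"]:
        headline["stop_time_reduction_pct"] = round(-out["mean_change_pct"]["stop_time"])
    out["headline"] = headline
    return out
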