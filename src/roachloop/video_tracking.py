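"""Camera pipeline: Gaussian smoothing, Canny edges, morphology, ellipse fit.

Recovers the body-center trajectory from grayscale frames.  Each frame
is smoothed, edge-detected, closed morphologically and hole-filled; the
largest connected component whose moment-ellipse axes fall inside the
configured bounds is kept, and a least-squares ellipse is fitted to its
contour to give the sub-pixel center of mass.  Pixel coordinates follow
the image convention (origin top-left, y downward); the calibration map
to normalized arena coordinates flips the y axis so arena "up" is +y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature, measure, morphology

from roachloop.config import SAMPLE_RATE_HZ

__all__ = ["TrackerConfig", "EllipseFit", "track_frame", "track_sequence",
           "pixels_to_normalized"]


@dataclass(frozen=True)
class TrackerConfig:
    """Tracker parameters and the pixel→normalized arena calibration."""

    center_px: tuple[float, float]
    radius_px: float
    gaussian_sigma_px: float = 1.5
    canny_low: float = 0.1
    canny_high: float = 0.3
    morphology_radius_px: int = 3
    min_axis_px: float = 2.0
    max_axis_px: float = 60.0

    def __post_init__(self) -> None:
        if not self.canny_low < self.canny_high:
            raise ValueError("require canny_low < canny_high")
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")


@dataclass(frozen=True)
class EllipseFit:
    """Per-frame fit; ``valid`` is False when no acceptable body was found."""

    cx_px: float
    cy_px: float
    major_px: float
    minor_px: float
    orientation_rad: float
    valid: bool


_INVALID = EllipseFit(np.nan, np.nan, np.nan, np.nan, np.nan, False)


def track_frame(frame: np.ndarray, config: TrackerConfig) -> EllipseFit:
    """Locate the body ellipse in one single-channel frame."""
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("frame must be a non-empty 2-D array")
    img = img / 255.0 if img.max() > 1.5 else img
    edges = feature.canny(img, sigma=config.gaussian_sigma_px,
                          low_threshold=config.canny_low,
                          high_threshold=config.canny_high)
    closed = morphology.closing(
        edges, morphology.disk(config.morphology_radius_px))
    filled = ndimage.binary_fill_holes(closed)
    labels = measure.label(filled)
    best = None
    for region in measure.regionprops(labels):
        major = region.axis_major_length / 2.0
        minor = region.axis_minor_length / 2.0
        if not (config.min_axis_px <= major <= config.max_axis_px):
            continue
        if best is None or region.area > best.area:
            best = region
    if best is None:
        return _INVALID
    cy, cx = best.centroid
    major = best.axis_major_length / 2.0
    minor = best.axis_minor_length / 2.0
    orient = best.orientation
    # refine with a least-squares ellipse fit on the component's contour
    mask = labels == best.label
    contours = measure.find_contours(mask.astype(float), 0.5)
    if contours:
        contour = max(contours, key=len)
        model = measure.EllipseModel.from_estimate(contour[:, ::-1])
        if model and np.all(np.isfinite(model.center)):
            xc, yc = model.center
            hi, lo = max(model.axis_lengths), min(model.axis_lengths)
            if (config.min_axis_px <= hi <= config.max_axis_px
                    and np.hypot(xc - cx, yc - cy) <= max(2.0, hi)):
                cx, cy, major, minor, orient = xc, yc, hi, lo, model.theta
    return EllipseFit(float(cx), float(cy), float(major), float(minor),
                      float(orient), True)


def pixels_to_normalized(cx_px, cy_px, config: TrackerConfig) -> np.ndarray:
    """Map pixel centers to normalized arena coordinates (y flipped up)."""
    x = (np.asarray(cx_px, float) - config.center_px[0]) / config.radius_px
    y = (config.center_px[1] - np.asarray(cy_px, float)) / config.radius_px
    return np.column_stack([x, y])


def track_sequence(frames, config: TrackerConfig, *,
                   frame_rate: float = SAMPLE_RATE_HZ) -> tuple[pd.DataFrame, int]:
    """Track a frame stack and return a normalized trajectory.

    Invalid frames hold the last valid position (causal gap filling);
    the number of invalid frames is returned alongside.  Raises if every
    frame is invalid.
    """
    fits = [track_frame(f, config) for f in frames]
    n_invalid = sum(1 for f in fits if not f.valid)
    if n_invalid == len(fits):
        raise ValueError("no frame produced a valid fit")
    first_valid = next(f for f in fits if f.valid)
    cx, cy = first_valid.cx_px, first_valid.cy_px
    centers = np.empty((len(fits), 2))
    for i, f in enumerate(fits):
        if f.valid:
            cx, cy = f.cx_px, f.cy_px
        centers[i] = (cx, cy)
    xy = pixels_to_normalized(centers[:, 0], centers[:, 1], config)
    traj = pd.DataFrame({"t": np.arange(len(fits)) / frame_rate,
                         "x": xy[:, 0], "y": xy[:, 1]})
    return traj, n_invalid
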