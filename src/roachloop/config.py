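"""Shared experimental constants and the arena geometry.

Every stage of the pipeline reads the sampling rate and arena geometry
from here; nothing else hard-codes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: IMU sampling rate in Hz. A 1.5-s analysis window holds 30 samples.
SAMPLE_RATE_HZ: float = 20.0

#: Trial duration of one open-field test, minutes.
TRIAL_MINUTES: float = 7.0


@dataclass(frozen=True)
class ArenaConfig:
    """Circular open-field arena, 80 cm diameter, normalized to the unit disk.

    The peripheral (thigmotaxis) zone is the 4-cm annulus along the wall;
    on a 40-cm radius that places the zone boundary at normalized radius
    (40 - 4) / 40 = 0.9.  ``d_min_cut`` is the virtual-sensor reach used by
    the search-rate metric, 0.1 of the normalized radius (4 cm).
    """

    radius_cm: float = 40.0
    peripheral_width_cm: float = 4.0
    grid_resolution: int = 100
    d_min_cut: float = 0.1
    normalized_radius: float = field(default=1.0, init=False)

    def __post_init__(self) -> None:
        if not self.radius_cm > self.peripheral_width_cm > 0:
            raise ValueError("require radius_cm > peripheral_width_cm > 0")
        if not 0 < self.d_min_cut < 1:
            raise ValueError("d_min_cut must lie in (0, 1)")
        if self.grid_resolution < 10:
            raise ValueError("grid_resolution must be >= 10")

    @property
    def zone_boundary(self) -> float:
        """Normalized radius separating central from peripheral zone."""
        return (self.radius_cm - self.peripheral_width_cm) / self.radius_cm
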