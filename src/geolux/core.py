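"""Shared containers and conventions.

Coordinates are signed decimal degrees, longitude in [-180, 180),
latitude positive north; all timestamps are UTC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
KM_PER_DEG = 2 * np.pi * EARTH_RADIUS_KM / 360.0  # 111.19 km at the equator


@dataclass
class LightSeries:
    """Timestamped light-level samples for one logger deployment.

    ``times`` is a monotone datetime64[ns] array (UTC) at fixed cadence,
    ``lux`` the recorded illuminance on a linear lux scale.
    ``no_twilight_dates`` lists civil dates on which the sun never crossed
    the simulator's reference angle (polar day/night).
    """

    times: np.ndarray
    lux: np.ndarray
    individual_id: str = ""
    no_twilight_dates: list = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.lux = np.asarray(self.lux, dtype=float)
        if self.times.shape != self.lux.shape:
            raise ValueError("times and lux must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > np.timedelta64(0, "ns")):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "lux": self.lux})


def wrap_lon(lon):
    """Wrap longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def validate_latlon(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any((lat < -90) | (lat > 90)):
        raise ValueError("latitude outside [-90, 90]")
    if np.any((lon < -180) | (lon >= 180)):
        raise ValueError("longitude outside [-180, 180)")
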