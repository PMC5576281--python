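"""Solar geometry and twilight handling.

Sun elevation is computed with a standard low-accuracy solar ephemeris
(USNO approximate solar coordinates: equation of time and declination
from a two-term equation of centre, then the hour-angle equation).
Accuracy is a few hundredths of a degree over 1990-2060, well inside the
tolerance that threshold geolocation needs (a 0.3 deg elevation error
maps to roughly one minute of twilight timing).

All times are UTC.  Longitudes are signed decimal degrees in [-180, 180),
latitudes positive north.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86400.0
MINUTES_PER_DAY = 1440.0

TwilightKind = Literal["sunrise", "sunset"]
TwilightQuality = Literal["ok", "interpolated", "flagged"]


@dataclass(frozen=True)
class TwilightEvent:
    """One detected or predicted threshold crossing.

    ``time`` is the UTC instant of the crossing, ``kind`` says whether the
    light was rising (sunrise) or falling (sunset), and ``quality`` flags
    events recovered from days with spurious extra crossings.
    """

    time: pd.Timestamp
    kind: TwilightKind
    quality: TwilightQuality = "ok"


def _as_utc_ns(times) -> np.ndarray:
    """Coerce scalar/array datetimes to a datetime64[ns] ndarray (UTC naive)."""
    t = pd.DatetimeIndex(np.atleast_1d(np.asarray(times, dtype="datetime64[ns]")))
    return t.values


def solar_coefficients(times) -> tuple[np.ndarray, np.ndarray]:
    """Equation of time (minutes) and solar declination (radians) at UTC times.

    Low-accuracy solar ephemeris (USNO approximate solar coordinates):
    mean anomaly and mean longitude linear in days since J2000, a
    two-term equation of centre, and a linear obliquity.  Good to a few
    hundredths of a degree across 1990-2060.
    """
    t = _as_utc_ns(times)
    # days since J2000.0 (2000-01-01 12:00 UTC)
    D = (t - np.datetime64("2000-01-01T12:00:00")) / np.timedelta64(1, "s") / 86400.0
    g = np.radians(357.529 + 0.98560028 * D)  # mean anomaly
    q = 280.459 + 0.98564736 * D  # mean longitude, deg
    L = np.radians(q + 1.915 * np.sin(g) + 0.020 * np.sin(2 * g))  # ecliptic lon
    eps = np.radians(23.439 - 0.00000036 * D)  # obliquity

    decl = np.arcsin(np.sin(eps) * np.sin(L))
    ra = np.degrees(np.arctan2(np.cos(eps) * np.sin(L), np.cos(L)))
    # equation of time = mean lon - right ascension, wrapped to +-180 deg
    eqtime = 4.0 * ((q - ra + 180.0) % 360.0 - 180.0)
    return eqtime, decl


def sun_elevation(times, lat, lon) -> np.ndarray | float:
    """Sun elevation angle (degrees, negative below horizon) at UTC ``times``.

    ``lat``/``lon`` may be scalars or arrays broadcastable against ``times``.
    Refraction is not applied; threshold calibration absorbs it into the
    sun-elevation angle.
    """
    t = _as_utc_ns(times)
    idx = pd.DatetimeIndex(t)
    eqtime, decl = solar_coefficients(t)
    minutes = (
        idx.hour.values * 60.0 + idx.minute.values + idx.second.values / 60.0
        + idx.microsecond.values / 6.0e7
    )
    lat_r = np.radians(np.asarray(lat, dtype=float))
    lon_d = np.asarray(lon, dtype=float)
    tst = minutes + eqtime + 4.0 * lon_d  # true solar time, minutes
    ha = np.radians(tst / 4.0 - 180.0)  # hour angle
    sin_el = np.sin(lat_r) * np.sin(decl) + np.cos(lat_r) * np.cos(decl) * np.cos(ha)
    el = np.degrees(np.arcsin(np.clip(sin_el, -1.0, 1.0)))
    if np.isscalar(lat) and np.ndim(times) == 0:
        return float(el[0])
    return el


def _hour_angle_deg(lat_deg, decl_rad, angle_deg):
    """Half day length as an hour angle in degrees; NaN where no crossing.

    Solves cos(h0) = (sin a - sin phi sin d) / (cos phi cos d).  Values
    outside [-1, 1] mean polar day (no sunset) or polar night (no sunrise).
    """
    phi = np.radians(np.asarray(lat_deg, dtype=float))
    a = np.radians(angle_deg)
    cos_h0 = (np.sin(a) - np.sin(phi) * np.sin(decl_rad)) / (
        np.cos(phi) * np.cos(decl_rad)
    )
    with np.errstate(invalid="ignore"):
        h0 = np.degrees(np.arccos(cos_h0))
    return h0, cos_h0


def day_length_minutes(lat_deg, decl_rad, angle_deg) -> np.ndarray:
    """Interval between threshold crossings, minutes; saturates at 0 / 1440.

    Polar night (sun never reaches ``angle_deg``) gives 0; polar day gives
    1440.  Vectorised over all arguments.
    """
    h0, cos_h0 = _hour_angle_deg(lat_deg, decl_rad, angle_deg)
    out = 8.0 * h0  # 2 * h0 deg * 4 min/deg
    out = np.where(cos_h0 >= 1.0, 0.0, out)
    out = np.where(cos_h0 <= -1.0, MINUTES_PER_DAY, out)
    return out


def predict_twilight(date, lat, lon, angle_deg=0.0, n_iter=3):
    """Predicted (sunrise, sunset) UTC instants for a calendar date.

    The hour-angle equation is inverted, then re-evaluated at the predicted
    instant so the equation of time and declination are self-consistent
    (three iterations reach well under 0.05 deg of elevation error).

    Returns ``(None, None)`` when the sun never crosses ``angle_deg`` on
    that date (polar day / polar night at that angle).
    """
    day = pd.Timestamp(date).normalize()
    # initial guess: coefficients at local solar noon
    guess = day + pd.Timedelta(hours=12) - pd.Timedelta(minutes=4.0 * lon)
    sunrise = sunset = None
    t_rise, t_set = guess, guess
    for _ in range(n_iter):
        eq_r, decl_r = solar_coefficients(t_rise)
        h0, cos_h0 = _hour_angle_deg(lat, decl_r[0], angle_deg)
        if not (-1.0 < cos_h0 < 1.0):
            return None, None
        rise_min = 720.0 - 4.0 * (lon + h0) - eq_r[0]
        t_rise = day + pd.Timedelta(minutes=float(rise_min))
        eq_s, decl_s = solar_coefficients(t_set)
        h0s, cos_h0s = _hour_angle_deg(lat, decl_s[0], angle_deg)
        if not (-1.0 < cos_h0s < 1.0):
            return None, None
        set_min = 720.0 - 4.0 * (lon - h0s) - eq_s[0]
        t_set = day + pd.Timedelta(minutes=float(set_min))
    sunrise, sunset = t_rise, t_set
    return sunrise, sunset


def _interp_crossing_times(times_ns, lux, threshold):
    """Linear sub-sample interpolation of threshold crossings.

    Returns (crossing times as datetime64[ns], direction +1 up / -1 down).
    """
    lux = np.asarray(lux, dtype=float)
    below = lux < threshold
    up = below[:-1] & ~below[1:]
    down = ~below[:-1] & below[1:]
    idx = np.nonzero(up | down)[0]
    if idx.size == 0:
        return np.array([], dtype="datetime64[ns]"), np.array([], dtype=int)
    frac = (threshold - lux[idx]) / (lux[idx + 1] - lux[idx])
    dt_ns = (times_ns[idx + 1] - times_ns[idx]).astype("timedelta64[ns]").astype(float)
    cross = times_ns[idx] + (frac * dt_ns).astype("timedelta64[ns]")
    direction = np.where(up[idx], 1, -1)
    return cross, direction


def detect_twilights(
    series,
    threshold_lx: float = 3.0,
    guard_window_min: float = 30.0,
    lon_hint: float = 0.0,
) -> list[TwilightEvent]:
    """Detect sunrise/sunset threshold crossings in a light series.

    Crossing instants are linearly interpolated between the straddling
    samples.  Each local solar day (calendar date at longitude
    ``lon_hint``) yields at most one sunrise (the earliest upward crossing)
    and one sunset (the latest downward crossing); extra crossings --
    shading dips -- are collapsed onto those outermost crossings.  Extras
    within ``guard_window_min`` minutes of the kept crossing are treated as
    sampling jitter; extras farther away flag the kept event.

    ``lon_hint`` only steers day assignment, not timing; for tropical and
    temperate longitudes the default of 0 is safe anywhere the bird is
    within a few hours of the Greenwich solar day.
    """
    times_ns = np.asarray(series.times, dtype="datetime64[ns]")
    cross, direction = _interp_crossing_times(times_ns, series.lux, threshold_lx)
    if cross.size == 0:
        return []
    local = pd.DatetimeIndex(cross) + pd.Timedelta(hours=lon_hint / 15.0)
    local_date = local.normalize()
    events: list[TwilightEvent] = []
    guard = np.timedelta64(int(guard_window_min * 60e9), "ns")
    for day in pd.unique(local_date):
        in_day = local_date == day
        for kind, sign, pick in (("sunrise", 1, "first"), ("sunset", -1, "last")):
            sel = np.nonzero(in_day & (direction == sign))[0]
            if sel.size == 0:
                continue
            keep = sel[0] if pick == "first" else sel[-1]
            quality: TwilightQuality = "ok"
            if sel.size > 1:
                others = cross[sel[sel != keep]]
                if np.any(np.abs(others - cross[keep]) > guard):
                    quality = "flagged"
            events.append(TwilightEvent(pd.Timestamp(cross[keep]), kind, quality))
    events.sort(key=lambda e: e.time)
    return events


def pair_twilights(events: list[TwilightEvent]) -> list[tuple[TwilightEvent, TwilightEvent]]:
    """Pair each sunrise with the next sunset (one noon fix per day)."""
    pairs = []
    pending: TwilightEvent | None = None
    for ev in events:
        if ev.kind == "sunrise":
            pending = ev
        elif pending is not None:
            if ev.time > pending.time:
                pairs.append((pending, ev))
            pending = None
    return pairs


def twilights_to_frame(events: list[TwilightEvent]) -> pd.DataFrame:
    """Twilight list as a tidy frame (time, kind, quality) for CSV round-trips."""
    return pd.DataFrame(
        {
            "time": [e.time for e in events],
            "kind": [e.kind for e in events],
            "quality": [e.quality for e in events],
        }
    )


def twilights_from_frame(df: pd.DataFrame) -> list[TwilightEvent]:
    return [
        TwilightEvent(pd.Timestamp(r.time), r.kind, r.quality)
        for r in df.itertuples(index=False)
    ]
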