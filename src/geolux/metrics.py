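"""Migration-timing summaries and connectivity-spread statistics.

Distances follow the loxodrome (rhumb line, constant bearing) on a sphere
of radius 6371 km: along a shared parallel the distance reduces to
``dlon * R * cos(lat)``.  Population centres of mass are arithmetic means
of decimal degrees, valid for longitude spans well away from the
antimeridian (this study spans roughly -15 to +20 deg E).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import EARTH_RADIUS_KM, wrap_lon


# ---------------------------------------------------------------- rhumb lines

def _meridional(phi_rad):
    return np.log(np.tan(np.pi / 4 + phi_rad / 2))


def rhumb_distance(p1, p2, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Rhumb-line (loxodromic) distance in km between (lat, lon) points.

    Uses meridional parts; raises at the poles where they diverge.
    Symmetric, zero iff the points coincide, and never shorter than the
    great circle.
    """
    lat1, lon1 = float(p1[0]), float(p1[1])
    lat2, lon2 = float(p2[0]), float(p2[1])
    if abs(lat1) >= 90 or abs(lat2) >= 90:
        raise ValueError("rhumb distance undefined at the poles")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(wrap_lon(lon2 - lon1))
    dpsi = _meridional(phi2) - _meridional(phi1)
    q = dphi / dpsi if abs(dpsi) > 1e-12 else math.cos(phi1)
    return radius_km * math.hypot(dphi, q * dlam)


def rhumb_bearing(p1, p2) -> float:
    """Constant bearing (degrees clockwise from north) of the rhumb p1 -> p2."""
    phi1, phi2 = math.radians(p1[0]), math.radians(p2[0])
    dlam = math.radians(wrap_lon(p2[1] - p1[1]))
    dpsi = _meridional(phi2) - _meridional(phi1)
    return math.degrees(math.atan2(dlam, dpsi)) % 360.0


def rhumb_destination(lat, lon, bearing_deg, distance_km,
                      radius_km: float = EARTH_RADIUS_KM) -> tuple[float, float]:
    """End point of a rhumb line of given bearing and length from (lat, lon)."""
    if abs(lat) >= 90:
        raise ValueError("rhumb destination undefined at the poles")
    theta = math.radians(bearing_deg)
    delta = distance_km / radius_km
    phi1 = math.radians(lat)
    phi2 = phi1 + delta * math.cos(theta)
    if abs(phi2) >= math.pi / 2:
        raise ValueError("rhumb line runs off the pole")
    dpsi = _meridional(phi2) - _meridional(phi1)
    q = (phi2 - phi1) / dpsi if abs(dpsi) > 1e-12 else math.cos(phi1)
    dlam = delta * math.sin(theta) / q
    lon2 = wrap_lon(lon + math.degrees(dlam))
    return math.degrees(phi2), float(lon2)


# ------------------------------------------------------------- winter spread

def winter_spread(tracks: dict[str, pd.DataFrame], bin_days: int = 5,
                  start=None, end=None) -> pd.DataFrame:
    """Longitudinal spread of individuals around the population centre.

    ``tracks`` maps individual id -> daily fix frame with columns
    ``date``, ``lon``, ``lat``.  Time is cut into consecutive ``bin_days``
    intervals; each individual's centre of mass per interval is the
    arithmetic mean of its positions, the population centre longitude is
    the mean of the individual centre longitudes, and each individual's
    spread is the rhumb distance from the population-centre longitude to
    its own centre, measured along its own latitude.

    Bins holding a single individual get a missing spread (a centre of one
    is not a population).
    """
    frames = []
    for ind, df in tracks.items():
        d = df[["date", "lon", "lat"]].copy()
        d["individual"] = ind
        frames.append(d)
    if not frames:
        return pd.DataFrame(
            columns=["bin", "bin_start", "individual", "lat", "lon",
                     "centre_lon", "n_individuals", "distance_km"]
        )
    allf = pd.concat(frames, ignore_index=True)
    allf["date"] = pd.to_datetime(allf["date"])
    t0 = pd.Timestamp(start) if start is not None else allf["date"].min()
    if end is not None:
        allf = allf[allf["date"] <= pd.Timestamp(end)]
    allf = allf[allf["date"] >= t0]
    allf["bin"] = ((allf["date"] - t0).dt.days // bin_days).astype(int)

    cent = (
        allf.groupby(["bin", "individual"], as_index=False)
        .agg(lat=("lat", "mean"), lon=("lon", "mean"))
    )
    pop = cent.groupby("bin")["lon"].agg(["mean", "size"]).rename(
        columns={"mean": "centre_lon", "size": "n_individuals"}
    )
    cent = cent.merge(pop, on="bin")
    cent["bin_start"] = t0 + pd.to_timedelta(cent["bin"] * bin_days, unit="D")

    def _dist(row):
        if row["n_individuals"] < 2 or not np.isfinite(row["lat"]):
            return np.nan
        return rhumb_distance((row["lat"], row["centre_lon"]), (row["lat"], row["lon"]))

    cent["distance_km"] = cent.apply(_dist, axis=1)
    return cent[["bin", "bin_start", "individual", "lat", "lon",
                 "centre_lon", "n_individuals", "distance_km"]].sort_values(
        ["bin", "individual"]
    ).reset_index(drop=True)


# --------------------------------------------------------- detour projection

def project_detour_latitude(start_lat: float, start_lon: float,
                            westernmost_lon: float, elapsed_days: float,
                            speed_km_day: float = 300.0) -> float:
    """Latitude reached at the westernmost longitude of a coastal detour.

    The bird is assumed to leave the last European staging site and travel
    along a single rhumb line at ``speed_km_day`` for ``elapsed_days``; the
    bearing is solved so that the leg ends exactly at ``westernmost_lon``
    (which must lie west of the start).  The latitude of that end point is
    returned.  Used to place the detour turn when the equinox masks
    latitude.
    """
    if speed_km_day <= 0:
        raise ValueError("speed must be positive")
    dlon = wrap_lon(westernmost_lon - start_lon)
    if elapsed_days == 0:
        if abs(dlon) > 1e-9:
            raise ValueError("zero travel time cannot reach a different longitude")
        return float(start_lat)
    if dlon >= 0:
        raise ValueError("westernmost longitude must lie west of the start")
    dist = speed_km_day * elapsed_days

    def lon_err(bearing):
        return wrap_lon(rhumb_destination(start_lat, start_lon, bearing, dist)[1]
                        - westernmost_lon)

    # southwest quadrant: bearings between due south and due west
    lo, hi = 180.0 + 1e-6, 270.0 - 1e-6
    try:
        f_lo, f_hi = lon_err(lo), lon_err(hi)
    except ValueError as exc:
        raise ValueError(f"detour leg unreachable: {exc}") from exc
    if f_lo * f_hi > 0:
        raise ValueError(
            "westernmost longitude unreachable at this speed/duration "
            f"(need dlon={dlon:.2f} deg in {elapsed_days:.1f} d at {speed_km_day} km/day)"
        )
    bearing = brentq(lon_err, lo, hi, xtol=1e-10)
    return rhumb_destination(start_lat, start_lon, bearing, dist)[0]


def westernmost_longitude(fixes: pd.DataFrame, n: int = 3) -> float:
    """Mean longitude of the ``n`` westernmost fixes (detour-turn smoother)."""
    lons = np.sort(np.asarray(fixes["lon"], dtype=float))
    if lons.size == 0:
        raise ValueError("no fixes")
    return float(np.mean(lons[: min(n, lons.size)]))


# -------------------------------------------------------------- timing table

@dataclass
class TrackTiming:
    """Per-individual migration timing extracted from labelled periods."""

    individual: str
    departure_breeding: pd.Timestamp | None
    arrival_winter: pd.Timestamp | None
    duration_days: float
    n_staging_sites_banded: int  # staging periods of 5-12 days duration
    n_staging_sites_total: int
    staging_days_before_sahara: int
    staging_days_after_sahara: int


def _period_days(p) -> int:
    return (p.end - p.start).days + 1


def track_timing(individual: str, periods, sahara_lat: float = 20.0,
                 staging_band=(5, 12)) -> TrackTiming:
    """Timing summary for one track from its labelled stationary periods.

    Breeding departure is the end of the breeding period, winter arrival
    the start of the first winter period.  Staging periods are split at the
    Sahara by their median latitude (north/south of ``sahara_lat``); a
    staging period with masked latitude inherits the side of its
    predecessor.
    """
    breeding = [p for p in periods if p.label == "breeding"]
    winter = [p for p in periods if p.label == "winter"]
    staging = [p for p in periods if p.label == "staging"]
    dep = breeding[-1].end if breeding else None
    arr = winter[0].start if winter else None
    dur = float((arr - dep).days) if dep is not None and arr is not None else np.nan
    before = after = 0
    side_north = True
    for p in staging:
        if p.median_lat is not None and np.isfinite(p.median_lat):
            side_north = p.median_lat >= sahara_lat
        days = _period_days(p)
        if side_north:
            before += days
        else:
            after += days
    lo, hi = staging_band
    banded = sum(1 for p in staging if lo <= _period_days(p) <= hi)
    return TrackTiming(individual, dep, arr, dur, banded, len(staging), before, after)


def timing_table(timings: list[TrackTiming]) -> pd.DataFrame:
    """Population summary: mean (+-SD), median, min, max per migration event.

    Dates are summarised on the day-of-year scale and reported as dates of
    a nominal year; durations and counts are in their natural units.
    """
    rows = []

    def _date_row(name, dates):
        dates = [d for d in dates if d is not None]
        if not dates:
            rows.append({"event": name, "mean": np.nan, "sd": np.nan,
                         "median": np.nan, "min": np.nan, "max": np.nan, "n": 0})
            return
        doy = np.array([d.dayofyear + (d.hour / 24.0) for d in dates], dtype=float)
        year = dates[0].year

        def fmt(v):
            return (pd.Timestamp(year=year, month=1, day=1)
                    + pd.Timedelta(days=float(v) - 1)).strftime("%d %b")

        rows.append({"event": name, "mean": fmt(doy.mean()),
                     "sd": float(doy.std(ddof=1)) if doy.size > 1 else np.nan,
                     "median": fmt(np.median(doy)), "min": fmt(doy.min()),
                     "max": fmt(doy.max()), "n": len(dates)})

    def _num_row(name, vals):
        vals = np.asarray([v for v in vals if np.isfinite(v)], dtype=float)
        if vals.size == 0:
            rows.append({"event": name, "mean": np.nan, "sd": np.nan,
                         "median": np.nan, "min": np.nan, "max": np.nan, "n": 0})
            return
        rows.append({"event": name, "mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                     "median": float(np.median(vals)), "min": float(vals.min()),
                     "max": float(vals.max()), "n": int(vals.size)})

    _date_row("Departure breeding", [t.departure_breeding for t in timings])
    _date_row("Arrival winter", [t.arrival_winter for t in timings])
    _num_row("Migration duration (days)", [t.duration_days for t in timings])
    _num_row("Number of staging sites (5-12 days)",
             [float(t.n_staging_sites_banded) for t in timings])
    _num_row("Duration of staging before Sahara (days)",
             [float(t.staging_days_before_sahara) for t in timings])
    _num_row("Duration of staging after Sahara (days)",
             [float(t.staging_days_after_sahara) for t in timings])
    return pd.DataFrame(rows)
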