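"""Threshold-method position estimation and sun-elevation calibration.

Longitude comes from the midpoint of a sunrise/sunset pair (local solar
noon against 12:00 UTC, equation-of-time corrected -- omitting that
correction would inject a seasonal bias of up to about 1 deg).  Latitude
comes from the day length between the two threshold crossings, solved on
the closed-form day-length equation at the calibrated sun-elevation
angle.  Near the equinoxes day length is almost independent of latitude;
fixes whose day-length sensitivity falls below a conditioning floor are
reported with missing latitude while longitude is kept -- the reason
threshold geolocation discards only latitude around the equinoxes.

Calibration scans a grid of candidate angles (default [-6, +1] in 0.25
deg steps).  Hill-Ekstrom calibration picks the angle minimising the
latitude variance over known-stationary windows; known-site calibration
minimises the RMS distance to a known location instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import astro
from .core import wrap_lon
from .metrics import rhumb_distance

DEFAULT_ANGLE_GRID = np.round(np.arange(-6.0, 1.0 + 1e-9, 0.25), 4)


class CalibrationError(RuntimeError):
    """Raised when no scanned angle yields enough valid latitudes."""


@dataclass(frozen=True)
class PositionFix:
    """One twilight-pair position estimate."""

    date: pd.Timestamp
    longitude: float
    latitude: float  # NaN when masked or degenerate
    lat_masked_equinox: bool = False
    outlier: bool = False
    degenerate: bool = False
    sunrise: pd.Timestamp | None = None
    sunset: pd.Timestamp | None = None
    quality: str = "ok"


@dataclass
class CalibrationResult:
    """Chosen sun-elevation angle and the per-angle objective curve."""

    chosen_angle: float
    objective_curve: pd.Series  # index: angle (deg); values: objective
    method: str  # "hill_ekstrom" | "known_site"
    n_windows_used: int = 0
    diagnostics: dict = field(default_factory=dict)


def latitude_from_day_length(day_length_min, decl_rad, angle_deg,
                             conditioning_floor_min_per_deg: float = 1.0,
                             n_iter: int = 55):
    """Latitude(s) whose day length at the threshold angle matches the data.

    Vectorised bisection on the closed-form day-length equation.  Uses the
    symmetry D(phi, decl) = D(-phi, -decl) to reduce to a monotone
    problem.  Solutions where |d(day length)/d(lat)| falls below the
    conditioning floor (default 1 min/deg -- the equinox degeneracy), or
    where no latitude reproduces the day length, come back as NaN.
    """
    D = np.atleast_1d(np.asarray(day_length_min, dtype=float))
    decl = np.atleast_1d(np.asarray(decl_rad, dtype=float))
    D, decl = np.broadcast_arrays(D, decl)
    sign = np.where(decl < 0, -1.0, 1.0)
    dabs = np.abs(decl)
    lo = np.full(D.shape, -89.9)
    hi = np.full(D.shape, 89.9)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        f = astro.day_length_minutes(mid, dabs, angle_deg)
        too_low = f < D
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    phi = 0.5 * (lo + hi)
    resid = np.abs(astro.day_length_minutes(phi, dabs, angle_deg) - D)
    dDdphi = (astro.day_length_minutes(phi + 0.5, dabs, angle_deg)
              - astro.day_length_minutes(phi - 0.5, dabs, angle_deg))
    bad = (resid > 0.5) | (np.abs(dDdphi) < conditioning_floor_min_per_deg)
    out = np.where(bad, np.nan, sign * phi)
    return out if np.ndim(day_length_min) else float(out[0])


def _pair_arrays(pairs):
    sr = np.array([p[0].time.to_datetime64() for p in pairs], dtype="datetime64[ns]")
    ss = np.array([p[1].time.to_datetime64() for p in pairs], dtype="datetime64[ns]")
    if np.any(ss <= sr):
        raise ValueError("each sunset must follow its sunrise")
    mid = sr + (ss - sr) / 2
    day_len = (ss - sr).astype("timedelta64[s]").astype(float) / 60.0
    eqtime, decl = astro.solar_coefficients(mid)
    return sr, ss, mid, day_len, eqtime, decl


def positions_from_pairs(pairs, angle_deg: float,
                         conditioning_floor_min_per_deg: float = 1.0) -> pd.DataFrame:
    """Position fixes for a list of (sunrise, sunset) twilight pairs.

    Returns one row per pair: date (local solar date of the fix), lon, lat
    (NaN where degenerate), flags and the source twilights.  Longitude is
    always present; latitude may be missing.
    """
    if not pairs:
        return pd.DataFrame(columns=["date", "lon", "lat", "lat_masked_equinox",
                                     "outlier", "degenerate", "sunrise", "sunset",
                                     "quality"])
    sr, ss, mid, day_len, eqtime, decl = _pair_arrays(pairs)
    idx = pd.DatetimeIndex(mid)
    minutes = (idx.hour.values * 60.0 + idx.minute.values
               + idx.second.values / 60.0 + idx.microsecond.values / 6.0e7)
    lon = wrap_lon((720.0 - minutes - eqtime) / 4.0)
    lat = latitude_from_day_length(day_len, decl, angle_deg,
                                   conditioning_floor_min_per_deg)
    lat = np.atleast_1d(lat)
    # fix date: local solar calendar date at the estimated longitude
    local = idx + pd.to_timedelta(lon / 15.0, unit="h")
    quality = ["ok" if (p[0].quality == "ok" and p[1].quality == "ok") else "flagged"
               for p in pairs]
    return pd.DataFrame({
        "date": local.normalize(),
        "lon": lon,
        "lat": lat,
        "lat_masked_equinox": False,
        "outlier": False,
        "degenerate": ~np.isfinite(lat),
        "sunrise": sr,
        "sunset": ss,
        "quality": quality,
    })


def position_from_pair(sunrise: astro.TwilightEvent, sunset: astro.TwilightEvent,
                       angle_deg: float) -> PositionFix:
    """Single-pair convenience wrapper around :func:`positions_from_pairs`."""
    row = positions_from_pairs([(sunrise, sunset)], angle_deg).iloc[0]
    return PositionFix(row["date"], float(row["lon"]), float(row["lat"]),
                       degenerate=bool(row["degenerate"]),
                       sunrise=sunrise.time, sunset=sunset.time,
                       quality=row["quality"])


def _equinox_mask_dates(dates: pd.DatetimeIndex, window_days: int) -> np.ndarray:
    from .segment import equinox_dates  # local import avoids a cycle
    eqs = equinox_dates(range(dates.year.min() - 1, dates.year.max() + 2))
    mask = np.zeros(len(dates), dtype=bool)
    for eq in eqs:
        mask |= np.abs((dates - eq).days) <= window_days
    return mask


def _resolve_pairs(series_or_pairs, threshold_lx, lon_hint=0.0):
    if isinstance(series_or_pairs, list):
        return series_or_pairs
    events = astro.detect_twilights(series_or_pairs, threshold_lx, lon_hint=lon_hint)
    return astro.pair_twilights(events)


def _lat_matrix(pairs, angle_grid):
    """Latitude of every pair at every candidate angle: shape (n_angles, n_pairs)."""
    _, _, mid, day_len, _, decl = _pair_arrays(pairs)
    angles = np.asarray(angle_grid, dtype=float)
    lats = np.empty((angles.size, day_len.size))
    for i, a in enumerate(angles):
        lats[i] = latitude_from_day_length(day_len, decl, a)
    dates = (pd.DatetimeIndex(mid)).normalize()
    return angles, lats, dates


def _argmin_tie_toward_zero(angles: np.ndarray, objective: np.ndarray) -> float:
    finite = np.isfinite(objective)
    if not finite.any():
        raise CalibrationError("objective not finite at any scanned angle")
    best = np.nanmin(objective[finite])
    ties = finite & (objective <= best * (1 + 1e-12) + 1e-15)
    return float(angles[np.nonzero(ties)[0].max()])  # least-negative angle wins


def calibrate_hill_ekstrom(series_or_pairs, stationary_windows,
                           angle_grid=None, threshold_lx: float = 3.0,
                           equinox_window_days: int = 10,
                           min_latitudes: int = 5) -> CalibrationResult:
    """Choose the sun-elevation angle minimising stationary latitude variance.

    ``stationary_windows`` is a list of (start, end) date ranges during
    which the bird is known (or assumed) not to move.  For each candidate
    angle the latitudes of all non-equinox fixes inside each window are
    computed; the objective is the summed per-window sample variance.
    Windows yielding fewer than ``min_latitudes`` finite latitudes at an
    angle are skipped at that angle; an angle with no usable window gets an
    infinite objective.  Ties in the argmin break toward the least
    negative angle.
    """
    pairs = _resolve_pairs(series_or_pairs, threshold_lx)
    if not pairs:
        raise CalibrationError("no twilight pairs to calibrate on")
    if angle_grid is None:
        angle_grid = DEFAULT_ANGLE_GRID
    angles, lats, dates = _lat_matrix(pairs, angle_grid)
    eq_mask = _equinox_mask_dates(dates, equinox_window_days)

    # variances are only comparable across angles when computed on the
    # same fixes, so each window uses only fixes whose latitude is finite
    # at every scanned angle; windows left with fewer than min_latitudes
    # such fixes (e.g. post-equinox stubs) drop out of the scan entirely.
    # Window variances combine df-weighted (the pooled within-window
    # variance): a plain sum lets a short noisy window drown out a long
    # well-conditioned residency.
    n_win = len(stationary_windows)
    var = np.full((n_win, angles.size), np.nan)
    dof = np.zeros(n_win)
    for w, (w0, w1) in enumerate(stationary_windows):
        w0, w1 = pd.Timestamp(w0), pd.Timestamp(w1)
        sel = np.asarray((dates >= w0) & (dates <= w1) & ~eq_mask)
        block = lats[:, sel]
        finite_all = np.isfinite(block).all(axis=0)
        if finite_all.sum() >= min_latitudes:
            var[w] = np.var(block[:, finite_all], axis=1, ddof=1)
            dof[w] = finite_all.sum() - 1
    usable = np.isfinite(var).all(axis=1)
    if not usable.any():
        raise CalibrationError(
            "no stationary window with enough well-conditioned latitudes")
    objective = (dof[usable, None] * var[usable]).sum(axis=0) / dof[usable].sum()
    n_windows = int(usable.sum())
    chosen = _argmin_tie_toward_zero(angles, objective)
    curve = pd.Series(objective, index=angles, name="latitude_variance")
    return CalibrationResult(chosen, curve, "hill_ekstrom", n_windows_used=n_windows)


def calibrate_known_site(series_or_pairs, known_lat: float, known_lon: float,
                         window, angle_grid=None, threshold_lx: float = 3.0,
                         equinox_window_days: int = 10,
                         min_fixes: int = 3) -> CalibrationResult:
    """Choose the angle minimising RMS distance to a known site.

    The comparator calibration: over a pre-departure window at the capture
    site, each candidate angle's fixes are scored by their root mean
    square rhumb distance (km) to the known location; the angle with the
    smallest RMS wins, ties toward the least negative angle.
    """
    w0, w1 = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if (w1 - w0).days + 1 < 5:
        raise CalibrationError("known-site calibration window shorter than 5 days")
    pairs = _resolve_pairs(series_or_pairs, threshold_lx, lon_hint=known_lon)
    if angle_grid is None:
        angle_grid = DEFAULT_ANGLE_GRID
    if not pairs:
        raise CalibrationError("no valid twilight pairs in calibration window")
    angles, lats, dates = _lat_matrix(pairs, angle_grid)
    _, _, mid, day_len, eqtime, _ = _pair_arrays(pairs)
    idx = pd.DatetimeIndex(mid)
    minutes = (idx.hour.values * 60.0 + idx.minute.values
               + idx.second.values / 60.0 + idx.microsecond.values / 6.0e7)
    lons = wrap_lon((720.0 - minutes - eqtime) / 4.0)
    eq_mask = _equinox_mask_dates(dates, equinox_window_days)
    sel = (dates >= w0) & (dates <= w1) & ~eq_mask
    if not sel.any():
        raise CalibrationError("no valid twilight pairs in calibration window")

    objective = np.full(angles.size, np.inf)
    for i in range(angles.size):
        la = lats[i, sel]
        lo = lons[sel]
        ok = np.isfinite(la)
        if ok.sum() < min_fixes:
            continue
        d2 = [rhumb_distance((known_lat, known_lon), (a, b)) ** 2
              for a, b in zip(la[ok], lo[ok])]
        objective[i] = float(np.sqrt(np.mean(d2)))
    chosen = _argmin_tie_toward_zero(angles, objective)
    curve = pd.Series(objective, index=angles, name="rms_distance_km")
    return CalibrationResult(chosen, curve, "known_site")
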