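"""Segmentation of daily fixes into stationary periods, plus masking rules.

A stationary (staging/winter) period is a maximal run of days with no
overall change in longitude: every daily longitude stays within
``dev_tol`` of the window median and the mean longitude of the first two
days differs from that of the last two by at most ``net_tol``.  Only
longitude enters the criterion -- latitude is unusable near the equinoxes
-- but period latitude statistics are reported.  Runs must span at least
``min_days`` calendar days (the >= 5-day staging rule).

Latitude is excluded within ten days of each equinox, and fixes more
than 10 deg from the period median longitude/latitude are discarded in a
single pass before period statistics are computed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

EQUINOX_MONTH_DAY = ((3, 20), (9, 22))


@dataclass
class StationaryPeriod:
    """A segmented stationary site with robust location and dates."""

    start: pd.Timestamp
    end: pd.Timestamp
    median_lon: float
    median_lat: float | None  # None/NaN when all latitudes masked
    lon_sd: float
    lat_sd: float
    label: str = "staging"  # breeding | staging | winter
    n_fixes_used: int = 0
    n_outliers_removed: int = 0

    @property
    def duration_days(self) -> int:
        return (self.end - self.start).days + 1


def equinox_dates(years) -> list[pd.Timestamp]:
    """March and September equinoxes (fixed to Mar 20 / Sep 22) for ``years``."""
    return [pd.Timestamp(year=y, month=m, day=d)
            for y in years for (m, d) in EQUINOX_MONTH_DAY]


def mask_equinox(fixes: pd.DataFrame, window_days: int = 10) -> pd.DataFrame:
    """Set latitude missing within ``window_days`` of each equinox.

    Longitude is untouched.  Returns a copy with ``lat`` NaN and
    ``lat_masked_equinox`` True on masked rows; the mask count is
    len(out[out.lat_masked_equinox]).
    """
    out = fixes.copy()
    if out.empty:
        if "lat_masked_equinox" not in out:
            out["lat_masked_equinox"] = pd.Series(dtype=bool)
        return out
    dates = pd.DatetimeIndex(pd.to_datetime(out["date"])).normalize()
    eqs = equinox_dates(range(dates.year.min() - 1, dates.year.max() + 2))
    mask = np.zeros(len(out), dtype=bool)
    for eq in eqs:
        mask |= np.abs((dates - eq).days) <= window_days
    out["lat"] = np.where(mask, np.nan, out["lat"].values)
    out["lat_masked_equinox"] = mask
    return out


def _window_feasible(lons_sorted: list, first2_mean: float, last2_mean: float,
                     dev_tol: float, net_tol: float) -> bool:
    n = len(lons_sorted)
    med = (lons_sorted[n // 2] if n % 2 else
           0.5 * (lons_sorted[n // 2 - 1] + lons_sorted[n // 2]))
    if lons_sorted[-1] - med > dev_tol or med - lons_sorted[0] > dev_tol:
        return False
    return abs(first2_mean - last2_mean) <= net_tol


def find_stationary(fixes: pd.DataFrame, min_days: int = 5,
                    dev_tol: float = 2.0, net_tol: float = 2.0) -> list[tuple[int, int]]:
    """Maximal no-overall-longitude-change windows, as (start, end) row indices.

    Greedy left-to-right: from each candidate start the window is extended
    to the farthest feasible end; a window is kept when it spans at least
    ``min_days`` calendar days, and the scan resumes after it.  Every kept
    window is maximal -- extending it either way violates a tolerance or
    runs into an already-kept window.  Date gaps inside the fix series are
    allowed; feasibility is evaluated on the fixes present.
    """
    if fixes.empty:
        return []
    dates = pd.DatetimeIndex(pd.to_datetime(fixes["date"])).normalize()
    lons = np.asarray(fixes["lon"], dtype=float)
    n = len(lons)
    windows: list[tuple[int, int]] = []
    i = 0
    while i < n:
        srt = [lons[i]]
        best_j = -1
        for j in range(i + 1, n):
            bisect.insort(srt, lons[j])
            first2 = lons[i] if j == i else float(np.mean(lons[i:i + 2]))
            last2 = float(np.mean(lons[max(i, j - 1):j + 1]))
            if _window_feasible(srt, first2, last2, dev_tol, net_tol):
                if (dates[j] - dates[i]).days + 1 >= min_days:
                    best_j = j
        if best_j >= 0:
            windows.append((i, best_j))
            i = best_j + 1
        else:
            i += 1
    return windows


def merge_windows(fixes: pd.DataFrame, windows: list[tuple[int, int]],
                  lon_tol: float = 2.0, max_gap_days: int = 3) -> list[tuple[int, int]]:
    """Merge adjacent windows that are really one stay split by noise.

    Longitude noise can break a long residency into several windows
    separated by a day or two of jitter.  Consecutive windows whose
    median longitudes differ by at most ``lon_tol`` and whose date gap is
    at most ``max_gap_days`` are re-joined; moves below the geolocation
    noise floor cannot be resolved anyway.
    """
    if not windows:
        return []
    dates = pd.DatetimeIndex(pd.to_datetime(fixes["date"])).normalize()
    lons = np.asarray(fixes["lon"], dtype=float)
    merged = [windows[0]]
    for (i, j) in windows[1:]:
        pi, pj = merged[-1]
        gap = (dates[i] - dates[pj]).days
        if (gap <= max_gap_days
                and abs(np.median(lons[i:j + 1]) - np.median(lons[pi:pj + 1]))
                <= lon_tol):
            merged[-1] = (pi, j)
        else:
            merged.append((i, j))
    return merged


def filter_outliers(period_fixes: pd.DataFrame, radius_deg: float = 10.0):
    """Drop fixes > ``radius_deg`` from the period median (single pass).

    A fix is removed iff its longitude deviates from the median longitude
    by strictly more than ``radius_deg``, or its latitude is present and
    deviates likewise from the median latitude.  Exactly-at-the-radius
    fixes are retained.  Returns (retained frame, n_removed); raises if
    nothing survives.
    """
    if len(period_fixes) < 3:
        raise ValueError("outlier filtering needs at least 3 fixes")
    lon = np.asarray(period_fixes["lon"], dtype=float)
    lat = np.asarray(period_fixes["lat"], dtype=float)
    med_lon = float(np.median(lon))
    finite = np.isfinite(lat)
    med_lat = float(np.median(lat[finite])) if finite.any() else np.nan
    bad = np.abs(lon - med_lon) > radius_deg
    if np.isfinite(med_lat):
        bad |= finite & (np.abs(lat - med_lat) > radius_deg)
    if bad.all():
        raise ValueError("all fixes removed as outliers; period unusable")
    retained = period_fixes.loc[~bad].copy()
    return retained, int(bad.sum())


def build_periods(fixes: pd.DataFrame, windows: list[tuple[int, int]],
                  outlier_radius_deg: float = 10.0) -> list[StationaryPeriod]:
    """Turn detected windows into periods with post-outlier-removal statistics."""
    periods = []
    for (i, j) in windows:
        sub = fixes.iloc[i:j + 1]
        if len(sub) >= 3:
            retained, n_removed = filter_outliers(sub, outlier_radius_deg)
        else:
            retained, n_removed = sub, 0
        lon = np.asarray(retained["lon"], dtype=float)
        lat = np.asarray(retained["lat"], dtype=float)
        lat = lat[np.isfinite(lat)]
        d = pd.DatetimeIndex(pd.to_datetime(retained["date"]))
        periods.append(StationaryPeriod(
            start=d.min(), end=d.max(),
            median_lon=float(np.median(lon)),
            median_lat=float(np.median(lat)) if lat.size else np.nan,
            lon_sd=float(np.std(lon, ddof=1)) if lon.size > 1 else 0.0,
            lat_sd=float(np.std(lat, ddof=1)) if lat.size > 1 else np.nan,
            n_fixes_used=int(len(retained)),
            n_outliers_removed=n_removed,
        ))
    return periods


def label_periods(periods: list[StationaryPeriod], sahara_lat: float = 20.0,
                  winter_min_days: int = 14, breeding_lon_tol: float = 2.0,
                  westernmost_lon: float | None = None,
                  east_of_turn_deg: float = 2.0,
                  turn_date=None) -> list[StationaryPeriod]:
    """Assign breeding / staging / winter labels by the calendar rule.

    The leading run of periods still at the deployment longitude (within
    ``breeding_lon_tol`` of the first period's median) is the breeding
    stay -- longitude noise can split a long residency into several
    windows, and all of them precede departure.  Winter opens at the
    first period that is south of the Sahara (median latitude below
    ``sahara_lat``; a masked latitude inherits the side of the previous
    period), lasts at least ``winter_min_days``, and lies clearly east
    (``east_of_turn_deg``) of the track's westernmost longitude -- the
    coastal detour turn, passed before winter settlement.  Everything
    from there on is winter, the rest is staging.  The 14-day winter
    floor separates brief post-Sahara staging (the 5-12 day band) from
    winter residency; both readings of the staging count are available
    downstream.
    """
    if not periods:
        return []
    labels = [""] * len(periods)
    lon0 = periods[0].median_lon
    k = 0
    while k < len(periods) and abs(periods[k].median_lon - lon0) <= breeding_lon_tol:
        labels[k] = "breeding"
        k += 1
    rest = list(range(k, len(periods)))
    # side of the Sahara: by median latitude where known; a fully masked
    # period is south when it starts after the detour turn (the turn is
    # already in the Sahel), otherwise it inherits the previous side
    south = np.zeros(len(periods), dtype=bool)
    s = False
    for i, p in enumerate(periods):
        if p.median_lat is not None and np.isfinite(p.median_lat):
            s = p.median_lat < sahara_lat
        elif turn_date is not None and p.start > pd.Timestamp(turn_date):
            s = True
        south[i] = s
    winter_at = None
    if rest:
        if westernmost_lon is None:
            westernmost_lon = min(periods[i].median_lon for i in rest)
        for i in rest:
            if (south[i] and periods[i].duration_days >= winter_min_days
                    and periods[i].median_lon
                    >= westernmost_lon + east_of_turn_deg):
                winter_at = i
                break
        if winter_at is None:  # no detour geometry: fall back to duration rule
            for i in rest:
                if south[i] and periods[i].duration_days >= winter_min_days:
                    winter_at = i
                    break
    for i in rest:
        labels[i] = ("winter" if winter_at is not None and i >= winter_at
                     else "staging")
    return [replace(p, label=l) for p, l in zip(periods, labels)]


def segment_track(fixes: pd.DataFrame, min_days: int = 5, dev_tol: float = 2.0,
                  net_tol: float = 2.0, equinox_window_days: int = 10,
                  outlier_radius_deg: float = 10.0, sahara_lat: float = 20.0,
                  winter_min_days: int = 14):
    """Full per-track segmentation: mask -> windows -> outliers -> labels.

    Returns (masked fixes, labelled periods).
    """
    masked = mask_equinox(fixes, equinox_window_days)
    windows = find_stationary(masked, min_days, dev_tol, net_tol)
    windows = merge_windows(masked, windows, lon_tol=dev_tol)
    periods = build_periods(masked, windows, outlier_radius_deg)
    lons = np.asarray(masked["lon"], dtype=float)
    west = turn_date = None
    if lons.size >= 3:
        order = np.argsort(lons)[:3]
        west = float(np.mean(lons[order]))
        turn_date = pd.to_datetime(masked["date"]).iloc[order].min()
    return masked, label_periods(periods, sahara_lat, winter_min_days,
                                 westernmost_lon=west, turn_date=turn_date)


def periods_to_frame(periods: list[StationaryPeriod],
                     individual_id: str = "") -> pd.DataFrame:
    rows = []
    for p in periods:
        rows.append({
            "individual_id": individual_id, "label": p.label,
            "start": p.start, "end": p.end, "duration_days": p.duration_days,
            "median_lon": p.median_lon, "median_lat": p.median_lat,
            "lon_sd": p.lon_sd, "lat_sd": p.lat_sd,
            "n_fixes_used": p.n_fixes_used,
            "n_outliers_removed": p.n_outliers_removed,
        })
    return pd.DataFrame(rows)
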