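"""NDVI extraction at winter sites and vegetation analyses.

Rasters are 16-day vegetation-index composites on a regular lat/lon grid
(MOD13C1-style), held as an xarray DataArray with dims (time, lat, lon)
and timestamped at composite start.  Site means are taken over pixels
whose centres fall inside a geodesic circle (great-circle distance on the
6371-km sphere) of the requested radius -- pixel-centre inclusion, not
area weighting, which at 0.05 deg resolution versus a 50 km radius agrees
with area weighting to within about one pixel ring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .core import EARTH_RADIUS_KM
from . import stats as glstats


@dataclass
class NDVIRaster:
    """Gridded NDVI time series; wraps an xarray DataArray (time, lat, lon)."""

    data: xr.DataArray

    def __post_init__(self):
        if tuple(self.data.dims) != ("time", "lat", "lon"):
            raise ValueError("NDVI raster must have dims (time, lat, lon)")
        t = pd.DatetimeIndex(self.data.time.values)
        if len(t) > 1 and not t.is_monotonic_increasing:
            raise ValueError("time axis must be strictly increasing")
        for ax in ("lat", "lon"):
            v = np.diff(self.data[ax].values)
            if v.size and (np.any(v <= 0) or not np.allclose(v, v[0], rtol=1e-6)):
                raise ValueError(f"{ax} axis must be uniformly increasing")

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data.time.values)

    @property
    def resolution(self) -> float:
        lat = self.data.lat.values
        return float(lat[1] - lat[0]) if lat.size > 1 else np.nan

    def to_netcdf(self, path) -> None:
        # NetCDF3 via the scipy engine; CF-style time axis
        self.data.to_dataset(name="ndvi").to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "NDVIRaster":
        ds = xr.open_dataset(path, engine="scipy")
        return cls(ds["ndvi"].load())


def _haversine_km(lat1, lon1, lat2, lon2):
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def extract_buffer_mean(raster: NDVIRaster, site, radius_km: float = 50.0,
                        date_range=None, site_name: str = "site") -> pd.DataFrame:
    """Mean NDVI within ``radius_km`` of a site, per composite.

    Returns a frame with columns ``date`` (composite start) and ``ndvi``.
    Raises when the buffer circle is not fully covered by the grid of
    pixel centres.  ``radius_km = 0`` degenerates to the single pixel
    containing the site.
    """
    lat0, lon0 = float(site[0]), float(site[1])
    lats = raster.data.lat.values
    lons = raster.data.lon.values
    res = raster.resolution
    rad_deg_lat = radius_km / 111.195
    rad_deg_lon = radius_km / (111.195 * max(np.cos(np.radians(lat0)), 1e-6))
    if (lat0 - rad_deg_lat < lats[0] - res / 2 or lat0 + rad_deg_lat > lats[-1] + res / 2
            or lon0 - rad_deg_lon < lons[0] - res / 2
            or lon0 + rad_deg_lon > lons[-1] + res / 2):
        raise ValueError(
            f"buffer of {radius_km} km around {site_name} ({lat0:.2f}, {lon0:.2f}) "
            "extends beyond the raster extent"
        )
    if radius_km == 0:
        i = int(np.argmin(np.abs(lats - lat0)))
        j = int(np.argmin(np.abs(lons - lon0)))
        vals = raster.data.values[:, i, j]
    else:
        # restrict to the bounding box before the geodesic test
        li = np.nonzero(np.abs(lats - lat0) <= rad_deg_lat + res)[0]
        lj = np.nonzero(np.abs(lons - lon0) <= rad_deg_lon + res)[0]
        glat, glon = np.meshgrid(lats[li], lons[lj], indexing="ij")
        inside = _haversine_km(lat0, lon0, glat, glon) <= radius_km
        if not inside.any():
            i = int(np.argmin(np.abs(lats - lat0)))
            j = int(np.argmin(np.abs(lons - lon0)))
            vals = raster.data.values[:, i, j]
        else:
            block = raster.data.values[:, li[0]:li[-1] + 1, lj[0]:lj[-1] + 1]
            vals = block[:, inside].mean(axis=1)
    out = pd.DataFrame({"date": raster.times, "ndvi": vals})
    if date_range is not None:
        # a composite [t, t + period) is kept when it overlaps the range,
        # so the composite covering the range start is included
        a, b = pd.Timestamp(date_range[0]), pd.Timestamp(date_range[1])
        t = raster.times
        period = (t[1] - t[0]) if len(t) > 1 else pd.Timedelta(days=16)
        out = out[(out["date"] + period > a) & (out["date"] <= b)]
    return out.reset_index(drop=True)


def within_site_trend(samples: pd.DataFrame):
    """OLS slope of NDVI per day and Pearson r of NDVI against time.

    ``samples`` needs columns ``date`` and ``ndvi`` with at least three
    composites.  Returns ``(slope_per_day, TestResult)``; for constant
    NDVI the slope is 0 and the correlation is reported missing.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 composites for a trend")
    t = (pd.to_datetime(samples["date"]) - pd.to_datetime(samples["date"]).min()
         ).dt.total_seconds().values / 86400.0
    y = np.asarray(samples["ndvi"], dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("constant time axis")
    slope = float(np.polyfit(t, y, 1)[0])
    if np.ptp(y) == 0:
        return 0.0, None
    return slope, glstats.pearson_r(t, y)


def between_site_change(periods, samples_by_period: dict) -> pd.DataFrame:
    """Per-move changes between consecutive winter sites of one track.

    For each move the NDVI change is the first composite mean at the new
    site minus the last composite mean at the old site (composites nearest
    each period's occupancy); latitude/longitude changes are differences
    of period medians.  Single-site tracks yield an empty frame.
    """
    winters = [p for p in periods if p.label == "winter"]
    rows = []
    for a, b in zip(winters[:-1], winters[1:]):
        sa = samples_by_period.get(id(a))
        sb = samples_by_period.get(id(b))
        if sa is None or sb is None or sa.empty or sb.empty:
            continue
        rows.append({
            "d_ndvi": float(sb["ndvi"].iloc[0]) - float(sa["ndvi"].iloc[-1]),
            "d_lat": (b.median_lat - a.median_lat)
            if (b.median_lat is not None and a.median_lat is not None) else np.nan,
            "d_lon": b.median_lon - a.median_lon,
        })
    return pd.DataFrame(rows, columns=["d_ndvi", "d_lat", "d_lon"])


def among_year_consistency(raster: NDVIRaster, sites, winters,
                           radius_km: float = 50.0,
                           winter_months=(11, 12, 1, 2)) -> pd.DataFrame:
    """Correlation of site-specific winter NDVI between winters.

    ``sites`` is a list of (lat, lon); ``winters`` a list of season-start
    years (a winter spans Nov of year y through Feb of y+1).  For each
    winter the mean NDVI over the winter months is taken per site, and
    Pearson r is computed between the site-vectors of every winter pair.
    Needs at least three sites for r to be defined.
    """
    sites = list(sites)
    if len(sites) < 3:
        raise ValueError("need at least 3 sites to correlate site vectors")
    times = raster.times
    mat = np.full((len(winters), len(sites)), np.nan)
    for j, site in enumerate(sites):
        series = extract_buffer_mean(raster, site, radius_km, site_name=f"site{j}")
        dates = pd.to_datetime(series["date"])
        for i, y in enumerate(winters):
            sel = ((dates >= pd.Timestamp(year=y, month=winter_months[0], day=1))
                   & (dates < pd.Timestamp(year=y + 1, month=3, day=1)))
            if sel.any():
                mat[i, j] = series.loc[sel.values, "ndvi"].mean()
    labels = [f"winter_{y}" for y in winters]
    out = pd.DataFrame(np.eye(len(winters)), index=labels, columns=labels)
    for i in range(len(winters)):
        for k in range(i + 1, len(winters)):
            ok = np.isfinite(mat[i]) & np.isfinite(mat[k])
            if ok.sum() >= 3 and np.ptp(mat[i, ok]) > 0 and np.ptp(mat[k, ok]) > 0:
                r = glstats.pearson_r(mat[i, ok], mat[k, ok]).statistic
            else:
                r = np.nan
            out.iloc[i, k] = out.iloc[k, i] = r
    return out
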