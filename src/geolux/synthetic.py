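"""Synthetic study generator: trajectories, light series, NDVI fields.

Emulates an archival-light-logger study of a small trans-Saharan migrant:
multi-site itineraries with movement legs at a fixed daily travel speed
(default 300 km/day, the assumed migration speed of the study species),
lux curves driven by solar elevation with shading and clock noise, bird
biometrics, and seasonal NDVI composites with a stable north-south
greenness gradient and a linear dry-season decline.

Everything is seeded and deterministic; see the individual generators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from . import astro
from .core import LightSeries, validate_latlon
from .environment import NDVIRaster
from .metrics import rhumb_bearing, rhumb_destination, rhumb_distance

# study conditions (capture site of the source study population)
CAPTURE_SITE = (55.61, 12.57)
DEFAULT_TRAVEL_SPEED = 300.0  # km/day


@dataclass(frozen=True)
class ShadingModel:
    """Noise surrogate for vegetation shading and logger clock error.

    Shading events attenuate light multiplicatively (they never brighten),
    so a shaded sunrise is detected late and a shaded sunset early -- the
    asymmetric twilight bias that sun-angle calibration must absorb.

    event_rate    events per day (Poisson)
    attenuation   multiplicative light reduction during an event, in (0, 1]
    clock_jitter  sd (minutes) of a per-twilight timing perturbation
    event_duration_min  mean event length, minutes
    """

    event_rate: float = 0.0
    attenuation: float = 0.2
    clock_jitter: float = 0.0
    event_duration_min: float = 90.0

    def __post_init__(self):
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")
        if not (0 < self.attenuation <= 1):
            raise ValueError("attenuation must be in (0, 1]")
        if self.clock_jitter < 0:
            raise ValueError("clock_jitter must be >= 0")


@dataclass(frozen=True)
class Site:
    """A stationary occupancy: position plus arrival/departure dates."""

    lat: float
    lon: float
    arrival: pd.Timestamp
    departure: pd.Timestamp
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "arrival", pd.Timestamp(self.arrival).normalize())
        object.__setattr__(self, "departure", pd.Timestamp(self.departure).normalize())
        validate_latlon(self.lat, self.lon)
        if self.departure < self.arrival:
            raise ValueError(f"site {self.name!r}: departure before arrival")


@dataclass(frozen=True)
class TrajectorySpec:
    """Ground-truth itinerary for one simulated individual."""

    individual_id: str
    sites: tuple
    travel_speed: float = DEFAULT_TRAVEL_SPEED
    shading: ShadingModel = field(default_factory=ShadingModel)
    seed: int = 0
    interpolation: str = "rhumb"  # or "greatcircle"

    def __post_init__(self):
        object.__setattr__(self, "sites", tuple(self.sites))
        if not self.sites:
            raise ValueError("need at least one site")
        if self.travel_speed <= 0:
            raise ValueError("travel_speed must be positive")
        for a, b in zip(self.sites[:-1], self.sites[1:]):
            if b.arrival <= a.departure:
                raise ValueError(
                    f"site intervals must be strictly ordered: "
                    f"{a.name!r} departs {a.departure.date()}, "
                    f"{b.name!r} arrives {b.arrival.date()}"
                )


def _greatcircle_point(s1: Site, s2: Site, frac: float) -> tuple[float, float]:
    """Spherical linear interpolation between two sites."""
    def vec(lat, lon):
        la, lo = math.radians(lat), math.radians(lon)
        return np.array([math.cos(la) * math.cos(lo), math.cos(la) * math.sin(lo),
                         math.sin(la)])
    v1, v2 = vec(s1.lat, s1.lon), vec(s2.lat, s2.lon)
    omega = math.acos(np.clip(np.dot(v1, v2), -1, 1))
    if omega < 1e-12:
        return s1.lat, s1.lon
    v = (math.sin((1 - frac) * omega) * v1 + math.sin(frac * omega) * v2) / math.sin(omega)
    return math.degrees(math.asin(v[2])), math.degrees(math.atan2(v[1], v[0]))


def simulate_trajectory(spec: TrajectorySpec) -> pd.DataFrame:
    """One (lat, lon) per UTC date from first arrival to last departure.

    Days inside a site's interval sit exactly at the site.  Days in the gap
    between consecutive sites are interpolated along the rhumb line (or
    great circle) at uniform fractions, and the gap must be long enough to
    cover the leg at ``travel_speed`` (ceil(distance / speed) days).
    """
    rows = []
    for i, site in enumerate(spec.sites):
        for d in pd.date_range(site.arrival, site.departure, freq="D"):
            rows.append((d, site.lat, site.lon))
        if i + 1 < len(spec.sites):
            nxt = spec.sites[i + 1]
            gap_days = (nxt.arrival - site.departure).days - 1
            dist = rhumb_distance((site.lat, site.lon), (nxt.lat, nxt.lon))
            need = math.ceil(dist / spec.travel_speed)
            if gap_days < need:
                raise ValueError(
                    f"leg {site.name or i!r} -> {nxt.name or i + 1!r}: "
                    f"{dist:.0f} km needs {need} travel days at "
                    f"{spec.travel_speed:.0f} km/day but only {gap_days} available"
                )
            bearing = rhumb_bearing((site.lat, site.lon), (nxt.lat, nxt.lon))
            for k in range(1, gap_days + 1):
                frac = k / (gap_days + 1)
                if spec.interpolation == "greatcircle":
                    la, lo = _greatcircle_point(site, nxt, frac)
                else:
                    la, lo = rhumb_destination(site.lat, site.lon, bearing, dist * frac)
                rows.append((site.departure + pd.Timedelta(days=k), la, lo))
    df = pd.DataFrame(rows, columns=["date", "lat", "lon"])
    df["individual_id"] = spec.individual_id
    return df.sort_values("date").reset_index(drop=True)


def simulate_light(
    truth: pd.DataFrame,
    shading: ShadingModel | None = None,
    sampling_interval_min: int = 5,
    seed: int = 0,
    reference_angle_deg: float = -1.5,
    threshold_anchor_lx: float = 3.0,
    decade_width_deg: float = 3.0,
    ceiling_lx: float = 10000.0,
    individual_id: str = "",
) -> LightSeries:
    """Light series for a daily ground-truth track.

    The noise-free lux curve is an exponential function of sun elevation,
    anchored so the light level equals ``threshold_anchor_lx`` exactly when
    the sun sits at ``reference_angle_deg`` (one decade of lux per
    ``decade_width_deg`` degrees of elevation), clipped at a full-sun
    ceiling.  The default transition width (3 deg per decade) keeps the
    linear-in-lux crossing interpolation accurate to well under a minute
    at the default 5-minute cadence.  Shading events multiply the curve by the attenuation factor,
    so they can only darken, delaying sunrise and advancing sunset at the
    threshold.  Clock jitter perturbs each day's morning and evening
    timing independently.

    Identical seeds give bit-identical series.  Days on which the sun
    never crosses the reference angle (polar day/night) are listed in
    ``no_twilight_dates``.
    """
    if shading is None:
        shading = ShadingModel()
    if 1440 % sampling_interval_min != 0:
        raise ValueError("sampling interval must divide 1440 minutes")
    if len(truth) == 0:
        raise ValueError("empty truth track")
    rng = np.random.default_rng(seed)
    n_per_day = 1440 // sampling_interval_min
    dates = pd.DatetimeIndex(pd.to_datetime(truth["date"])).normalize()
    lat = np.repeat(np.asarray(truth["lat"], dtype=float), n_per_day)
    lon = np.repeat(np.asarray(truth["lon"], dtype=float), n_per_day)
    offs = np.arange(n_per_day) * sampling_interval_min
    times = (np.repeat(dates.values, n_per_day)
             + np.tile(offs, len(dates)).astype("timedelta64[m]"))

    # clock jitter: per-day morning/evening shifts of the evaluation time
    eval_times = times
    if shading.clock_jitter > 0:
        jit = rng.normal(0.0, shading.clock_jitter, size=(len(dates), 2))
        local_hour = (times - np.repeat(dates.values, n_per_day)).astype(
            "timedelta64[m]").astype(float) / 60.0 + np.repeat(
            np.asarray(truth["lon"], dtype=float), n_per_day) / 15.0
        morning = (local_hour % 24.0) < 12.0
        day_idx = np.repeat(np.arange(len(dates)), n_per_day)
        shift_min = np.where(morning, jit[day_idx, 0], jit[day_idx, 1])
        eval_times = times + (shift_min * 60e9).astype("timedelta64[ns]")

    elev = astro.sun_elevation(eval_times, lat, lon)
    lux = threshold_anchor_lx * np.power(
        10.0, (elev - reference_angle_deg) / decade_width_deg
    )
    np.minimum(lux, ceiling_lx, out=lux)

    # shading events
    if shading.event_rate > 0:
        minutes_of_day = np.tile(offs.astype(float), len(dates))
        day_idx = np.repeat(np.arange(len(dates)), n_per_day)
        n_events = rng.poisson(shading.event_rate, size=len(dates))
        for di in np.nonzero(n_events)[0]:
            for _ in range(n_events[di]):
                start = rng.uniform(0.0, 1440.0)
                dur = rng.exponential(shading.event_duration_min)
                sel = (day_idx == di) & (minutes_of_day >= start) & (
                    minutes_of_day < start + dur)
                lux[sel] *= shading.attenuation

    # flag days without a reference-angle crossing
    elev_by_day = elev.reshape(len(dates), n_per_day)
    no_tw = ((elev_by_day.min(axis=1) >= reference_angle_deg)
             | (elev_by_day.max(axis=1) <= reference_angle_deg))
    no_twilight_dates = [d for d, f in zip(dates, no_tw) if f]

    return LightSeries(times.astype("datetime64[ns]"), lux,
                       individual_id=individual_id,
                       no_twilight_dates=no_twilight_dates)


# ------------------------------------------------------------- NDVI fields

@dataclass(frozen=True)
class SeasonalNDVIModel:
    """Spatially graded NDVI with a triangular wet/dry seasonal cycle.

    The dry season (1 Oct - 1 Mar) declines linearly at ``dry_slope``
    NDVI/day (default -0.0025/day, a typical Sahel dry-down rate); the wet
    season rises linearly back, making the cycle continuous.  The spatial
    field is greener toward the south (``lat_gradient`` < 0) and optionally
    graded west-east.  ``interannual_sd`` adds a per-winter random pixel
    field (destroys among-year consistency); ``noise_sd`` is white
    per-composite noise.
    """

    base: float = 0.45
    lat_gradient: float = -0.015  # NDVI per degree latitude
    lon_gradient: float = 0.0
    lat_ref: float = 12.0
    lon_ref: float = 0.0
    dry_slope: float = -0.0025  # NDVI per day during the dry season
    noise_sd: float = 0.0
    interannual_sd: float = 0.0


def _season_term(times: pd.DatetimeIndex, dry_slope: float) -> np.ndarray:
    """Triangle-wave seasonal anomaly, anchored at 1 Oct / 1 Mar."""
    out = np.empty(len(times))
    for i, t in enumerate(times):
        if t.month >= 10:
            dry0 = pd.Timestamp(year=t.year, month=10, day=1)
        elif t.month < 3:
            dry0 = pd.Timestamp(year=t.year - 1, month=10, day=1)
        else:
            dry0 = None
        if dry0 is not None:
            dry_len = (pd.Timestamp(year=dry0.year + 1, month=3, day=1) - dry0).days
            amp = abs(dry_slope) * dry_len / 2.0
            out[i] = amp + dry_slope * (t - dry0).days
        else:
            wet0 = pd.Timestamp(year=t.year, month=3, day=1)
            wet_len = (pd.Timestamp(year=t.year, month=10, day=1) - wet0).days
            dry_len = (wet0 - pd.Timestamp(year=wet0.year - 1, month=10, day=1)).days
            amp = abs(dry_slope) * dry_len / 2.0
            out[i] = -amp + (2 * amp / wet_len) * (t - wet0).days
    return out


def simulate_ndvi_raster(
    extent: tuple[float, float, float, float],
    start,
    end,
    resolution: float = 0.05,
    composite_days: int = 16,
    model: SeasonalNDVIModel | None = None,
    seed: int = 0,
) -> NDVIRaster:
    """16-day NDVI composites over ``extent`` = (lat_min, lat_max, lon_min, lon_max).

    Composites are timestamped at period start, values clipped to [-1, 1].
    Deterministic given ``seed``; with zero noise the within-pixel
    dry-season regression slope equals the configured ``dry_slope``
    exactly (the seasonal term is piecewise linear in time).
    """
    if model is None:
        model = SeasonalNDVIModel()
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    lat_min, lat_max, lon_min, lon_max = extent
    if lat_max <= lat_min or lon_max <= lon_min:
        raise ValueError("degenerate extent")
    rng = np.random.default_rng(seed)
    lats = np.arange(lat_min + resolution / 2, lat_max, resolution)
    lons = np.arange(lon_min + resolution / 2, lon_max, resolution)
    times = pd.date_range(pd.Timestamp(start).normalize(), pd.Timestamp(end),
                          freq=f"{composite_days}D")
    spatial = (model.base
               + model.lat_gradient * (lats[:, None] - model.lat_ref)
               + model.lon_gradient * (lons[None, :] - model.lon_ref)
               ).astype(np.float32)
    season = _season_term(times, model.dry_slope).astype(np.float32)

    # winter-season index (Jul-Jun) for interannual fields
    season_year = np.array([t.year if t.month >= 7 else t.year - 1 for t in times])
    uniq_years = np.unique(season_year)
    year_fields = {
        y: (rng.normal(0.0, model.interannual_sd, size=(lats.size, lons.size))
            .astype(np.float32) if model.interannual_sd > 0
            else np.zeros((lats.size, lons.size), dtype=np.float32))
        for y in uniq_years
    }
    vals = np.empty((len(times), lats.size, lons.size), dtype=np.float32)
    for i, t in enumerate(times):
        vals[i] = spatial + season[i] + year_fields[season_year[i]]
    if model.noise_sd > 0:
        vals += rng.normal(0.0, model.noise_sd, size=vals.shape).astype(np.float32)
    np.clip(vals, -1.0, 1.0, out=vals)
    da = xr.DataArray(vals, coords={"time": times, "lat": lats, "lon": lons},
                      dims=("time", "lat", "lon"), name="ndvi")
    return NDVIRaster(da)


# ------------------------------------------------------------ study builder

@dataclass
class StudySimulation:
    """A full synthetic deployment: specs, truth tracks and biometrics."""

    specs: dict
    truth: dict  # individual_id -> daily (date, lat, lon) frame
    biometrics: pd.DataFrame  # id, capture_lat, capture_lon, mass_g, wing_mm, year
    moved_to_second_site: dict  # individual_id -> bool


def _days(dist_km: float, speed: float) -> int:
    return max(1, math.ceil(dist_km / speed))


def make_study(
    n_birds: int = 15,
    seed: int = 0,
    years: tuple[int, int] = (2014, 2015),
    shading: ShadingModel | None = None,
    travel_speed: float = DEFAULT_TRAVEL_SPEED,
    n_movers: int | None = None,
) -> StudySimulation:
    """Synthetic multi-bird study shaped like the source deployment.

    Each bird breeds at the capture site (55.61 N, 12.57 E), departs in
    early August, stages in Iberia, detours along the West African coast
    to a westernmost turn near -14.4 deg E at ~11.7 deg N, then moves east
    to a first winter site with longitude drawn uniformly on
    [-11.5, 19.7] deg (the spread regime of the study population).  Most
    birds (default 12 of 15) later shift to a second winter site south and
    east of the first.  The Iberia -> turn leg runs at exactly
    ``travel_speed`` so the detour projection is recoverable; European
    passage includes slack days (real passage is slower than flight days).
    """
    if shading is None:
        shading = ShadingModel()
    if n_movers is None:
        n_movers = min(12, n_birds)
    rng = np.random.default_rng(seed)
    specs: dict[str, TrajectorySpec] = {}
    truth: dict[str, pd.DataFrame] = {}
    moved: dict[str, bool] = {}
    bio_rows = []
    mover_flags = np.zeros(n_birds, dtype=bool)
    mover_flags[:n_movers] = True
    rng.shuffle(mover_flags)

    for b in range(n_birds):
        ind = f"ww{b + 1:02d}"
        year = years[b % len(years)]
        dep_b = pd.Timestamp(year=year, month=8, day=3) + pd.Timedelta(
            days=int(round(rng.normal(0, 6))))
        breeding = Site(*CAPTURE_SITE, pd.Timestamp(year=year, month=5, day=25),
                        dep_b, name="breeding")

        ib_lat = rng.normal(40.0, 1.2)
        ib_lon = rng.normal(-4.5, 1.5)
        d1 = rhumb_distance(CAPTURE_SITE, (ib_lat, ib_lon))
        ib_arr = dep_b + pd.Timedelta(days=_days(d1, travel_speed) + 1)
        stay_ib = int(np.clip(round(rng.normal(13.6, 5.0)), 7, 34))
        iberia = Site(ib_lat, ib_lon, ib_arr, ib_arr + pd.Timedelta(days=stay_ib - 1),
                      name="iberia")

        turn_lat = rng.normal(11.7, 0.8)
        turn_lon = rng.normal(-14.4, 1.4)
        d2 = rhumb_distance((ib_lat, ib_lon), (turn_lat, turn_lon))
        # this leg runs at exactly travel_speed: gap = ceil(dist / speed)
        turn_arr = iberia.departure + pd.Timedelta(days=_days(d2, travel_speed) + 1)
        stay_turn = int(np.clip(round(abs(rng.normal(0, 6.9)) - 2), 0, 21))
        turn = Site(turn_lat, turn_lon, turn_arr,
                    turn_arr + pd.Timedelta(days=max(stay_turn - 1, 0)), name="sahel_turn")

        w1_lon = rng.uniform(-11.5, 19.7)
        w1_lat = rng.normal(10.3, 1.2)
        d3 = rhumb_distance((turn_lat, turn_lon), (w1_lat, w1_lon))
        w1_arr = turn.departure + pd.Timedelta(days=_days(d3, travel_speed) + 1)
        track_end = pd.Timestamp(year=year + 1, month=2, day=20)
        is_mover = bool(mover_flags[b])
        sites = [breeding, iberia, turn]
        if is_mover:
            stay_w1 = int(np.clip(round(rng.normal(50, 12)), 25, 75))
            w1_dep = w1_arr + pd.Timedelta(days=stay_w1 - 1)
            # itinerancy moves below the threshold method's ~2 deg
            # longitudinal resolution would be invisible to the analysis,
            # so simulated moves stay above it (as any detected move must)
            w2_lat = w1_lat - float(np.clip(abs(rng.normal(1.8, 0.7)), 1.0, 4.0))
            w2_lon = min(w1_lon + float(np.clip(abs(rng.normal(3.5, 1.5)), 2.5, 8.0)),
                         23.0)
            d4 = rhumb_distance((w1_lat, w1_lon), (w2_lat, w2_lon))
            w2_arr = w1_dep + pd.Timedelta(days=_days(d4, travel_speed) + 1)
            sites += [Site(w1_lat, w1_lon, w1_arr, w1_dep, name="winter1"),
                      Site(w2_lat, w2_lon, w2_arr, track_end, name="winter2")]
        else:
            sites += [Site(w1_lat, w1_lon, w1_arr, track_end, name="winter1")]

        spec = TrajectorySpec(ind, tuple(sites), travel_speed=travel_speed,
                              shading=shading,
                              seed=int(rng.integers(0, 2 ** 31 - 1)))
        specs[ind] = spec
        truth[ind] = simulate_trajectory(spec)
        moved[ind] = is_mover
        bio_rows.append({
            "individual_id": ind,
            "capture_lat": CAPTURE_SITE[0], "capture_lon": CAPTURE_SITE[1],
            "mass_g": float(rng.normal(9.3, 0.6)),
            "wing_mm": float(rng.normal(68.0, 1.5)),
            "year": year,
        })
    return StudySimulation(specs, truth, pd.DataFrame(bio_rows), moved)
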