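"""Study configuration, file formats, and end-to-end orchestration.

``StudyConfig`` aggregates every analysis constant at its published
default (3 lx threshold, equinox window of ten days, 10-deg outlier
radius, 50-km NDVI buffer, 300 km/day travel speed, five-day spread
bins, five-day minimum staging).  ``run_study`` chains
simulate -> geolocate -> segment -> metrics/environment/stats into one
reproducible bundle with a manifest whose record counts reconcile across
every filtering stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import environment as env
from . import metrics, segment
from . import stats as glstats
from . import synthetic
from .core import LightSeries


@dataclass
class StudyConfig:
    """All tunable analysis and simulation constants (units in names)."""

    # threshold geolocation
    threshold_lx: float = 3.0
    angle_grid: tuple | None = None  # None -> [-6, +1] step 0.25
    guard_window_min: float = 30.0
    calibration_days: int = 30
    # masking / segmentation
    equinox_window_days: int = 10
    calibration_equinox_buffer_days: int = 25
    calibration_max_lat: float = 35.0
    calibration_min_fixes: int = 20
    min_staging_days: int = 5
    outlier_radius_deg: float = 10.0
    stationary_dev_tol: float = 2.0
    stationary_net_tol: float = 2.0
    sahara_lat: float = 20.0
    winter_min_days: int = 14
    # metrics / environment
    buffer_radius_km: float = 50.0
    travel_speed_km_day: float = 300.0
    spread_bin_days: int = 5
    ndvi_resolution_deg: float = 0.1
    # simulation (study conditions)
    n_birds: int = 15
    n_movers: int = 12
    years: tuple = (2014, 2015)
    sampling_interval_min: int = 5
    reference_angle_deg: float = -1.5
    light_decade_width_deg: float = 3.0
    shading_event_rate: float = 0.5
    shading_attenuation: float = 0.2
    clock_jitter_min: float = 2.0
    ndvi_noise_sd: float = 0.01
    ndvi_interannual_sd: float = 0.005
    seed: int = 0

    def __post_init__(self):
        for name in ("threshold_lx", "equinox_window_days", "min_staging_days",
                     "outlier_radius_deg", "buffer_radius_km",
                     "travel_speed_km_day", "spread_bin_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def shading(self) -> synthetic.ShadingModel:
        return synthetic.ShadingModel(self.shading_event_rate,
                                      self.shading_attenuation,
                                      self.clock_jitter_min)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["angle_grid"] = list(self.angle_grid) if self.angle_grid else None
        d["years"] = list(self.years)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        """Read ``key = value`` lines (# comments allowed)."""
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise ValueError(f"{path}:{ln}: unknown config key {key!r}")
            if key in ("angle_grid", "years"):
                kwargs[key] = tuple(float(x) if key == "angle_grid" else int(x)
                                    for x in val.replace(",", " ").split())
            elif types[key] in ("int", int):
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)


# ------------------------------------------------------------------ file I/O

def write_light(series: LightSeries, path, fmt: str | None = None) -> None:
    """Write a light series as CSV or 2-column '.lux'-style text."""
    path = Path(path)
    if fmt is None:
        fmt = "lux" if path.suffix == ".lux" else "csv"
    df = series.to_frame()
    if fmt == "csv":
        df.to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            fh.write("# geolux light series\n")
            fh.write(f"# individual: {series.individual_id}\n")
            fh.write("# UTC-timestamp\tlight(lux)\n")
            for t, l in zip(df["time"], df["lux"]):
                fh.write(f"{pd.Timestamp(t).isoformat()}\t{l:.4f}\n")


def read_light(path, individual_id: str | None = None) -> LightSeries:
    """Tolerant reader for timestamped lux text (CSV or .lux-style).

    Header and comment lines are skipped; the first field(s) are the UTC
    timestamp, the last field the lux value.  Non-monotone timestamps
    raise with the offending line number.
    """
    path = Path(path)
    times_raw: list[str] = []
    lux: list[float] = []
    line_nos: list[int] = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "//", ";")):
            continue
        for delim in ("\t", ",", ";"):
            if delim in line:
                parts = [p.strip() for p in line.split(delim) if p.strip()]
                break
        else:
            parts = line.split()
        if len(parts) < 2:
            continue
        try:
            val = float(parts[-1])
        except ValueError:
            continue  # header row
        times_raw.append(" ".join(parts[:-1]))
        lux.append(val)
        line_nos.append(ln)
    if not times_raw:
        raise ValueError(f"{path}: no parseable light samples")
    try:
        times = pd.to_datetime(times_raw, format="ISO8601")
    except (ValueError, TypeError):
        times = pd.to_datetime(times_raw, dayfirst=True)
    tv = times.values
    diffs = np.diff(tv)
    if np.any(diffs <= np.timedelta64(0, "ns")):
        bad = int(np.nonzero(diffs <= np.timedelta64(0, "ns"))[0][0]) + 1
        raise ValueError(
            f"{path}:{line_nos[bad]}: non-monotone timestamp {times_raw[bad]!r}")
    return LightSeries(tv, np.asarray(lux),
                       individual_id=individual_id or path.stem)


def write_tables(bundle: "StudyBundle", outdir) -> None:
    """Write the bundle's tables as UTF-8 CSV with ISO-8601 dates."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.fixes.to_csv(outdir / "fixes.csv", index=False, date_format="%Y-%m-%d")
    bundle.periods.to_csv(outdir / "periods.csv", index=False,
                          date_format="%Y-%m-%d")
    bundle.timing_table.to_csv(outdir / "timing_table.csv", index=False)
    bundle.spread.to_csv(outdir / "spread.csv", index=False,
                         date_format="%Y-%m-%d")
    bundle.env_samples.to_csv(outdir / "env_samples.csv", index=False,
                              date_format="%Y-%m-%d")
    bundle.stats.to_csv(outdir / "stats.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, default=str)


# --------------------------------------------------------------- run_study

@dataclass
class StudyBundle:
    """Everything one reproducible study run produces."""

    config: StudyConfig
    results: dict  # individual -> GeolocationResult
    fixes: pd.DataFrame
    periods: pd.DataFrame
    timing_table: pd.DataFrame
    timings: list
    spread: pd.DataFrame
    detour: pd.DataFrame
    env_samples: pd.DataFrame
    env_trends: pd.DataFrame
    env_moves: pd.DataFrame
    consistency: pd.DataFrame
    stats: pd.DataFrame
    manifest: dict
    simulation: synthetic.StudySimulation


def _detour_rows(results, cfg) -> list[dict]:
    rows = []
    for ind, res in results.items():
        staging_eu = [p for p in res.periods
                      if p.label == "staging" and p.median_lat is not None
                      and np.isfinite(p.median_lat) and p.median_lat > 30.0]
        if not staging_eu:
            continue
        last_eu = staging_eu[-1]
        f = res.fixes
        west_lon = metrics.westernmost_longitude(f, n=3)
        # first arrival at the westernmost area: earliest of the three
        # westernmost fixes (a multi-day turn stay has near-tied longitudes)
        west_date = pd.Timestamp(
            f.loc[f["lon"].nsmallest(3).index, "date"].min())
        elapsed = (west_date - last_eu.end).days
        if elapsed <= 0:
            continue
        try:
            lat = metrics.project_detour_latitude(
                last_eu.median_lat, last_eu.median_lon, west_lon, elapsed,
                cfg.travel_speed_km_day)
        except ValueError:
            continue
        rows.append({"individual_id": ind, "last_eu_lat": last_eu.median_lat,
                     "last_eu_lon": last_eu.median_lon,
                     "westernmost_lon": west_lon, "elapsed_days": elapsed,
                     "projected_lat": lat})
    return rows


def run_study(config: StudyConfig | None = None, outdir=None,
              progress: bool = False) -> StudyBundle:
    """Simulate a deployment and run the full analysis on it.

    Re-running with the same config (seed included) is bit-identical.
    Any stage failure propagates with the individual and stage named.
    """
    from .model import GeolocatorModel  # deferred: model imports StudyConfig

    cfg = config or StudyConfig()
    rng = np.random.default_rng(cfg.seed)

    sim = synthetic.make_study(cfg.n_birds, seed=cfg.seed, years=cfg.years,
                               shading=cfg.shading(),
                               travel_speed=cfg.travel_speed_km_day,
                               n_movers=cfg.n_movers)
    results = {}
    counts = {}
    for ind, spec in sim.specs.items():
        if progress:
            print(f"  geolocating {ind} ...")
        try:
            series = synthetic.simulate_light(
                sim.truth[ind], spec.shading, cfg.sampling_interval_min,
                seed=spec.seed, reference_angle_deg=cfg.reference_angle_deg,
                threshold_anchor_lx=cfg.threshold_lx,
                decade_width_deg=cfg.light_decade_width_deg, individual_id=ind)
            res = GeolocatorModel(series, capture_site=synthetic.CAPTURE_SITE,
                                  config=cfg).fit("hill_ekstrom")
        except Exception as exc:
            raise RuntimeError(f"stage geolocate failed for {ind}: {exc}") from exc
        results[ind] = res
        counts[ind] = {
            "light_samples": len(series),
            "twilight_pairs": len(res.model.twilight_pairs),
            "fixes": res.n_fixes,
            "lat_masked_equinox": res.n_masked,
            "lat_unmasked": res.n_fixes - res.n_masked,
            "outliers_removed": res.n_outliers_removed,
            "fixes_in_periods_retained": int(sum(p.n_fixes_used for p in res.periods)),
            "periods": len(res.periods),
        }

    fixes_all = pd.concat([r.fixes for r in results.values()], ignore_index=True)
    periods_all = pd.concat(
        [r.periods_frame() for r in results.values()], ignore_index=True)

    timings = [metrics.track_timing(ind, res.periods, cfg.sahara_lat)
               for ind, res in results.items()]
    timing_df = metrics.timing_table(timings)

    tracks = {ind: res.fixes[["date", "lon", "lat"]] for ind, res in results.items()}
    spread = metrics.winter_spread(tracks, cfg.spread_bin_days)
    detour = pd.DataFrame(_detour_rows(results, cfg))

    # ---------------------------------------------------------- environment
    y0 = min(cfg.years)
    raster = synthetic.simulate_ndvi_raster(
        extent=(2.0, 22.0, -20.0, 26.0),
        start=pd.Timestamp(year=y0 - 3, month=7, day=2),
        end=pd.Timestamp(year=max(cfg.years) + 1, month=4, day=1),
        resolution=cfg.ndvi_resolution_deg,
        model=synthetic.SeasonalNDVIModel(noise_sd=cfg.ndvi_noise_sd,
                                          interannual_sd=cfg.ndvi_interannual_sd),
        seed=cfg.seed + 1,
    )
    env_rows, trend_rows, move_frames = [], [], []
    first_site_ndvi = {}
    samples_by_period_all = {}
    for ind, res in results.items():
        winters = [p for p in res.periods if p.label == "winter"]
        for k, p in enumerate(winters):
            if p.median_lat is None or not np.isfinite(p.median_lat):
                continue
            try:
                s = env.extract_buffer_mean(raster, (p.median_lat, p.median_lon),
                                            cfg.buffer_radius_km,
                                            date_range=(p.start, p.end),
                                            site_name=f"{ind}/winter{k + 1}")
            except ValueError as exc:
                raise RuntimeError(f"stage environment failed for {ind}: {exc}")
            samples_by_period_all[id(p)] = s
            for _, row in s.iterrows():
                env_rows.append({"individual_id": ind, "site": k + 1,
                                 "date": row["date"], "ndvi": row["ndvi"]})
            if k == 0 and not s.empty:
                first_site_ndvi[ind] = float(s["ndvi"].mean())
            if len(s) >= 3:
                slope, r = env.within_site_trend(s)
                trend_rows.append({"individual_id": ind, "site": k + 1,
                                   "slope_per_day": slope,
                                   "pearson_r": r.statistic if r else np.nan,
                                   "n_composites": len(s)})
        mv = env.between_site_change(res.periods, samples_by_period_all)
        if not mv.empty:
            mv.insert(0, "individual_id", ind)
            move_frames.append(mv)
    env_samples = pd.DataFrame(env_rows)
    env_trends = pd.DataFrame(trend_rows)
    env_moves = (pd.concat(move_frames, ignore_index=True)
                 if move_frames else pd.DataFrame(columns=["individual_id",
                                                           "d_ndvi", "d_lat", "d_lon"]))

    first_sites = []
    for res in results.values():
        ws = [p for p in res.periods if p.label == "winter"
              and p.median_lat is not None and np.isfinite(p.median_lat)]
        if ws:
            first_sites.append((ws[0].median_lat, ws[0].median_lon))
    consistency = (env.among_year_consistency(
        raster, first_sites, [y0 - 3, y0 - 2, y0 - 1], cfg.buffer_radius_km)
        if len(first_sites) >= 3 else pd.DataFrame())

    # ---------------------------------------------------------------- stats
    stats_rows = []

    def add(label, tr: glstats.TestResult | None):
        if tr is None:
            return
        stats_rows.append({"test": tr.name, "comparison": label,
                           "statistic": tr.statistic,
                           "df": str(tr.df), "p_value": tr.p_value,
                           "n": tr.n_used})

    bio = sim.biometrics.set_index("individual_id")
    per_bird = []
    for ind, res in results.items():
        ws = [p for p in res.periods if p.label == "winter"
              and p.median_lat is not None and np.isfinite(p.median_lat)]
        t = next(tt for tt in timings if tt.individual == ind)
        per_bird.append({
            "individual_id": ind,
            "year": int(bio.loc[ind, "year"]),
            "mass_g": float(bio.loc[ind, "mass_g"]),
            "wing_mm": float(bio.loc[ind, "wing_mm"]),
            "winter_lon": ws[0].median_lon if ws else np.nan,
            "winter_lat": ws[0].median_lat if ws else np.nan,
            "winter_ndvi": first_site_ndvi.get(ind, np.nan),
            "arrival_doy": (t.arrival_winter.dayofyear
                            if t.arrival_winter is not None else np.nan),
            "departure_doy": (t.departure_breeding.dayofyear
                              if t.departure_breeding is not None else np.nan),
            "move_doy": np.nan,
        })
    pb = pd.DataFrame(per_bird).set_index("individual_id")
    for ind, res in results.items():
        ws = [p for p in res.periods if p.label == "winter"]
        if len(ws) >= 2:
            pb.loc[ind, "move_doy"] = float(ws[1].start.dayofyear)

    years = sorted(pb["year"].unique())
    if len(years) == 2:
        a, b = (pb[pb["year"] == y] for y in years)
        for col, label in (("winter_lat", "latitude between years"),
                           ("winter_lon", "longitude between years"),
                           ("winter_ndvi", "NDVI between years")):
            try:
                add(label, glstats.welch_t(a[col], b[col]))
            except ValueError:
                pass
    try:
        add("timing variability (departure/arrival/winter move)",
            glstats.levene_test(pb["departure_doy"].dropna(),
                                pb["arrival_doy"].dropna(),
                                pb["move_doy"].dropna()))
    except ValueError:
        pass
    for col, label in (("arrival_doy", "winter longitude vs arrival"),
                       ("mass_g", "winter longitude vs body mass"),
                       ("wing_mm", "winter longitude vs wing length"),
                       ("winter_ndvi", "winter longitude vs NDVI")):
        try:
            add(label, glstats.pearson_r(pb["winter_lon"], pb[col]))
        except ValueError:
            pass
    if not env_moves.empty:
        for col, positive_means, label in (
                ("d_lat", False, "second site south of first"),
                ("d_lon", True, "second site east of first"),
                ("d_ndvi", True, "greener after winter move")):
            v = env_moves[col].dropna()
            v = v[v != 0]
            if len(v):
                npos = int((v > 0).sum())
                add(label, glstats.sign_test(npos, len(v) - npos))
    stats_df = pd.DataFrame(stats_rows)

    import geolux

    manifest = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "versions": {"geolux": geolux.__version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "per_individual_counts": counts,
        "totals": {
            "individuals": len(results),
            "fixes": int(len(fixes_all)),
            "lat_masked_equinox": int(fixes_all["lat_masked_equinox"].sum()),
            "outliers_removed": int(periods_all["n_outliers_removed"].sum()),
            "periods": int(len(periods_all)),
        },
    }
    for ind, c in counts.items():
        if c["lat_masked_equinox"] + c["lat_unmasked"] != c["fixes"]:
            raise RuntimeError(f"manifest count mismatch (equinox mask) for {ind}")

    bundle = StudyBundle(cfg, results, fixes_all, periods_all, timing_df, timings,
                         spread, detour, env_samples, env_trends, env_moves,
                         consistency, stats_df, manifest, sim)
    if outdir is not None:
        write_tables(bundle, outdir)
    return bundle
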