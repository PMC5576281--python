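"""Model/Results interface to the threshold-geolocation pipeline.

``GeolocatorModel`` is built from one logger's light series (plus optional
capture-site metadata); ``fit()`` calibrates the sun-elevation angle,
estimates daily positions, applies the equinox and outlier masks, and
segments the track, returning a ``GeolocationResult`` that carries the
fixes, the calibration diagnostics, the labelled stationary periods and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import astro, geolocate, segment
from .core import LightSeries
from .io import StudyConfig


class GeolocatorModel:
    """Threshold-method geolocation model for one deployment.

    Parameters
    ----------
    series : LightSeries
        The raw light record.
    capture_site : (lat, lon), optional
        Known deployment location; enables known-site calibration and
        steers twilight day-assignment.
    config : StudyConfig, optional
        Analysis constants (threshold, angle grid, masking windows ...).
    """

    def __init__(self, series: LightSeries, capture_site=None,
                 config: StudyConfig | None = None):
        self.series = series
        self.capture_site = capture_site
        self.config = config or StudyConfig()
        self._events = None
        self._pairs = None

    @property
    def twilights(self):
        if self._events is None:
            lon_hint = self.capture_site[1] if self.capture_site else 0.0
            self._events = astro.detect_twilights(
                self.series, self.config.threshold_lx,
                self.config.guard_window_min, lon_hint=lon_hint)
            self._pairs = astro.pair_twilights(self._events)
        return self._events

    @property
    def twilight_pairs(self):
        self.twilights
        return self._pairs

    def default_calibration_window(self):
        """Pre-departure stationary window: the first ``calibration_days`` dates."""
        t0 = pd.Timestamp(self.series.times[0]).normalize()
        return (t0, t0 + pd.Timedelta(days=self.config.calibration_days - 1))

    def auto_stationary_windows(self, min_days: int = 10) -> list:
        """Stationary windows eligible for Hill-Ekstrom calibration.

        Longitude does not depend on the sun-elevation angle, so the track
        can be segmented before calibration; the detected stationary
        windows then supply the known-stationary latitudes the
        calibration needs.  Two classes of window are screened out
        because the latitude-variance objective misbehaves there:

        * temperate-summer stays (provisional |latitude| above
          ``calibration_max_lat``) -- near the polar-day boundary the
          variance keeps shrinking as candidate angles push latitudes
          poleward, so the scan degenerates;
        * windows without at least ``calibration_min_fixes`` fixes
          farther than ``calibration_equinox_buffer_days`` from an
          equinox -- the day-length/latitude conditioning is too poor.

        In an autumn-to-winter deployment this leaves the winter
        residencies, which is where this calibration is classically
        applied; the breeding stay is instead the basis of known-site
        calibration.  Provisional latitudes use the centre of the angle
        scan; the screen only needs them to be coarse.
        """
        cfg = self.config
        fixes = geolocate.positions_from_pairs(self.twilight_pairs, -2.5)
        wins = segment.find_stationary(fixes, min_days=min_days,
                                       dev_tol=cfg.stationary_dev_tol,
                                       net_tol=cfg.stationary_net_tol)
        dates = pd.DatetimeIndex(pd.to_datetime(fixes["date"]))
        buffered = segment.mask_equinox(fixes, cfg.calibration_equinox_buffer_days)
        out = []
        for (i, j) in wins:
            lats = buffered["lat"].values[i:j + 1]
            lats = lats[np.isfinite(lats)]
            if len(lats) < cfg.calibration_min_fixes:
                continue
            if abs(float(np.median(lats))) > cfg.calibration_max_lat:
                continue
            out.append((dates[i], dates[j]))
        if not out:  # let calibration decide whether anything is usable
            out = [(dates[i], dates[j]) for (i, j) in wins]
        return out

    def fit(self, method: str = "hill_ekstrom", stationary_windows=None,
            angle: float | None = None) -> "GeolocationResult":
        """Calibrate (unless ``angle`` is given) and run the full pipeline."""
        cfg = self.config
        pairs = self.twilight_pairs
        if not pairs:
            raise geolocate.CalibrationError(
                f"no twilight pairs in series {self.series.individual_id!r}")
        calibration = None
        if angle is None:
            if stationary_windows is None:
                stationary_windows = (self.auto_stationary_windows()
                                      if method == "hill_ekstrom"
                                      else [self.default_calibration_window()])
            if method == "hill_ekstrom":
                calibration = geolocate.calibrate_hill_ekstrom(
                    pairs, stationary_windows, cfg.angle_grid,
                    threshold_lx=cfg.threshold_lx,
                    equinox_window_days=cfg.calibration_equinox_buffer_days)
            elif method == "known_site":
                if self.capture_site is None:
                    raise ValueError("known-site calibration needs a capture site")
                calibration = geolocate.calibrate_known_site(
                    pairs, *self.capture_site, stationary_windows[0],
                    cfg.angle_grid, threshold_lx=cfg.threshold_lx,
                    equinox_window_days=cfg.equinox_window_days)
            else:
                raise ValueError(f"unknown calibration method {method!r}")
            angle = calibration.chosen_angle
        fixes = geolocate.positions_from_pairs(pairs, angle)
        fixes.insert(0, "individual_id", self.series.individual_id)
        masked, periods = segment.segment_track(
            fixes, min_days=cfg.min_staging_days, dev_tol=cfg.stationary_dev_tol,
            net_tol=cfg.stationary_net_tol,
            equinox_window_days=cfg.equinox_window_days,
            outlier_radius_deg=cfg.outlier_radius_deg,
            sahara_lat=cfg.sahara_lat, winter_min_days=cfg.winter_min_days)
        return GeolocationResult(self, float(angle), calibration, masked, periods)


@dataclass
class GeolocationResult:
    """Fitted positions, calibration and segmentation for one deployment."""

    model: GeolocatorModel
    angle: float
    calibration: geolocate.CalibrationResult | None
    fixes: pd.DataFrame
    periods: list = field(default_factory=list)

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    @property
    def n_masked(self) -> int:
        return int(self.fixes["lat_masked_equinox"].sum())

    @property
    def n_outliers_removed(self) -> int:
        return int(sum(p.n_outliers_removed for p in self.periods))

    def periods_frame(self) -> pd.DataFrame:
        return segment.periods_to_frame(
            self.periods, self.model.series.individual_id)

    def summary(self) -> str:
        lines = [
            "Threshold geolocation fit",
            "=" * 60,
            f"individual:        {self.model.series.individual_id or '<unnamed>'}",
            f"light samples:     {len(self.model.series)}",
            f"twilight pairs:    {len(self.model.twilight_pairs)}",
            f"sun elevation:     {self.angle:+.2f} deg"
            + (f"  ({self.calibration.method})" if self.calibration else "  (fixed)"),
            f"position fixes:    {self.n_fixes}"
            f"  (equinox-masked latitudes: {self.n_masked},"
            f" outliers removed: {self.n_outliers_removed})",
            f"stationary periods: {len(self.periods)}",
            "",
        ]
        pf = self.periods_frame()
        if not pf.empty:
            pf = pf.copy()
            pf["start"] = pf["start"].dt.strftime("%Y-%m-%d")
            pf["end"] = pf["end"].dt.strftime("%Y-%m-%d")
            cols = ["label", "start", "end", "duration_days",
                    "median_lon", "median_lat", "lon_sd", "lat_sd"]
            lines.append(pf[cols].round(2).to_string(index=False))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Longitude and latitude against date, with stationary periods shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(2, 1, sharex=True, figsize=(9, 6))
        f = self.fixes
        ax[0].plot(f["date"], f["lon"], ".", ms=3, color="0.4")
        ax[0].set_ylabel("longitude (deg E)")
        ax[1].plot(f["date"], f["lat"], ".", ms=3, color="0.4")
        ax[1].set_ylabel("latitude (deg N)")
        colors = {"breeding": "tab:green", "staging": "tab:orange",
                  "winter": "tab:blue"}
        for p in self.periods:
            for a in ax:
                a.axvspan(p.start, p.end, color=colors.get(p.label, "0.8"),
                          alpha=0.2)
        return ax
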