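"""Simulator contracts: trajectories, light curves, NDVI fields."""

import numpy as np
import pandas as pd
import pytest

from geolux import astro, synthetic
from geolux.environment import extract_buffer_mean
from geolux.metrics import rhumb_distance
from geolux.synthetic import SeasonalNDVIModel, ShadingModel, Site, TrajectorySpec


def _site(lat, lon, a, b, name=""):
    return Site(lat, lon, pd.Timestamp(a), pd.Timestamp(b), name)


class TestSimulateTrajectory:
    def test_single_site_constant(self):
        spec = TrajectorySpec("x", (_site(10, 5, "2015-01-01", "2015-01-10"),))
        df = synthetic.simulate_trajectory(spec)
        assert len(df) == 10
        assert (df["lat"] == 10).all() and (df["lon"] == 5).all()

    def test_600km_leg_needs_two_travel_days(self):
        a = _site(0, 0, "2015-01-01", "2015-01-05", "a")
        lat2, lon2 = 0.0, 600.0 / 111.195  # 600 km east on the equator
        b = _site(lat2, lon2, "2015-01-08", "2015-01-12", "b")
        df = synthetic.simulate_trajectory(TrajectorySpec("x", (a, b)))
        travel = df[(df["date"] > a.departure) & (df["date"] < b.arrival)]
        assert len(travel) == 2
        # too-short gap errors, naming the leg
        b_fast = _site(lat2, lon2, "2015-01-07", "2015-01-12", "b")
        with pytest.raises(ValueError, match="a.*b"):
            synthetic.simulate_trajectory(TrajectorySpec("x", (a, b_fast)))

    def test_westernmost_longitude_is_westernmost_site(self):
        """A detour itinerary's path minimum equals the turn site's longitude."""
        sites = (
            _site(55.61, 12.57, "2014-05-25", "2014-08-01", "breeding"),
            _site(40.0, -4.5, "2014-08-10", "2014-08-24", "iberia"),
            _site(11.7, -14.4, "2014-09-05", "2014-09-08", "turn"),
            _site(10.0, 2.0, "2014-09-16", "2014-12-01", "winter"),
        )
        df = synthetic.simulate_trajectory(TrajectorySpec("x", sites))
        assert df["lon"].min() == pytest.approx(-14.4, abs=1e-9)
        # brute-force check: every travel day lies between its leg's endpoints
        for a, b in zip(sites[:-1], sites[1:]):
            leg = df[(df["date"] > a.departure) & (df["date"] < b.arrival)]
            lo, hi = sorted((a.lon, b.lon))
            assert ((leg["lon"] >= lo - 1e-9) & (leg["lon"] <= hi + 1e-9)).all()
            assert np.all(np.abs(np.diff(leg["lon"])) > 0)

    def test_leg_daily_steps_respect_speed(self):
        a = _site(40, -5, "2015-08-01", "2015-08-05", "a")
        b = _site(12, -14, "2015-08-17", "2015-08-20", "b")
        spec = TrajectorySpec("x", (a, b), travel_speed=300.0)
        df = synthetic.simulate_trajectory(spec).set_index("date")
        path = df.loc["2015-08-05":"2015-08-17"]
        steps = [rhumb_distance((path.iloc[i].lat, path.iloc[i].lon),
                                (path.iloc[i + 1].lat, path.iloc[i + 1].lon))
                 for i in range(len(path) - 1)]
        assert max(steps) <= 300.0 + 1e-6

    def test_overlapping_site_intervals_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            TrajectorySpec("x", (_site(0, 0, "2015-01-01", "2015-01-10"),
                                 _site(1, 1, "2015-01-10", "2015-01-20")))


class TestSimulateLight:
    def test_equatorial_day_length_near_12h(self):
        truth = pd.DataFrame({"date": pd.date_range("2015-03-01", periods=10),
                              "lat": 0.0, "lon": 0.0})
        s = synthetic.simulate_light(truth, ShadingModel(), 5, seed=0)
        pairs = astro.pair_twilights(astro.detect_twilights(s, 3.0))
        for sr, ss in pairs:
            assert (ss.time - sr.time).total_seconds() / 3600 == pytest.approx(
                12.0, abs=0.4)

    def test_denmark_june_day_exceeds_16h(self):
        truth = pd.DataFrame({"date": [pd.Timestamp("2015-06-01")],
                              "lat": 55.61, "lon": 12.57})
        s = synthetic.simulate_light(truth, ShadingModel(), 5, seed=0,
                                     reference_angle_deg=0.0)
        pairs = astro.pair_twilights(astro.detect_twilights(s, 3.0, lon_hint=12.57))
        assert pairs and (pairs[0][1].time - pairs[0][0].time
                          ).total_seconds() / 3600 > 16

    def test_seed_determinism(self):
        truth = pd.DataFrame({"date": pd.date_range("2015-10-01", periods=10),
                              "lat": 10.0, "lon": 0.0})
        sh = ShadingModel(event_rate=1.0, attenuation=0.3, clock_jitter=3.0)
        a = synthetic.simulate_light(truth, sh, 5, seed=42)
        b = synthetic.simulate_light(truth, sh, 5, seed=42)
        assert np.array_equal(a.lux, b.lux) and np.array_equal(a.times, b.times)
        c = synthetic.simulate_light(truth, sh, 5, seed=43)
        assert not np.array_equal(a.lux, c.lux)

    def test_hemisphere_day_length_symmetry(self):
        """Light at (+lat, d) mirrors (-lat, d+182) within 10 min of twilight."""
        def day_len(lat, start):
            truth = pd.DataFrame({"date": pd.date_range(start, periods=3),
                                  "lat": lat, "lon": 0.0})
            s = synthetic.simulate_light(truth, ShadingModel(), 5, seed=0)
            pairs = astro.pair_twilights(astro.detect_twilights(s, 3.0))
            return np.mean([(b.time - a.time).total_seconds() for a, b in pairs])

        for lat, start in [(40.0, "2015-01-10"), (25.0, "2015-04-01")]:
            north = day_len(lat, start)
            south = day_len(-lat, pd.Timestamp(start) + pd.Timedelta(days=182))
            assert abs(north - south) <= 600

    def test_shading_only_darkens(self):
        truth = pd.DataFrame({"date": pd.date_range("2015-10-01", periods=20),
                              "lat": 10.0, "lon": 0.0})
        clean = synthetic.simulate_light(truth, ShadingModel(), 5, seed=7)
        shaded = synthetic.simulate_light(
            truth, ShadingModel(event_rate=2.0, attenuation=0.2), 5, seed=7)
        assert np.all(shaded.lux <= clean.lux + 1e-9)

    def test_sampling_interval_must_divide_day(self):
        truth = pd.DataFrame({"date": [pd.Timestamp("2015-01-01")],
                              "lat": 0.0, "lon": 0.0})
        with pytest.raises(ValueError, match="1440"):
            synthetic.simulate_light(truth, ShadingModel(), 7, seed=0)


class TestSimulateNDVI:
    extent = (8.0, 14.0, -2.0, 4.0)

    def test_constant_field(self):
        model = SeasonalNDVIModel(base=0.4, lat_gradient=0, dry_slope=0)
        r = synthetic.simulate_ndvi_raster(self.extent, "2014-10-01",
                                           "2015-02-01", 0.1, model=model, seed=0)
        assert np.allclose(r.data.values, 0.4, atol=1e-6)

    def test_dry_season_slope_exact(self):
        """Noise-free per-pixel regression recovers the configured slope."""
        model = SeasonalNDVIModel(noise_sd=0.0, interannual_sd=0.0)
        r = synthetic.simulate_ndvi_raster(self.extent, "2014-10-05",
                                           "2015-02-20", 0.1, model=model, seed=0)
        t = (r.times - r.times[0]).days.values.astype(float)
        px = r.data.values[:, 10, 10]
        slope = np.polyfit(t, px, 1)[0]
        assert slope == pytest.approx(-0.0025, abs=1e-9)

    def test_spatial_gradient_difference(self):
        """Buffer means at two sites differ by gradient times separation."""
        model = SeasonalNDVIModel(lat_gradient=-0.015, dry_slope=0.0,
                                  noise_sd=0.0)
        r = synthetic.simulate_ndvi_raster(self.extent, "2014-11-01",
                                           "2014-12-31", 0.05, model=model, seed=0)
        a = extract_buffer_mean(r, (9.5, 1.0), 50.0)["ndvi"].mean()
        b = extract_buffer_mean(r, (12.5, 1.0), 50.0)["ndvi"].mean()
        assert a - b == pytest.approx(0.015 * 3.0, abs=0.0008)

    def test_values_bounded_and_deterministic(self):
        model = SeasonalNDVIModel(noise_sd=0.3, interannual_sd=0.2)
        r1 = synthetic.simulate_ndvi_raster(self.extent, "2013-10-01",
                                            "2015-03-01", 0.2, model=model, seed=3)
        r2 = synthetic.simulate_ndvi_raster(self.extent, "2013-10-01",
                                            "2015-03-01", 0.2, model=model, seed=3)
        assert np.array_equal(r1.data.values, r2.data.values)
        assert r1.data.values.min() >= -1 and r1.data.values.max() <= 1


class TestMakeStudy:
    def test_study_structure(self):
        sim = synthetic.make_study(6, seed=0, n_movers=4)
        assert len(sim.specs) == 6 and len(sim.truth) == 6
        assert sum(sim.moved_to_second_site.values()) == 4
        assert set(sim.biometrics.columns) >= {"individual_id", "mass_g",
                                               "wing_mm", "year"}
        for spec in sim.specs.values():
            for a, b in zip(spec.sites[:-1], spec.sites[1:]):
                assert b.arrival > a.departure
            names = [s.name for s in spec.sites]
            assert names[0] == "breeding" and "winter1" in names

    def test_round_trip_recovery_noise_free(self, clean_study):
        """Zero-noise light inverted by the pipeline lands on the true sites."""
        for ind, res in clean_study.results.items():
            spec = clean_study.simulation.specs[ind]
            f = res.fixes
            for s in spec.sites:
                if (s.departure - s.arrival).days + 1 < 5:
                    continue
                sel = (f["date"] >= s.arrival) & (f["date"] <= s.departure)
                assert abs(np.median(f.loc[sel, "lon"]) - s.lon) <= 0.5
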