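"""Rhumb geometry, connectivity spread, detour projection, timing table."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from geolux import metrics
from geolux.segment import StationaryPeriod

DATA = Path(__file__).parent / "data"


def _haversine_km(p1, p2, R=6371.0):
    la1, lo1, la2, lo2 = map(np.radians, (p1[0], p1[1], p2[0], p2[1]))
    a = (np.sin((la2 - la1) / 2) ** 2
         + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2)
    return 2 * R * np.arcsin(np.sqrt(a))


class TestRhumbDistance:
    def test_one_degree_on_equator(self):
        assert metrics.rhumb_distance((0, 0), (0, 1)) == pytest.approx(111.19,
                                                                       abs=0.01)

    def test_zero_for_identical_points(self):
        assert metrics.rhumb_distance((12.3, -4.5), (12.3, -4.5)) == 0.0

    def test_matches_geosphere_oracle(self):
        """Frozen distRhumb values (R package geosphere) within 0.1%."""
        d = pd.read_csv(DATA / "rhumb_oracle.csv")
        for r in d.itertuples():
            mine = metrics.rhumb_distance((r.lat1, r.lon1), (r.lat2, r.lon2))
            assert mine == pytest.approx(r.dist_km, rel=1e-3)
            if abs(r.lon2 - r.lon1) <= 180:  # geosphere does not wrap bearings
                brg = metrics.rhumb_bearing((r.lat1, r.lon1), (r.lat2, r.lon2))
                assert abs((brg - r.bearing + 180) % 360 - 180) < 1e-6

    def test_symmetric_and_at_least_great_circle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p1 = (rng.uniform(-60, 60), rng.uniform(-179, 179))
            p2 = (rng.uniform(-60, 60), rng.uniform(-179, 179))
            d12 = metrics.rhumb_distance(p1, p2)
            assert d12 == pytest.approx(metrics.rhumb_distance(p2, p1), rel=1e-9)
            assert d12 >= _haversine_km(p1, p2) - 1e-6

    def test_poles_rejected(self):
        with pytest.raises(ValueError):
            metrics.rhumb_distance((90.0, 0.0), (0.0, 0.0))

    def test_winter_extremes_span_over_3000_km(self):
        """The printed extreme first-winter longitudes along 11.7 N."""
        d = metrics.rhumb_distance((11.7, -11.5), (11.7, 19.7))
        along_parallel = (19.7 - (-11.5)) * 111.195 * np.cos(np.radians(11.7))
        assert d == pytest.approx(along_parallel, rel=1e-3)
        assert d > 3000


class TestRhumbDestination:
    def test_matches_geosphere_oracle(self):
        d = pd.read_csv(DATA / "rhumb_dest_oracle.csv")
        for r in d.itertuples():
            la, lo = metrics.rhumb_destination(r.lat, r.lon, r.brg, r.dist)
            assert la == pytest.approx(r.dest_lat, abs=1e-6)
            assert abs((lo - r.dest_lon + 180) % 360 - 180) < 1e-6

    def test_round_trip_with_bearing(self):
        p1, p2 = (40.0, -5.0), (11.7, -14.4)
        brg = metrics.rhumb_bearing(p1, p2)
        dist = metrics.rhumb_distance(p1, p2)
        la, lo = metrics.rhumb_destination(*p1, brg, dist)
        assert la == pytest.approx(p2[0], abs=1e-6)
        assert lo == pytest.approx(p2[1], abs=1e-6)


def _track(ind, lons, lats, start="2014-11-01"):
    dates = pd.date_range(start, periods=len(lons))
    return pd.DataFrame({"date": dates, "lon": lons, "lat": lats})


class TestWinterSpread:
    def test_identical_positions_zero_spread(self):
        tracks = {f"b{i}": _track(i, [5.0] * 10, [10.0] * 10) for i in range(4)}
        sp = metrics.winter_spread(tracks)
        assert (sp["distance_km"].dropna() == 0).all()

    def test_two_birds_symmetric_about_centre(self):
        tracks = {"w": _track("w", [-10.0] * 10, [10.0] * 10),
                  "e": _track("e", [10.0] * 10, [10.0] * 10)}
        sp = metrics.winter_spread(tracks)
        expect = 10 * 111.195 * np.cos(np.radians(10.0))
        assert sp["distance_km"].dropna().values == pytest.approx(
            np.full(sp["distance_km"].notna().sum(), expect), rel=1e-3)

    def test_single_individual_missing_spread(self):
        sp = metrics.winter_spread({"solo": _track("solo", [0.0] * 7, [5.0] * 7)})
        assert sp["distance_km"].isna().all()

    def test_duplicate_at_centre_does_not_inflate(self):
        tracks = {"w": _track("w", [-10.0] * 10, [10.0] * 10),
                  "e": _track("e", [10.0] * 10, [10.0] * 10)}
        before = metrics.winter_spread(tracks)
        tracks["c"] = _track("c", [0.0] * 10, [10.0] * 10)
        after = metrics.winter_spread(tracks)
        for ind in ("w", "e"):
            b = before[before["individual"] == ind]["distance_km"].dropna()
            a = after[after["individual"] == ind]["distance_km"].dropna()
            assert (a.values <= b.values + 1e-9).all()

    def test_uniform_winter_longitudes_spread_beyond_3000km(self):
        """15 birds drawn uniformly over the observed longitude span."""
        rng = np.random.default_rng(0)
        maxes = []
        for _ in range(30):
            lons = rng.uniform(-11.5, 19.7, 15)
            d = [metrics.rhumb_distance((11.7, a), (11.7, b))
                 for a in lons for b in lons]
            maxes.append(max(d))
        assert np.mean(maxes) >= 3000


class TestDetourProjection:
    def test_zero_travel_returns_start_latitude(self):
        assert metrics.project_detour_latitude(40.0, -5.0, -5.0, 0.0) == 40.0

    def test_southwest_travel_lowers_latitude(self):
        lat = metrics.project_detour_latitude(40.0, -5.0, -14.4, 12.0, 300.0)
        assert lat < 40.0

    def test_unreachable_longitude_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            metrics.project_detour_latitude(40.0, -5.0, -60.0, 3.0, 300.0)

    def test_east_of_start_rejected(self):
        with pytest.raises(ValueError, match="west"):
            metrics.project_detour_latitude(40.0, -5.0, 5.0, 10.0, 300.0)

    def test_recovers_turn_latitude_from_leg_geometry(self):
        """Projection inverts a rhumb leg built at the assumed speed."""
        start = (40.0, -4.5)
        turn = (11.7, -14.4)
        dist = metrics.rhumb_distance(start, turn)
        days = dist / 300.0
        lat = metrics.project_detour_latitude(start[0], start[1], turn[1],
                                              days, 300.0)
        assert lat == pytest.approx(turn[0], abs=0.01)

    def test_study_projection_close_to_true_turn(self, clean_study):
        """The population-average projected turn latitude (the reported
        quantity) lands on the true average; single birds scatter with the
        +-2-day ambiguity of the turn date."""
        d = clean_study.detour
        assert len(d) >= 10
        true_lats = [next(s.lat for s in clean_study.simulation.specs[r].sites
                          if s.name == "sahel_turn")
                     for r in d["individual_id"]]
        assert abs(d["projected_lat"].mean() - np.mean(true_lats)) <= 1.5


def _period(label, start, end, lon, lat):
    return StationaryPeriod(pd.Timestamp(start), pd.Timestamp(end), lon, lat,
                            0.1, 0.1, label=label)


class TestTimingTable:
    def test_single_track_duration(self):
        periods = [_period("breeding", "2014-05-25", "2014-08-01", 12.6, 55.6),
                   _period("staging", "2014-08-10", "2014-08-20", -4.0, 40.0),
                   _period("winter", "2014-10-09", "2015-02-01", 2.0, 10.0)]
        t = metrics.track_timing("b1", periods)
        assert t.duration_days == 69
        assert t.staging_days_before_sahara == 11
        assert t.staging_days_after_sahara == 0
        assert t.n_staging_sites_banded == 1

    def test_staging_band_boundaries(self):
        periods = [_period("breeding", "2014-05-25", "2014-08-01", 12.6, 55.6),
                   _period("staging", "2014-08-05", "2014-08-09", -4.0, 40.0),
                   _period("staging", "2014-08-15", "2014-08-26", -6.0, 38.0),
                   _period("staging", "2014-09-01", "2014-09-13", -10.0, 30.0),
                   _period("staging", "2014-09-20", "2014-09-24", -14.0, 12.0),
                   _period("winter", "2014-10-09", "2015-02-01", 2.0, 10.0)]
        t = metrics.track_timing("b1", periods)
        # 5-day and 12-day stays are inside the band; 13-day is out
        assert t.n_staging_sites_banded == 3
        assert t.staging_days_after_sahara == 5

    def test_masked_latitude_inherits_side(self):
        periods = [_period("breeding", "2014-05-25", "2014-08-01", 12.6, 55.6),
                   _period("staging", "2014-08-10", "2014-08-20", -4.0, 40.0),
                   _period("staging", "2014-09-10", "2014-09-16", -14.0, np.nan),
                   _period("winter", "2014-10-09", "2015-02-01", 2.0, 10.0)]
        t = metrics.track_timing("b1", periods)
        assert t.staging_days_before_sahara == 18  # nan side follows Iberia

    def test_pooled_statistics_match_brute_force(self):
        rng = np.random.default_rng(1)
        timings = []
        durations = []
        for i in range(12):
            dep = pd.Timestamp("2014-08-01") + pd.Timedelta(
                days=int(rng.integers(0, 15)))
            arr = dep + pd.Timedelta(days=int(rng.integers(50, 92)))
            periods = [_period("breeding", "2014-05-25", dep, 12.6, 55.6),
                       _period("winter", arr, "2015-02-01", 2.0, 10.0)]
            timings.append(metrics.track_timing(f"b{i}", periods))
            durations.append((arr - dep).days)
        table = metrics.timing_table(timings)
        row = table[table["event"] == "Migration duration (days)"].iloc[0]
        assert row["mean"] == pytest.approx(np.mean(durations))
        assert row["sd"] == pytest.approx(np.std(durations, ddof=1))
        assert row["median"] == pytest.approx(np.median(durations))
        assert row["min"] == min(durations) and row["max"] == max(durations)

    def test_empty_track_set(self):
        table = metrics.timing_table([])
        assert len(table) == 6
        assert (table["n"] == 0).all()
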