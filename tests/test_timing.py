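import numpy as np
import pandas as pd
import pytest

from migdivide.geodesy import GeoPoint
from migdivide.synth import generate_timing_cohort
from migdivide.timing import (
    TimingModelSpec,
    TrackSeries,
    build_thresholds,
    crossing_time,
    days_from_equinox,
    dedupe_repeat_tracks,
    equinox_filter,
    fit_timing_model,
    migration_duration,
    migration_speed,
    truncate_late_winter,
)


def equatorial_track(lons, start="2018-09-01", spread=None, bird="b1"):
    dates = pd.date_range(start, periods=len(lons), freq="D")
    return TrackSeries(bird_id=bird, season="autumn", dates=dates,
                       lats=np.zeros(len(lons)), lons=np.asarray(lons, float),
                       spread_km=spread)


class TestThresholds:
    def test_equatorial_route_anchor_and_azimuth(self):
        lines = build_thresholds(GeoPoint(0, 0), GeoPoint(0, 10), fractions=[0.5])
        line = lines[0]
        assert line.anchor.lon == pytest.approx(5.0, abs=1e-9)
        assert line.anchor.lat == pytest.approx(0.0, abs=1e-9)
        # route azimuth 90 -> perpendicular runs north-south
        assert line.perpendicular_azimuth % 180.0 == pytest.approx(0.0, abs=1e-9)

    def test_anchors_ordered_along_route(self):
        lines = build_thresholds(GeoPoint(48, 14), GeoPoint(36, 5))
        lats = [l.anchor.lat for l in lines]
        assert lats[0] > lats[1] > lats[2]

    def test_meridian_anchor_is_latitude_fraction(self):
        lines = build_thresholds(GeoPoint(48, 14), GeoPoint(38, 14), fractions=[0.3])
        assert lines[0].anchor.lat == pytest.approx(48 - 3.0, abs=1e-9)

    def test_identical_endpoints_rejected(self):
        with pytest.raises(ValueError):
            build_thresholds(GeoPoint(48, 14), GeoPoint(48, 14))


class TestCrossingTime:
    def test_linear_track_crosses_thirty_percent_on_day_three(self):
        track = equatorial_track(np.linspace(0, 10, 11))
        line = build_thresholds(GeoPoint(0, 0), GeoPoint(0, 10), fractions=[0.3])[0]
        est = crossing_time(track, line)
        # day 3 of a Sep-1 start, up to float rounding of the interpolation
        assert abs(est.time - pd.Timestamp("2018-09-04")) < pd.Timedelta(seconds=1)

    def test_stationary_track_flags_no_transit(self):
        track = equatorial_track(np.full(8, 1.0))
        line = build_thresholds(GeoPoint(0, 0), GeoPoint(0, 10), fractions=[0.5])[0]
        est = crossing_time(track, line)
        assert est.time is None
        assert "no-transit" in est.flags

    def test_wobbling_track_flags_multi_transit(self):
        track = equatorial_track([0, 4, 2, 4, 2, 4, 10])
        line = build_thresholds(GeoPoint(0, 0), GeoPoint(0, 10), fractions=[0.3])[0]
        est = crossing_time(track, line)
        assert est.time is None
        assert "multi-transit" in est.flags

    def test_time_translation_equivariance(self):
        lons = np.linspace(0, 10, 11)
        line = build_thresholds(GeoPoint(0, 0), GeoPoint(0, 10), fractions=[0.7])[0]
        t1 = crossing_time(equatorial_track(lons, start="2018-09-01"), line).time
        t2 = crossing_time(equatorial_track(lons, start="2018-09-21"), line).time
        assert (t2 - t1) == pd.Timedelta(days=20)

    def test_ordered_crossings_on_monotone_track(self):
        track = equatorial_track(np.linspace(0, 10, 21))
        lines = build_thresholds(GeoPoint(0, 0), GeoPoint(0, 10))
        t30, t50, t70 = (crossing_time(track, l).time for l in lines)
        assert t30 <= t50 <= t70

    def test_ensemble_median_close_to_truth(self):
        # noisy ensembles around a linear track: median crossing within a
        # day of the noiseless crossing in >= 90 of 100 seeds
        lons = np.linspace(0, 10, 11)
        line = build_thresholds(GeoPoint(0, 0), GeoPoint(0, 10), fractions=[0.5])[0]
        truth = pd.Timestamp("2018-09-06")
        hits = 0
        for seed in range(100):
            track = equatorial_track(lons, spread=np.full(11, 40.0))
            est = crossing_time(track, line, n_draws=50, seed=seed)
            if est.time is not None and abs((est.time - truth) / pd.Timedelta(days=1)) <= 1.0:
                hits += 1
        assert hits >= 90

    def test_seeded_ensemble_reproducible(self):
        track = equatorial_track(np.linspace(0, 10, 11), spread=np.full(11, 60.0))
        line = build_thresholds(GeoPoint(0, 0), GeoPoint(0, 10), fractions=[0.5])[0]
        assert crossing_time(track, line, seed=9).time == crossing_time(track, line, seed=9).time


class TestDurationSpeed:
    def test_floor_at_one_day(self):
        assert migration_duration(pd.Timestamp("2018-09-05 00:00"),
                                  pd.Timestamp("2018-09-05 09:36")) == 1.0

    def test_fractional_days_pass_through(self):
        assert migration_duration(pd.Timestamp("2018-09-05"),
                                  pd.Timestamp("2018-09-10 04:48")) == pytest.approx(5.2)

    def test_exactly_one_day(self):
        assert migration_duration(pd.Timestamp("2018-09-05"),
                                  pd.Timestamp("2018-09-06")) == 1.0

    def test_reversed_order_rejected(self):
        with pytest.raises(ValueError):
            migration_duration(pd.Timestamp("2018-09-10"), pd.Timestamp("2018-09-05"))

    def test_speed(self):
        assert migration_speed(1000, 5) == 200.0
        assert migration_speed(940, 1) == 940.0


class TestEquinoxFilter:
    @pytest.mark.parametrize("date,bearing,keep", [
        ("2018-09-25", 170.0, False),   # near equinox, near due south
        ("2018-09-25", 120.0, True),    # near equinox but oblique route
        ("2018-07-01", 180.0, True),    # far from any equinox
        ("2018-03-18", 355.0, False),   # spring equinox, near due north
        ("2018-09-30", 170.0, True),    # 7-day window exceeded
    ])
    def test_rule(self, date, bearing, keep):
        assert equinox_filter(pd.Timestamp(date), bearing) is keep

    def test_idempotent(self):
        d, b = pd.Timestamp("2018-09-25"), 170.0
        assert equinox_filter(d, b) == equinox_filter(d, b)

    def test_days_from_equinox_wraps_years(self):
        # 1 Jan 2019 is 101 d after the autumn equinox but only 78 d before
        # the next spring equinox, which is therefore the nearest one
        assert days_from_equinox(pd.Timestamp("2019-01-01")) == pytest.approx(78.0)
        assert days_from_equinox(pd.Timestamp("2018-10-02")) == pytest.approx(10.0)


class TestTruncateLateWinter:
    def winter_track(self, end):
        dates = pd.date_range("2018-11-01", end, freq="D")
        n = len(dates)
        return TrackSeries("b", "autumn", dates, np.full(n, 40.0),
                           np.linspace(14, 10, n))

    def test_tag_dying_near_equinox_truncated(self):
        track = self.winter_track("2019-03-10")
        out, truncated = truncate_late_winter(track)
        assert truncated
        assert out.last_fix_date == pd.Timestamp("2019-01-01")

    def test_tag_dying_well_before_equinox_unchanged(self):
        track = self.winter_track("2019-02-01")
        out, truncated = truncate_late_winter(track)
        assert not truncated and len(out) == len(track)

    def test_tag_surviving_past_window_unchanged(self):
        track = self.winter_track("2019-04-15")
        out, truncated = truncate_late_winter(track)
        assert not truncated and len(out) == len(track)

    def test_idempotent(self):
        once, _ = truncate_late_winter(self.winter_track("2019-03-10"))
        twice, again = truncate_late_winter(once)
        assert not again and len(twice) == len(once)


class TestDedupe:
    def test_one_row_per_bird_and_reproducible(self):
        df = pd.DataFrame({"bird_id": ["a", "a", "b", "c", "c", "c"],
                           "val": range(6)})
        out1 = dedupe_repeat_tracks(df, seed=5)
        out2 = dedupe_repeat_tracks(df, seed=5)
        assert list(out1["bird_id"]) == ["a", "b", "c"]
        assert out1.equals(out2)

    def test_unique_input_identity(self):
        df = pd.DataFrame({"bird_id": ["a", "b"], "val": [1, 2]})
        assert dedupe_repeat_tracks(df, seed=0).equals(df)


class TestTimingModel:
    def test_known_shift_recovered(self):
        ests = []
        for seed in range(40):
            df = generate_timing_cohort({"SW": 20, "SE": 20}, {"SW": -7.0}, 6.0, seed=seed)
            out = fit_timing_model(df, TimingModelSpec(comparison="SWvsSE"))
            ests.append(out["estimate"].iloc[0])
        assert np.mean(ests) == pytest.approx(-7.0, abs=0.75)

    def test_identical_groups_give_null_contrast(self):
        df = generate_timing_cohort({"SW": 30, "SE": 30}, {}, 6.0, seed=3)
        out = fit_timing_model(df, TimingModelSpec(comparison="SWvsSE"))
        assert abs(out["t"].iloc[0]) < 3.0
        assert abs(out["estimate"].iloc[0]) < 5.0

    def test_null_covariates_usually_dropped(self):
        dropped = 0
        n = 60
        for seed in range(n):
            df = generate_timing_cohort({"SW": 20, "SE": 20}, {"SW": -7.0}, 6.0, seed=seed)
            out = fit_timing_model(df, TimingModelSpec(
                comparison="SWvsSE", covariates=("year",)))
            if "year" not in out["retained_covariates"].iloc[0]:
                dropped += 1
        # a zero-effect covariate survives only when its p falls below 0.10
        assert dropped >= 0.85 * n

    def test_log_response_reported_as_ratio(self):
        rng = np.random.default_rng(0)
        df = generate_timing_cohort({"NW": 25, "SW": 25}, {}, 5.0, seed=1)
        df["duration_days"] = np.where(df["phenotype"] == "NW",
                                       rng.lognormal(np.log(8), 0.3, len(df)),
                                       rng.lognormal(np.log(20), 0.3, len(df)))
        spec = TimingModelSpec(comparison="NWvsSW", responses=("duration_days",),
                               covariates=(), log_responses=("duration_days",))
        out = fit_timing_model(df, spec)
        assert out["ratio"].iloc[0] == pytest.approx(0.4, rel=0.2)

    def test_sex_restricted_to_comparison_three(self):
        with pytest.raises(ValueError):
            TimingModelSpec(comparison="SWvsSE", covariates=("sex",))

    def test_small_group_rejected(self):
        df = generate_timing_cohort({"SW": 1, "SE": 10}, {}, 6.0, seed=0)
        with pytest.raises(ValueError):
            fit_timing_model(df, TimingModelSpec(comparison="SWvsSE"))

    def test_collinear_terms_named(self):
        df = generate_timing_cohort({"SW": 10, "SE": 10}, {}, 6.0, seed=2)
        df["breed_lon"] = df["breed_lat"] * 2.0  # exactly collinear
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_timing_model(df, TimingModelSpec(
                comparison="SWvsSE", covariates=("breed_lat", "breed_lon")))
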