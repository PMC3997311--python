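"""Season assignment, detection-event grouping, proximity counts and the
encounter-table contract, each against brute-force oracles."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from camtel.encounters import (
    CameraDeployment,
    assign_season,
    available_pairs,
    build_encounter_table,
    count_relocations_within,
    group_detections,
    validate_encounter_table,
)
from camtel.homerange import TelemetryTrack


class TestSeasons:
    @pytest.mark.parametrize(
        "date,expected",
        [
            (dt.date(2009, 3, 15), "FallWinter"),
            (dt.date(2009, 3, 16), "Excluded"),
            (dt.date(2009, 4, 20), "Excluded"),
            (dt.date(2009, 5, 31), "Excluded"),
            (dt.date(2009, 6, 1), "Summer"),
            (dt.date(2009, 9, 30), "Summer"),
            (dt.date(2009, 10, 1), "FallWinter"),
            (dt.date(2009, 12, 31), "FallWinter"),
            (dt.date(2010, 2, 28), "FallWinter"),
        ],
    )
    def test_boundaries(self, date, expected):
        assert assign_season(date) == expected

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.dates(dt.date(2008, 1, 1), dt.date(2011, 12, 31)))
    def test_every_date_classified(self, date):
        assert assign_season(date) in ("FallWinter", "Summer", "Excluded")


class TestGroupDetections:
    T0 = pd.Timestamp("2009-01-01 12:00:00")

    def test_within_gap_one_event(self):
        events = group_detections([self.T0, self.T0 + pd.Timedelta(minutes=10)])
        assert len(events) == 1

    def test_beyond_gap_two_events(self):
        events = group_detections([self.T0, self.T0 + pd.Timedelta(minutes=16)])
        assert len(events) == 2

    def test_exact_gap_starts_new_event(self):
        # "at least 15 min" separation: exactly 15 min is a new event
        events = group_detections([self.T0, self.T0 + pd.Timedelta(minutes=15)])
        assert len(events) == 2

    def test_empty(self):
        assert group_detections([]) == []

    def test_gap_measured_from_last_image(self):
        # chained close images stay one event even if the span exceeds 15 min
        ts = [self.T0 + pd.Timedelta(minutes=10 * i) for i in range(5)]
        assert len(group_detections(ts)) == 1

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(0, 5000), min_size=0, max_size=30),
    )
    def test_event_count_bounds_and_order_invariance(self, minutes):
        ts = [self.T0 + pd.Timedelta(minutes=m) for m in minutes]
        events = group_detections(ts)
        n = len(set(minutes))
        assert len(events) <= max(len(minutes), 1)
        if minutes:
            assert 1 <= len(events)
        rev = group_detections(list(reversed(ts)))
        assert len(rev) == len(events)


def _make_track(xy, dates, animal_id="A1", sex="F"):
    dates = pd.to_datetime(dates)
    return TelemetryTrack(
        animal_id, sex, dates.min().date(), dates.max().date(),
        pd.DataFrame({"date": dates, "x": xy[:, 0], "y": xy[:, 1]}),
    )


class TestProximityCounts:
    def test_empty_window_zero(self):
        track = _make_track(
            np.zeros((3, 2)), ["2009-01-01", "2009-01-02", "2009-01-03"]
        )
        cam = CameraDeployment("C1", 0.0, 0.0, dt.date(2009, 6, 1),
                               dt.date(2009, 6, 30))
        assert count_relocations_within(
            track, cam, 250.0, window=(cam.start, cam.end)
        ) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 80))
        xy = rng.uniform(-2000, 2000, size=(n, 2))
        dates = pd.to_datetime("2009-01-01") + pd.to_timedelta(
            rng.integers(0, 60, n), unit="D"
        )
        track = _make_track(xy, dates)
        cam = CameraDeployment(
            "C1", float(rng.uniform(-500, 500)), float(rng.uniform(-500, 500)),
            dt.date(2009, 1, 1), dt.date(2009, 3, 1),
        )
        for radius in (250.0, 500.0):
            w0, w1 = dt.date(2009, 1, 10), dt.date(2009, 2, 10)
            expected = 0
            for (d, x, y) in zip(dates, xy[:, 0], xy[:, 1]):
                if w0 <= d.date() <= w1 and np.hypot(x - cam.x, y - cam.y) <= radius:
                    expected += 1
            got = count_relocations_within(track, cam, radius, window=(w0, w1))
            assert got == expected

    def test_unique_counting_with_spaced_cameras(self):
        """Cameras >= 1000 m apart and radius 500: summed counts never
        exceed the number of relocations."""
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 4000, size=(300, 2))
        dates = pd.to_datetime("2009-01-01") + pd.to_timedelta(
            rng.integers(0, 50, 300), unit="D"
        )
        track = _make_track(xy, dates)
        cams = [
            CameraDeployment(f"C{i}{j}", 500 + 1000 * i, 500 + 1000 * j,
                             dt.date(2009, 1, 1), dt.date(2009, 3, 1))
            for i in range(4) for j in range(4)
        ]
        total = sum(
            count_relocations_within(t_c, c, 500.0,
                                     window=(dt.date(2009, 1, 1),
                                             dt.date(2009, 3, 1)))
            for c in cams for t_c in [track]
        )
        assert total <= 300


class TestAvailability:
    def _deploy(self, start, end, x=0.0, y=0.0, cid="C1"):
        return CameraDeployment(cid, x, y, start, end)

    def _track(self, start, end):
        dates = pd.date_range(start, end, freq="3D")
        rng = np.random.default_rng(0)
        xy = rng.normal(0, 500.0, size=(len(dates), 2))
        return _make_track(xy, dates)

    def test_reproductive_window_excluded(self):
        track = self._track(dt.date(2009, 1, 1), dt.date(2009, 9, 30))
        cam = self._deploy(dt.date(2009, 4, 1), dt.date(2009, 5, 20))
        assert available_pairs([track], None, [cam]) == []

    def test_full_overlap_exposure(self):
        track = self._track(dt.date(2009, 1, 1), dt.date(2009, 3, 10))
        cam = self._deploy(dt.date(2009, 1, 10), dt.date(2009, 2, 10))
        (pair,) = available_pairs([track], None, [cam])
        assert pair["exposure_days"] == 32.0  # inclusive dates, all in season

    def test_monotone_in_tracking_window(self):
        """Enlarging the tracking window never removes a pair."""
        cam = self._deploy(dt.date(2009, 1, 10), dt.date(2009, 2, 10))
        short = self._track(dt.date(2009, 1, 1), dt.date(2009, 2, 1))
        long = self._track(dt.date(2008, 12, 1), dt.date(2009, 3, 1))
        p_short = available_pairs([short], None, [cam])
        p_long = available_pairs([long], None, [cam])
        keys = lambda ps: {(p["animal_id"], p["camera_id"]) for p in ps}
        assert keys(p_short) <= keys(p_long)

    def test_zero_length_deployment_dropped(self, caplog):
        track = self._track(dt.date(2009, 1, 1), dt.date(2009, 3, 1))
        cam = self._deploy(dt.date(2009, 1, 10), dt.date(2009, 1, 10))
        assert available_pairs([track], None, [cam]) == []

    def test_spatial_filter_uses_isopleth(self, small_study, seasonal_surfaces,
                                          homerange_table):
        """Every homerange-mode record sits inside its animal's seasonal
        90% isopleth."""
        from camtel.homerange import ud_at

        cams = {c.camera_id: c for c in small_study.cameras}
        for row in homerange_table.itertuples(index=False):
            ud, isos = seasonal_surfaces[(row.animal_id, row.season)]
            dens = float(ud_at(ud, np.array([cams[row.camera_id].x,
                                             cams[row.camera_id].y])))
            assert dens >= isos.threshold(90)


class TestEncounterTable:
    def test_single_animal_no_photos(self):
        track = _make_track(
            np.random.default_rng(1).normal(0, 300, (40, 2)),
            pd.date_range("2009-01-01", periods=40, freq="2D"),
        )
        cam = CameraDeployment("C1", 0.0, 0.0, dt.date(2009, 1, 10),
                               dt.date(2009, 2, 10))
        table = build_encounter_table([track], None, [cam], None, "proximity")
        assert len(table) == 1
        assert table["detected"].iloc[0] == 0
        assert table["photo_count"].iloc[0] == 0

    def test_invariants_on_simulated_tables(self, proximity_table,
                                            homerange_table):
        validate_encounter_table(proximity_table, "proximity")
        validate_encounter_table(homerange_table, "homerange")
        assert (proximity_table["n_locs_250"]
                <= proximity_table["n_locs_500"]).all()
        assert ((homerange_table["isopleth_pct"] <= 50)
                == homerange_table["core"]).all()

    def test_photo_count_conservation(self, small_study, proximity_table):
        """Events inside available pair windows all land in the table."""
        from camtel.encounters import _pair_events, DEFAULT_MIN_GAP

        events = _pair_events(small_study.detections, DEFAULT_MIN_GAP)
        total_events = sum(len(v) for v in events.values())
        counted = int(proximity_table["photo_count"].sum())
        # cameras run all year for every animal here, so only events in the
        # excluded season can drop
        dropped = sum(
            1 for starts in events.values() for t in starts
            if assign_season(t) == "Excluded"
        )
        assert counted == total_events - dropped

    def test_seasonal_split_rows(self, proximity_table):
        """A deployment straddling the season boundary yields one row per
        season for the same pair."""
        dup = proximity_table.groupby(["animal_id", "camera_id"]).size()
        assert dup.max() <= 2
        both = proximity_table.groupby(["animal_id", "camera_id"])[
            "season"
        ].nunique()
        assert (both <= 2).all()

    def test_nlocs_brute_force_recount(self, small_study, proximity_table):
        rng = np.random.default_rng(0)
        tracks = {t.animal_id: t for t in small_study.tracks}
        cams = {c.camera_id: c for c in small_study.cameras}
        sample = proximity_table.sample(40, random_state=1)
        for row in sample.itertuples(index=False):
            track, cam = tracks[row.animal_id], cams[row.camera_id]
            rel = track.relocations
            d = pd.to_datetime(rel["date"])
            seasons = d.apply(assign_season)
            # reconstruct the per-season record window
            days = pd.date_range(cam.start, cam.end, freq="D")
            m, dayn = days.month, days.day
            if row.season == "FallWinter":
                keep = (m >= 10) | (m <= 2) | ((m == 3) & (dayn <= 15))
            else:
                keep = (m >= 6) & (m <= 9)
            w0, w1 = days[keep].min(), days[keep].max()
            inwin = (d >= w0) & (d <= w1)
            dist = np.hypot(rel["x"] - cam.x, rel["y"] - cam.y)
            assert row.n_locs_250 == int(((dist <= 250) & inwin).sum())
            assert row.n_locs_500 == int(((dist <= 500) & inwin).sum())
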