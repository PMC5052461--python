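"""Geofence distance, visit detection, cohort filters, and windows."""

import numpy as np
import pandas as pd
import pytest

import geoseek as gs
from geoseek.errors import ControlPoolError, InsufficientHistoryError
from geoseek.geofence import choose_control_endpoint, day_index

from conftest import records_frame

POLICY = gs.GeofencePolicy()
DAY = 86_400


# ---------------------------------------------------------------------------
# haversine


class TestHaversine:
    def test_fourth_decimal_of_latitude_is_eleven_meters(self):
        d = gs.haversine_distance(0.0, 0.0, 0.0001, 0.0)
        assert round(float(d)) == 11

    def test_identity_and_symmetry(self):
        assert gs.haversine_distance(12.3, 45.6, 12.3, 45.6) == 0.0
        d1 = gs.haversine_distance(10.0, 20.0, -30.0, 40.0)
        d2 = gs.haversine_distance(-30.0, 40.0, 10.0, 20.0)
        assert d1 == pytest.approx(d2)

    def test_agrees_with_law_of_cosines_oracle(self):
        # independent spherical-law-of-cosines formula on random pairs
        rng = np.random.default_rng(0)
        lat1, lat2 = rng.uniform(-80, 80, (2, 1000))
        lon1, lon2 = rng.uniform(-179, 179, (2, 1000))
        d = gs.haversine_distance(lat1, lon1, lat2, lon2)
        p1, p2 = np.radians(lat1), np.radians(lat2)
        cosc = (np.sin(p1) * np.sin(p2)
                + np.cos(p1) * np.cos(p2) * np.cos(np.radians(lon2 - lon1)))
        oracle = 6_371_000.0 * np.arccos(np.clip(cosc, -1, 1))
        np.testing.assert_allclose(d, oracle, rtol=1e-6, atol=1e-3)

    def test_rejects_invalid_coordinates(self):
        with pytest.raises(ValueError):
            gs.haversine_distance(95.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            gs.haversine_distance(0.0, 200.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# visit detection

FACILITIES = pd.DataFrame({
    "facility_id": ["F0"], "lat": [0.0], "lon": [0.0], "name": ["hospital"]})


def _at_distance(meters):
    # ~50 m north of the facility per 0.00045 deg
    return meters / 111_195.0


class TestVisitDetection:
    def test_run_of_three_searches_gives_one_event(self):
        lat = _at_distance(50)
        recs = records_frame([("u", t, lat, 0.0, ("a",)) for t in (0, 500, 1000)])
        ev = gs.detect_facility_visits(recs, FACILITIES, POLICY)
        assert len(ev) == 1
        assert ev.loc[0, "dwell_s"] == 1000
        assert ev.loc[0, "n_searches_in_fence"] == 3
        assert ev.loc[0, "facility_id"] == "F0"

    def test_short_dwell_discarded(self):
        lat = _at_distance(50)
        recs = records_frame([("u", 0, lat, 0.0, ("a",)),
                              ("u", 600, lat, 0.0, ("a",))])
        ev = gs.detect_facility_visits(recs, FACILITIES, POLICY)
        assert len(ev) == 0  # 600 s < 900 s

    def test_outside_fence_no_events(self):
        lat = _at_distance(500)
        recs = records_frame([("u", t, lat, 0.0, ("a",)) for t in (0, 2000)])
        assert len(gs.detect_facility_visits(recs, FACILITIES, POLICY)) == 0

    def test_out_of_fence_search_breaks_the_run(self):
        lat = _at_distance(50)
        recs = records_frame([
            ("u", 0, lat, 0.0, ("a",)),
            ("u", 500, _at_distance(5000), 0.0, ("a",)),
            ("u", 1000, lat, 0.0, ("a",)),
        ])
        assert len(gs.detect_facility_visits(recs, FACILITIES, POLICY)) == 0

    def test_long_gap_breaks_the_run(self):
        lat = _at_distance(50)
        recs = records_frame([("u", 0, lat, 0.0, ("a",)),
                              ("u", int(7 * 3600), lat, 0.0, ("a",))])
        assert len(gs.detect_facility_visits(recs, FACILITIES, POLICY)) == 0

    def test_empty_facilities_rejected(self):
        recs = records_frame([("u", 0, 0.0, 0.0, ("a",))])
        with pytest.raises(gs.GeoseekError):
            gs.detect_facility_visits(recs, FACILITIES.iloc[:0], POLICY)

    def test_shuffle_invariance(self, world, cohort):
        shuffled = cohort["records"].sample(frac=1.0, random_state=3)
        ev = gs.detect_facility_visits(shuffled, world.facilities, POLICY)
        pd.testing.assert_frame_equal(ev, cohort["visits"])


# ---------------------------------------------------------------------------
# cohort filters


def _user_stream(user, days, lat=1.0, lon=1.0, start_day=0):
    rows = []
    for d in range(start_day, start_day + days):
        rows.append((user, d * DAY + 12 * 3600, lat, lon, ("w",)))
    return rows


class TestCohortFilters:
    def _base(self):
        """One clean patient: a 1000 s visit on day 50, 45 prior search days."""
        lat_in = _at_distance(50)
        rows = _user_stream("pat", 45)
        rows += [("pat", 50 * DAY + t, lat_in, 0.0, ("w",)) for t in (0, 500, 1000)]
        return rows

    def test_clean_patient_included(self):
        recs = records_frame(self._base())
        visits = gs.detect_facility_visits(recs, FACILITIES, POLICY)
        pats = gs.apply_cohort_filters(recs, visits, FACILITIES, POLICY)
        assert list(pats["user_id"]) == ["pat"]
        assert pats.loc[0, "n_prior_search_days"] == 45

    def test_sixteen_monthly_proximal_searches_excluded(self):
        lat_in = _at_distance(100)
        rows = self._base()
        # 13 extra proximal searches in the visit month (epoch days 45-58
        # are all February, like visit day 50; 3 + 13 = 16 > 15); each on
        # its own day so no extra dwell event forms
        for d in list(range(45, 50)) + list(range(51, 59)):
            rows.append(("pat", d * DAY, lat_in, 0.0, ("w",)))
        recs = records_frame(rows)
        visits = gs.detect_facility_visits(recs, FACILITIES, POLICY)
        pats = gs.apply_cohort_filters(recs, visits, FACILITIES, POLICY)
        assert len(pats) == 0

    def test_six_distinct_facilities_excluded(self):
        facs = pd.DataFrame({
            "facility_id": [f"F{i}" for i in range(6)],
            "lat": [i * 0.1 for i in range(6)],
            "lon": [0.0] * 6, "name": ["h"] * 6})
        rows = _user_stream("pat", 45, lat=3.0)
        rows += [("pat", 50 * DAY + t, _at_distance(50), 0.0, ("w",))
                 for t in (0, 500, 1000)]
        for i in range(1, 6):  # one brief search near each other facility
            rows.append(("pat", (51 + i) * DAY, i * 0.1 + _at_distance(50),
                         0.0, ("w",)))
        recs = records_frame(rows)
        visits = gs.detect_facility_visits(recs, facs, POLICY)
        pats = gs.apply_cohort_filters(recs, visits, facs, POLICY)
        assert len(pats) == 0

    def test_insufficient_history_excluded(self):
        lat_in = _at_distance(50)
        rows = _user_stream("pat", 30)
        rows += [("pat", 50 * DAY + t, lat_in, 0.0, ("w",)) for t in (0, 500, 1000)]
        recs = records_frame(rows)
        visits = gs.detect_facility_visits(recs, FACILITIES, POLICY)
        assert len(gs.apply_cohort_filters(recs, visits, FACILITIES, POLICY)) == 0

    def test_filters_commute_with_detection_inputs(self, world, cohort):
        # conjunctive predicates: recomputing from scratch equals the fixture
        pats = gs.apply_cohort_filters(cohort["records"], cohort["visits"],
                                       world.facilities, cohort["policy"])
        pd.testing.assert_frame_equal(pats, cohort["patients"])


# ---------------------------------------------------------------------------
# control matching


class TestControlMatching:
    def test_exact_day_count_match_when_available(self):
        rows = []
        rows += _user_stream("p1", 45)
        rows += [("p1", 50 * DAY + t, _at_distance(50), 0.0, ("w",))
                 for t in (0, 500, 1000)]
        # patient has 46 search days total (45 history + the visit day)
        rows += _user_stream("c_exact", 46, lat=2.0)
        rows += _user_stream("c_other", 60, lat=2.0)
        recs = records_frame(rows)
        visits = gs.detect_facility_visits(recs, FACILITIES, POLICY)
        pats = gs.apply_cohort_filters(recs, visits, FACILITIES, POLICY)
        ctl = gs.sample_controls(recs, pats, visits, POLICY, seed=0)
        assert list(ctl["user_id"]) == ["c_exact"]
        assert bool(ctl.loc[0, "exact_match"])

    def test_nearest_fallback_flagged(self):
        rows = []
        rows += _user_stream("p1", 50)
        rows += [("p1", 55 * DAY + t, _at_distance(50), 0.0, ("w",))
                 for t in (0, 500, 1000)]
        rows += _user_stream("c49", 49, lat=2.0)
        recs = records_frame(rows)
        visits = gs.detect_facility_visits(recs, FACILITIES, POLICY)
        pats = gs.apply_cohort_filters(recs, visits, FACILITIES, POLICY)
        ctl = gs.sample_controls(recs, pats, visits, POLICY, seed=0)
        assert list(ctl["user_id"]) == ["c49"]
        assert not bool(ctl.loc[0, "exact_match"])
        assert ctl.loc[0, "n_search_days"] == 49

    def test_pool_shortfall_raises(self, world, cohort):
        no_pool = cohort["records"][
            cohort["records"]["user_id"].isin(cohort["patients"]["user_id"])]
        with pytest.raises(ControlPoolError):
            gs.sample_controls(no_pool, cohort["patients"], cohort["visits"],
                               POLICY, seed=0)

    def test_seed_determinism(self, world, cohort):
        c1 = gs.sample_controls(cohort["records"], cohort["patients"],
                                cohort["visits"], POLICY, seed=7)
        pd.testing.assert_frame_equal(c1, cohort["controls"])


# ---------------------------------------------------------------------------
# analysis windows


class TestPartitionWindow:
    def test_qualifying_patient_gets_exactly_41_buckets(self, cohort):
        for w in cohort["windows"]:
            assert w.records["day_bucket"].nunique() == 41
            assert set(w.records["day_bucket"]).issubset(range(1, 42))

    def test_insufficient_history_raises_typed_error(self):
        recs = records_frame(_user_stream("u", 30))
        with pytest.raises(InsufficientHistoryError) as err:
            gs.partition_window(recs, 35 * DAY, "patient", POLICY)
        assert err.value.n_days == 30

    def test_no_record_at_or_after_endpoint(self, cohort):
        # exhaustive scan of every bucket of every window
        for w in cohort["windows"]:
            assert (w.records["ts"] < w.endpoint_time).all()

    def test_bucket_one_is_nearest_the_endpoint(self):
        recs = records_frame(_user_stream("u", 50))
        w = gs.partition_window(recs, 45 * DAY, "patient", POLICY)
        nearest = w.records.loc[w.records["day_bucket"] == 1, "ts"].max()
        farthest = w.records.loc[w.records["day_bucket"] == 41, "ts"].max()
        assert nearest > farthest

    def test_endpoint_day_itself_excluded(self):
        recs = records_frame(_user_stream("u", 50))
        ep = 45 * DAY + 13 * 3600  # mid-day endpoint on a search day
        w = gs.partition_window(recs, ep, "patient", POLICY)
        ep_day = 45
        assert not (day_index(w.records["ts"].to_numpy()) == ep_day).any()

    def test_control_endpoint_always_partitionable(self):
        recs = records_frame(_user_stream("u", 48))
        rng = np.random.default_rng(0)
        for _ in range(10):
            ep = choose_control_endpoint(recs, POLICY, rng)
            w = gs.partition_window(recs, ep, "control", POLICY)
            assert w.records["day_bucket"].nunique() == 41
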