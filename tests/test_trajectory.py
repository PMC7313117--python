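"""Great-circle geometry, step metrics and trip segmentation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cpforage import (
    Trip,
    assign_stage,
    habitat_time,
    haversine_distance,
    initial_bearing,
    segment_trips,
    step_metrics,
    trip_descriptors,
)
from cpforage.trajectory import EARTH_RADIUS_M, destination_point

from conftest import make_fixes

NEST = (40.65, 16.60)


def _slc_distance(lat1, lon1, lat2, lon2):
    """Spherical law of cosines: independent distance oracle."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2 - lon1)
    c = np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl)
    return EARTH_RADIUS_M * np.arccos(np.clip(c, -1, 1))


class TestHaversine:
    def test_zero_for_identical_points(self):
        assert haversine_distance(40.65, 16.60, 40.65, 16.60) == 0.0

    def test_one_degree_of_equatorial_longitude(self):
        d = haversine_distance(0, 0, 0, 1)
        assert d == pytest.approx(_slc_distance(0, 0, 0, 1), abs=1e-6)
        assert d == pytest.approx(111_195, rel=1e-4)

    @settings(deadline=None, max_examples=50)
    @given(
        lat1=st.floats(-80, 80), lon1=st.floats(-179, 179),
        lat2=st.floats(-80, 80), lon2=st.floats(-179, 179),
    )
    def test_symmetry_and_law_of_cosines_agreement(self, lat1, lon1, lat2, lon2):
        d_ab = haversine_distance(lat1, lon1, lat2, lon2)
        d_ba = haversine_distance(lat2, lon2, lat1, lon1)
        assert d_ab == pytest.approx(d_ba, abs=1e-9)
        # the law-of-cosines oracle loses precision near zero separation
        assert d_ab == pytest.approx(_slc_distance(lat1, lon1, lat2, lon2), abs=1.0)

    def test_rejects_invalid_coordinates(self):
        with pytest.raises(ValueError):
            haversine_distance(91.0, 0.0, 0.0, 0.0)

    def test_destination_point_round_trip(self):
        lat2, lon2 = destination_point(40.65, 16.60, 73.0, 5000.0)
        assert haversine_distance(40.65, 16.60, lat2, lon2) == pytest.approx(5000.0, rel=1e-9)
        assert initial_bearing(40.65, 16.60, lat2, lon2) == pytest.approx(73.0, abs=1e-3)


class TestStepMetrics:
    def test_collinear_eastward_track_has_zero_turns(self):
        times = pd.date_range("2017-06-05 06:00", periods=5, freq="min")
        fixes = make_fixes(times, [40.0] * 5, [16.0 + 0.01 * k for k in range(5)])
        m = step_metrics(fixes)
        assert np.allclose(m["turn"].dropna(), 0.0, atol=1e-6)

    def test_reversal_point_turn_is_pi(self):
        times = pd.date_range("2017-06-05 06:00", periods=3, freq="min")
        fixes = make_fixes(times, [40.0, 40.01, 40.0], [16.0, 16.0, 16.0])
        m = step_metrics(fixes)
        assert m["turn"].iloc[1] == pytest.approx(np.pi, abs=1e-9)

    def test_600m_per_minute_is_10_mps(self):
        lat2, lon2 = destination_point(40.0, 16.0, 90.0, 600.0)
        lat3, lon3 = destination_point(lat2, lon2, 90.0, 600.0)
        times = pd.date_range("2017-06-05 06:00", periods=3, freq="min")
        fixes = make_fixes(times, [40.0, lat2, lat3], [16.0, lon2, lon3])
        m = step_metrics(fixes)
        assert m["speed"].iloc[0] == pytest.approx(10.0, rel=1e-9)

    def test_duplicate_timestamps_rejected(self):
        times = ["2017-06-05 06:00"] * 2 + ["2017-06-05 06:01"]
        fixes = make_fixes(times, [40.0, 40.01, 40.02], [16.0] * 3)
        with pytest.raises(ValueError, match="strictly increasing"):
            step_metrics(fixes)


def _fixes_around_nest(offsets_m, bearings=None, start="2017-06-05 06:00"):
    """Fixes at given radial offsets (m) from the nest along given bearings."""
    n = len(offsets_m)
    bearings = bearings or [90.0] * n
    lats, lons = [], []
    for d, b in zip(offsets_m, bearings):
        lat, lon = destination_point(NEST[0], NEST[1], b, d)
        lats.append(lat)
        lons.append(lon)
    times = pd.date_range(start, periods=n, freq="min")
    return make_fixes(times, lats, lons)


class TestSegmentTrips:
    def test_all_fixes_at_nest_yield_no_trips(self):
        fixes = _fixes_around_nest([0, 10, 20, 5, 0])
        assert segment_trips(fixes, NEST) == []

    def test_single_bounded_excursion_is_one_trip(self):
        fixes = _fixes_around_nest([0] + [500 + 100 * k for k in range(10)] + [0])
        trips = segment_trips(fixes, NEST)
        assert len(trips) == 1
        # trip includes the two bounding nest fixes
        assert trips[0].n_fixes == 12
        assert trips[0].has_start_bound and trips[0].has_end_bound

    def test_distant_first_fix_of_day_discarded(self):
        fixes = _fixes_around_nest([3000, 3100, 3200, 0])
        trips = segment_trips(fixes, NEST)
        assert trips == []

    def test_near_first_fix_of_day_kept(self):
        fixes = _fixes_around_nest([800, 900, 1000, 0])
        trips = segment_trips(fixes, NEST)
        assert len(trips) == 1 and not trips[0].has_start_bound

    def test_urban_only_excursion_dropped(self):
        fixes = _fixes_around_nest([0, 500, 600, 700, 0])
        fixes["habitat"] = ["artificial"] * 5
        assert segment_trips(fixes, NEST) == []

    def test_segmentation_is_idempotent(self, small_study):
        _, bundle, _ = small_study
        ind = bundle.fixes["individual_id"].iloc[0]
        fx = bundle.fixes[bundle.fixes["individual_id"] == ind]
        nest = (bundle.nests["lat"].iloc[0], bundle.nests["lon"].iloc[0])
        trips1 = segment_trips(fx, nest)
        refix = pd.concat([t.fixes for t in trips1]).drop_duplicates(subset="t")
        trips2 = segment_trips(refix.sort_values("t"), nest)
        assert len(trips1) == len(trips2)
        for a, b in zip(trips1, trips2):
            assert a.n_fixes == b.n_fixes
            assert a.start_t == b.start_t

    def test_missing_nest_is_an_error(self):
        fixes = _fixes_around_nest([0, 500, 0])
        with pytest.raises(ValueError):
            segment_trips(fixes, None)


class TestTripDescriptors:
    def test_straight_out_and_back(self):
        offs = [0, 1000, 2000, 3000, 4000, 5000, 4000, 3000, 2000, 1000, 0]
        trip = Trip("t", "A", _fixes_around_nest(offs))
        d = trip_descriptors(trip, NEST)
        assert d["length_km"] == pytest.approx(10.0, rel=1e-9)
        assert d["max_distance_km"] == pytest.approx(5.0, rel=1e-9)
        assert d["tortuosity"] == pytest.approx(2.0, rel=1e-9)

    def test_unit_square_loop_matches_planar_oracle(self):
        # nest-cornered 1-km square: length 4 km, max sqrt(2) km
        corners = [(0, 0), (1000, 90), (np.sqrt(2) * 1000, 45), (1000, 0), (0, 0)]
        lats, lons = [], []
        for d, b in corners:
            lat, lon = destination_point(NEST[0], NEST[1], b, d)
            lats.append(lat)
            lons.append(lon)
        times = pd.date_range("2017-06-05 06:00", periods=5, freq="min")
        trip = Trip("t", "A", make_fixes(times, lats, lons))
        d = trip_descriptors(trip, NEST)
        assert d["length_km"] == pytest.approx(4.0, rel=1e-4)
        assert d["max_distance_km"] == pytest.approx(np.sqrt(2), rel=1e-6)
        assert d["tortuosity"] == pytest.approx(4.0 / np.sqrt(2), rel=1e-4)

    def test_duration_in_hours(self):
        fixes = _fixes_around_nest([0] + [500] * 59 + [0])
        trip = Trip("t", "A", fixes)
        d = trip_descriptors(trip, NEST)
        assert d["duration_h"] == pytest.approx(1.0, rel=1e-12)


class TestStageAndHabitat:
    def _records(self, eggs, nestlings):
        return pd.DataFrame(
            {"date": [pd.Timestamp("2017-06-05")], "eggs": [eggs], "nestlings": [nestlings]}
        )

    def test_eggs_only_is_incubation(self):
        assert assign_stage("2017-06-05", self._records(4, 0)) == "incubation"

    def test_any_nestling_is_rearing(self):
        assert assign_stage("2017-06-05", self._records(1, 2)) == "nestling_rearing"

    def test_empty_nest_is_an_error(self):
        with pytest.raises(ValueError):
            assign_stage("2017-06-05", self._records(0, 0))

    def test_uncovered_date_is_an_error(self):
        with pytest.raises(ValueError):
            assign_stage("2017-06-09", self._records(4, 0))

    def test_habitat_proportions(self):
        hab = ["arable", "arable", "arable", "grassland"]
        beh = ["perch"] * 4
        p = habitat_time(hab, beh)
        assert p["arable"] == pytest.approx(0.75)
        assert p["grassland"] == pytest.approx(0.25)
        assert sum(p.values()) == pytest.approx(1.0)

    def test_relocation_fixes_do_not_count(self):
        hab = ["arable"] * 3 + ["grassland"] + ["wooded"] * 10
        beh = ["perch"] * 4 + ["relocation"] * 10
        p = habitat_time(hab, beh)
        assert p["arable"] == pytest.approx(0.75)
        assert p["wooded"] == 0.0

    def test_all_relocation_flagged_undefined(self):
        p = habitat_time(["arable", "arable"], ["relocation", "relocation"])
        assert all(np.isnan(v) for v in p.values())
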