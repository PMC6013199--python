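"""Facility assignment, the time budget, and delayed-escape classification.

The frozen expected values are the published display columns of the Kochi
case study: nurse leg (0.1 min), walk leg (0.1 min), total (0.1 min) for
all 21 recipients, and the margin for the nine rows whose printed margin is
arithmetically consistent with arrival-minus-total.
"""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from tsunevac import (
    HazardFields,
    ModelParameters,
    SiteRecord,
    assign_shelter,
    assign_station,
    classify_delayed,
    compute_timing,
    plan_evacuations,
)
from tsunevac.planner import UnassignableError
from tsunevac.road_network import build_graph, shortest_path

# id -> (t_nurse, t_walk, t_total) as printed, all 21 recipients
PRINTED_TIME_COLUMNS = {
    "3": (1.7, 56.8, 63.4),
    "8": (2.3, 63.8, 71.0),
    "14": (2.6, 62.9, 70.5),
    "22": (7.5, 136.4, 148.8),
    "27": (3.7, 42.6, 51.2),
    "48": (4.9, 40.1, 49.9),
    "11": (5.1, 63.4, 73.3),
    "18": (2.2, 8.0, 15.1),
    "19": (5.7, 61.1, 71.7),
    "21": (5.1, 99.8, 109.8),
    "29": (2.3, 50.5, 57.7),
    "30": (3.5, 81.8, 90.2),
    "32": (1.8, 19.7, 26.3),
    "39": (2.7, 26.0, 33.6),
    "46": (2.2, 55.0, 62.0),
    "47": (3.1, 14.5, 22.5),
    "51": (3.2, 117.4, 125.5),
    "5": (2.1, 27.4, 34.4),
    "34": (0.2, 15.7, 20.7),
    "49": (1.6, 32.3, 38.8),
    "50": (5.8, 10.0, 20.7),
}

# the nine rows whose printed margin equals arrival - total
PRINTED_CONSISTENT_MARGINS = {
    "48": 10.1,
    "11": -13.3,
    "18": 34.9,
    "19": -21.7,
    "32": 23.7,
    "47": 37.5,
    "5": 15.6,
    "34": 29.3,
    "49": 11.2,
}


def grid_world(rng=None, n=6, spacing=200.0):
    """Small connected grid graph for assignment tests."""
    lines = []
    for i in range(n):
        for j in range(n):
            if i + 1 < n:
                lines.append([(i * spacing, j * spacing), ((i + 1) * spacing, j * spacing)])
            if j + 1 < n:
                lines.append([(i * spacing, j * spacing), (i * spacing, (j + 1) * spacing)])
    return build_graph(lines)


class TestComputeTiming:
    def test_time_columns_reproduce_case_study_for_all_recipients(self, kochi_rows):
        for row in kochi_rows:
            t = compute_timing(row.d_station, row.d_shelter, row.arrival_min)
            p_nurse, p_walk, p_total = PRINTED_TIME_COLUMNS[row.recipient_id]
            assert t.t_nurse == pytest.approx(p_nurse, abs=0.05), row.recipient_id
            assert t.t_walk == pytest.approx(p_walk, abs=0.05), row.recipient_id
            assert t.t_total == pytest.approx(p_total, abs=0.05), row.recipient_id

    def test_margins_reproduce_consistent_case_study_rows(self, kochi_by_id):
        for rid, printed in PRINTED_CONSISTENT_MARGINS.items():
            row = kochi_by_id[rid]
            t = compute_timing(row.d_station, row.d_shelter, row.arrival_min)
            assert t.margin == pytest.approx(printed, abs=0.05), rid

    def test_transfer_only_budget(self):
        t = compute_timing(0, 0, 60)
        assert t.t_total == pytest.approx(4.9)
        assert t.margin == pytest.approx(55.1)

    def test_total_is_exact_sum_of_parts(self):
        t = compute_timing(1748, 1336, 60)
        assert t.t_total == pytest.approx(t.t_nurse + t.t_transfer + t.t_walk, abs=1e-9)

    def test_undefined_arrival_gives_undefined_margin_and_flag(self):
        t = compute_timing(599, 1892, None)
        assert t.margin is None and t.delayed is None

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            compute_timing(-1, 100, 60)

    def test_parameters_must_be_positive(self):
        with pytest.raises(ValueError):
            ModelParameters(walk_speed=0)

    @given(
        d=st.floats(1, 5000),
        speed=st.floats(1, 400),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_halving_walk_speed_doubles_walk_time(self, d, speed):
        slow = compute_timing(0, d, None, ModelParameters(walk_speed=speed / 2))
        base = compute_timing(0, d, None, ModelParameters(walk_speed=speed))
        assert slow.t_walk == pytest.approx(2 * base.t_walk, rel=1e-12)

    @given(
        d1=st.floats(0, 5000),
        d2=st.floats(0, 5000),
        bump=st.floats(1, 1000),
        arrival=st.floats(10, 120),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_margin_monotone_in_distances_and_arrival(self, d1, d2, bump, arrival):
        base = compute_timing(d1, d2, arrival)
        assert compute_timing(d1 + bump, d2, arrival).margin < base.margin
        assert compute_timing(d1, d2 + bump, arrival).margin < base.margin
        assert compute_timing(d1, d2, arrival + bump).margin > base.margin


class TestClassifyDelayed:
    def test_negative_margin_is_delayed(self):
        t = compute_timing(1821, 2110, 60)  # margin ~ -13.3
        assert classify_delayed(t) is True

    def test_base_case_threshold_is_strict(self):
        t = compute_timing(0, 0, 4.9)  # margin exactly 0
        assert t.margin == pytest.approx(0, abs=1e-12)
        assert classify_delayed(t) is False

    def test_zero_at_integer_display_counts_as_delayed(self):
        # a margin of +0.38 displays as 0 in the sensitivity tables
        t = compute_timing(975, 866, 60, ModelParameters(walk_speed=33.3 / 2))
        assert 0 < t.margin < 0.5
        assert classify_delayed(t, granularity="integer") is True
        assert classify_delayed(t) is False

    def test_undefined_margin_stays_undefined(self):
        t = compute_timing(599, 1892, None)
        assert classify_delayed(t, granularity="integer") is None


def _sites(graph, node_ids, role, prefix):
    return [
        SiteRecord(f"{prefix}{i}", role, *graph.position(n))
        for i, n in enumerate(node_ids, start=1)
    ]


class TestAssignment:
    def test_single_station_distance(self):
        g = build_graph([[(0, 0), (599, 0)]])
        recipient = SiteRecord("r", "recipient", 599, 0)
        station = SiteRecord("s", "station", 0, 0)
        sid, d = assign_station(recipient, [station], g)
        assert (sid, d) == ("s", pytest.approx(599))

    def test_equidistant_stations_tie_to_lower_id(self):
        g = build_graph([[(0, 0), (100, 0)], [(100, 0), (200, 0)]])
        recipient = SiteRecord("r", "recipient", 100, 0)
        stations = [
            SiteRecord("st_b", "station", 200, 0),
            SiteRecord("st_a", "station", 0, 0),
        ]
        sid, d = assign_station(recipient, stations, g)
        assert (sid, d) == ("st_a", pytest.approx(100))

    def test_station_assignment_matches_per_station_shortest_paths(self):
        g = grid_world()
        rng = random.Random(5)
        nodes = list(g.graph.nodes)
        recipient = SiteRecord("r", "recipient", *g.position(rng.choice(nodes)))
        stations = _sites(g, rng.sample(nodes, 4), "station", "st")
        sid, d = assign_station(recipient, stations, g)
        from tsunevac.road_network import snap_site

        rnode = snap_site(g, recipient.location)
        exhaustive = min(
            (
                (shortest_path(g, rnode, snap_site(g, s.location)).length_m, s.id)
                for s in stations
            ),
        )
        assert (d, sid) == (pytest.approx(exhaustive[0]), exhaustive[1])

    def test_no_station_reachable_raises_naming_recipient(self):
        g = build_graph([[(0, 0), (10, 0)], [(100, 100), (110, 100)]])
        recipient = SiteRecord("r42", "recipient", 0, 0)
        station = SiteRecord("s", "station", 100, 100)
        with pytest.raises(UnassignableError, match="r42"):
            assign_station(recipient, [station], g)

    def test_level3_nearest_shelter_is_skipped_for_second_nearest(self):
        # nearest shelter sits in a level-3 zone; recipient must go to the
        # second-nearest, in a level-2 zone
        g = build_graph([[(0, 0), (500, 0)], [(500, 0), (2000, 0)]])
        fields = HazardFields(
            level_zones=[(box(-10, -10, 100, 10), 3), (box(1500, -10, 2100, 10), 2)]
        )
        recipient = SiteRecord("r", "recipient", 500, 0)
        shelters = [
            SiteRecord("near_lv3", "shelter", 0, 0),
            SiteRecord("far_lv2", "shelter", 2000, 0),
        ]
        assert assign_shelter(recipient, shelters, g, fields) == (
            "far_lv2",
            pytest.approx(1500),
        )

    def test_single_level1_shelter_is_chosen(self):
        g = build_graph([[(0, 0), (500, 0)]])
        fields = HazardFields(level_zones=[(box(-10, -10, 10, 10), 1)])
        recipient = SiteRecord("r", "recipient", 500, 0)
        assert assign_shelter(
            recipient, [SiteRecord("s1", "shelter", 0, 0)], g, fields
        ) == ("s1", pytest.approx(500))

    def test_all_shelters_level3_is_unassignable(self):
        g = build_graph([[(0, 0), (500, 0)]])
        fields = HazardFields(level_zones=[(box(-10, -10, 600, 10), 3)])
        recipient = SiteRecord("r", "recipient", 500, 0)
        assert (
            assign_shelter(recipient, [SiteRecord("s1", "shelter", 0, 0)], g, fields)
            is None
        )

    def test_shelter_assignment_matches_exhaustive_minimum_over_eligible(self):
        g = grid_world()
        rng = random.Random(9)
        nodes = list(g.graph.nodes)
        fields = HazardFields(level_zones=[(box(-50, -50, 1050, 300), 3)])
        recipient = SiteRecord("r", "recipient", *g.position(rng.choice(nodes)))
        shelters = _sites(g, rng.sample(nodes, 8), "shelter", "sh")
        from tsunevac.hazard_fields import flood_level_at
        from tsunevac.road_network import snap_site

        result = assign_shelter(recipient, shelters, g, fields)
        rnode = snap_site(g, recipient.location)
        eligible = [s for s in shelters if flood_level_at(fields, s.location) != 3]
        exhaustive = min(
            (shortest_path(g, rnode, snap_site(g, s.location)).length_m, s.id)
            for s in eligible
        )
        assert result == (exhaustive[1], pytest.approx(exhaustive[0]))


class TestPlanEvacuations:
    def test_uses_arrival_time_at_assigned_shelter(self):
        g = build_graph([[(0, 0), (500, 0)], [(500, 0), (500, 1000)]])
        fields = HazardFields(
            level_zones=[(box(-10, -10, 600, 10), 2)],
            arrival_zones=[(box(-10, -10, 600, 10), 35.0)],
        )
        recipients = [SiteRecord("r1", "recipient", 500, 0)]
        stations = [SiteRecord("n1", "station", 500, 1000)]
        shelters = [SiteRecord("s1", "shelter", 0, 0)]
        plans, timings = plan_evacuations(recipients, stations, shelters, g, fields)
        (t,) = timings
        assert t.t_arrival == 35.0
        assert t.d_station == pytest.approx(1000)
        assert t.d_shelter == pytest.approx(500)

    def test_unassignable_recipient_reported_and_run_continues(self):
        g = build_graph([[(0, 0), (500, 0)]])
        fields = HazardFields(level_zones=[(box(-10, -10, 600, 10), 3)])
        recipients = [
            SiteRecord("r1", "recipient", 0, 0),
            SiteRecord("r2", "recipient", 500, 0),
        ]
        stations = [SiteRecord("n1", "station", 0, 0)]
        shelters = [SiteRecord("s1", "shelter", 500, 0)]
        plans, timings = plan_evacuations(recipients, stations, shelters, g, fields)
        assert [p.assigned for p in plans] == [False, False]
        assert timings == []
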