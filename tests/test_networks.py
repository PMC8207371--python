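"""Association-matrix construction: presence, binning, weights, alignment."""

import datetime as dt
import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from roostnet import (
    AssociationMatrix,
    ColonyConfig,
    StudyWindow,
    align_matrices,
    bin_detections,
    build_cohabitation,
    build_intraroost,
    daily_presence,
    dichotomize,
    simulate_colony,
)
from roostnet.simulate import antenna_registry_for

from conftest import ev


class TestDailyPresence:
    def test_repeated_entry_reads_collapse_to_one_triple(self, registry, season):
        events = [
            ev("2017-07-01 05:59:00", "A", "R0_E0"),
            ev("2017-07-01 16:03:00", "A", "R0_E0"),
        ]
        p = daily_presence(events, registry, season)
        assert len(p) == 1
        assert tuple(p.iloc[0]) == ("A", dt.date(2017, 7, 1), "R0")

    def test_ceiling_only_detection_gives_no_presence(self, registry, season):
        events = [ev("2017-07-01 10:00:00", "B", "R0_C0")]
        assert daily_presence(events, registry, season).empty

    def test_matches_ground_truth_with_perfect_entry_detection(self):
        """p_entry_detect=1: the presence table equals the planted roost
        assignments restricted to tagged, attending bats."""
        config = ColonyConfig(
            n_bats=20, tagged_fraction=0.5, n_roosts=2, zones_per_roost=2,
            antennas_per_roost_ceiling=2, n_subgroups=2, p_entry_detect=1.0,
            p_ceiling_detect=0.0,
            season=StudyWindow(dt.date(2017, 6, 10), dt.date(2017, 6, 24)),
            residency_minutes_per_day=60, seed=9,
        )
        events, truth = simulate_colony(config)
        registry = antenna_registry_for(config)
        p = daily_presence(events, registry, config.season)
        got = {(r.tag_id, r.roost_day.isoformat(), r.roost_id) for r in p.itertuples()}
        tagged = set(truth.tagged_ids())
        want = {
            (r.bat_id, r.date, r.roost_id)
            for r in truth.assignments.itertuples()
            if r.bat_id in tagged and r.roost_id != "offsite"
        }
        assert got == want


class TestCohabitation:
    def test_shared_days_become_weights(self, registry, season):
        events = []
        for day in ("2017-07-01", "2017-07-02", "2017-07-03"):
            events += [ev(f"{day} 06:00:00", "A", "R0_E0"),
                       ev(f"{day} 06:01:00", "B", "R0_E0")]
        events.append(ev("2017-07-04 06:00:00", "A", "R1_E0"))
        m = build_cohabitation(daily_presence(events, registry, season))
        assert m.weight("A", "B") == 3

    def test_lone_bat_kept_as_isolate(self, registry, season):
        events = [
            ev("2017-07-01 06:00:00", "A", "R0_E0"),
            ev("2017-07-01 06:00:00", "B", "R0_E0"),
            ev("2017-07-05 06:00:00", "C", "R1_E0"),  # alone that day
        ]
        m = build_cohabitation(daily_presence(events, registry, season))
        assert "C" in m.nodes
        assert m.weights[m.nodes.index("C")].sum() == 0

    def test_same_day_different_roosts_no_weight(self, registry, season):
        events = [
            ev("2017-07-01 06:00:00", "A", "R0_E0"),
            ev("2017-07-01 06:00:00", "B", "R1_E0"),
        ]
        m = build_cohabitation(daily_presence(events, registry, season))
        assert m.weight("A", "B") == 0

    def test_empty_presence_rejected(self, registry, season):
        with pytest.raises(ValueError):
            build_cohabitation(daily_presence([], registry, season))

    def test_matches_brute_force_double_loop(self):
        """Simulator fixture vs an independent double loop over every
        (day, roost) cell of the presence table."""
        config = ColonyConfig(
            n_bats=5, tagged_fraction=1.0, n_roosts=2, zones_per_roost=2,
            antennas_per_roost_ceiling=2, n_subgroups=2, p_entry_detect=0.9,
            season=StudyWindow(dt.date(2017, 6, 10), dt.date(2017, 6, 30)),
            residency_minutes_per_day=60, seed=21,
        )
        events, _ = simulate_colony(config)
        registry = antenna_registry_for(config)
        presence = daily_presence(events, registry, config.season)
        m = build_cohabitation(presence)

        triples = {(r.tag_id, r.roost_day, r.roost_id) for r in presence.itertuples()}
        tags = sorted({t for t, _, _ in triples})
        cells = {(d, r) for _, d, r in triples}
        for a, b in itertools.combinations(tags, 2):
            expected = sum(
                1 for d, r in cells
                if (a, d, r) in triples and (b, d, r) in triples
            )
            assert m.weight(a, b) == expected


class TestBinDetections:
    @pytest.mark.parametrize(
        "ts,bin_index",
        [
            ("2017-07-01 00:07:30", 1),
            ("2017-07-01 00:00:00", 0),
            ("2017-07-01 23:59:59", 287),
        ],
    )
    def test_bin_boundaries(self, registry, season, ts, bin_index):
        b = bin_detections([ev(ts, "A", "R0_C0")], registry, season)
        assert b.iloc[0]["bin_index"] == bin_index

    def test_repeated_scans_collapse(self, registry, season):
        events = [
            ev(f"2017-07-01 10:00:{s:02d}", "A", "R0_C0") for s in range(0, 60, 5)
        ]
        assert len(bin_detections(events, registry, season)) == 1

    def test_entry_scans_excluded(self, registry, season):
        assert bin_detections(
            [ev("2017-07-01 10:00:00", "A", "R0_E0")], registry, season
        ).empty

    def test_rollover_anchors_bins_at_roost_day_start(self, registry):
        w = StudyWindow(dt.date(2017, 6, 10), dt.date(2017, 8, 15),
                        day_rollover_hour=12)
        b = bin_detections([ev("2017-07-01 12:07:00", "A", "R0_C0")], registry, w)
        assert b.iloc[0]["roost_day"] == dt.date(2017, 7, 1)
        assert b.iloc[0]["bin_index"] == 1  # 7 min past the roost-day start


class TestIntraroost:
    def test_shared_bins_become_weights(self, registry, season):
        events = []
        for m in (0, 5, 10, 15):
            events += [ev(f"2017-07-01 10:{m:02d}:01", "A", "R0_C0"),
                       ev(f"2017-07-01 10:{m:02d}:02", "B", "R0_C0")]
        mat = build_intraroost(bin_detections(events, registry, season))
        assert mat.weight("A", "B") == 4  # 20 minutes together

    def test_same_bin_different_antennas_no_weight(self, registry, season):
        events = [
            ev("2017-07-01 10:00:01", "A", "R0_C0"),
            ev("2017-07-01 10:00:02", "B", "R0_C1"),
        ]
        mat = build_intraroost(bin_detections(events, registry, season))
        assert mat.weight("A", "B") == 0

    def test_matches_planted_co_location_counts(self):
        """Full coverage and perfect per-bin detection: weights equal the
        ground-truth count of shared (day, zone) slots times bins/day."""
        config = ColonyConfig(
            n_bats=8, tagged_fraction=1.0, n_roosts=1, zones_per_roost=2,
            antennas_per_roost_ceiling=2, n_subgroups=2, zone_cohesion=0.7,
            p_ceiling_detect=1.0, mean_attendance=1.0,
            season=StudyWindow(dt.date(2017, 6, 10), dt.date(2017, 6, 19)),
            residency_minutes_per_day=30, seed=13,
        )
        events, truth = simulate_colony(config)
        registry = antenna_registry_for(config)
        mat = build_intraroost(bin_detections(events, registry, config.season))
        slots = {
            (r.bat_id, r.date, r.zone_id) for r in truth.assignments.itertuples()
        }
        bins_per_day = config.residency_minutes_per_day // 5
        for a, b in itertools.combinations(sorted(mat.nodes), 2):
            shared_days = sum(
                1 for (bat, d, z) in slots if bat == a and (b, d, z) in slots
            )
            assert mat.weight(a, b) == shared_days * bins_per_day


class TestDichotomize:
    def test_threshold_one(self):
        m = AssociationMatrix(("a", "b", "c"),
                              np.array([[0, 1, 3], [1, 0, 0], [3, 0, 0]]), "cohabitation")
        d = dichotomize(m)
        assert d.weights.tolist() == [[0, 1, 1], [1, 0, 0], [1, 0, 0]]

    def test_all_zero_stays_zero(self):
        m = AssociationMatrix(("a", "b"), np.zeros((2, 2), dtype=int), "cohabitation")
        assert dichotomize(m).weights.sum() == 0

    def test_higher_threshold_drops_weak_ties(self):
        m = AssociationMatrix(("a", "b"), np.array([[0, 1], [1, 0]]), "cohabitation")
        assert dichotomize(m, threshold=2).weights.sum() == 0

    def test_threshold_below_one_rejected(self):
        m = AssociationMatrix(("a", "b"), np.zeros((2, 2), dtype=int), "cohabitation")
        with pytest.raises(ValueError):
            dichotomize(m, threshold=0)


class TestAlignment:
    def test_union_pads_missing_nodes(self):
        a = AssociationMatrix(("A", "B"), np.array([[0, 2], [2, 0]]), "cohabitation")
        b = AssociationMatrix(("B", "C"), np.array([[0, 5], [5, 0]]), "intraroost")
        a2, b2 = align_matrices(a, b, "union")
        assert a2.nodes == b2.nodes == ("A", "B", "C")
        assert a2.weight("A", "B") == 2 and a2.weight("B", "C") == 0
        assert b2.weight("B", "C") == 5 and b2.weight("A", "B") == 0

    def test_intersection_restricts(self):
        a = AssociationMatrix(("A", "B"), np.array([[0, 2], [2, 0]]), "cohabitation")
        b = AssociationMatrix(("B", "C"), np.array([[0, 5], [5, 0]]), "intraroost")
        a2, b2 = align_matrices(a, b, "intersection")
        assert a2.nodes == b2.nodes == ("B",)

    def test_disjoint_intersection_rejected(self):
        a = AssociationMatrix(("A",), np.zeros((1, 1), dtype=int), "cohabitation")
        b = AssociationMatrix(("B",), np.zeros((1, 1), dtype=int), "intraroost")
        with pytest.raises(ValueError):
            align_matrices(a, b, "intersection")

    def test_self_alignment_is_identity_up_to_order(self):
        rng = np.random.default_rng(0)
        w = rng.integers(0, 4, (5, 5))
        w = np.triu(w, 1) + np.triu(w, 1).T
        a = AssociationMatrix(tuple("EDCBA"), w, "cohabitation")
        a2, b2 = align_matrices(a, a, "union")
        assert a2.nodes == tuple(sorted(a.nodes))
        for x in a.nodes:
            for y in a.nodes:
                if x != y:
                    assert a2.weight(x, y) == a.weight(x, y) == b2.weight(x, y)

    def test_every_shared_dyad_preserved_on_random_fixture(self):
        rng = np.random.default_rng(42)
        def rand_mat(nodes, kind):
            n = len(nodes)
            w = rng.integers(0, 6, (n, n))
            w = np.triu(w, 1) + np.triu(w, 1).T
            return AssociationMatrix(tuple(nodes), w, kind)

        a = rand_mat(["A", "B", "C", "D", "E"], "cohabitation")
        b = rand_mat(["C", "D", "E", "F"], "intraroost")
        for mode in ("union", "intersection"):
            a2, b2 = align_matrices(a, b, mode)
            for x, y in itertools.combinations(a2.nodes, 2):
                if x in a.nodes and y in a.nodes:
                    assert a2.weight(x, y) == a.weight(x, y)
                if x in b.nodes and y in b.nodes:
                    assert b2.weight(x, y) == b.weight(x, y)


class TestInvariantsAndRoundTrips:
    def test_matrix_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            AssociationMatrix(("a", "b"), np.array([[0, 1], [0, 0]]), "cohabitation")
        with pytest.raises(ValueError, match="diagonal"):
            AssociationMatrix(("a", "b"), np.array([[1, 1], [1, 0]]), "cohabitation")
        with pytest.raises(ValueError, match="duplicates"):
            AssociationMatrix(("a", "a"), np.zeros((2, 2), dtype=int), "cohabitation")

    def test_matrix_csv_round_trip(self, tmp_path):
        m = AssociationMatrix(("A", "B", "C"),
                              np.array([[0, 2, 0], [2, 0, 7], [0, 7, 0]]),
                              "intraroost")
        p = tmp_path / "m.csv"
        m.to_csv(p)
        again = AssociationMatrix.read_csv(p, kind="intraroost")
        assert again.nodes == m.nodes
        assert np.array_equal(again.weights, m.weights)

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=20, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_weights_invariant_to_event_order(self, registry, season, rnd):
        events = [
            ev(f"2017-07-{1 + i % 5:02d} 06:{i % 30:02d}:00",
               f"T{i % 6}", ["R0_E0", "R1_E0", "R0_C0", "R1_C1"][i % 4])
            for i in range(40)
        ]
        shuffled = events[:]
        rnd.shuffle(shuffled)
        m1 = build_cohabitation(daily_presence(events, registry, season))
        m2 = build_cohabitation(daily_presence(shuffled, registry, season))
        assert m1.nodes == m2.nodes
        assert np.array_equal(m1.weights, m2.weights)
        b1 = build_intraroost(bin_detections(events, registry, season))
        b2 = build_intraroost(bin_detections(shuffled, registry, season))
        assert np.array_equal(b1.weights, b2.weights)

    def test_perfect_detection_intraroost_tie_implies_cohabitation_tie(self):
        """With perfect detection at every antenna and covered zones only,
        sharing a ceiling bin entails sharing the roost that day."""
        config = ColonyConfig(
            n_bats=16, tagged_fraction=1.0, n_roosts=2, zones_per_roost=2,
            antennas_per_roost_ceiling=2, n_subgroups=2, p_entry_detect=1.0,
            p_ceiling_detect=1.0,
            season=StudyWindow(dt.date(2017, 6, 10), dt.date(2017, 6, 24)),
            residency_minutes_per_day=60, seed=8,
        )
        events, _ = simulate_colony(config)
        registry = antenna_registry_for(config)
        coh = build_cohabitation(daily_presence(events, registry, config.season))
        intra = build_intraroost(bin_detections(events, registry, config.season))
        a, b = align_matrices(coh, intra, "union")
        assert np.all(dichotomize(a).weights >= dichotomize(b).weights)
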