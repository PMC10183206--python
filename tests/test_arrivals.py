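"""Arrival detection, the three association methods, window slicing."""

import numpy as np
import pandas as pd
import pytest

from conftest import (brute_force_dyad_counts, make_arrivals, make_visits,
                      random_arrival_stream)
from flocknet import ArrivalParams
from flocknet.arrivals import (associate_arrivals, detect_arrivals,
                               gambit_of_group, slice_windows,
                               time_window_overlap)


class TestDetectArrivals:
    def test_gap_rule_splits_bouts(self, params):
        # detections at 0, 100, 600: gap 500 > 300 starts a new bout
        visits = make_visits({"A": [0, 100, 600]})
        arr = detect_arrivals(visits, params)
        assert list(arr["arrival_time"]) == [0.0, 600.0]
        assert list(arr["bout_end"]) == [100.0, 600.0]

    def test_single_detection_is_its_own_bout(self, params):
        arr = detect_arrivals(make_visits({"A": [50]}), params)
        assert len(arr) == 1
        assert arr.loc[0, "arrival_time"] == arr.loc[0, "bout_end"] == 50.0

    def test_gap_exactly_delta_i_stays_one_bout(self, params):
        # the absence must strictly exceed 300 s
        arr = detect_arrivals(make_visits({"A": [0, 300]}), params)
        assert len(arr) == 1
        arr2 = detect_arrivals(make_visits({"A": [0, 301]}), params)
        assert len(arr2) == 2

    def test_unsorted_input_rejected(self, params):
        visits = make_visits({"A": [0, 100]}).iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="sorted"):
            detect_arrivals(visits, params)

    def test_empty_input(self, params):
        assert detect_arrivals(make_visits({}), params).empty


class TestAssociateArrivals:
    def test_dyadic_not_transitive(self, params):
        # A@0, B@100, C@200: A-B and B-C associated, A-C not (gap 200)
        counts = associate_arrivals(
            make_arrivals({"A": [0], "B": [100], "C": [200]}), params)
        assert counts.get("A", "B") == 1
        assert counts.get("B", "C") == 1
        assert counts.get("A", "C") == 0

    def test_boundary_inclusive(self, params):
        counts = associate_arrivals(
            make_arrivals({"A": [0], "B": [150]}), params)
        assert counts.get("A", "B") == 1
        counts2 = associate_arrivals(
            make_arrivals({"A": [0], "B": [151]}), params)
        assert counts2.get("A", "B") == 0

    def test_lone_arrival_has_no_dyads(self, params):
        counts = associate_arrivals(make_arrivals({"A": [0]}), params)
        assert counts.x == {} and counts.n == {"A": 1}

    def test_one_to_one_matching_caps_counts(self, params):
        # one arrival of A cannot be matched against two bouts of B
        counts = associate_arrivals(
            make_arrivals({"A": [500], "B": [400, 600]}), params)
        assert counts.get("A", "B") == 1

    def test_binary_per_window_counting(self, params):
        arr = make_arrivals({"A": [0, 1000], "B": [50, 1050]})
        per_event = associate_arrivals(arr, params, "per_event")
        binary = associate_arrivals(arr, params, "binary_per_window")
        assert per_event.get("A", "B") == 2
        assert binary.get("A", "B") == 1

    def test_empty_arrivals(self, params):
        counts = associate_arrivals(make_arrivals({}), params)
        assert counts.x == {}

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_brute_force_oracle(self, seed, params):
        """Greedy matcher equals the O(n^2) all-pairs oracle exactly."""
        rng = np.random.default_rng(seed)
        stream = random_arrival_stream(rng, n_max=80)
        counts = associate_arrivals(stream, params)
        oracle = brute_force_dyad_counts(stream, params.delta_t)
        assert counts.x == oracle
        counts.validate()

    def test_symmetry_and_validity_on_simulated_stream(self, small_sim,
                                                       params):
        arr = detect_arrivals(small_sim["visits"], params)
        counts = associate_arrivals(arr, params)
        counts.validate()
        for (a, b), v in counts.x.items():
            assert a < b and v >= 1
            assert counts.get(b, a) == v


class TestGambitOfGroup:
    def test_single_linkage_chains_into_one_group(self):
        counts = gambit_of_group(
            make_arrivals({"A": [0], "B": [100], "C": [200]}), gap=150)
        assert counts.get("A", "B") == counts.get("B", "C") \
            == counts.get("A", "C") == 1

    def test_distant_arrivals_form_singletons(self):
        counts = gambit_of_group(
            make_arrivals({"A": [0], "B": [1000]}), gap=150)
        assert counts.x == {}

    def test_gambit_links_where_arrival_time_does_not(self, params):
        # the overestimation contrast between methods
        arr = make_arrivals({"A": [0], "B": [100], "C": [200]})
        gambit = gambit_of_group(arr, gap=params.delta_t)
        dyadic = associate_arrivals(arr, params)
        assert gambit.get("A", "C") == 1 and dyadic.get("A", "C") == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_gambit_edges_superset_of_arrival_time(self, seed, params):
        rng = np.random.default_rng(1000 + seed)
        stream = random_arrival_stream(rng, n_max=60)
        gambit = gambit_of_group(stream, gap=params.delta_t)
        dyadic = associate_arrivals(stream, params)
        assert set(dyadic.x) <= set(gambit.x)

    def test_invalid_gap(self):
        with pytest.raises(ValueError):
            gambit_of_group(make_arrivals({"A": [0]}), gap=0)


class TestTimeWindowOverlap:
    def test_overlapping_bouts_counted(self, params):
        visits = make_visits({"A": [0, 50], "B": [40, 90]})
        counts = time_window_overlap(visits, params)
        assert counts.get("A", "B") == 1

    def test_extended_interval_still_misses(self, params):
        # A present [0,50] extends to [0,200]; B starts at 210
        visits = make_visits({"A": [0, 50], "B": [210, 260]})
        counts = time_window_overlap(visits, params)
        assert counts.get("A", "B") == 0

    def test_chain_structure_without_closure(self):
        # chained presence produces A-B and B-C but not A-C
        params = ArrivalParams(delta_t=10, delta_i=300)
        visits = make_visits({"A": [0, 100], "B": [95, 200], "C": [195, 300]})
        counts = time_window_overlap(visits, params)
        assert counts.get("A", "B") == 1
        assert counts.get("B", "C") == 1
        assert counts.get("A", "C") == 0


class TestSliceWindows:
    def test_fifteen_week_event_yields_fifteen_slices(self):
        visits = make_visits({"A": [0]})
        out = slice_windows(visits, [("2015-11-01", "2016-02-14")])
        assert len(out) == 15

    def test_boundary_detection_in_first_week(self):
        t0 = int(pd.Timestamp("2015-11-01").timestamp())
        visits = make_visits({"A": [t0]})
        out = slice_windows(visits, [("2015-11-01", "2015-11-15")])
        assert len(out[0]["visits"]) == 1 and out[0]["week"] == 0

    def test_empty_weeks_retained_and_out_of_window_dropped(self):
        t0 = int(pd.Timestamp("2015-11-01").timestamp())
        visits = make_visits({"A": [t0 - 10, t0 + 8 * 86_400]})
        out = slice_windows(visits, [("2015-11-01", "2015-11-15")])
        assert [len(w["visits"]) for w in out] == [0, 1]

    def test_bout_assigned_to_week_of_arrival(self, params):
        # detections straddling a week boundary stay one bout in the
        # arrival week when detected within the same slice
        t0 = int(pd.Timestamp("2015-11-01").timestamp())
        wk = 7 * 86_400
        visits = make_visits({"A": [t0 + wk - 100, t0 + wk + 100]})
        out = slice_windows(visits, [("2015-11-01", "2015-11-15")])
        # the two detections land in different week slices by the
        # half-open convention
        assert len(out[0]["visits"]) == 1 and len(out[1]["visits"]) == 1
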