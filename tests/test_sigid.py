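"""Loop merging, contour matching and the REWT/SIGID classification rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_unit, make_units
from sigwhistle.contours import WhistleContour
from sigwhistle.experiments import brute_force_status
from sigwhistle.sigid import (MatchParams, build_rewt_catalog, classify_signature,
                              contour_distance, merge_loops, unit_gap)


def sweep_contour(t0, duration=0.4, session_id="S1", f0=5000.0, f1=15000.0, n=40):
    t = t0 + np.linspace(0.0, duration, n)
    return WhistleContour(session_id, t, np.linspace(f0, f1, n))


class TestMergeLoops:
    def test_gap_below_threshold_merges(self):
        a, b = sweep_contour(0.0), sweep_contour(0.6)  # 0.200 s gap
        (unit,) = merge_loops([a, b])
        assert unit.n_loops == 2

    def test_gap_at_exactly_threshold_does_not_merge(self):
        a, b = sweep_contour(0.0), sweep_contour(0.65)  # exactly 0.250 s
        units = merge_loops([a, b])
        assert [u.n_loops for u in units] == [1, 1]

    def test_single_contour_is_one_unit(self):
        (unit,) = merge_loops([sweep_contour(0.0)])
        assert unit.n_loops == 1 and unit.t_start == 0.0

    def test_merging_spans_chains(self):
        contours = [sweep_contour(0.5 * k) for k in range(4)]  # 0.1 s gaps
        (unit,) = merge_loops(contours)
        assert unit.n_loops == 4
        assert unit.t_end == pytest.approx(1.9)

    def test_sessions_never_merge_together(self):
        a = sweep_contour(0.0, session_id="A")
        b = sweep_contour(0.5, session_id="B")
        assert len(merge_loops([a, b])) == 2

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=30.0), min_size=1,
                    max_size=10, unique=True))
    def test_order_independence_and_idempotence(self, starts):
        contours = [sweep_contour(t0) for t0 in sorted(starts)]
        fwd = merge_loops(contours)
        rev = merge_loops(contours[::-1])
        assert [(u.t_start, u.n_loops) for u in fwd] == \
               [(u.t_start, u.n_loops) for u in rev]
        again = merge_loops([c for u in fwd for c in u.contours])
        assert [(u.t_start, u.n_loops) for u in again] == \
               [(u.t_start, u.n_loops) for u in fwd]


class TestContourDistance:
    def test_identity_is_zero(self):
        c = sweep_contour(0.0)
        assert contour_distance(c, c) == 0.0

    def test_time_shift_invariance(self):
        c = sweep_contour(0.0)
        assert contour_distance(c, c.shifted(5.0)) == pytest.approx(0.0, abs=1e-12)

    def test_frequency_offset_invariance(self):
        c = sweep_contour(0.0)
        d = WhistleContour("S1", c.times, c.freqs + 3000.0)
        assert contour_distance(c, d) == pytest.approx(0.0, abs=1e-12)

    def test_mirror_exceeds_threshold(self):
        up = sweep_contour(0.0)
        down = WhistleContour("S1", up.times, up.freqs[::-1].copy())
        assert contour_distance(up, down) > MatchParams().threshold

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = WhistleContour("S1", np.linspace(0, 1, 30), 5000 + rng.uniform(0, 5000, 30))
        b = WhistleContour("S1", np.linspace(0, 2, 40), 6000 + rng.uniform(0, 5000, 40))
        assert contour_distance(a, b) == pytest.approx(contour_distance(b, a))

    def test_dtw_metric_available(self):
        a, b = sweep_contour(0.0), sweep_contour(0.0)
        p = MatchParams(metric="dtw")
        assert contour_distance(a, b, p) == pytest.approx(0.0, abs=1e-12)


class TestRewtRule:
    def test_two_matching_units_five_seconds_apart_are_rewt(self):
        units = make_units([0.0, 5.5])  # end-to-start gap 5.0 s
        cat = build_rewt_catalog(units)
        assert [e.status for e in cat.entries] == ["REWT"]

    def test_two_matching_units_fifteen_seconds_apart_are_ow(self):
        units = make_units([0.0, 15.5])
        cat = build_rewt_catalog(units)
        assert [e.status for e in cat.entries] == ["OW"]

    def test_rule_is_scoped_to_one_session(self):
        units = (make_units([0.0], session_id="A")
                 + make_units([5.0], session_id="B"))
        cat = build_rewt_catalog(units)
        assert [e.status for e in cat.entries] == ["OW"]

    def test_gap_boundaries_are_inclusive(self):
        # end-to-start gaps of exactly 0.25 and exactly 10 s qualify
        for gap in (0.25, 10.0):
            units = make_units([0.0, 0.5 + gap])
            assert build_rewt_catalog(units).entries[0].status == "REWT"
        for gap in (0.249, 10.001):
            units = make_units([0.0, 0.5 + gap])
            expected = "REWT" if 0.25 <= gap <= 10 else "OW"
            assert build_rewt_catalog(units).entries[0].status == expected


class TestSigidRule:
    def classify(self, starts, duration=0.5):
        units = make_units(starts, duration)
        return classify_signature(build_rewt_catalog(units), units)

    def test_four_units_evenly_spaced_are_sw(self):
        cat = self.classify([0.0, 3.0, 6.0, 9.0])
        assert cat.entries[0].status == "SW"
        assert cat.entries[0].sw_id == "SW01"

    def test_three_units_are_not_sw(self):
        cat = self.classify([0.0, 3.0, 6.0])
        assert cat.entries[0].status == "REWT"

    def test_three_of_four_in_window_is_exactly_enough(self):
        cat = self.classify([0.0, 3.0, 6.0, 60.0])
        assert cat.entries[0].status == "SW"

    def test_all_gaps_too_long_is_not_sw(self):
        cat = self.classify([0.0, 30.0, 60.0, 90.0])
        assert cat.entries[0].status == "OW"  # 30 s gaps also fail REWT

    def test_dense_subsecond_bout_is_rewt_not_sw(self):
        cat = self.classify([0.0, 1.0, 2.0, 3.0])  # gaps 0.5 s each
        assert cat.entries[0].status == "REWT"

    def test_sw_id_propagates_across_sessions(self):
        units = (make_units([0.0, 3.0, 6.0, 9.0], session_id="A")
                 + make_units([0.0], session_id="B"))
        cat = classify_signature(build_rewt_catalog(units), units)
        assert set(cat.assignments["sw_id"]) == {"SW01"}

    def test_adding_a_compliant_unit_never_demotes(self):
        starts = [0.0, 3.0, 6.0, 9.0]
        base = self.classify(starts)
        assert base.entries[0].status == "SW"
        for extra in (12.0, 13.5, 50.0):
            grown = self.classify(starts + [extra])
            assert grown.entries[0].status == "SW"


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_sessions(self):
        """Catalogue classification equals pair/gap enumeration (small sweep;
        the full 1000-session sweep runs in the acceptance suite)."""
        from sigwhistle.experiments import sigid_oracle_sweep

        assert sigid_oracle_sweep(n_sessions=60, seed=17) == 0

    def test_brute_force_agrees_on_textbook_cases(self):
        units = make_units([0.0, 3.0, 6.0, 60.0])
        assert brute_force_status(units, [0, 0, 0, 0]) == ["SW"] * 4
        units = make_units([0.0, 30.0, 60.0, 90.0])
        assert brute_force_status(units, [0, 0, 0, 0]) == ["OW"] * 4


def test_unit_gap_is_symmetric_and_nonnegative():
    a, b = make_unit(0.0), make_unit(3.0)
    assert unit_gap(a, b) == unit_gap(b, a) == pytest.approx(2.5)
    overlapping = make_unit(0.2)
    assert unit_gap(a, overlapping) == 0.0
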