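import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvasync import (
    AsynchronyMetrics,
    DataError,
    MetricError,
    compute_easyn,
    compute_rms,
    loop_area,
    moving_average_easyn,
    summarize_cohort,
)


class TestLoopArea:
    def test_unit_square(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        assert loop_area(pts) == pytest.approx(1.0)

    def test_right_triangle(self):
        pts = np.array([[0, 0], [1, 0], [1, 1]], float)
        assert loop_area(pts) == pytest.approx(0.5)

    def test_figure_eight_nets_signed_areas(self):
        # unit square (ccw, +1) chained to a 0.5x0.5 square traversed cw
        # (-0.25): |net| = 0.75
        eight = np.array([
            [0, 0], [1, 0], [1, 1], [0, 1], [0, 0],
            [0.5, 0], [0.5, -0.5], [0, -0.5],
        ], float)
        assert loop_area(eight) == pytest.approx(0.75)

    def test_figure_eight_split_rule_sums_subloops(self):
        pytest.importorskip("shapely")
        eight = np.array([
            [0, 0], [1, 0], [1, 1], [0, 1], [0, 0],
            [0.5, 0], [0.5, -0.5], [0, -0.5],
        ], float)
        assert loop_area(eight, rule="split") == pytest.approx(1.25)

    def test_degenerate_loop_rejected(self):
        with pytest.raises(DataError):
            loop_area(np.array([[0, 0], [1, 1]], float))

    def test_matches_shapely_on_simple_loops(self):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import Polygon

        rng = np.random.default_rng(5)
        theta = np.sort(rng.uniform(0, 2 * np.pi, 40))
        r = 1 + 0.3 * np.cos(3 * theta)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        assert loop_area(pts) == pytest.approx(Polygon(pts).area, abs=1e-12)

    def test_matches_analytic_piecewise_loop(self):
        # closure-consistent quadrilateral loop: vertices at the breakpoints
        k1, k2, k3 = 25.0, 10.0, 40.0
        vm1, vmax = 0.1, 0.5
        top = k1 * vm1 + k2 * (vmax - vm1)
        vm2 = 0.421875
        k4 = (top - k3 * (vmax - vm2)) / vm2
        pts = np.array([
            [0, 0], [vm1, k1 * vm1], [vmax, top],
            [vm2, top - k3 * (vmax - vm2)],
        ])
        insp = k1 * vm1**2 / 2 + k1 * vm1 * (vmax - vm1) + k2 * (vmax - vm1) ** 2 / 2
        exp = k4 * vm2**2 / 2 + (top - k3 * (vmax - vm2) / 2) * (vmax - vm2)
        assert loop_area(pts) == pytest.approx(insp - exp, abs=1e-9)


class TestEasyn:
    def test_direct_formula(self):
        e, flags = compute_easyn(2.0, 1.0)
        assert e == pytest.approx(50.0)
        assert flags == []

    def test_equal_areas_mean_no_asynchrony(self):
        e, _ = compute_easyn(1.7, 1.7)
        assert e == 0.0

    def test_negative_clamped_and_flagged(self):
        e, flags = compute_easyn(1.0, 1.1)
        assert e == 0.0
        assert "clamped_negative" in flags

    def test_zero_reference_area_undefined(self):
        with pytest.raises(MetricError):
            compute_easyn(0.0, 1.0)

    @given(st.floats(1e-3, 1e3), st.floats(0.0, 1e3),
           st.floats(1e-3, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, a_vent, a_asyn, c):
        e1, _ = compute_easyn(a_vent, a_asyn)
        e2, _ = compute_easyn(c * a_vent, c * a_asyn)
        assert e1 == pytest.approx(e2, abs=1e-6)


class TestRms:
    def test_identity_is_zero(self):
        p = np.linspace(5, 12, 50)
        assert compute_rms(p, p) == 0.0

    def test_constant_offset(self):
        assert compute_rms(np.full(30, 10.0), np.full(30, 11.0)) == pytest.approx(10.0)

    def test_matches_two_pass_brute_force(self):
        rng = np.random.default_rng(12)
        p = 8 + rng.normal(0, 2, 300)
        q = p + rng.normal(0, 0.5, 300)
        acc = 0.0
        for a, b in zip(p, q):
            acc += (a - b) ** 2
        expected = 100.0 * np.sqrt(acc / len(p)) / (sum(p) / len(p))
        assert compute_rms(p, q) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_is_contract_error(self):
        with pytest.raises(DataError):
            compute_rms(np.ones(5), np.ones(6))


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        out, skipped = moving_average_easyn(np.full(12, 7.0), 4)
        np.testing.assert_allclose(out, 7.0)
        assert skipped == 0

    def test_window_one_is_identity(self):
        x = np.array([1.0, 5.0, 2.0])
        out, _ = moving_average_easyn(x, 1)
        np.testing.assert_allclose(out, x)

    def test_trailing_mean_hand_computed(self):
        out, _ = moving_average_easyn(np.array([0.0, 10.0, 20.0]), 2)
        np.testing.assert_allclose(out, [0.0, 5.0, 15.0])

    def test_skips_infeasible_breaths(self):
        out, skipped = moving_average_easyn(
            np.array([10.0, np.nan, 20.0]), 2)
        assert skipped == 1
        np.testing.assert_allclose(out, [10.0, 10.0, 20.0])

    def test_empty_series(self):
        out, skipped = moving_average_easyn(np.array([]), 1)
        assert out.size == 0 and skipped == 0


class TestCohortSummary:
    def metrics(self, e_values, rms=None):
        return [AsynchronyMetrics(a_ventilated=1.0, a_asyn=1.0, e_asyn=e,
                                  rms_error=rms) for e in e_values]

    def test_all_zero_lands_in_zero_bin(self):
        s = summarize_cohort(self.metrics([0.0] * 5))
        assert s.e_asyn_bins == {"0": 5, "(0,10]": 0, "(10,50]": 0,
                                 "(50,100]": 0}

    def test_bin_edges(self):
        s = summarize_cohort(self.metrics([0.0, 5.0, 30.0, 80.0]))
        assert list(s.e_asyn_bins.values()) == [1, 1, 1, 1]

    def test_counts_match_brute_force_recount(self):
        rng = np.random.default_rng(17)
        vals = rng.uniform(0, 100, 200)
        vals[rng.uniform(size=200) < 0.3] = 0.0
        s = summarize_cohort(self.metrics(list(vals)))
        brute = {
            "0": sum(1 for v in vals if v <= 0),
            "(0,10]": sum(1 for v in vals if 0 < v <= 10),
            "(10,50]": sum(1 for v in vals if 10 < v <= 50),
            "(50,100]": sum(1 for v in vals if 50 < v <= 100),
        }
        assert s.e_asyn_bins == brute
        assert sum(s.e_asyn_bins.values()) == s.n_scored

    def test_rms_cdf_sorted(self):
        ms = self.metrics([1.0, 2.0, 3.0], rms=None)
        for m, r in zip(ms, [5.0, 1.0, 3.0]):
            m.rms_error = r
        s = summarize_cohort(ms)
        np.testing.assert_allclose(s.rms_cdf, [1.0, 3.0, 5.0])
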