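import itertools

import numpy as np
import pytest

from pvasync import (
    UnsegmentableError,
    build_pv_loop,
    extract_breakpoints,
    fit_segments,
    segment_loop,
    select_segment_count,
    superimpose_effort,
)
from pvasync.hla import _dp_segment, _piece_costs


def two_piece_inspiration(k_a=25.0, k_b=10.0, v_break=0.10, v_max=0.5,
                          peep=5.0, n=60, noise=0.0, seed=0):
    v = np.linspace(0.0, v_max, n)
    p = peep + k_a * np.minimum(v, v_break) + k_b * np.clip(v - v_break, 0, None)
    if noise:
        p = p + np.random.default_rng(seed).normal(0, noise, n)
    return v, p


class TestFitSegments:
    def test_recovers_two_piece_slopes_and_break(self):
        v, p = two_piece_inspiration()
        segs = fit_segments(v, p, 2)
        assert segs[0].slope_k == pytest.approx(25.0, abs=1e-6)
        assert segs[1].slope_k == pytest.approx(10.0, abs=1e-6)
        junction = 0.5 * (segs[0].v_end + segs[1].v_start)
        assert abs(junction - 0.10) <= v[1] - v[0]

    def test_straight_limb_split_in_two_keeps_true_slope(self):
        v = np.linspace(0, 0.5, 40)
        p = 5 + 12.5 * v
        segs = fit_segments(v, p, 2)
        for s in segs:
            assert s.slope_k == pytest.approx(12.5, abs=1e-6)

    def test_reverse_trigger_sign_pattern(self, scenario_breath_pairs):
        cfg, vent, asyn = scenario_breath_pairs["reverse_triggering"]
        elastic = asyn.pressure - cfg.r * asyn.flow
        ti = asyn.turning_index
        segs = fit_segments(asyn.volume[: ti + 1], elastic[: ti + 1], 4)
        signs = [np.sign(s.slope_k) for s in segs]
        assert signs == [1, 1, -1, 1]

    def test_too_few_samples_is_infeasible(self):
        with pytest.raises(UnsegmentableError):
            fit_segments(np.linspace(0, 1, 5), np.linspace(0, 1, 5), 2, min_span=3)

    def test_segments_tile_the_index_range(self):
        v, p = two_piece_inspiration(noise=0.2, seed=1)
        segs = fit_segments(v, p, 3)
        assert segs[0].index_range[0] == 0
        assert segs[-1].index_range[1] == len(v) - 1
        for a, b in zip(segs[:-1], segs[1:]):
            assert b.index_range[0] == a.index_range[1] + 1


class TestSelectSegmentCount:
    def test_ventilated_halves_select_two(self, clean_vc_breath):
        b = clean_vc_breath
        elastic = b.pressure - 10.0 * b.flow
        ti = b.turning_index
        insp = select_segment_count(b.volume[: ti + 1], elastic[: ti + 1])
        exp = select_segment_count(b.volume[ti:], elastic[ti:])
        assert insp.n_segments == 2
        assert exp.n_segments == 2

    def test_reverse_trigger_inspiration_selects_four(self, scenario_breath_pairs):
        cfg, _, asyn = scenario_breath_pairs["reverse_triggering"]
        elastic = asyn.pressure - cfg.r * asyn.flow
        ti = asyn.turning_index
        insp = select_segment_count(asyn.volume[: ti + 1], elastic[: ti + 1])
        assert insp.n_segments == 4

    def test_premature_expiration_selects_three(self, scenario_breath_pairs):
        cfg, _, asyn = scenario_breath_pairs["premature_cycling"]
        elastic = asyn.pressure - cfg.r * asyn.flow
        ti = asyn.turning_index
        exp = select_segment_count(asyn.volume[ti:], elastic[ti:])
        assert exp.n_segments == 3

    def test_flat_half_cycle_unsegmentable(self):
        v = np.linspace(0, 0.5, 50)
        with pytest.raises(UnsegmentableError):
            select_segment_count(v, np.full(50, 5.0) + 0.01 * v)

    def test_residual_monotone_in_segment_count(self):
        v, p = two_piece_inspiration(noise=0.3, seed=7, n=80)
        cost = _piece_costs(v, p)
        rss, _ = _dp_segment(cost, 6, 3)
        vals = [rss[k] for k in sorted(rss)]
        assert all(a >= b - 1e-9 for a, b in zip(vals[:-1], vals[1:]))


class TestExhaustiveOracle:
    """DP breakpoints equal brute-force search over all index partitions."""

    def brute_force(self, v, p, k, min_span=3):
        n = len(v)

        def sse(i, j):
            if j - i + 1 < 2:
                return float(np.var(p[i:j + 1]) * (j - i + 1))
            coef = np.polyfit(v[i:j + 1], p[i:j + 1], 1)
            r = p[i:j + 1] - np.polyval(coef, v[i:j + 1])
            return float(np.sum(r * r))

        best, best_bounds = np.inf, None
        for cuts in itertools.combinations(range(min_span, n - min_span + 1),
                                           k - 1):
            bounds = list(zip((0,) + cuts, tuple(c - 1 for c in cuts) + (n - 1,)))
            if any(e - s + 1 < min_span for s, e in bounds):
                continue
            total = sum(sse(s, e) for s, e in bounds)
            if total < best:
                best, best_bounds = total, bounds
        return best, best_bounds

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_brute_force(self, k):
        v, p = two_piece_inspiration(n=40)
        # make a genuinely 3-piece curve for k=3
        p = p + np.where(v > 0.35, 30.0 * (v - 0.35), 0.0)
        segs = fit_segments(v, p, k)
        dp_sse = sum(s.rms_resid**2 * (s.index_range[1] - s.index_range[0] + 1)
                     for s in segs)
        bf_sse, bf_bounds = self.brute_force(v, p, k)
        assert dp_sse == pytest.approx(bf_sse, abs=1e-9)
        if k > 1:
            assert [s.index_range for s in segs] == [tuple(b) for b in bf_bounds]


class TestBreakpoints:
    def test_known_breakpoints_recovered(self):
        # closure-consistent loop with breakpoints (0.10, 0.35, 0.50)
        k1, k2, k3 = 25.0, 10.0, 30.0
        vm1, vm2, vmax, peep = 0.10, 0.35, 0.50, 5.0
        top = k1 * vm1 + k2 * (vmax - vm1)
        k4 = (top - k3 * (vmax - vm2)) / vm2
        v_i = np.linspace(0, vmax, 70)
        p_i = peep + k1 * np.minimum(v_i, vm1) + k2 * np.clip(v_i - vm1, 0, None)
        v_e = np.linspace(vmax, 0, 70)
        p_e = np.where(v_e >= vm2, peep + top - k3 * (vmax - v_e),
                       peep + k4 * v_e)
        from pvasync.waveforms import PVLoop

        loop = PVLoop(volume=np.concatenate([v_i, v_e[1:]]),
                      pressure=np.concatenate([p_i, p_e[1:]]),
                      insp_slice=slice(0, 70), exp_slice=slice(69, 139))
        seg = segment_loop(loop)
        got = extract_breakpoints(seg)
        dv = vmax / 69
        assert got[0] == pytest.approx(vm1, abs=dv)
        assert got[1] == pytest.approx(vm2, abs=dv)
        assert got[2] == pytest.approx(vmax, abs=1e-12)

    def test_single_segment_inspiration_has_no_vm1(self):
        from pvasync.waveforms import PVLoop

        v_i = np.linspace(0, 0.5, 50)
        p_i = 5 + 13 * v_i
        v_e = np.linspace(0.5, 0, 50)
        p_e = np.where(v_e >= 0.42, 11.5 - 40 * (0.5 - v_e), 5 + 8.36 * v_e)
        loop = PVLoop(volume=np.concatenate([v_i, v_e[1:]]),
                      pressure=np.concatenate([p_i, p_e[1:]]),
                      insp_slice=slice(0, 50), exp_slice=slice(49, 99))
        seg = segment_loop(loop)
        assert len(seg.insp_segments) == 1
        assert seg.vm1 is None

    def test_vmax_is_volume_maximum(self, clean_vc_breath):
        loop = build_pv_loop(clean_vc_breath)
        seg = segment_loop(loop)
        assert seg.vmax == pytest.approx(np.max(loop.volume), abs=1e-12)


class TestNoisyRecovery:
    def test_median_stiffness_error_under_noise(self, clean_vc_breath):
        """Slope recovery within a few percent at sensor noise (subset of
        the full 100-seed acceptance property)."""
        from conftest import add_noise
        from pvasync import analyze_cycle

        errs = {k: [] for k in ("k1", "k2", "k3", "k4")}
        true = dict(k1=25.0, k2=10.0, k3=40.0, k4=8.0)
        for s in range(20):
            res = analyze_cycle(add_noise(clean_vc_breath, 100 + s))
            assert res.ok
            for k, tv in true.items():
                errs[k].append(abs(getattr(res.params, k) - tv) / tv)
        for k, v in errs.items():
            assert np.median(v) < 0.05, k
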