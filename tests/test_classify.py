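import numpy as np
import pytest

from pvasync import (
    InfeasibleError,
    analyze_cycle,
    build_pv_loop,
    classify_asynchrony,
    line_intersection,
    map_parameters,
    segment_loop,
)
from pvasync.hla import Segment

from conftest import add_noise


def make_line(slope, intercept):
    return Segment(slope_k=slope, intercept=intercept, v_start=0.0, v_end=1.0,
                   index_range=(0, 1), rms_resid=0.0)


class TestLineIntersection:
    def test_analytic_example(self):
        # P = 5 + 10(V - 0.1) and P = 2 + 40(V - 0.3) cross at V = 0.4667 L
        a = make_line(10.0, 5.0 - 10.0 * 0.1)
        b = make_line(40.0, 2.0 - 40.0 * 0.3)
        v, p = line_intersection(a, b)
        assert v == pytest.approx(0.46666666666, abs=1e-9)

    def test_matches_dense_evaluation_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            k1, k2 = rng.uniform(-50, 50, 2)
            if abs(k1 - k2) < 0.5:
                continue
            b1, b2 = rng.uniform(-10, 10, 2)
            v, _ = line_intersection(make_line(k1, b1), make_line(k2, b2))
            grid = np.linspace(v - 1e-5, v + 1e-5, 200001)
            gap = np.abs((b1 + k1 * grid) - (b2 + k2 * grid))
            assert abs(grid[np.argmin(gap)] - v) < 1e-9

    def test_parallel_lines_infeasible(self):
        with pytest.raises(InfeasibleError):
            line_intersection(make_line(10.0, 1.0), make_line(10.0, 2.0))


def segment_elastic(cfg, breath):
    elastic = breath.pressure - cfg.r * breath.flow
    return segment_loop(build_pv_loop(breath, pressure=elastic))


class TestClassification:
    def test_ventilated_breath_is_none(self, clean_vc_breath):
        seg = segment_loop(build_pv_loop(
            clean_vc_breath,
            pressure=clean_vc_breath.pressure - 10.0 * clean_vc_breath.flow))
        assert classify_asynchrony(seg).label == "none"

    @pytest.mark.parametrize("scenario", [
        "reverse_triggering", "premature_cycling", "double_triggering"])
    def test_each_scenario_recognised(self, scenario, scenario_breath_pairs):
        cfg, _, asyn = scenario_breath_pairs[scenario]
        call = classify_asynchrony(segment_elastic(cfg, asyn))
        assert call.label == scenario

    def test_double_trigger_carries_vmax2(self, scenario_breath_pairs):
        cfg, _, asyn = scenario_breath_pairs["double_triggering"]
        call = classify_asynchrony(segment_elastic(cfg, asyn))
        assert call.vmax2 is not None
        assert call.vmax2 > cfg.vt

    def test_unclassifiable_is_a_value(self, scenario_breath_pairs):
        cfg, _, asyn = scenario_breath_pairs["double_triggering"]
        seg = segment_elastic(cfg, asyn)
        from dataclasses import replace

        # stacking evidence with too few inspiratory segments
        broken = replace(seg, insp_segments=seg.insp_segments[:2])
        call = classify_asynchrony(broken)
        assert call.label == "unclassifiable"
        assert call.evidence["volume_stacking"]


class TestMapping:
    def test_identity_mapping_for_none(self, clean_vc_breath):
        seg = segment_loop(build_pv_loop(
            clean_vc_breath,
            pressure=clean_vc_breath.pressure - 10.0 * clean_vc_breath.flow))
        call = classify_asynchrony(seg)
        vp = map_parameters(call, seg)
        assert vp.k1 == pytest.approx(seg.insp_segments[0].slope_k)
        assert vp.k2 == pytest.approx(seg.insp_segments[1].slope_k)
        assert vp.k3 == pytest.approx(seg.exp_segments[0].slope_k)
        assert vp.k4 == pytest.approx(seg.exp_segments[1].slope_k)

    @pytest.mark.parametrize("scenario", [
        "reverse_triggering", "premature_cycling", "double_triggering"])
    def test_recovers_ventilated_parameters(self, scenario,
                                            scenario_breath_pairs):
        """Noise-free asynchronous breaths map back to the generator's
        ventilated stiffnesses and breakpoints within 10%."""
        cfg, vent, asyn = scenario_breath_pairs[scenario]
        res = analyze_cycle(asyn)
        assert res.ok
        true = dict(k1=cfg.k1, k2=cfg.k2, k3=cfg.k3, k4=cfg.k4,
                    vm1=cfg.vm1, vm2=cfg.vm2, vmax=cfg.vt)
        for name, tv in true.items():
            assert abs(getattr(res.params, name) - tv) / tv < 0.10, name

    def test_mapping_requires_segments(self, clean_vc_breath):
        seg = segment_loop(build_pv_loop(
            clean_vc_breath,
            pressure=clean_vc_breath.pressure - 10.0 * clean_vc_breath.flow))
        call = classify_asynchrony(seg)
        from dataclasses import replace

        with pytest.raises(InfeasibleError):
            map_parameters(call, replace(seg, insp_segments=seg.insp_segments[:1]))


class TestAccuracyUnderNoise:
    def test_default_noise_classification(self, scenario_breath_pairs):
        """All three asynchrony types and the unaffected breath classify
        correctly across seeded sensor-noise draws at the default level."""
        good, tot = 0, 0
        for sc, (cfg, vent, asyn) in scenario_breath_pairs.items():
            for s in range(8):
                res_v = analyze_cycle(add_noise(vent, 300 + s))
                res_a = analyze_cycle(add_noise(asyn, 600 + s))
                good += (res_v.label == "none") + (res_a.label == sc)
                tot += 2
        assert good == tot
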