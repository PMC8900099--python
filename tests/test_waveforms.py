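import numpy as np
import pandas as pd
import pytest

from pvasync import (
    DataError,
    FormatError,
    InfeasibleError,
    ScenarioConfig,
    WaveformRecord,
    build_pv_loop,
    generate_scenario_set,
    integrate_flow_to_volume,
    read_waveform_csv,
    split_breaths,
    write_waveform_csv,
)


def make_record(time, pressure, flow, rate=50.0, meta=None):
    return WaveformRecord(np.asarray(time, float), np.asarray(pressure, float),
                          np.asarray(flow, float), rate, meta or {})


class TestReadWrite:
    def test_identity_read(self, tmp_path):
        p = tmp_path / "w.csv"
        pd.DataFrame({"time": [0.0, 0.02, 0.04],
                      "pressure": [5.0, 6.0, 7.0],
                      "flow": [0.0, 0.5, 0.5]}).to_csv(p, index=False)
        rec = read_waveform_csv(p)
        assert len(rec) == 3
        assert rec.sample_rate == pytest.approx(50.0)
        np.testing.assert_allclose(rec.pressure, [5.0, 6.0, 7.0])

    def test_flow_unit_conversion(self, tmp_path):
        p = tmp_path / "w.csv"
        pd.DataFrame({"t": [0.0, 0.02], "paw": [5.0, 6.0],
                      "q": [30.0, 30.0]}).to_csv(p, index=False)
        rec = read_waveform_csv(
            p, {"columns": {"time": "t", "pressure": "paw", "flow": "q"},
                "units": {"flow": "L/min"}})
        np.testing.assert_allclose(rec.flow, [0.5, 0.5])

    def test_expected_sample_count_20min_50hz(self):
        # 20 minutes at 50 Hz
        assert 20 * 60 * 50 == 60_000

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "w.csv"
        pd.DataFrame({"time": [0.0], "pressure": [5.0]}).to_csv(p, index=False)
        with pytest.raises(FormatError):
            read_waveform_csv(p)

    def test_non_monotone_time_is_data_error(self, tmp_path):
        p = tmp_path / "w.csv"
        pd.DataFrame({"time": [0.0, 0.02, 0.01], "pressure": [5, 5, 5],
                      "flow": [0, 0, 0]}).to_csv(p, index=False)
        with pytest.raises(DataError):
            read_waveform_csv(p)

    def test_empty_file_is_format_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(FormatError):
            read_waveform_csv(p)

    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        rec = make_record(np.arange(100) * 0.02,
                          5 + rng.normal(size=100), rng.normal(size=100))
        path = tmp_path / "rt.csv"
        write_waveform_csv(rec, path)
        back = read_waveform_csv(path)
        np.testing.assert_array_equal(back.time, rec.time)
        np.testing.assert_array_equal(back.pressure, rec.pressure)
        np.testing.assert_array_equal(back.flow, rec.flow)


class TestVolumeIntegration:
    def test_constant_flow_integral(self):
        t = np.arange(51) * 0.02
        rec = make_record(t, np.full(51, 5.0), np.full(51, 0.5))
        v = integrate_flow_to_volume(rec)
        assert v[-1] == pytest.approx(0.5, abs=1e-12)

    def test_zero_flow_zero_volume(self):
        t = np.arange(50) * 0.02
        v = integrate_flow_to_volume(make_record(t, np.full(50, 5.0), np.zeros(50)))
        np.testing.assert_allclose(v, 0.0)

    def test_full_sine_period_nets_zero(self):
        t = np.linspace(0, 1, 2001)
        flow = np.sin(2 * np.pi * t)
        v = integrate_flow_to_volume(make_record(t, np.full_like(t, 5.0), flow,
                                                 rate=2000))
        # closed form: integral of sin over a full period is 0
        assert abs(v[-1]) < 1e-6

    def test_rezeroed_at_each_breath(self):
        lbs = generate_scenario_set(ScenarioConfig(
            scenario="none", n_breaths=3, seed=2,
            noise_sd_pressure=0.0, noise_sd_flow=0.0))
        v = integrate_flow_to_volume(lbs.record)
        n = lbs.config.n_samples
        for b in range(3):
            assert abs(v[b * n]) < 1e-9


class TestSplitBreaths:
    def test_counts_match_simulator(self):
        lbs = generate_scenario_set(ScenarioConfig(
            scenario="reverse_triggering", n_breaths=3, seed=11))
        cycles = split_breaths(lbs.record)
        assert len(cycles) == 6  # 3 ventilated + 3 asynchronous

    def test_single_breath_peaks_at_tidal_volume(self, clean_vc_breath):
        rec = make_record(clean_vc_breath.time, clean_vc_breath.pressure,
                          clean_vc_breath.flow, meta={"peep": 5.0})
        cycles = split_breaths(rec)
        assert len(cycles) == 1
        assert cycles[0].v_max_observed == pytest.approx(0.5, abs=1e-9)
        assert cycles[0].volume[0] == pytest.approx(0.0, abs=1e-12)

    def test_flat_line_yields_no_breaths(self):
        t = np.arange(200) * 0.02
        with pytest.warns(UserWarning):
            cycles = split_breaths(make_record(t, np.full(200, 5.0),
                                               np.zeros(200)))
        assert cycles == []

    def test_split_concat_preserves_samples(self):
        lbs = generate_scenario_set(ScenarioConfig(
            scenario="premature_cycling", n_breaths=4, seed=13))
        cycles = split_breaths(lbs.record)
        assert sum(c.n for c in cycles) == len(lbs.record)

    def test_effort_flow_bumps_do_not_split_breaths(self):
        # premature cycling and double triggering produce positive flow
        # during expiration; the volume guard must keep each breath whole
        for sc in ("premature_cycling", "double_triggering"):
            lbs = generate_scenario_set(ScenarioConfig(
                scenario=sc, n_breaths=5, seed=4))
            assert len(split_breaths(lbs.record)) == 10


class TestPVLoop:
    def test_phases_split_at_volume_peak(self, clean_vc_breath):
        loop = build_pv_loop(clean_vc_breath)
        ti = clean_vc_breath.turning_index
        assert loop.insp_slice == slice(0, ti + 1)
        assert loop.exp_slice.start == ti
        assert np.argmax(loop.volume) == ti

    def test_loop_closes_near_zero_volume(self, clean_vc_breath):
        loop = build_pv_loop(clean_vc_breath)
        assert abs(loop.volume[0]) < 1e-9
        assert abs(loop.volume[-1]) < 0.02 * 0.5  # within 2% of VT

    def test_truncated_breath_is_infeasible(self):
        t = np.arange(100) * 0.02
        rec_vol_only_up = make_record(t, 5 + 10 * t, np.full(100, 0.5))
        cycles = split_breaths(rec_vol_only_up)
        assert len(cycles) == 1
        with pytest.raises(InfeasibleError):
            build_pv_loop(cycles[0])
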