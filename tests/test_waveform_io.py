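"""Waveform loading, segmentation, holds, loop extraction and QC."""

from __future__ import annotations

import numpy as np
import pytest

from peepopt import synthetic_data, waveform_io
from peepopt.waveform_io import (IoConfig, PressureFlowRecord,
                                 correct_resistive_pressure,
                                 estimate_auto_peep, estimate_resistance,
                                 extract_pv_loops,
                                 flag_pressure_drop_anomaly, load_waveform,
                                 read_loops_csv, segment_breaths,
                                 write_loops_csv)


def _write_csv(path, time, paw, flow):
    import pandas as pd
    pd.DataFrame({"time_s": time, "paw_cmH2O": paw,
                  "flow_lps": flow}).to_csv(path, index=False)


class TestLoadWaveform:
    def test_constant_flow_integrates_to_half_litre(self, tmp_path):
        t = np.arange(0, 1.0, 0.01)
        path = tmp_path / "wf.csv"
        _write_csv(path, t, np.full(t.size, 10.0), np.full(t.size, 0.5))
        rec = load_waveform(path)
        # 0.5 L/s for 0.99 s of trapezoid support
        assert rec.volume[-1] == pytest.approx(495.0, abs=0.5)
        assert rec.volume[0] == 0.0

    def test_zero_flow_gives_zero_volume(self, tmp_path):
        t = np.arange(0, 1.0, 0.01)
        path = tmp_path / "wf.csv"
        _write_csv(path, t, np.full(t.size, 5.0), np.zeros(t.size))
        rec = load_waveform(path)
        assert np.all(rec.volume == 0.0)

    def test_missing_column_raises(self, tmp_path):
        import pandas as pd
        path = tmp_path / "bad.csv"
        pd.DataFrame({"time_s": [0, 0.01], "paw_cmH2O": [5, 6]}).to_csv(
            path, index=False)
        with pytest.raises(ValueError, match="flow_lps"):
            load_waveform(path)

    def test_non_monotonic_time_raises(self, tmp_path):
        path = tmp_path / "bad.csv"
        _write_csv(path, [0.0, 0.02, 0.01], [5, 5, 5], [0, 0, 0])
        with pytest.raises(ValueError, match="increasing"):
            load_waveform(path)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            load_waveform(path)

    def test_round_trip_matches_generator_volume(self, twin_manoeuvre,
                                                 tmp_path):
        """Integrated volume reproduces the generator's own volume trace."""
        path = tmp_path / "twin.csv"
        waveform_io.write_waveform_csv(twin_manoeuvre.record, path)
        rec = load_waveform(path)
        assert np.max(np.abs(rec.volume - twin_manoeuvre.true_volume)) < 0.5


class TestSegmentBreaths:
    def test_staircase_breath_count(self, plain_manoeuvre):
        """5 breaths per each of 6 PEEP steps -> 30 segments."""
        segs = segment_breaths(plain_manoeuvre.record)
        assert len(segs) == 30

    def test_zero_flow_returns_empty_with_warning(self):
        t = np.arange(0, 2, 0.01)
        rec = PressureFlowRecord.from_channels(
            t, np.full(t.size, 5.0), np.zeros(t.size))
        with pytest.warns(UserWarning, match="no breaths"):
            assert segment_breaths(rec) == []

    def test_square_wave_single_breath(self):
        """One square-wave breath: tidal volume = amplitude x insp time."""
        t = np.arange(0, 3, 0.01)
        flow = np.where(t < 1.0, 0.4, -0.2)
        flow[t >= 2.99] = 0.0
        rec = PressureFlowRecord.from_channels(
            t, np.full(t.size, 10.0), flow)
        segs = segment_breaths(rec)
        assert len(segs) == 1
        assert segs[0].tidal_volume_ml == pytest.approx(400.0, rel=0.02)

    def test_small_breaths_discarded(self):
        t = np.arange(0, 4, 0.01)
        flow = np.zeros(t.size)
        flow[(t >= 0) & (t < 1)] = 0.4        # 400 ml breath
        flow[(t >= 1) & (t < 2)] = -0.4
        flow[(t >= 2) & (t < 2.1)] = 0.2      # 20 ml blip < 50 ml threshold
        flow[(t >= 2.1) & (t < 2.2)] = -0.2
        rec = PressureFlowRecord.from_channels(t, np.full(t.size, 5.0), flow)
        assert len(segment_breaths(rec)) == 1

    def test_segments_are_ordered_and_disjoint(self, twin_manoeuvre):
        segs = segment_breaths(twin_manoeuvre.record)
        for a, b in zip(segs, segs[1:]):
            assert a.i_exp_end <= b.i_insp_start


class TestExtractLoops:
    def test_one_loop_per_peep_level(self, plain_manoeuvre):
        """Staircase 0->25 by 5 yields six loops at {0,5,10,15,20,25}."""
        segs = segment_breaths(plain_manoeuvre.record)
        loops = extract_pv_loops(plain_manoeuvre.record, segs)
        assert [l.peep for l in loops] == [0.0, 5.0, 10.0, 15.0, 20.0, 25.0]

    def test_noise_free_inflation_matches_forward_model(
            self, plain_manoeuvre):
        """Extracted inflation limbs lie on the generating CDF."""
        man = plain_manoeuvre
        segs = segment_breaths(man.record)
        loops = extract_pv_loops(man.record, segs, baseline_ml=man.frc_ml)
        truth = man.truth
        for loop in loops:
            mu = truth.top_mean(loop.peep)
            from scipy.special import ndtr
            pred = truth.tlc_ml * ndtr(
                (loop.inflation_p - mu) / truth.inflation_sd)
            assert np.max(np.abs(pred - loop.inflation_v)) < 3.0

    def test_loop_invariants(self, twin_pipeline):
        for loop in twin_pipeline["raw_loops"]:
            assert np.all(np.diff(loop.inflation_p) >= 0)
            assert np.all(np.diff(loop.deflation_p) <= 0)
            assert np.all(loop.inflation_v >= 0)
            assert loop.inflation_p.max() <= 45.0

    def test_twin_reaches_off_grid_top_level(self, twin_pipeline):
        """The pressure cap truncates the staircase between grid steps."""
        peeps = [l.peep for l in twin_pipeline["raw_loops"]]
        assert peeps == [10.0, 15.0, 20.0, 25.0, 27.0]

    def test_loops_csv_round_trip(self, twin_pipeline, tmp_path):
        loops = twin_pipeline["raw_loops"]
        path = tmp_path / "loops.csv"
        write_loops_csv(loops, path)
        back = read_loops_csv(path)
        assert [l.peep for l in back] == [l.peep for l in loops]
        np.testing.assert_allclose(back[0].inflation_v,
                                   loops[0].inflation_v, atol=1e-3)


class TestHolds:
    def test_auto_peep_from_twin_hold(self, twin_pipeline):
        """ZEEP hold plateau of the 10-cmH2O-auto-PEEP twin reads ~10."""
        assert twin_pipeline["auto_peep"] == pytest.approx(10.0, abs=0.5)

    def test_hold_at_set_peep_gives_zero(self):
        t = np.arange(0, 1, 0.01)
        rec = PressureFlowRecord.from_channels(
            t, np.full(t.size, 8.0), np.zeros(t.size))
        assert estimate_auto_peep(rec, (0.2, 0.8), set_peep=8.0) == 0.0

    def test_plateau_below_set_peep_clips_to_zero(self):
        t = np.arange(0, 1, 0.01)
        rec = PressureFlowRecord.from_channels(
            t, np.full(t.size, 7.0), np.zeros(t.size))
        assert estimate_auto_peep(rec, (0.2, 0.8), set_peep=8.0) == 0.0

    def test_nonzero_flow_invalidates_hold(self):
        t = np.arange(0, 1, 0.01)
        rec = PressureFlowRecord.from_channels(
            t, np.full(t.size, 10.0), np.full(t.size, 0.3))
        with pytest.raises(ValueError, match="invalid hold"):
            estimate_auto_peep(rec, (0.2, 0.8))

    def test_synthetic_auto_peep_six(self):
        truth = synthetic_data.GroundTruth(
            seed=3, auto_peep=6.0, noise_sd_pressure=0.0, noise_sd_flow=0.0)
        script = synthetic_data.ProtocolScript(
            peep_steps=(0, 5, 10), tidal_volume_ml=300.0)
        man = synthetic_data.generate_manoeuvre(truth, script)
        est = estimate_auto_peep(man.record, man.hold_windows["end_exp"],
                                 set_peep=0.0)
        assert est == pytest.approx(6.0, abs=0.5)

    def test_resistance_arithmetic(self):
        """Peak 30, plateau 24, flow at peak 0.6 L/s -> R = 10."""
        t = np.arange(0, 2, 0.01)
        paw = np.where(t < 1.0, 20 + 10 * t, 24.0)
        flow = np.where(t < 1.0, 0.6, 0.0)
        rec = PressureFlowRecord.from_channels(t, paw, flow)
        r = estimate_resistance(rec, (1.0, 1.9))
        assert r == pytest.approx(10.0, rel=0.02)

    def test_resistance_recovered_within_ten_percent(self, twin_pipeline):
        assert twin_pipeline["resistance"] == pytest.approx(8.0, rel=0.10)

    def test_zero_flow_at_peak_fails(self):
        t = np.arange(0, 2, 0.01)
        rec = PressureFlowRecord.from_channels(
            t, np.full(t.size, 24.0), np.zeros(t.size))
        with pytest.raises(ValueError):
            estimate_resistance(rec, (1.0, 1.9))

    def test_hold_measurements_invariants(self):
        with pytest.raises(ValueError, match="plateau"):
            waveform_io.HoldMeasurements(
                auto_peep=5.0, inspiratory_resistance=8.0,
                peak_pressure=24.0, plateau_pressure=30.0)
        ok = waveform_io.HoldMeasurements(
            auto_peep=5.0, inspiratory_resistance=8.0,
            peak_pressure=30.0, plateau_pressure=24.0)
        assert ok.auto_peep == 5.0


class TestResistiveCorrection:
    def test_zero_resistance_is_identity(self, twin_pipeline):
        loop = twin_pipeline["raw_loops"][0]
        out = correct_resistive_pressure(loop, 0.0)
        np.testing.assert_array_equal(out.inflation_p, loop.inflation_p)
        np.testing.assert_array_equal(out.deflation_p, loop.deflation_p)

    def test_square_flow_shifts_inflation_down_exactly(self):
        p = np.linspace(10, 30, 11)
        v = np.linspace(100, 500, 11)
        loop = waveform_io.PVLoop(
            peep=5.0, inflation_p=p, inflation_v=v,
            deflation_p=p[::-1], deflation_v=v[::-1],
            inflation_q=np.full(11, 0.5), deflation_q=np.full(11, -0.5))
        out = correct_resistive_pressure(loop, 10.0)
        np.testing.assert_allclose(out.inflation_p, p - 5.0)
        np.testing.assert_allclose(out.deflation_p, p[::-1] + 5.0)

    def test_correction_is_linear_in_resistance(self, twin_pipeline):
        loop = twin_pipeline["raw_loops"][2]
        a = correct_resistive_pressure(loop, 2.0)
        b = correct_resistive_pressure(loop, 4.0)
        shift_a = loop.inflation_p[:a.inflation_p.size] - a.inflation_p
        shift_b = loop.inflation_p[:b.inflation_p.size] - b.inflation_p
        n = min(shift_a.size, shift_b.size)
        np.testing.assert_allclose(2 * shift_a[:n], shift_b[:n], atol=1e-9)

    def test_correction_narrows_the_loop(self, twin_pipeline):
        """Corrected TOP means drop and TCP means rise (same trends).

        Means are re-fitted at the trial's fitted SDs/TLC so the
        uncorrected and corrected loops are compared like for like."""
        from peepopt.recruitment_model import fit_limb_mean
        trial = twin_pipeline["trial"]
        v0, tlc = trial.baseline_ml, trial.tlc_ml
        raw_top, cor_top, raw_tcp, cor_tcp = {}, {}, {}, {}
        for raw, cor in zip(twin_pipeline["raw_loops"],
                            twin_pipeline["loops"]):
            for loop, top, tcp in ((raw, raw_top, raw_tcp),
                                   (cor, cor_top, cor_tcp)):
                top[loop.peep] = fit_limb_mean(
                    (loop.inflation_p, loop.inflation_v + v0),
                    trial.inflation_sd, tlc).distribution.mean
                tcp[loop.peep] = fit_limb_mean(
                    (loop.deflation_p, loop.deflation_v + v0),
                    trial.deflation_sd, tlc).distribution.mean
        assert all(cor_top[p] < raw_top[p] for p in raw_top)
        assert all(cor_tcp[p] > raw_tcp[p] for p in raw_tcp)
        # trends preserved: TOP falling, TCP rising, both before and after
        for means in (raw_top, cor_top):
            vals = [means[p] for p in sorted(means)]
            assert all(b < a for a, b in zip(vals, vals[1:]))
        for means in (raw_tcp, cor_tcp):
            vals = [means[p] for p in sorted(means)]
            assert all(b > a for a, b in zip(vals, vals[1:]))


class TestAnomalyFlag:
    def test_clean_record_has_no_flags(self, plain_manoeuvre):
        segs = segment_breaths(plain_manoeuvre.record)
        assert flag_pressure_drop_anomaly(plain_manoeuvre.record, segs) == []

    def test_injected_dip_is_flagged(self, plain_manoeuvre):
        rec = synthetic_data.inject_anomaly(plain_manoeuvre.record, 7, 3.0)
        segs = segment_breaths(rec)
        assert flag_pressure_drop_anomaly(rec, segs) == [7]

    def test_zero_drop_leaves_record_unchanged(self, plain_manoeuvre):
        rec = synthetic_data.inject_anomaly(plain_manoeuvre.record, 3, 0.0)
        np.testing.assert_array_equal(rec.paw, plain_manoeuvre.record.paw)

    def test_injection_outside_inspiration_fails(self, plain_manoeuvre):
        segs = segment_breaths(plain_manoeuvre.record)
        exp_sample = segs[0].i_insp_end + 10   # expiration phase
        with pytest.raises(ValueError, match="inspiration"):
            synthetic_data.inject_anomaly(plain_manoeuvre.record,
                                          exp_sample, 3.0, by="sample")

    def test_breath_index_out_of_range_fails(self, plain_manoeuvre):
        with pytest.raises(IndexError):
            synthetic_data.inject_anomaly(plain_manoeuvre.record, 999, 2.0)
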