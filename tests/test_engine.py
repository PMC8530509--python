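import numpy as np
import pytest
from scipy.signal import argrelmax, hilbert

import ratclas as rc
from ratclas.engine import StreamingFilters, _pink, trailing_rms


class TestStreamingFilters:
    def test_chunked_equals_single_pass(self):
        rng = np.random.default_rng(0)
        fs = 610.35
        eeg = rng.standard_normal(int(30 * fs))
        emg = rng.standard_normal(len(eeg))

        whole = StreamingFilters(fs).process(eeg, emg)

        chunked = StreamingFilters(fs)
        bounds = np.sort(rng.choice(np.arange(1, len(eeg)), 7, replace=False))
        outs = {k: [] for k in whole}
        for a, b in zip(np.r_[0, bounds], np.r_[bounds, len(eeg)]):
            res = chunked.process(eeg[a:b], emg[a:b])
            for k in outs:
                outs[k].append(res[k])
        for k in whole:
            np.testing.assert_allclose(np.concatenate(outs[k]), whole[k], atol=1e-10)

    def test_50hz_notch_attenuation(self):
        fs = 2000.0
        t = np.arange(int(30 * fs)) / fs
        filt = StreamingFilters(fs)
        hum = filt.process(np.zeros_like(t), np.sin(2 * np.pi * 50 * t))["emg"]
        ref = StreamingFilters(fs).process(np.zeros_like(t), np.sin(2 * np.pi * 100 * t))["emg"]
        steady = slice(len(t) // 2, None)
        att_db = 20 * np.log10(
            np.sqrt(np.mean(ref[steady] ** 2)) / np.sqrt(np.mean(hum[steady] ** 2))
        )
        assert att_db >= 40.0

    def test_narrowband_unity_gain_at_center(self):
        fs = 610.35
        t = np.arange(int(120 * fs)) / fs
        x = np.sin(2 * np.pi * 1.0 * t)
        nb = StreamingFilters(fs).process(x, np.zeros_like(x))["narrow"]
        steady = nb[len(nb) // 2 :]
        assert np.abs(steady).max() == pytest.approx(1.0, rel=0.05)

    def test_fs_too_low_rejected(self):
        with pytest.raises(ValueError):
            StreamingFilters(50.0)


class TestPhaseDetector:
    def test_sample_count_arithmetic(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        nb = np.sin(2 * np.pi * 1.0 * t)
        phase = rc.detect_phase(nb, fs, 1.0)
        crossings = np.flatnonzero((nb[:-1] < 0) & (nb[1:] >= 0)) + 1
        assert phase[crossings[0] + 250] == pytest.approx(90.0)
        assert phase[crossings[0]] == 0.0

    def test_phase_at_true_peak_is_90(self):
        fs = 1000.0
        t = np.arange(int(20 * fs)) / fs
        nb = np.sin(2 * np.pi * 1.0 * t)
        phase = rc.detect_phase(nb, fs, 1.0)
        peaks = argrelmax(nb, order=100)[0]
        assert np.nanmax(np.abs(phase[peaks] - 90.0)) < 2.0

    def test_matches_hilbert_oracle_on_clean_sine(self):
        fs = 500.0
        t = np.arange(int(60 * fs)) / fs
        nb = np.sin(2 * np.pi * 1.0 * t)
        phase = rc.detect_phase(nb, fs, 1.0)
        href = (np.degrees(np.angle(hilbert(nb))) + 90.0) % 360.0
        steady = slice(int(5 * fs), int(55 * fs))
        diff = np.angle(np.exp(1j * np.deg2rad(phase[steady] - href[steady])))
        assert np.mean(np.abs(np.degrees(diff))) < 3.0

    def test_nan_before_first_crossing(self):
        nb = np.concatenate([np.ones(100), -np.ones(100), np.ones(100)])
        phase = rc.detect_phase(nb, 100.0, 1.0)
        assert np.all(np.isnan(phase[:200]))
        assert np.isfinite(phase[200:]).all()


class TestGate:
    def test_elementwise_examples(self):
        thr = rc.CalibrationThresholds(4.0, 1.0, {})
        assert rc.nrem_gate(np.array([5.0]), np.array([0.5]), thr)[0]
        assert not rc.nrem_gate(np.array([5.0]), np.array([2.0]), thr)[0]
        assert not rc.nrem_gate(np.array([3.0]), np.array([0.5]), thr)[0]

    def test_equals_brute_force_conjunction(self):
        rng = np.random.default_rng(2)
        ratio = rng.uniform(0, 10, 10000)
        emg = rng.uniform(0, 5, 10000)
        thr = rc.CalibrationThresholds(4.0, 2.0, {})
        got = rc.nrem_gate(ratio, emg, thr)
        want = np.array([r > 4.0 and e < 2.0 for r, e in zip(ratio, emg)])
        np.testing.assert_array_equal(got, want)

    def test_nan_ratio_gates_false(self):
        thr = rc.CalibrationThresholds(-np.inf, np.inf, {})
        assert not rc.nrem_gate(np.array([np.nan]), np.array([0.0]), thr)[0]


class TestClosedLoop:
    def test_gate_never_satisfied_gives_empty_log(self, clean_nrem):
        _, _, rec, _ = clean_nrem
        closed = rc.CalibrationThresholds(np.inf, -np.inf, {})
        res = rc.run_closed_loop(rec, closed, rc.EngineConfig())
        assert len(res.trigger_log) == 0

    def test_mock_matches_up_run_with_mute_flag(self, clean_nrem, open_gate):
        _, _, rec, _ = clean_nrem
        up = rc.run_closed_loop(rec, open_gate, rc.EngineConfig(target_phase_deg=60, condition="up"))
        mock = rc.run_closed_loop(rec, open_gate, rc.EngineConfig(target_phase_deg=60, condition="mock"))
        np.testing.assert_array_equal(up.trigger_log.onsets, mock.trigger_log.onsets)
        assert mock.trigger_log.muted is True
        assert up.trigger_log.muted is False

    def test_sixty_seconds_of_1hz_yields_one_trigger_per_cycle(self, open_gate):
        fs = 500.0
        t = np.arange(int(60 * fs)) / fs
        eeg = 100 * np.sin(2 * np.pi * 1.0 * t)
        rec = rc.Recording(channels={"EEG1": eeg, "EMG": np.zeros_like(eeg)}, fs=fs)
        res = rc.run_closed_loop(
            rec, open_gate, rc.EngineConfig(target_phase_deg=90.0, latency_s=0.0)
        )
        assert 58 <= len(res.trigger_log) <= 60
        ph = (np.degrees(np.angle(hilbert(eeg))) + 90.0) % 360.0
        idx = np.round(res.trigger_log.onsets * fs).astype(int)
        stats = rc.circular_stats(ph[idx])
        assert abs(stats.mean_deg - 90.0) < 5.0

    def test_at_most_one_trigger_per_cycle(self, default_synth):
        cfg, hyp, rec, _ = default_synth
        series = rc.compute_staging_series(rec)
        thr = rc.calibrate_thresholds(series, hyp)
        res = rc.run_closed_loop(rec, thr, rc.EngineConfig(target_phase_deg=60))
        onsets = res.trigger_log.onsets
        nb = res.narrowband
        pos = nb >= 0
        crossings = (np.flatnonzero(~pos[:-1] & pos[1:]) + 1) / rec.fs
        cycle_of = np.searchsorted(crossings, onsets, side="right")
        assert len(np.unique(cycle_of)) == len(onsets)
        if len(onsets) > 1:
            assert np.diff(onsets).min() >= 1.0 / rec.fs

    def test_determinism(self, default_synth):
        cfg, hyp, rec, _ = default_synth
        thr = rc.calibrate_thresholds(rc.compute_staging_series(rec), hyp)
        a = rc.run_closed_loop(rec, thr, rc.EngineConfig(target_phase_deg=60))
        b = rc.run_closed_loop(rec, thr, rc.EngineConfig(target_phase_deg=60))
        np.testing.assert_array_equal(a.trigger_log.onsets, b.trigger_log.onsets)

    def test_triggers_enriched_in_nrem(self, default_synth):
        """Triggers should fall in NREM far above the chance rate."""
        cfg, hyp, rec, _ = default_synth
        thr = rc.calibrate_thresholds(rc.compute_staging_series(rec), hyp)
        res = rc.run_closed_loop(rec, thr, rc.EngineConfig(target_phase_deg=60))
        assert len(res.trigger_log) > 0
        breakdown = rc.trigger_stage_breakdown(res.trigger_log, hyp)
        frac_time_n = np.mean(hyp.states() == "N")
        assert breakdown["proportions"]["N"] > frac_time_n


class TestTrailingRms:
    def test_equals_brute_force(self):
        rng = np.random.default_rng(4)
        fs = 100.0
        x = rng.standard_normal(1000)
        got = trailing_rms(x, fs, 1.0)
        w = 100
        want = np.array(
            [np.sqrt(np.mean(x[max(0, k - w + 1) : k + 1] ** 2)) for k in range(len(x))]
        )
        np.testing.assert_allclose(got, want, rtol=1e-9)


class TestStimulus:
    def test_duration_in_samples(self):
        w = rc.make_stimulus_waveform(rc.StimulusConfig(), 48000)
        assert len(w) == 1440

    def test_ramps_start_and_end_at_zero(self):
        w = rc.make_stimulus_waveform(rc.StimulusConfig(), 48000)
        assert w[0] == 0.0
        assert w[-1] == 0.0
        assert np.abs(w).max() == pytest.approx(1.0)

    def test_pink_spectral_slope(self):
        from scipy.signal import welch

        x = _pink(2**18, np.random.default_rng(0))
        f, p = welch(x, fs=48000, nperseg=8192)
        m = (f > 100) & (f < 10000)
        slope = np.polyfit(np.log2(f[m]), 10 * np.log10(p[m]), 1)[0]
        assert slope == pytest.approx(-3.0, abs=1.0)

    def test_duration_must_exceed_ramps(self):
        with pytest.raises(ValueError):
            rc.StimulusConfig(duration_s=0.003, ramp_s=0.002)

    def test_scaled_duration_for_rat_so_peak(self):
        assert rc.scale_stimulus_duration() == pytest.approx(0.030)
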