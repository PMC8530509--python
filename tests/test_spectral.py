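import numpy as np
import pandas as pd
import pytest

import ratclas as rc
from ratclas.spectral import ANALYSIS_FS, BandScheme, WIDE_BANDS, contrast_pp


class TestFermiTaper:
    def test_edge_length_600_samples_at_300hz(self):
        w = rc.fermi_taper(3000, 300.0)
        assert np.all(w[600:-600] == 1.0)
        assert w[599] < 1.0

    def test_half_amplitude_at_sample_250(self):
        w = rc.fermi_taper(3000, 300.0)
        # n = 250 from the edge (1-based) -> index 249
        assert w[249] == pytest.approx(0.5)
        assert w[-250] == pytest.approx(0.5)

    def test_monotone_rise(self):
        w = rc.fermi_taper(3000, 300.0)
        assert np.all(np.diff(w[:600]) >= 0)


class TestPreprocess:
    def test_passband_sine_amplitude_preserved(self):
        fs = 610.35
        t = np.arange(int(60 * fs)) / fs
        x = 50 * np.sin(2 * np.pi * 2.0 * t)
        y = rc.preprocess_eeg(x, fs)
        interior = y[int(10 * ANALYSIS_FS) : -int(10 * ANALYSIS_FS)]
        assert np.abs(interior).max() == pytest.approx(50.0, rel=0.02)

    def test_output_rate_is_300hz(self):
        fs = 610.35
        x = np.zeros(int(20 * fs))
        y = rc.preprocess_eeg(x, fs)
        assert len(y) == pytest.approx(20 * 300, abs=2)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            rc.preprocess_eeg(np.zeros(100), 610.35)


class TestArtifactInterpolation:
    def _base_trace(self, seed=0, n_epochs=30):
        rng = np.random.default_rng(seed)
        n = int(n_epochs * 4 * ANALYSIS_FS)
        return rng.standard_normal(n), rc.Hypnogram(["N"] * n_epochs)

    def test_clean_trace_untouched(self):
        x, hyp = self._base_trace()
        y, log = rc.interpolate_artifacts(x, hyp)
        np.testing.assert_array_equal(x, y)
        assert log == []

    def test_brief_spike_repaired_below_threshold(self):
        x, hyp = self._base_trace(1)
        q75, q25 = np.percentile(x, [75, 25])
        iqr = q75 - q25
        x[5000:5005] = 100 * iqr
        y, log = rc.interpolate_artifacts(x, hyp)
        assert any(e["repaired"] for e in log)
        assert np.all(np.abs(y[5000:5005]) < 8 * iqr)

    def test_long_excursion_left_but_logged(self):
        x, hyp = self._base_trace(2)
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        x[7000:7020] = 50 * iqr
        y, log = rc.interpolate_artifacts(x, hyp)
        np.testing.assert_array_equal(y[7000:7020], x[7000:7020])
        assert any(not e["repaired"] and e["length"] >= 10 for e in log)

    def test_spikes_outside_nrem_not_repaired(self):
        x, hyp_n = self._base_trace(3)
        hyp_w = rc.Hypnogram(["W"] * len(hyp_n))
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        x[5000:5004] = 100 * iqr
        y, log = rc.interpolate_artifacts(x, hyp_w)
        np.testing.assert_array_equal(x, y)


class TestPsdEpochs:
    def test_quarter_hz_resolution(self):
        rng = np.random.default_rng(0)
        hyp = rc.Hypnogram(["N"] * 10)
        x = rng.standard_normal(int(40 * ANALYSIS_FS))
        table = rc.psd_epochs(x, hyp)
        assert np.allclose(np.diff(table.freqs), 0.25)

    def test_normalization_sums_to_one(self):
        rng = np.random.default_rng(1)
        hyp = rc.Hypnogram(["N", "W", "R", "N", "aN"] * 4)
        x = rng.standard_normal(int(len(hyp) * 4 * ANALYSIS_FS))
        table = rc.psd_epochs(x, hyp)
        mask = table.band_mask(*table.total_range)
        sums = table.rel_power[:, mask].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_pure_delta_tone_dominates(self):
        rng = np.random.default_rng(2)
        hyp = rc.Hypnogram(["N"] * 10)
        n = int(40 * ANALYSIS_FS)
        t = np.arange(n) / ANALYSIS_FS
        x = 50 * np.sin(2 * np.pi * 2.0 * t) + 0.5 * rng.standard_normal(n)
        table = rc.psd_epochs(x, hyp)
        delta = table.rel_power[:, table.band_mask(0.5, 4.0)].sum(axis=1)
        assert np.all(delta > 0.9)


class TestBandPower:
    def _random_table(self, seed=0, n_epochs=40):
        rng = np.random.default_rng(seed)
        freqs = np.arange(0, 48.25, 0.25)
        p = rng.uniform(0.1, 1.0, (n_epochs, len(freqs)))
        mask = (freqs > 0.5) & (freqs <= 30.0)
        p /= p[:, mask].sum(axis=1, keepdims=True)
        stages = rng.choice(["W", "N", "R"], n_epochs)
        artifact = rng.random(n_epochs) < 0.1
        return rc.SpectralTable(
            freqs=freqs, rel_power=p, stages=stages, artifact=artifact
        )

    def test_single_epoch_group_mean_is_epoch_value(self):
        table = self._random_table()
        i = int(np.flatnonzero((table.stages == "N") & ~table.artifact)[0])
        one = rc.SpectralTable(
            freqs=table.freqs,
            rel_power=table.rel_power[i : i + 1],
            stages=table.stages[i : i + 1],
            artifact=table.artifact[i : i + 1],
        )
        bp = rc.band_power(one, group=None)
        want = table.rel_power[i, table.band_mask(0.5, 4.0)].sum()
        assert bp["delta"].iloc[0] == pytest.approx(want)

    def test_bands_plus_residual_partition_total(self):
        table = self._random_table(1)
        scheme = BandScheme(bands={**rc.BandScheme().bands, "residual": (20.0, 30.0)})
        bp = rc.band_power(table, scheme, group=None)
        assert bp.sum(axis=1).iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_wide_beta_variant_accepted(self):
        table = self._random_table(2)
        bp = rc.band_power(table, BandScheme(bands=dict(WIDE_BANDS)), group=None)
        assert bp["beta"].iloc[0] > 0

    def test_grouped_means_match_brute_force(self):
        table = self._random_table(3, n_epochs=100)
        bp = rc.band_power(table, group="hour")
        sel = (table.stages == "N") & ~table.artifact
        mask = table.band_mask(0.5, 4.0)
        keys = (np.arange(100) * 4 // 3600).astype(int) + 1
        for key in np.unique(keys):
            rows = sel & (keys == key)
            want = table.rel_power[rows][:, mask].sum(axis=1).mean() if rows.any() else np.nan
            got = bp.loc[key, "delta"]
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want)

    def test_permuting_epochs_within_day_leaves_mean(self):
        table = self._random_table(4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(table))
        shuffled = rc.SpectralTable(
            freqs=table.freqs,
            rel_power=table.rel_power[perm],
            stages=table.stages[perm],
            artifact=table.artifact[perm],
        )
        a = rc.band_power(table, group="day")
        b = rc.band_power(shuffled, group="day")
        pd.testing.assert_frame_equal(a, b)


class TestChangeFromBaseline:
    def test_identical_series_zero_change(self):
        s = pd.Series([1.0, 2.0], index=[1, 2])
        assert (rc.change_from_baseline(s, s) == 0).all()

    def test_23_percent_increase(self):
        b = pd.Series([2.0], index=[1])
        assert rc.change_from_baseline(1.23 * b, b).iloc[0] == pytest.approx(23.0)

    def test_zero_baseline_flagged(self):
        out = rc.change_from_baseline(pd.Series([1.0]), pd.Series([0.0]))
        assert np.isnan(out.iloc[0])

    def test_random_matches_formula_and_contrast(self):
        rng = np.random.default_rng(5)
        b = pd.Series(rng.uniform(1, 2, 24))
        x = pd.Series(rng.uniform(1, 2, 24))
        y = pd.Series(rng.uniform(1, 2, 24))
        cx = rc.change_from_baseline(x, b)
        np.testing.assert_allclose(cx.values, 100 * (x - b) / b)
        np.testing.assert_allclose(
            contrast_pp(cx, rc.change_from_baseline(y, b)).values,
            100 * (x - b) / b - 100 * (y - b) / b,
        )


class TestSleepArchitecture:
    def test_two_bouts_of_five_epochs(self):
        arch = rc.sleep_architecture(rc.Hypnogram(["N", "N", "N", "W", "N", "N"]))
        assert arch.n_bouts == 2
        assert arch.n_nrem_epochs == 5
        assert arch.fragmentation_index == pytest.approx(0.4)

    def test_nrem_minutes(self):
        arch = rc.sleep_architecture(rc.Hypnogram(["N"] * 150))
        assert arch.nrem_minutes == pytest.approx(10.0)
        assert arch.n_bouts == 1

    def test_artifact_nrem_counts_toward_minutes(self):
        arch = rc.sleep_architecture(rc.Hypnogram(["N", "aN", "N"]))
        assert arch.nrem_minutes == pytest.approx(0.2)
        assert arch.n_bouts == 1

    def test_no_nrem_flagged(self):
        arch = rc.sleep_architecture(rc.Hypnogram(["W", "R"]))
        assert np.isnan(arch.fragmentation_index)

    def test_bout_split_strictly_increases_index(self):
        labels = ["N"] * 20
        before = rc.sleep_architecture(rc.Hypnogram(labels)).fragmentation_index
        labels[10] = "W"
        after = rc.sleep_architecture(rc.Hypnogram(labels)).fragmentation_index
        assert after > before
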