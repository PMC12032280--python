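"""Spectral decomposition, dB baselining, lateralisation and filtering."""

import numpy as np
import pytest

import volatok as v

FS = 200.0


def _sine(freq, n_sec=4.0, amp=1.0, phase=0.0):
    t = np.arange(int(n_sec * FS)) / FS
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestSTFT:
    def test_pure_tone_peaks_at_its_frequency(self):
        tfr = v.stft_power(_sine(20.0), FS)
        interior = ~np.isnan(tfr.power[0, :])
        peak = tfr.freqs[np.argmax(tfr.power[:, interior], axis=0)]
        assert np.all(peak == 20.0)

    def test_zero_signal_zero_power(self):
        tfr = v.stft_power(np.zeros(800), FS)
        assert np.nanmax(tfr.power) == 0.0

    def test_equal_amplitude_tones_equal_power(self):
        x = _sine(10.0) + _sine(25.0, phase=1.0)
        tfr = v.stft_power(x, FS)
        interior = ~np.isnan(tfr.power[0, :])
        p10 = tfr.power[tfr.freqs == 10.0, interior].mean()
        p25 = tfr.power[tfr.freqs == 25.0, interior].mean()
        assert p10 == pytest.approx(p25, rel=0.01)

    def test_unit_amplitude_normalisation(self):
        tfr = v.stft_power(_sine(20.0), FS)
        interior = ~np.isnan(tfr.power[0, :])
        assert tfr.power[tfr.freqs == 20.0, interior].mean() == pytest.approx(
            1.0, rel=0.01
        )

    def test_edges_are_marked_missing(self):
        tfr = v.stft_power(_sine(20.0, n_sec=1.0), FS)
        assert np.isnan(tfr.power[0, 0]) and np.isnan(tfr.power[0, -1])
        assert not np.isnan(tfr.power[0, len(tfr.times) // 2])

    def test_white_noise_power_scales_with_variance(self):
        """Total in-band power grows linearly with input variance."""
        rng = np.random.default_rng(0)
        base = rng.standard_normal(4000)
        totals = []
        scales = [1.0, 2.0, 3.0]
        for s in scales:
            tfr = v.stft_power(s * base, FS)
            totals.append(np.nanmean(tfr.power))
        ratio21 = totals[1] / totals[0]
        ratio31 = totals[2] / totals[0]
        assert ratio21 == pytest.approx(4.0, rel=0.05)
        assert ratio31 == pytest.approx(9.0, rel=0.05)

    def test_rejects_short_data(self):
        with pytest.raises(ValueError):
            v.stft_power(np.zeros(40), FS)


class TestDbBaseline:
    def _tfr(self, power, times):
        return v.TFR(power=power, freqs=np.arange(1.0, 4.0), times=times)

    def test_power_equal_to_baseline_is_zero_db(self):
        times = np.linspace(-0.2, 1.0, 241)
        power = np.ones((5, 2, 3, len(times)))
        out = v.db_baseline(self._tfr(power, times))
        np.testing.assert_allclose(out.power, 0.0, atol=1e-12)

    def test_tenfold_power_is_ten_db(self):
        times = np.linspace(-0.2, 1.0, 241)
        power = np.ones((4, 1, 3, len(times)))
        power[..., times > 0] = 10.0
        out = v.db_baseline(self._tfr(power, times))
        np.testing.assert_allclose(out.power[..., times > 0], 10.0, atol=1e-9)

    def test_global_scaling_invariance(self):
        times = np.linspace(-0.2, 1.0, 241)
        rng = np.random.default_rng(1)
        power = rng.random((3, 2, 3, len(times))) + 0.1
        a = v.db_baseline(self._tfr(power, times)).power
        b = v.db_baseline(self._tfr(7.3 * power, times)).power
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_baseline_window_averages_to_zero_db(self):
        times = np.linspace(-0.2, 1.0, 241)
        rng = np.random.default_rng(2)
        power = rng.random((6, 2, 3, len(times))) + 0.1
        out = v.db_baseline(self._tfr(power, times))
        sel = (times >= -0.1) & (times <= 0.0)
        # trial-average of 10^(dB/10) over the baseline window is 1 by
        # construction; the dB mean itself is close to 0 for small spread
        lin = 10 ** (out.power[..., sel] / 10.0)
        np.testing.assert_allclose(lin.mean(axis=(0, -1)), 1.0, atol=1e-9)

    def test_double_conversion_rejected(self):
        times = np.linspace(-0.2, 1.0, 241)
        out = v.db_baseline(self._tfr(np.ones((2, 1, 3, 241)), times))
        with pytest.raises(ValueError):
            v.db_baseline(out)


class TestMBLIndex:
    def _db_tfr(self, power):
        t = np.linspace(0, 1, power.shape[-1])
        return v.TFR(power=power, freqs=np.arange(10.0, 35.0), times=t, is_db=True)

    def test_mirror_symmetric_data_gives_zero(self):
        rng = np.random.default_rng(3)
        half = rng.standard_normal((4, 2, 25, 50))
        power = np.concatenate([half, half], axis=1)
        out = v.mbl_index(self._db_tfr(power), [0, 1], [2, 3])
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_swapping_groups_flips_sign(self):
        rng = np.random.default_rng(4)
        power = rng.standard_normal((4, 4, 25, 50))
        tfr = self._db_tfr(power)
        a = v.mbl_index(tfr, [0, 1], [2, 3])
        b = v.mbl_index(tfr, [2, 3], [0, 1])
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_band_selection_is_inclusive(self):
        power = np.zeros((1, 2, 25, 10))
        freqs = np.arange(10.0, 35.0)
        power[0, 0, (freqs >= 13) & (freqs <= 30), :] = 1.0
        tfr = v.TFR(power=power, freqs=freqs, times=np.arange(10.0), is_db=True)
        out = v.mbl_index(tfr, [0], [1], band=(13, 30))
        np.testing.assert_allclose(out, 1.0)

    def test_validates_groups(self):
        tfr = self._db_tfr(np.zeros((1, 4, 25, 5)))
        with pytest.raises(ValueError):
            v.mbl_index(tfr, [0, 1], [1, 2])
        with pytest.raises(ValueError):
            v.mbl_index(tfr, [], [1])
        with pytest.raises(ValueError):
            v.mbl_index(tfr, [0], [9])


class TestButterworth:
    def test_highpass_removes_dc(self):
        x = np.full(2000, 5.0) + _sine(8.0, n_sec=10.0)
        y = v.butterworth(x, FS, "high", 1.0)
        assert abs(y[400:-400].mean()) < 0.05  # <1% of the 5-unit offset

    def test_lowpass_preserves_slow_component(self):
        x = _sine(2.0, n_sec=10.0)
        y = v.butterworth(x, FS, "low", 6.0)
        mid = slice(400, -400)
        amp = (y[mid].max() - y[mid].min()) / 2
        assert amp == pytest.approx(1.0, rel=0.02)

    def test_lowpass_attenuates_fast_component(self):
        x = _sine(30.0, n_sec=10.0)
        y = v.butterworth(x, FS, "low", 6.0)
        assert np.abs(y[400:-400]).max() < 0.05

    def test_near_idempotent_in_passband(self):
        rng = np.random.default_rng(5)
        x = v.butterworth(rng.standard_normal(4000), FS, "low", 6.0)
        y = v.butterworth(x, FS, "low", 40.0)
        mid = slice(500, -500)
        assert np.sqrt(np.mean((x[mid] - y[mid]) ** 2)) < 0.02 * x[mid].std()

    def test_rejects_bad_cutoff(self):
        with pytest.raises(ValueError):
            v.butterworth(np.zeros(100), FS, "low", 120.0)
        with pytest.raises(ValueError):
            v.butterworth(np.zeros(100), FS, "band", 10.0)


class TestEpoching:
    def test_constant_signal_constant_epochs(self):
        times = -0.4 + np.arange(1160) / FS
        data = np.full((3, 1160), 2.5)
        onsets = 0.4 * np.arange(1, 11)
        ep = v.epoch_samples(data, times, onsets, FS)
        assert ep.shape == (3, 10, 200)
        np.testing.assert_allclose(ep, 2.5)

    def test_onset_index_arithmetic(self):
        times = -0.4 + np.arange(1160) / FS
        data = np.arange(1160, dtype=float)[None, :]
        onsets = 0.4 * np.arange(1, 11)
        ep = v.epoch_samples(data, times, onsets, FS, window=(0.0, 0.05))
        for s in range(10):
            start = round(FS * (0.4 * (s + 1) + 0.4))
            assert ep[0, s, 0] == start

    def test_scalar_difference_on_linear_ramp(self):
        times = -0.4 + np.arange(1160) / FS
        slope = 3.0
        data = (slope * times)[None, :]
        onsets = 0.4 * np.arange(1, 11)
        sc = v.sample_scalars(data, times, onsets, FS)
        d = np.diff(sc[0])
        np.testing.assert_allclose(d, slope * 0.4, atol=1e-9)

    def test_out_of_range_onset_rejected(self):
        times = -0.4 + np.arange(1160) / FS
        with pytest.raises(ValueError):
            v.epoch_samples(np.zeros((1, 1160)), times, [5.0], FS)


class TestMBLRoutesAgree:
    def test_pipeline_mbl_matches_full_tfr_route(self):
        """The memory-bounded per-channel pipeline equals the reference
        route (full motor TFR -> dB -> mbl_index)."""
        cfg = v.SynthConfig()
        tcfg = v.TaskConfig(n_trials=16, seed=777)
        p = next(iter(v.simulate_cohort(1, tcfg, synth_config=cfg, seed=777)))
        from volatok.pipeline import compute_mbl

        fast = compute_mbl(p.eeg)
        left = p.eeg.channel_indices("left_motor")
        right = p.eeg.channel_indices("right_motor")
        motor = np.concatenate([left, right])
        tfr = v.stft_power(
            p.eeg.data[:, motor, :].astype(float), cfg.fs,
            freqs=np.arange(13.0, 31.0), times=p.eeg.time,
        )
        tfr_db = v.db_baseline(tfr)
        ref = v.mbl_index(tfr_db, np.arange(len(left)),
                          len(left) + np.arange(len(right)))
        np.testing.assert_allclose(fast, ref, atol=1e-9, equal_nan=True)


class TestERPConditioningChain:
    def test_kernel_peak_latency_survives_filtering(self):
        """0.1 Hz HP -> 6 Hz LP -> pre-trial baseline keeps the evoked
        kernel's peak within 25 ms on noiseless centroparietal channels."""
        cfg = v.SynthConfig(erp_noise_sd=0.0, drift_amp=0.0, sigma_eta=0.0,
                            session_offset=0.0)
        tcfg = v.TaskConfig(n_trials=30, seed=900)
        p = next(iter(v.simulate_cohort(1, tcfg, synth_config=cfg, seed=900)))
        from volatok.pipeline import conditioned_erp

        erp = conditioned_erp(p.eeg, "centroparietal", highpass=0.1)
        onsets = cfg.onset_times(10)
        ep = v.epoch_samples(erp, p.eeg.time, onsets, cfg.fs)
        amp = np.abs(np.nan_to_num(p.traces.delta_psi))
        # use the strongest update of each trial for a clean single peak
        tsel = np.arange(len(ep))
        strongest = amp.argmax(axis=1)
        waves = ep[tsel, strongest, :]
        peaks = waves.argmax(axis=1) / cfg.fs
        assert np.median(np.abs(peaks - cfg.kernel_peak)) < 0.025
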