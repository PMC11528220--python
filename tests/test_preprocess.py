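import numpy as np
import pytest
from scipy import signal as sg

from lfpdyn import (
    BinnedFeatures,
    BroadbandRecording,
    FrequencyBand,
    PowerSpec,
    ValidationError,
    channel_qc,
    clean_and_bin_spikes,
    compute_lfp_power,
    detect_threshold_crossings,
    downsample_for_band,
    extract_lfp,
    gaussian_smooth,
    generate_broadband_tone,
    log_and_causal_zscore,
    quantize,
)
from lfpdyn.preprocess import dequantize_scale


def stft_power_oracle(x, fs, spec):
    """Brute-force per-window DFT-and-sum, independent of the rfft path."""
    win = int(round(fs / spec.freq_res_hz))
    hop = int(round(spec.shift_frac * win))
    n_frames = (len(x) - win) // hop + 1
    out = np.empty(n_frames)
    for k in range(n_frames):
        frame = x[k * hop : k * hop + win]
        total = 0.0
        for m in range(win // 2 + 1):
            f = m * fs / win
            if spec.band.lo_hz <= f < spec.band.hi_hz:
                c = np.sum(frame * np.exp(-2j * np.pi * m * np.arange(win) / win))
                total += abs(c) ** 2
        out[k] = total
    return out


class TestLfpExtraction:
    def test_dc_attenuated_by_monkey_pipeline(self):
        fs = 30000.0
        rec = BroadbandRecording(np.full((1, int(fs * 10)), 50.0), fs, ["c"])
        out = extract_lfp(rec, "monkey")
        # after several 0.3 Hz high-pass time constants the DC step has decayed
        assert np.abs(out.samples[0, -2000:]).max() < 1.0

    def test_60hz_notch(self):
        fs = 30000.0
        t = np.arange(int(fs * 10)) / fs
        rec = BroadbandRecording(np.sin(2 * np.pi * 60 * t)[None, :], fs, ["c"])
        out = extract_lfp(rec, "monkey")
        rms_out = np.sqrt((out.samples[0, 4000:] ** 2).mean())
        assert rms_out < 0.1 * np.sqrt(0.5)

    def test_passband_gain_matches_analytic_response(self):
        fs = 30000.0
        t = np.arange(int(fs * 10)) / fs
        rec = BroadbandRecording(np.sin(2 * np.pi * 200 * t)[None, :], fs, ["c"])
        out = extract_lfp(rec, "monkey")
        b, a = sg.butter(1, [0.3, 500.0], btype="bandpass", fs=fs)
        _, h = sg.freqz(b, a, worN=[200.0], fs=fs)
        gain = np.sqrt((out.samples[0, 8000:-2000] ** 2).mean()) / np.sqrt(0.5)
        # small extra dip from the 120/180 Hz notch skirts
        assert gain == pytest.approx(abs(h[0]), rel=0.03)

    def test_human_pipeline_rate_and_lowpass(self):
        fs = 30000.0
        t = np.arange(int(fs * 2)) / fs
        x = np.sin(2 * np.pi * 300 * t) + np.sin(2 * np.pi * 5000 * t)
        out = extract_lfp(BroadbandRecording(x[None, :], fs, ["c"]), "human")
        assert out.fs_hz == 2000.0
        # 5 kHz component is gone; 300 Hz survives
        freqs = np.fft.rfftfreq(out.n_samples, 1 / out.fs_hz)
        spec = np.abs(np.fft.rfft(out.samples[0]))
        assert spec[np.argmin(np.abs(freqs - 300))] > 100 * spec[np.argmin(np.abs(freqs - 900))]

    def test_fs_too_low_rejected(self):
        rec = BroadbandRecording(np.zeros((1, 100)), 500.0, ["c"])
        with pytest.raises(ValidationError):
            extract_lfp(rec, "monkey")


class TestThresholdCrossings:
    def make_noise(self, fs=30000.0, dur=1.0, seed=0):
        rng = np.random.default_rng(seed)
        return rng.standard_normal(int(fs * dur)) * 10.0

    def test_flat_trace_no_crossings(self):
        rec = BroadbandRecording(np.zeros((1, 30000)), 30000.0, ["c"])
        out = detect_threshold_crossings(rec)
        assert out.values.sum() == 0

    def test_injected_spikes_counted(self):
        fs = 30000.0
        x = self.make_noise(fs)
        b, a = sg.butter(4, [250, 5000], btype="bandpass", fs=fs)
        rms = np.sqrt((sg.lfilter(b, a, x) ** 2).mean())
        # biphasic template, scaled so its *filtered* trough is 8x RMS deep
        tpl = np.concatenate([-np.sin(np.linspace(0, np.pi, 15)), 0.5 * np.sin(np.linspace(0, np.pi, 15))])
        pad = np.zeros(3000)
        tpl_peak = np.abs(sg.lfilter(b, a, np.concatenate([pad, tpl, pad]))).max()
        k = 7
        spike_times = (np.arange(k) + 1) * 3000
        for st in spike_times:
            x[st : st + 30] += 8 * rms / tpl_peak * tpl
        out = detect_threshold_crossings(BroadbandRecording(x[None, :], fs, ["c"]))
        assert out.values.sum() == k

    def test_unreachable_threshold(self):
        x = self.make_noise()
        out = detect_threshold_crossings(
            BroadbandRecording(x[None, :], 30000.0, ["c"]), threshold_rms=-1000.0
        )
        assert out.values.sum() == 0


class TestStftPower:
    def test_matches_dft_oracle(self, rng):
        fs = 2000.0
        x = rng.standard_normal(int(fs * 1.0))
        spec = PowerSpec(FrequencyBand(150, 450))
        rec = BroadbandRecording(x[None, :], fs, ["c"])
        got = compute_lfp_power(rec, spec).values[0]
        want = stft_power_oracle(x, fs, spec)
        np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_zero_signal_zero_power(self):
        rec = BroadbandRecording(np.zeros((2, 4000)), 2000.0, ["a", "b"])
        out = compute_lfp_power(rec, PowerSpec(FrequencyBand(150, 450)))
        assert np.all(out.values == 0)

    def test_tone_in_band_constant_out_of_band_rejected(self):
        rec = generate_broadband_tone([200.0], [1.0], fs_hz=2000.0, duration_s=5.0)
        p_in = compute_lfp_power(rec, PowerSpec(FrequencyBand(150, 450))).values[0]
        p_out = compute_lfp_power(rec, PowerSpec(FrequencyBand(25, 50))).values[0]
        assert p_in[5:].std() / p_in[5:].mean() < 0.01
        assert 10 * np.log10(p_out[5:].mean() / p_in[5:].mean()) < -40

    def test_quadratic_amplitude_scaling(self):
        r1 = generate_broadband_tone([200.0], [1.0], duration_s=2.0)
        r2 = generate_broadband_tone([200.0], [2.0], duration_s=2.0)
        spec = PowerSpec(FrequencyBand(150, 450))
        p1 = compute_lfp_power(r1, spec).values
        p2 = compute_lfp_power(r2, spec).values
        np.testing.assert_allclose(p2, 4 * p1, rtol=1e-9)

    def test_signal_shorter_than_window_rejected(self):
        rec = BroadbandRecording(np.zeros((1, 100)), 2000.0, ["c"])
        with pytest.raises(ValidationError):
            compute_lfp_power(rec, PowerSpec(FrequencyBand(150, 450)))

    def test_powerspec_hop_invariant(self):
        with pytest.raises(ValidationError):
            PowerSpec(FrequencyBand(150, 450), freq_res_hz=5.0, shift_frac=0.5)

    def test_low_band_resolution_variant(self):
        # the 0-8 Hz band uses 2 Hz resolution and 4% hop -> same 20 ms bins
        spec = PowerSpec(FrequencyBand(0, 8), freq_res_hz=2.0, shift_frac=0.04)
        rec = generate_broadband_tone([4.0], [1.0], fs_hz=2000.0, duration_s=3.0)
        out = compute_lfp_power(rec, spec)
        assert out.bin_ms == 20.0
        assert out.values[0].mean() > 0


class TestChannelQC:
    def test_homogeneous_all_keep(self):
        p = BinnedFeatures(np.ones((5, 50)), 20.0, kind="lfp_power")
        rep = channel_qc(p)
        assert rep.flags == ["keep"] * 5

    def test_disconnected_channel_flagged(self, rng):
        v = 1.0 + 0.01 * rng.standard_normal((96, 200))
        v[13] *= 0.1
        rep = channel_qc(BinnedFeatures(v, 20.0, kind="lfp_power"))
        assert rep.flags[13] == "disconnected"
        assert rep.flags.count("disconnected") == 1

    def test_overactive_channel_flagged(self, rng):
        v = 1.0 + 0.01 * rng.standard_normal((96, 200))
        v[40] *= 10.0
        rep = channel_qc(BinnedFeatures(v, 20.0, kind="lfp_power"))
        assert rep.flags[40] == "overactive"
        assert rep.flags.count("overactive") == 1

    def test_flags_invariant_to_channel_order(self, rng):
        v = np.abs(1.0 + 0.3 * rng.standard_normal((20, 100)))
        v[3] *= 0.05
        p = BinnedFeatures(v, 20.0, kind="lfp_power")
        rep = channel_qc(p)
        perm = rng.permutation(20)
        rep_p = channel_qc(BinnedFeatures(v[perm], 20.0, kind="lfp_power"))
        assert [rep.flags[i] for i in perm] == rep_p.flags

    def test_requires_two_channels(self):
        with pytest.raises(ValidationError):
            channel_qc(BinnedFeatures(np.ones((1, 10)), 20.0, kind="lfp_power"))

    def test_rejects_normalized_input(self):
        p = BinnedFeatures(np.ones((3, 10)), 20.0, kind="lfp_power")
        z = log_and_causal_zscore(p)
        with pytest.raises(ValidationError):
            channel_qc(z)


class TestCausalZscore:
    def test_constant_input_zero_after_warmup(self):
        p = BinnedFeatures(np.full((2, 100), 5.0), 20.0, kind="lfp_power")
        z = log_and_causal_zscore(p)
        np.testing.assert_allclose(z.values[:, 10:], 0.0, atol=1e-6)

    def test_causality_future_mutation_invariant(self, rng):
        v = np.abs(rng.standard_normal((3, 300))) + 0.1
        p1 = BinnedFeatures(v.copy(), 20.0, kind="lfp_power")
        v2 = v.copy()
        v2[:, 200:] = 1000.0
        p2 = BinnedFeatures(v2, 20.0, kind="lfp_power")
        z1 = log_and_causal_zscore(p1)
        z2 = log_and_causal_zscore(p2)
        np.testing.assert_array_equal(z1.values[:, :200], z2.values[:, :200])

    def test_matches_naive_rolling_recomputation(self, rng):
        v = np.abs(rng.standard_normal((2, 400))) + 0.1
        v[:, 150:] *= 8.0  # step change
        p = BinnedFeatures(v, 20.0, kind="lfp_power")
        w = 50  # bins in a 1-minute window at 20 ms... use 1 min for speed
        z = log_and_causal_zscore(p, window_min=w * 20.0 / 60000.0)
        x = np.log(np.maximum(v, 1e-8))
        for t in [9, 20, 100, 151, 199, 250, 399]:
            lo = max(t + 1 - w, 0)
            seg = x[:, lo : t + 1]
            mu, sd = seg.mean(axis=1), seg.std(axis=1)
            want = (x[:, t] - mu) / np.maximum(sd, 1e-8)
            np.testing.assert_allclose(z.values[:, t], want, rtol=1e-8, atol=1e-8)

    def test_flags_record_transform(self):
        p = BinnedFeatures(np.ones((2, 50)), 20.0, kind="lfp_power")
        z = log_and_causal_zscore(p)
        assert z.flags.log_transformed and z.flags.zscored


class TestQuantize:
    def test_hand_example_with_clamp(self):
        p = BinnedFeatures(np.array([[0.0, 0.5, 1.0]]), 20.0, kind="lfp_power")
        q = quantize(p, bits=2)
        np.testing.assert_array_equal(q.values, [[0, 2, 3]])
        assert q.flags.quantized_bits == 2

    def test_constant_channel_maps_to_zero(self):
        p = BinnedFeatures(np.full((1, 10), 3.3), 20.0, kind="lfp_power")
        assert np.all(quantize(p, 4).values == 0)

    def test_16bit_roundtrip_error_bound(self, rng):
        v = rng.standard_normal((3, 200))
        p = BinnedFeatures(v, 20.0, kind="lfp_power")
        q = quantize(p, 16)
        back = dequantize_scale(p, q)
        span = v.max(axis=1, keepdims=True) - v.min(axis=1, keepdims=True)
        assert np.all(np.abs(back.values - v) <= span / 2**16 + 1e-12)

    def test_nonfinite_rejected(self):
        v = np.ones((1, 5))
        v[0, 2] = np.inf
        with pytest.raises(ValidationError):
            quantize(BinnedFeatures(v, 20.0, kind="lfp_power"), 4)


class TestDownsample:
    def test_target_rates(self):
        rec = generate_broadband_tone([100.0], [1.0], fs_hz=2000.0, duration_s=2.0)
        assert downsample_for_band(rec, FrequencyBand(150, 450)).fs_hz == 900.0
        assert downsample_for_band(rec, FrequencyBand(0, 8)).fs_hz == 50.0

    def test_band_above_nyquist_rejected(self):
        rec = generate_broadband_tone([10.0], [1.0], fs_hz=500.0, duration_s=1.0)
        with pytest.raises(ValidationError):
            downsample_for_band(rec, FrequencyBand(150, 450))

    def test_tone_survival_and_rejection(self):
        band = FrequencyBand(150, 450)  # new fs 900, Nyquist 450
        # 350 Hz sits below the 0.9x-Nyquist anti-alias cutoff (405 Hz)
        keep = generate_broadband_tone([350.0], [1.0], fs_hz=2000.0, duration_s=5.0)
        out = downsample_for_band(keep, band)
        rms = np.sqrt((out.samples[0, 500:-500] ** 2).mean())
        assert rms == pytest.approx(np.sqrt(0.5), rel=0.01)
        kill = generate_broadband_tone([600.0], [1.0], fs_hz=2000.0, duration_s=5.0)
        out2 = downsample_for_band(kill, band)
        rms2 = np.sqrt((out2.samples[0, 500:-500] ** 2).mean())
        assert 20 * np.log10(rms2 / np.sqrt(0.5)) < -40


class TestSpikeCleaning:
    def make_raster(self, values):
        return BinnedFeatures(np.asarray(values), 1.0, kind="spike_counts")

    def test_coincident_timestep_zeroed(self, rng):
        v = rng.poisson(0.02, (10, 2000))
        v[:4, 77] = 1  # 4/10 = 40% > 30%
        out, _ = clean_and_bin_spikes(self.make_raster(v), bin_ms=20.0)
        # bin 3 contains step 77; compare against the same raster minus step 77
        v2 = v.copy()
        v2[:, 77] = 0
        out2, _ = clean_and_bin_spikes(self.make_raster(v2), bin_ms=20.0)
        np.testing.assert_array_equal(out.values, out2.values)

    def test_exact_30_percent_kept(self, rng):
        v = rng.poisson(0.03, (10, 2000))
        v[:, 50] = 0
        v[:3, 50] = 1  # exactly 30% of channels spike at step 50: not > 30%
        out, removed = clean_and_bin_spikes(self.make_raster(v), bin_ms=20.0)
        assert removed == []
        v2 = v.copy()
        v2[:3, 50] = 0
        out2, _ = clean_and_bin_spikes(self.make_raster(v2), bin_ms=20.0)
        assert out.values[:, 2].sum() == out2.values[:, 2].sum() + 3

    def test_duplicated_pair_one_removed(self, rng):
        v = rng.poisson(0.05, (8, 5000))
        v = np.vstack([v, v[2:3]])  # channel 8 duplicates channel 2
        out, removed = clean_and_bin_spikes(self.make_raster(v))
        assert len(removed) == 1 and removed[0] in (2, 8)

    def test_fully_correlated_set_keeps_one_survivor(self):
        # greedy removal strips duplicates one at a time and never empties
        # (coincidence zeroing disabled so the correlation rule is isolated)
        v = np.tile(np.random.default_rng(0).poisson(0.5, (1, 500)), (3, 1))
        out, removed = clean_and_bin_spikes(self.make_raster(v), coincident_frac=1.01)
        assert out.values.shape[0] == 1 and removed == [0, 1]

    def test_binning_sums_half_open(self):
        v = np.zeros((4, 40), dtype=int)  # 1/4 spiking = 25%, below threshold
        v[0, [0, 19, 20, 39]] = 1
        out, _ = clean_and_bin_spikes(self.make_raster(v), bin_ms=20.0)
        np.testing.assert_array_equal(out.values[0], [2, 2])


class TestGaussianSmooth:
    def test_impulse_response_sums_preserved(self):
        v = np.zeros((1, 101))
        v[0, 50] = 1.0
        out = gaussian_smooth(BinnedFeatures(v, 20.0, kind="lfp_power"), sd_ms=30.0)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.argmax(out.values[0]) == 50

    def test_constant_preserved(self):
        v = np.full((2, 60), 7.7)
        out = gaussian_smooth(BinnedFeatures(v, 20.0, kind="lfp_power"), sd_ms=50.0)
        np.testing.assert_allclose(out.values, v, rtol=1e-12)

    def test_matches_dense_convolution_oracle(self, rng):
        v = rng.standard_normal((1, 50))
        sd_bins = 30.0 / 20.0
        half = int(np.ceil(4 * sd_bins))
        k = np.exp(-0.5 * (np.arange(-half, half + 1) / sd_bins) ** 2)
        k /= k.sum()
        want = np.empty(50)
        for t in range(50):
            num = den = 0.0
            for j in range(-half, half + 1):
                if 0 <= t + j < 50:
                    num += k[half + j] * v[0, t + j]
                    den += k[half + j]
            want[t] = num / den
        out = gaussian_smooth(BinnedFeatures(v, 20.0, kind="lfp_power"), sd_ms=30.0)
        np.testing.assert_allclose(out.values[0], want, rtol=1e-9, atol=1e-12)

    def test_causal_variant_ignores_future(self, rng):
        v = rng.standard_normal((1, 100))
        a = gaussian_smooth(BinnedFeatures(v.copy(), 20.0, kind="lfp_power"), 30.0, causal=True)
        v2 = v.copy()
        v2[0, 60:] = 99.0
        b = gaussian_smooth(BinnedFeatures(v2, 20.0, kind="lfp_power"), 30.0, causal=True)
        np.testing.assert_array_equal(a.values[0, :60], b.values[0, :60])

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValidationError):
            gaussian_smooth(BinnedFeatures(np.ones((1, 10)), 20.0, kind="lfp_power"), sd_ms=0)
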