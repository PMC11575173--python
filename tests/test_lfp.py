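"""LFP preprocessing, multitaper spectra, burst events and time courses."""
import numpy as np
import pytest

from striephys import lfp, synth
from striephys.core import ConfigError, Trace


def sine_trace(freq, fs, duration, amp=1.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(int(duration * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    if noise:
        x = x + rng.normal(0, noise, t.size)
    return Trace(x, fs, units="uV")


class TestPreprocess:
    def test_20hz_amplitude_preserved_through_decimation(self):
        raw = sine_trace(20.0, 30000.0, 10.0, amp=50.0)
        out = lfp.preprocess_lfp(raw)
        assert out.fs_hz == 1000.0
        amp_out = np.sqrt(2) * out.samples[2000:-2000].std()
        assert amp_out == pytest.approx(50.0, rel=0.01)

    def test_dc_offset_removed(self):
        raw = Trace(np.full(900000, 25.0), 30000.0)  # 30 s of +25 uV DC
        out = lfp.preprocess_lfp(raw)
        # ignore the ~1/(1 Hz) settling transient at the edges
        assert np.abs(out.samples[5000:-5000]).max() < 0.5

    def test_600hz_tone_attenuated_over_20_db(self):
        raw = sine_trace(600.0, 30000.0, 10.0, amp=50.0)
        out = lfp.preprocess_lfp(raw)
        assert out.samples[500:-500].std() < 0.1 * raw.samples.std()

    def test_low_rate_input_rejected(self):
        with pytest.raises(ConfigError):
            lfp.preprocess_lfp(Trace(np.zeros(1000) + np.arange(1000), 500.0))


class TestSegmentation:
    def test_95_seconds_give_9_segments(self):
        tr = Trace(np.random.default_rng(0).normal(0, 1, 95000), 1000.0)
        assert len(lfp.segment_lfp(tr)) == 9

    def test_artifact_drops_only_its_segment(self):
        tr = Trace(np.random.default_rng(0).normal(0, 1, 95000), 1000.0)
        mask = np.zeros(95000, bool)
        mask[15000] = True  # t = 15 s -> segment 2
        assert len(lfp.segment_lfp(tr, mask)) == 8

    def test_fully_masked_warns_and_returns_empty(self):
        tr = Trace(np.zeros(30000) + 1.0, 1000.0)
        with pytest.warns(UserWarning):
            segs = lfp.segment_lfp(tr, np.ones(30000, bool))
        assert segs == []

    def test_artifact_mask_flags_large_excursions(self):
        x = np.random.default_rng(1).normal(0, 10, 20000)
        x[5000:5050] += 500.0
        mask = lfp.default_artifact_mask(Trace(x, 1000.0))
        assert mask[5000:5050].any()
        assert mask.mean() < 0.01


class TestMultitaper:
    def test_sine_peak_at_20_hz(self):
        tr = sine_trace(20.0, 1000.0, 60.0, noise=0.1)
        freqs, psd = lfp.multitaper_psd(lfp.segment_lfp(tr), 1000.0)
        assert freqs[np.argmax(psd)] == pytest.approx(20.0, abs=0.1)

    def test_white_noise_variance_shrinks_with_tapers_and_segments(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 60000)
        one = lfp.multitaper_psd([x[:10000]], 1000.0,
                                 lfp.SpectralConfig(n_tapers=1,
                                                    time_bandwidth=1.0))[1]
        segs = [x[i:i + 10000] for i in range(0, 60000, 10000)]
        many = lfp.multitaper_psd(segs, 1000.0)[1]
        sel = slice(50, 4500)
        ratio = np.var(one[sel] / one[sel].mean()) \
            / np.var(many[sel] / many[sel].mean())
        assert ratio > 8  # ~K x n_segments = 30 in expectation

    def test_two_tones_one_hz_apart_resolved(self):
        from scipy.signal import find_peaks
        fs = 1000.0
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * 20 * t) + np.sin(2 * np.pi * 21 * t)
        freqs, psd = lfp.multitaper_psd(
            lfp.segment_lfp(Trace(x, fs)), fs)
        sel = (freqs >= 18) & (freqs <= 23)
        peaks, _ = find_peaks(psd[sel])
        pk_freqs = freqs[sel][peaks]
        assert any(abs(f - 20.0) < 0.2 for f in pk_freqs)
        assert any(abs(f - 21.0) < 0.2 for f in pk_freqs)

    def test_taper_count_constraint_enforced(self):
        with pytest.raises(ConfigError):
            lfp.SpectralConfig(n_tapers=8, time_bandwidth=3.0).validate()


class TestNormalization:
    def test_mean_over_support_exactly_one(self):
        rng = np.random.default_rng(3)
        freqs = np.arange(0, 200.1, 0.1)
        psd = rng.uniform(0.5, 2.0, freqs.size)
        npsd = lfp.normalize_psd(freqs, psd)
        support = ((freqs >= 1) & (freqs <= 90)) \
            & ~((freqs >= 48) & (freqs <= 52))
        assert abs(npsd[support].mean() - 1.0) < 1e-9

    def test_flat_psd_normalizes_to_ones(self):
        freqs = np.arange(0, 100, 0.5)
        npsd = lfp.normalize_psd(freqs, np.full(freqs.size, 7.0))
        assert np.allclose(npsd, 1.0)

    def test_degenerate_spectrum_rejected(self):
        freqs = np.arange(0, 100, 0.5)
        with pytest.raises(ValueError, match="degenerate"):
            lfp.normalize_psd(freqs, np.zeros(freqs.size))

    def test_band_power(self):
        freqs = np.arange(0, 100, 0.5)
        flat = np.ones(freqs.size)
        for band in lfp.BANDS.values():
            assert lfp.band_power(freqs, flat, band) == 1.0
        conc = np.where((freqs >= 13) & (freqs < 30), 10.0, 0.1)
        assert lfp.band_power(freqs, conc, lfp.BANDS["beta"]) \
            > 10 * lfp.band_power(freqs, conc, lfp.BANDS["low_gamma"])
        with pytest.raises(ValueError):
            lfp.band_power(np.arange(0, 10.0), flat[:10],
                           lfp.BANDS["high_gamma"])


class TestBurstDetection:
    def test_strong_burst_detected_at_truth_time(self):
        cfg = synth.LfpSynthConfig(
            duration_s=30, seed=4,
            burst_specs=[synth.BurstSpec(19, 21, 2.0, 300.0, 14.0, "beta")])
        trace, truth = synth.gen_lfp(cfg)
        det = lfp.detect_osc_bursts(trace, lfp.BANDS["beta"])
        assert len(det) >= 1
        for e in truth:
            assert min(abs(d.peak_s - e.peak_s) for d in det) < 0.05

    def test_subthreshold_burst_not_detected_at_its_time(self):
        cfg = synth.LfpSynthConfig(
            duration_s=30, seed=5, edge_margin_s=14.9,
            burst_specs=[synth.BurstSpec(19, 21, 2.0, 300.0, 4.0, "beta")])
        trace, truth = synth.gen_lfp(cfg)
        det = lfp.detect_osc_bursts(trace, lfp.BANDS["beta"])
        for e in truth:  # 4 dB < 6 dB peak threshold
            assert all(abs(d.peak_s - e.peak_s) > 0.2 for d in det)

    def test_raising_peak_threshold_never_increases_count(self):
        cfg = synth.LfpSynthConfig(
            duration_s=120, seed=6,
            burst_specs=[synth.BurstSpec(13, 30, 10.0, name="beta")])
        trace, _ = synth.gen_lfp(cfg)
        counts = [len(lfp.detect_osc_bursts(
            trace, lfp.BANDS["beta"],
            lfp.BurstDetectConfig(db_peak=dbp)))
            for dbp in (6.0, 8.0, 10.0, 12.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_event_fields_consistent(self):
        cfg = synth.LfpSynthConfig(
            duration_s=60, seed=7,
            burst_specs=[synth.BurstSpec(13, 30, 8.0, name="beta")])
        trace, _ = synth.gen_lfp(cfg)
        for e in lfp.detect_osc_bursts(trace, lfp.BANDS["beta"]):
            assert e.start_s <= e.peak_s <= e.end_s
            assert e.duration_s == pytest.approx(e.end_s - e.start_s)
            assert 13 <= e.peak_freq_hz <= 30
            assert e.peak_db_over_background >= 6.0

    def test_burst_statistics(self):
        ev = [lfp.OscBurstEvent("beta", 0.0, 0.1, 0.3, 20.0, 8.0)] * 30
        s = lfp.burst_statistics(ev, 600.0)
        assert s["rate_per_min"] == 3.0
        assert s["mean_duration_s"] == pytest.approx(0.3)
        empty = lfp.burst_statistics([], 60.0)
        assert empty["rate_per_min"] == 0.0
        assert np.isnan(empty["mean_duration_s"])
        with pytest.raises(ValueError):
            lfp.burst_statistics(ev, 0.0)


class TestAlignedSpectrogram:
    def test_single_event_rows_normalized_to_one(self):
        tr = sine_trace(20.0, 1000.0, 4.0, noise=0.05)
        out = lfp.event_aligned_spectrogram(tr, [2.0], window_s=0.4)
        assert out["n_events"] == 1
        assert np.allclose(out["spectrogram"].max(axis=1), 1.0)

    def test_no_events_rejected(self):
        tr = sine_trace(20.0, 1000.0, 2.0)
        with pytest.raises(ValueError):
            lfp.event_aligned_spectrogram(tr, [])

    def test_alignment_to_injected_20hz_bursts(self):
        cfg = synth.LfpSynthConfig(
            duration_s=180, seed=8,
            burst_specs=[synth.BurstSpec(19, 21, 40.0, 300.0, 12.0, "beta")])
        trace, truth = synth.gen_lfp(cfg)
        out = lfp.event_aligned_spectrogram(
            trace, [e.peak_s for e in truth], window_s=0.5,
            overlay_band=lfp.BANDS["beta"])
        # restrict to the beta neighbourhood; row-normalized spectrogram
        sel = (out["freqs_hz"] >= 10) & (out["freqs_hz"] <= 40)
        sub = out["spectrogram"][sel]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        assert out["freqs_hz"][sel][i] == pytest.approx(20.0, abs=2.0)
        assert abs(out["times_s"][j]) <= 0.020
        assert "aligned_band_avg" in out


class TestBandPowerTimecourse:
    def test_stationary_signal_stays_near_one(self):
        tr = sine_trace(40.0, 1000.0, 120.0, noise=0.3)
        df = lfp.band_power_timecourse(tr, [lfp.BANDS["low_gamma"]],
                                       baseline_interval_s=(0, 60))
        assert np.allclose(df["low_gamma"], 1.0, atol=0.25)

    def test_doubled_amplitude_quadruples_power(self):
        fs = 1000.0
        t = np.arange(int(240 * fs)) / fs
        amp = np.where(t < 120, 1.0, 2.0)
        x = amp * np.sin(2 * np.pi * 40.0 * t) \
            + 0.05 * np.random.default_rng(9).standard_normal(t.size)
        df = lfp.band_power_timecourse(Trace(x, fs), [lfp.BANDS["low_gamma"]],
                                       baseline_interval_s=(0, 100))
        late = df[df["time_s"] > 140]["low_gamma"]
        assert late.mean() == pytest.approx(4.0, rel=0.1)

    def test_empty_baseline_rejected(self):
        tr = sine_trace(40.0, 1000.0, 60.0)
        with pytest.raises(ValueError):
            lfp.band_power_timecourse(tr, [lfp.BANDS["beta"]],
                                      baseline_interval_s=(500, 600))
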