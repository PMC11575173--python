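"""Hybrid PSC detector: baseline removal, candidates, measurement, filters."""
import numpy as np
import pytest

from striephys import psc, synth
from striephys.core import ConfigError, Trace


def event_trace(fs=25000.0, duration_s=2.0, onsets=(1.0,), amp=50.0,
                tau_rise_ms=0.5, tau_decay_ms=5.0, sign=-1.0, noise_sd=0.0,
                seed=0):
    """Kernel-superposition trace with exactly known events."""
    n = int(duration_s * fs)
    rng = np.random.default_rng(seed)
    x = rng.normal(0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    k = synth.psc_kernel(np.arange(int(10 * tau_decay_ms * 1e-3 * fs)) / fs,
                         tau_rise_ms, tau_decay_ms)
    for t0 in onsets:
        i0 = int(round(t0 * fs))
        seg = min(k.size, n - i0)
        x[i0:i0 + seg] += sign * amp * k[:seg]
    return Trace(x, fs)


class TestRemoveBaseline:
    def test_constant_trace_becomes_zero(self):
        out = psc.remove_baseline(Trace(np.full(20000, 17.0), 10000.0))
        assert np.allclose(out.samples, 0.0, atol=1e-9)

    def test_zero_trace_stays_zero(self):
        out = psc.remove_baseline(Trace(np.zeros(20000), 10000.0))
        assert np.all(out.samples == 0)

    def test_slow_sine_with_event_removed_vs_brute_force_median(self):
        fs = 5000.0
        t = np.arange(int(10 * fs)) / fs
        x = 20.0 * np.sin(2 * np.pi * t / 10.0)
        tr = event_trace(fs=fs, duration_s=10, onsets=(5.0,), amp=60.0)
        x = x + tr.samples
        out = psc.remove_baseline(Trace(x, fs), window_s=1.0)
        # brute-force centered running median as the oracle
        w, half = int(fs), int(fs) // 2
        check = np.arange(0, x.size, 997)  # spot-check grid
        oracle = np.array([np.median(x[max(0, c - half):c + half + 1])
                           for c in check])
        mask = np.abs(check / fs - 5.0) > 0.1  # outside the event
        assert np.max(np.abs((x[check] - out.samples[check]) - oracle)[mask]) < 2.0
        # residual baseline outside the event is small
        resid = out.samples[np.abs(t - 5.0) > 0.2]
        assert np.abs(np.median(resid)) < 2.0

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ConfigError):
            psc.remove_baseline(Trace(np.zeros(100), 1000.0), window_s=1.0)

    def test_output_length_preserved(self):
        tr = Trace(np.random.default_rng(0).normal(0, 1, 12345), 5000.0)
        assert psc.remove_baseline(tr).n_samples == 12345


class TestDetectSlope:
    def test_monotonically_rising_trace_has_no_candidates(self):
        tr = Trace(np.linspace(0, 100, 50000), 25000.0)
        assert psc.detect_slope(tr).size == 0

    def test_single_clean_event_yields_one_candidate_near_onset(self):
        tr = event_trace(onsets=(1.0,), amp=50.0)
        cands = psc.detect_slope(tr)
        assert cands.size == 1
        assert abs(cands[0] - 1.0) < 1e-3

    def test_two_distant_events_yield_two_candidates(self):
        tr = event_trace(onsets=(1.0, 1.05), amp=50.0)
        cands = psc.detect_slope(tr)
        assert cands.size == 2

    def test_trace_shorter_than_window_rejected(self):
        with pytest.raises(ConfigError):
            psc.detect_slope(Trace(np.zeros(10), 25000.0))


class TestDetectHighband:
    def test_pure_noise_false_rate_is_low(self):
        rng = np.random.default_rng(42)
        tr = Trace(rng.normal(0, 4.0, int(100 * 25000)), 25000.0)
        cands = psc.detect_highband(tr)
        assert cands.size <= 10  # 4.5 SD crossings are rare over 100 s

    def test_clean_event_detected(self):
        tr = event_trace(onsets=(1.0,), amp=50.0)
        cands = psc.detect_highband(tr)
        assert cands.size >= 1
        assert min(abs(cands - 1.0)) < 2e-3

    def test_zero_trace_has_no_candidates(self):
        assert psc.detect_highband(Trace(np.zeros(50000), 25000.0)).size == 0


class TestDetectMultiband:
    def test_slow_rising_event_caught_by_low_band(self):
        # 2 ms rise riding on noise: too slow for the high band alone,
        # caught by the 2-300 Hz band thresholds
        tr = event_trace(onsets=(1.0,), amp=40.0, tau_rise_ms=2.0,
                         tau_decay_ms=12.0, noise_sd=4.0, seed=1)
        cands = psc.detect_multiband(tr)
        assert cands.size >= 1
        assert min(abs(cands - 1.0)) < 2e-3

    def test_zero_trace_has_no_candidates(self):
        assert psc.detect_multiband(Trace(np.zeros(50000), 25000.0)).size == 0

    def test_per_band_hits_merge_to_single_candidate(self):
        # the event crosses threshold in every band; the per-band hits
        # must collapse to one candidate at the earliest crossing
        tr = event_trace(onsets=(1.0,), amp=40.0, noise_sd=4.0, seed=2)
        cands = psc.detect_multiband(tr)
        near = cands[np.abs(cands - 1.0) < 5e-3]
        assert near.size == 1

    def test_band_above_nyquist_rejected(self):
        cfg = psc.DetectorConfig(multiband_high_hz=3000.0)
        with pytest.raises(ConfigError):
            psc.detect_multiband(Trace(np.zeros(30000), 5000.0), cfg)


class TestCombineCandidates:
    def test_same_event_from_all_methods_is_one_event(self):
        onsets, tags = psc.combine_candidates(
            {"slope": [1.0], "highband": [1.0004], "multiband": [0.9998]})
        assert onsets.size == 1
        assert tags[0] == {"slope", "highband", "multiband"}
        assert onsets[0] == pytest.approx(0.9998)

    def test_disjoint_candidates_concatenate_sorted(self):
        onsets, tags = psc.combine_candidates(
            {"slope": [2.0], "highband": [1.0], "multiband": [3.0]})
        assert np.allclose(onsets, [1.0, 2.0, 3.0])
        assert [sorted(t) for t in tags] == [["highband"], ["slope"],
                                             ["multiband"]]

    def test_half_ms_apart_merged_keeping_earliest(self):
        onsets, _ = psc.combine_candidates(
            {"a": [1.0], "b": [1.0005]},
            psc.DetectorConfig(merge_tol_ms=2.0))
        assert onsets.size == 1 and onsets[0] == 1.0


class TestMeasureEvents:
    def test_clean_event_amplitude_within_two_percent(self):
        tr = event_trace(onsets=(1.0,), amp=50.0)
        (ev,) = psc.measure_events(tr, [1.0])
        assert ev.amplitude_pa == pytest.approx(50.0, rel=0.02)
        assert ev.onset_s < ev.peak_s

    def test_decay_tau_recovered_within_ten_percent(self):
        tr = event_trace(onsets=(1.0,), amp=50.0, tau_decay_ms=5.0)
        (ev,) = psc.measure_events(tr, [1.0])
        assert ev.decay_tau_ms == pytest.approx(5.0, rel=0.10)

    def test_truncated_decay_reports_amplitude_without_tau(self):
        fs = 25000.0
        tr = event_trace(fs=fs, duration_s=1.0 + 0.0015, onsets=(1.0,),
                         amp=50.0)
        (ev,) = psc.measure_events(tr, [1.0])
        assert ev.amplitude_pa == pytest.approx(50.0, rel=0.02)
        assert np.isnan(ev.decay_tau_ms)

    def test_onset_outside_trace_rejected(self):
        tr = event_trace()
        with pytest.raises(ValueError):
            psc.measure_events(tr, [99.0])

    def test_overlapping_events_truncate_each_other(self):
        tr = event_trace(onsets=(1.0, 1.004), amp=50.0)
        evs = psc.measure_events(tr, [1.0, 1.004])
        assert len(evs) == 2
        assert evs[0].peak_s <= 1.004  # first event window truncated


class TestPipelineLevel:
    def test_event_frequency(self):
        assert psc.event_frequency([], 100.0) == 0.0
        assert psc.event_frequency(list(range(200)), 100.0) == 2.0
        with pytest.raises(ValueError):
            psc.event_frequency([], 0.0)

    @pytest.mark.parametrize("holding,rs,ok,reason", [
        (-250.0, 20.0, False, "holding current"),
        (-100.0, 26.0, False, "series resistance"),
        (-100.0, 20.0, True, None),
    ])
    def test_include_recording_thresholds(self, holding, rs, ok, reason):
        meta = psc.RecordingMeta(-70.0, holding, rs)
        got_ok, got_reason = psc.include_recording(meta)
        assert got_ok is ok and got_reason == reason

    def test_offset_invariance(self):
        cfg = synth.PscSynthConfig(duration_s=20, fs_hz=10000, seed=21)
        tr, _ = synth.gen_psc_trace(cfg)
        ev1 = psc.detect_psc_events(tr, "sEPSC")
        shifted = Trace(tr.samples + 137.0, tr.fs_hz)
        ev2 = psc.detect_psc_events(shifted, "sEPSC")
        assert [e.onset_s for e in ev1] == [e.onset_s for e in ev2]

    def test_polarity_symmetry(self):
        cfg = synth.PscSynthConfig(duration_s=20, fs_hz=10000,
                                   polarity="outward", seed=22)
        tr, _ = synth.gen_psc_trace(cfg)
        ev_out = psc.detect_psc_events(tr, "sIPSC")
        flipped = Trace(-tr.samples, tr.fs_hz)
        dcfg = psc.DetectorConfig(use_slope_method=False)
        ev_in = psc.detect_psc_events(flipped, "sEPSC", dcfg)
        assert [e.onset_s for e in ev_out] == [e.onset_s for e in ev_in]
        assert np.allclose([e.amplitude_pa for e in ev_out],
                           [e.amplitude_pa for e in ev_in])

    def test_determinism(self):
        cfg = synth.PscSynthConfig(duration_s=10, fs_hz=10000, seed=23)
        tr, _ = synth.gen_psc_trace(cfg)
        ev1 = psc.detect_psc_events(tr, "sEPSC")
        ev2 = psc.detect_psc_events(tr, "sEPSC")
        assert [e.onset_s for e in ev1] == [e.onset_s for e in ev2]

    def test_events_frame_columns(self):
        tr = event_trace(onsets=(0.5, 1.0), amp=60.0)
        df = psc.events_to_frame(psc.detect_psc_events(tr, "sEPSC"))
        assert list(df.columns) == ["onset_s", "peak_s", "amplitude_pa",
                                    "rise_20_80_ms", "decay_tau_ms",
                                    "detected_by"]
        assert len(df) == 2
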