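"""Generator correctness: ground truth, statistics and determinism."""
import numpy as np
import pytest

from striephys import synth
from striephys.core import ConfigError


class TestPscTrace:
    def test_no_sources_gives_flat_zero_trace(self):
        cfg = synth.PscSynthConfig(duration_s=2, fs_hz=5000, event_rate_hz=0,
                                   noise_sd_pa=0, drift_amp_pa=0, seed=0)
        trace, truth = synth.gen_psc_trace(cfg)
        assert np.all(trace.samples == 0)
        assert truth.n_events == 0

    def test_single_event_peak_equals_configured_amplitude(self):
        # peak-normalized kernel: trace extremum == drawn amplitude
        cfg = synth.PscSynthConfig(duration_s=5, fs_hz=10000,
                                   event_rate_hz=0.4, amp_cv=0.0,
                                   amp_mean_pa=42.0, noise_sd_pa=0,
                                   drift_amp_pa=0, seed=4)
        trace, truth = synth.gen_psc_trace(cfg)
        assert truth.n_events >= 1
        assert abs(trace.samples.min() + 42.0) / 42.0 < 0.01  # inward

    def test_event_count_matches_poisson_mean_over_seeds(self):
        # rate x duration = 200; mean count over seeds within 3 SE
        rate, dur, n_seeds = 2.0, 100.0, 200
        counts = []
        for seed in range(n_seeds):
            cfg = synth.PscSynthConfig(duration_s=dur, fs_hz=5000,
                                       event_rate_hz=rate, noise_sd_pa=0,
                                       drift_amp_pa=0, seed=seed)
            _, truth = synth.gen_psc_trace(cfg)
            counts.append(truth.n_events)
        expected = rate * dur
        se = np.sqrt(expected / n_seeds)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_ground_truth_times_sorted_within_range(self):
        cfg = synth.PscSynthConfig(duration_s=30, fs_hz=5000, seed=7)
        trace, truth = synth.gen_psc_trace(cfg)
        assert np.all(np.diff(truth.onset_times_s) > 0)
        assert truth.onset_times_s[0] >= 0
        assert truth.onset_times_s[-1] <= cfg.duration_s
        assert truth.amplitudes_pa.size == truth.n_events

    def test_seed_determinism(self):
        cfg = synth.PscSynthConfig(duration_s=5, fs_hz=5000, seed=11)
        t1, g1 = synth.gen_psc_trace(cfg)
        t2, g2 = synth.gen_psc_trace(cfg)
        assert np.array_equal(t1.samples, t2.samples)
        assert np.array_equal(g1.onset_times_s, g2.onset_times_s)

    @pytest.mark.parametrize("field,value", [
        ("duration_s", -1.0), ("fs_hz", 100.0), ("amp_mean_pa", 0.0),
        ("polarity", "sideways"),
    ])
    def test_invalid_config_names_the_field(self, field, value):
        cfg = synth.PscSynthConfig(**{field: value})
        with pytest.raises(ConfigError, match=field):
            synth.gen_psc_trace(cfg)


class TestEvokedTrain:
    def test_full_depletion_gives_zero_second_pulse(self):
        cfg = synth.StpSynthConfig(release_prob=1.0, tau_rec_s=1e9,
                                   facil_incr=0.0)
        amps = synth.stp_amplitudes(cfg)
        assert amps[1] / amps[0] == pytest.approx(0.0, abs=1e-9)

    def test_full_recovery_gives_constant_train(self):
        cfg = synth.StpSynthConfig(release_prob=0.5, tau_rec_s=1e-4,
                                   facil_incr=0.0, amp1_pa=80.0)
        amps = synth.stp_amplitudes(cfg)
        assert np.allclose(amps, 80.0)

    def test_recurrence_matches_hand_iterated_oracle(self):
        # independent explicit iteration of the resource/utilization model
        cfg = synth.StpSynthConfig(release_prob=0.5, tau_rec_s=0.5,
                                   facil_incr=0.1, tau_facil_s=0.2,
                                   rate_hz=20.0, amp1_pa=100.0)
        dt = 0.05
        u, r, rel = 0.5, 1.0, []
        for _ in range(8):
            rel.append(u * r)
            r_post = r * (1 - u)
            u_post = u + 0.1 * (1 - u)
            r = 1 - (1 - r_post) * np.exp(-dt / 0.5)
            u = 0.5 + (u_post - 0.5) * np.exp(-dt / 0.2)
        expected = 100.0 * np.array(rel) / rel[0]
        assert np.allclose(synth.stp_amplitudes(cfg), expected)

    def test_pure_depression_is_strictly_decreasing(self):
        cfg = synth.StpSynthConfig(release_prob=0.6, tau_rec_s=0.8,
                                   facil_incr=0.0)
        amps = synth.stp_amplitudes(cfg)
        assert np.all(np.diff(amps) < 0)

    def test_trace_carries_stimulus_times(self):
        trace, amps = synth.gen_evoked_train(synth.StpSynthConfig(seed=2))
        stim = np.asarray(trace.meta["stim_times_s"])
        assert stim.size == 8
        assert np.allclose(np.diff(stim), 0.05)
        assert amps.size == 8


class TestSpikeTrain:
    def test_zero_duration_gives_empty_train(self):
        cfg = synth.SpikeSynthConfig(duration_s=0)
        assert synth.gen_spike_train(cfg).size == 0

    def test_poisson_count_within_three_se(self):
        cfg = synth.SpikeSynthConfig(duration_s=1000, rate_hz=10, seed=4)
        st = synth.gen_spike_train(cfg)
        assert abs(st.size - 10000) < 3 * np.sqrt(10000)
        assert np.all(np.diff(st) > 0)

    def test_bursty_modal_isi_near_configured(self):
        cfg = synth.SpikeSynthConfig(duration_s=200, mode="bursty",
                                     burst_rate_hz=1.0,
                                     spikes_per_burst_mean=5.0,
                                     intra_burst_isi_ms=5.0, seed=5)
        st = synth.gen_spike_train(cfg)
        isis_ms = np.diff(st) * 1e3
        hist, edges = np.histogram(isis_ms, bins=np.arange(0, 21, 1.0))
        mode = edges[np.argmax(hist)] + 0.5
        assert 2 < mode < 10

    def test_refractory_enforced(self):
        cfg = synth.SpikeSynthConfig(duration_s=100, rate_hz=50,
                                     refractory_ms=2.0, seed=6)
        st = synth.gen_spike_train(cfg)
        assert np.all(np.diff(st) >= 2e-3 - 1e-12)


class TestUnitWaveforms:
    def test_zero_count_gives_empty_list(self):
        assert synth.gen_unit_waveform("narrow", 0) == []

    def test_unknown_class_rejected(self):
        with pytest.raises(ConfigError):
            synth.gen_unit_waveform("medium", 1)

    @pytest.mark.parametrize("kind,lo,hi", [("narrow", 0.2, 0.4),
                                            ("wide", 0.6, 1.0)])
    def test_noise_free_template_trough_to_peak_in_range(self, kind, lo, hi):
        from striephys.spikes import waveform_features
        (w,) = synth.gen_unit_waveform(kind, 1, noise_frac=0.0)
        f = waveform_features(w, 30000.0)
        assert lo <= f["trough_to_peak_ms"] <= hi

    def test_two_class_features_separate_cleanly(self):
        # 2-means on trough-to-peak separates the classes >= 99%
        from sklearn.cluster import KMeans
        from striephys.spikes import waveform_features
        feats, labels = [], []
        for kind in ("narrow", "wide"):
            for w in synth.gen_unit_waveform(kind, 100, seed=8,
                                             noise_frac=0.1):
                feats.append(waveform_features(w, 30000.0)["trough_to_peak_ms"])
                labels.append(kind)
        X = np.asarray(feats)[:, None]
        km = KMeans(2, n_init=10, random_state=0).fit(X)
        lab = km.labels_
        narrow_cluster = 0 if X[lab == 0].mean() < X[lab == 1].mean() else 1
        pred = np.where(lab == narrow_cluster, "narrow", "wide")
        assert (pred == np.asarray(labels)).mean() >= 0.99


class TestLfp:
    def test_white_background_has_flat_spectrum(self):
        from striephys import lfp
        cfg = synth.LfpSynthConfig(duration_s=120, background_exponent=0.0,
                                   seed=9)
        trace, truth = synth.gen_lfp(cfg)
        assert truth == []
        freqs, psd = lfp.multitaper_psd(lfp.segment_lfp(trace), trace.fs_hz)
        lo = psd[(freqs > 5) & (freqs < 100)].mean()
        hi = psd[(freqs > 300) & (freqs < 450)].mean()
        assert 0.8 < lo / hi < 1.25

    def test_single_burst_envelope_peaks_at_ground_truth(self):
        from scipy.signal import hilbert, sosfiltfilt, butter
        cfg = synth.LfpSynthConfig(
            duration_s=20, background_sd_uv=1e-3, seed=10,
            burst_specs=[synth.BurstSpec(19, 21, 3.0, 300.0, 40.0, "beta")])
        trace, truth = synth.gen_lfp(cfg)
        assert len(truth) >= 1
        sos = butter(4, [13, 30], btype="bandpass", fs=trace.fs_hz,
                     output="sos")
        env = np.abs(hilbert(sosfiltfilt(sos, trace.samples)))
        t_peak = np.argmax(env) / trace.fs_hz
        best = min(abs(t_peak - e.peak_s) for e in truth)
        assert best < 0.010

    def test_burst_count_is_poisson(self):
        cfg = synth.LfpSynthConfig(
            duration_s=600, seed=11,
            burst_specs=[synth.BurstSpec(13, 30, 10.0, name="beta")])
        _, truth = synth.gen_lfp(cfg)
        assert abs(len(truth) - 100) < 3 * np.sqrt(100)

    def test_band_above_nyquist_rejected(self):
        cfg = synth.LfpSynthConfig(
            burst_specs=[synth.BurstSpec(400, 600, 1.0)])
        with pytest.raises(ConfigError):
            synth.gen_lfp(cfg)

    def test_seed_determinism(self):
        cfg = synth.LfpSynthConfig(
            duration_s=30, seed=12,
            burst_specs=[synth.BurstSpec(13, 30, 6.0, name="beta")])
        t1, g1 = synth.gen_lfp(cfg)
        t2, g2 = synth.gen_lfp(cfg)
        assert np.array_equal(t1.samples, t2.samples)
        assert [e.peak_s for e in g1] == [e.peak_s for e in g2]
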