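"""Synthetic-recovery benchmarks for every analysis stage.

Each benchmark generates data with the package's own synthetic module
at the study's reference conditions, runs the corresponding analysis,
and scores the result against ground truth.  They are used both by the
test suite and by ``scripts/acceptance.py``.
"""
from __future__ import annotations

import numpy as np

from . import bootstrap as bt
from . import evoked, lfp, psc, spikes, synth

__all__ = [
    "match_events", "psc_detection_benchmark", "burst_index_benchmark",
    "bootstrap_calibration_benchmark", "multitaper_benchmark",
    "lfp_burst_benchmark", "classification_benchmark", "stp_benchmark",
    "study_benchmark",
]


def match_events(detected_s, truth_s, tol_s: float) -> tuple[int, np.ndarray]:
    """Greedy one-to-one matching of detected to true event times.

    Returns (number matched, absolute time errors of the matches).
    """
    det = np.asarray(detected_s, dtype=float)
    used = np.zeros(det.size, dtype=bool)
    errs = []
    for t in np.asarray(truth_s, dtype=float):
        if not det.size:
            break
        d = np.abs(det - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_s:
            used[j] = True
            errs.append(d[j])
    return len(errs), np.asarray(errs)


def psc_detection_benchmark(seed: int, duration_s: float = 100.0,
                            fs_hz: float = 25000.0) -> dict:
    """Recall/precision of the hybrid detector at amplitude/noise = 5,
    2 Hz event rate, with +-2 ms onset matching; plus the false-event
    rate on an event-free noise trace."""
    cfg = synth.PscSynthConfig(duration_s=duration_s, fs_hz=fs_hz,
                               event_rate_hz=2.0, amp_mean_pa=20.0,
                               noise_sd_pa=4.0, seed=seed)
    trace, truth = synth.gen_psc_trace(cfg)
    events = psc.detect_psc_events(trace, "sEPSC")
    onsets = [e.onset_s for e in events]
    n_match, _ = match_events(onsets, truth.onset_times_s, 2e-3)
    recall = n_match / truth.n_events
    precision = n_match / len(onsets) if onsets else float("nan")

    noise_cfg = synth.PscSynthConfig(duration_s=duration_s, fs_hz=fs_hz,
                                     event_rate_hz=0.0, seed=seed + 1)
    noise_trace, _ = synth.gen_psc_trace(noise_cfg)
    n_false = len(psc.detect_psc_events(noise_trace, "sEPSC"))
    return {"recall": recall, "precision": precision,
            "false_rate_hz": n_false / duration_s, "n_true": truth.n_events}


def burst_index_benchmark(seed: int, rate_hz: float = 20.0,
                          n_spikes: int = 100_000) -> dict:
    """Burst index of a homogeneous Poisson train (flat autocorrelogram
    expectation (8-15)/(8+15) = -7/23)."""
    duration = n_spikes / rate_hz
    st = synth.gen_spike_train(synth.SpikeSynthConfig(
        duration_s=duration, rate_hz=rate_hz, seed=seed))
    bi = spikes.burst_index(spikes.autocorrelogram(st))
    return {"index": bi.index, "n_spikes": int(st.size)}


def bootstrap_calibration_benchmark(seed: int, n_datasets: int = 200,
                                    n: int = 30) -> dict:
    """Null significance rate for same-distribution groups, and point
    estimate / detection rate for a 2x mean shift (n = 50, 10% CV)."""
    rng = np.random.default_rng(seed)
    sig = 0
    for d in range(n_datasets):
        a = rng.normal(10.0, 2.0, n)
        b = rng.normal(10.0, 2.0, n)
        res = bt.bootstrap_contrast(a, b, bt.BootstrapConfig(
            seed=int(rng.integers(2**31))))
        sig += res.significant
    points, detected = [], 0
    n_shift_datasets = 50
    for d in range(n_shift_datasets):
        a = rng.normal(10.0, 1.0, 50)
        b = 2.0 * rng.normal(10.0, 1.0, 50)
        res = bt.bootstrap_contrast(a, b, bt.BootstrapConfig(
            seed=int(rng.integers(2**31))))
        points.append(res.point_estimate)
        detected += res.significant
    return {"null_sig_rate": sig / n_datasets,
            "shift_point_estimate": float(np.mean(points)),
            "shift_detection_rate": detected / n_shift_datasets,
            "n_datasets": n_datasets}


def multitaper_benchmark(seed: int) -> dict:
    """Peak-frequency recovery of a 20 Hz unit sine and exactness of the
    1-90 Hz normalization."""
    fs = 1000.0
    rng = np.random.default_rng(seed)
    t = np.arange(0, 60.0, 1 / fs)
    x = np.sin(2 * np.pi * 20.0 * t) + 0.2 * rng.standard_normal(t.size)
    trace = synth.Trace(x, fs, units="uV")
    segs = lfp.segment_lfp(trace)
    freqs, psd = lfp.multitaper_psd(segs, fs)
    cfg = lfp.SpectralConfig()
    npsd = lfp.normalize_psd(freqs, psd, cfg)
    support = ((freqs >= 1) & (freqs <= 90)) & ~((freqs >= 48) & (freqs <= 52))
    return {"peak_hz": float(freqs[np.argmax(psd)]),
            "norm_mean_error": float(abs(np.mean(npsd[support]) - 1.0)),
            "n_segments": len(segs)}


def lfp_burst_benchmark(seed: int, duration_s: float = 600.0) -> dict:
    """Recovery of injected beta bursts (count, median duration, peak
    timing) at the generator's supra-threshold default amplitude."""
    beta = lfp.BANDS["beta"]
    cfg = synth.LfpSynthConfig(
        duration_s=duration_s, seed=seed,
        burst_specs=[synth.BurstSpec(beta.lo_hz, beta.hi_hz,
                                     rate_per_min=10.0, name="beta")])
    trace, truth = synth.gen_lfp(cfg)
    det = lfp.detect_osc_bursts(trace, beta)
    n_match, errs = match_events([e.peak_s for e in det],
                                 [e.peak_s for e in truth], 0.05)
    return {
        "n_true": len(truth), "n_detected": len(det), "n_matched": n_match,
        "median_duration_true_s": float(np.median([e.duration_s
                                                   for e in truth])),
        "median_duration_det_s": (float(np.median([e.duration_s
                                                   for e in det]))
                                  if det else float("nan")),
        "median_peak_error_ms": (float(np.median(errs)) * 1e3
                                 if errs.size else float("nan")),
    }


def classification_benchmark(seed: int, n_seeds: int = 20) -> dict:
    """Agreement of the unsupervised two-way split with generator labels
    over independently drawn unit populations."""
    accs = []
    pv_always_narrower = True
    for k in range(n_seeds):
        units, labels = synth.gen_unit_population(12, 20, seed=seed + k)
        df = spikes.classify_spike_units(units, seed=seed)
        pred = df["unit_class"].map({"putative_PV_IN": "narrow",
                                     "putative_SPN": "wide"}).to_numpy()
        accs.append(float((pred == np.asarray(labels)).mean()))
        ttp_pv = df.loc[df["unit_class"] == "putative_PV_IN",
                        "trough_to_peak_ms"].mean()
        ttp_spn = df.loc[df["unit_class"] == "putative_SPN",
                         "trough_to_peak_ms"].mean()
        pv_always_narrower &= bool(ttp_pv < ttp_spn)
    return {"min_accuracy": float(np.min(accs)),
            "mean_accuracy": float(np.mean(accs)),
            "pv_always_narrower": pv_always_narrower, "n_seeds": n_seeds}


def stp_benchmark(seed: int) -> dict:
    """Recovery of the generator's pulse-2 ratio at 2% measurement noise."""
    cfg = synth.StpSynthConfig(noise_sd_pa=2.0, seed=seed)  # amp1 = 100 pA
    trace, true_amps = synth.gen_evoked_train(cfg)
    prof = evoked.stp_profile(evoked.EvokedRecording.from_trace(trace))
    true_p2 = true_amps[1] / true_amps[0]
    return {"p2_true": float(true_p2), "p2_measured": float(prof.ppr),
            "p2_error_pct": float(abs(prof.ppr - true_p2) / true_p2 * 100),
            "first_normalized": float(prof.normalized_amplitudes[0])}


def study_benchmark(seed: int, out_dir) -> dict:
    """End-to-end study: run the full pipeline on the demo design and
    check that its three imposed contrasts are recovered with the
    correct sign and significance."""
    import pandas as pd

    from .pipeline import demo_config, run_pipeline

    cfg = demo_config()
    cfg["stages"] = ["synth_study", "detect_psc", "evoked", "bootstrap",
                     "compare"]
    out = run_pipeline(cfg, out_dir, seed=seed)
    boot = pd.read_csv(out / "bootstrap_results.csv")
    r = boot[boot["mode"] == "ratio"].set_index(["cell_type", "window",
                                                 "measure"])
    pv_ipsc = r.loc[("PV_IN", "week3", "sIPSC_amplitude")]
    d1_epsc = r.loc[("D1_SPN", "week_gt3", "sEPSC_amplitude")]
    anova = pd.read_csv(out / "evoked_anova.csv").set_index("cell_type")
    pv = anova.loc["PV_IN"]
    rec1 = bool(pv_ipsc["significant"]) and pv_ipsc["point_estimate"] > 1
    rec2 = bool(d1_epsc["significant"]) and d1_epsc["point_estimate"] < 1
    rec3 = pv["p_value"] < 0.05 and pv["mean_b"] < pv["mean_a"]
    return {"pv_in_sipsc_up_week3": bool(rec1),
            "d1_spn_sepsc_down_late": bool(rec2),
            "pv_in_evoked_depression": bool(rec3),
            "n_recovered": int(rec1) + int(rec2) + int(rec3)}
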