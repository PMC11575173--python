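"""Hybrid detection of spontaneous EPSC/IPSC events in voltage-clamp traces.

Three complementary detectors run on the baseline-corrected trace and
their candidates are merged:

1. slope — the signal's slope in a 1 ms window, smoothed over 0.2 ms;
   positive slopes are zeroed and negative slopes accumulated within
   runs, emphasizing the fast rising phase of inward events.  Not used
   for IPSCs, whose rise is too slow for a slope criterion.
2. high-band amplitude — zero-phase high-pass above 10 Hz, threshold at
   4.5 robust SDs of the filtered trace.
3. multi-band amplitude — the same thresholding on band-passed versions
   of the signal (high cutoff 300 Hz, low cutoff 2-20 Hz), which
   captures slow-rising events the other two methods miss.

Candidates within a merge tolerance collapse to one event (earliest
onset kept, detector provenance recorded), then per-event amplitude and
kinetics are measured on the baseline-corrected trace.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .core import ConfigError, Trace, robust_sd

__all__ = [
    "RecordingMeta", "DetectorConfig", "PscEvent",
    "remove_baseline", "detect_slope", "detect_highband", "detect_multiband",
    "combine_candidates", "measure_events", "detect_psc_events",
    "events_to_frame", "event_frequency", "include_recording",
]

# Recording-level inclusion thresholds at -70 mV holding
HOLDING_CURRENT_MIN_PA = -200.0
SERIES_RESISTANCE_MAX_MOHM = 25.0


@dataclass
class RecordingMeta:
    """Whole-cell recording metadata used for inclusion filtering."""

    holding_potential_mv: float
    holding_current_pa: float
    series_resistance_mohm: float
    modality: str = "sEPSC"  # "sEPSC" (inward at -70 mV) or "sIPSC" (outward at 0 mV)


def include_recording(meta: RecordingMeta) -> tuple[bool, str | None]:
    """Recording-level quality gate.

    Excluded when the holding current is more negative than -200 pA (at
    -70 mV holding) or the series resistance exceeds 25 MOhm.
    """
    if meta.holding_current_pa < HOLDING_CURRENT_MIN_PA:
        return False, "holding current"
    if meta.series_resistance_mohm > SERIES_RESISTANCE_MAX_MOHM:
        return False, "series resistance"
    return True, None


@dataclass
class DetectorConfig:
    """Hybrid-detector parameters (times in ms, thresholds in robust SDs)."""

    slope_window_ms: float = 1.0
    slope_smooth_ms: float = 0.2
    slope_threshold_sd: float = 4.0
    highband_cut_hz: float = 10.0
    amp_threshold_sd: float = 4.5
    multiband_high_hz: float = 300.0
    multiband_low_hz_set: Sequence[float] = (2.0, 5.0, 10.0, 20.0)
    merge_tol_ms: float = 2.0
    debounce_ms: float = 1.0
    rearm_frac: float = 0.25
    min_amplitude_pa: float = 0.0
    min_amplitude_sd: float = 3.0
    rise_bounds_ms: tuple[float, float] = (0.1, 10.0)
    use_slope_method: bool = True

    def validate(self):
        for name in ("slope_window_ms", "slope_smooth_ms", "merge_tol_ms",
                     "debounce_ms"):
            if getattr(self, name) <= 0:
                raise ConfigError(name, "must be > 0")
        for name in ("slope_threshold_sd", "amp_threshold_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(name, "must be > 0")


@dataclass
class PscEvent:
    """One detected spontaneous synaptic current.

    ``amplitude_pa`` is the positive magnitude of peak minus local
    baseline regardless of polarity; ``detected_by`` records which of
    the hybrid's methods proposed the event.
    """

    onset_s: float
    peak_s: float
    amplitude_pa: float
    rise_20_80_ms: float
    decay_tau_ms: float
    detected_by: frozenset[str] = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# Baseline removal
# ---------------------------------------------------------------------------

def remove_baseline(trace: Trace, window_s: float = 1.0) -> Trace:
    """Subtract the running median (centered window, truncated at edges).

    For long traces the median is evaluated on a coarse grid (window/128
    stride) and linearly interpolated; the baseline it tracks varies on
    the 1 s scale, far slower than the grid.
    """
    fs = trace.fs_hz
    n = trace.n_samples
    w = int(round(window_s * fs))
    if w < 3:
        raise ConfigError("window_s", "window must span >= 3 samples")
    if w > n:
        raise ConfigError("window_s", "window longer than trace")
    half = w // 2
    stride = max(1, w // 128)
    centers = np.arange(0, n, stride)
    if centers[-1] != n - 1:
        centers = np.append(centers, n - 1)
    med = np.empty(centers.size)
    x = trace.samples
    for k, c in enumerate(centers):
        lo = max(0, c - half)
        hi = min(n, c + half + 1)
        med[k] = np.median(x[lo:hi])
    baseline = np.interp(np.arange(n), centers, med) if stride > 1 else med
    return Trace(x - baseline, fs, units=trace.units, t0_s=trace.t0_s,
                 meta=dict(trace.meta))


# ---------------------------------------------------------------------------
# Individual detectors (operate on baseline-removed, inward-negative traces)
# ---------------------------------------------------------------------------

def _scale_or_fallback(x: np.ndarray) -> float:
    """Robust SD, falling back to the plain SD on noise-free traces.

    A noise-free trace containing sparse events has zero MAD; the plain
    SD (dominated by the events) still provides a usable threshold
    scale there, while an all-zero trace yields 0 (no detections).
    """
    sd = robust_sd(x)
    return sd if sd > 0 else float(np.std(x))


def _crossing_onsets(yf: np.ndarray, thr: float, fs: float, debounce_ms: float,
                     rearm_frac: float = 0.5) -> np.ndarray:
    """Onset times of downward threshold excursions, with hysteresis.

    A new candidate requires the signal to have re-armed (risen above
    ``-rearm_frac * thr``) since the previous one; this prevents the
    hovering re-crossings during an event's decay phase from spawning
    spurious extra candidates.  Candidates are also debounced in time.
    """
    below = yf < -thr
    starts = np.flatnonzero(below & ~np.concatenate([[False], below[:-1]]))
    if starts.size == 0:
        return np.empty(0)
    armed_pts = np.flatnonzero(yf > -rearm_frac * thr)
    keep: list[int] = []
    deb = int(round(debounce_ms * 1e-3 * fs))
    last = -1
    for i in starts:
        if keep and i - keep[-1] < deb:
            continue
        if last >= 0:
            j = np.searchsorted(armed_pts, last, side="right")
            if j >= armed_pts.size or armed_pts[j] >= i:
                continue  # never re-armed since the previous event
        keep.append(int(i))
        last = int(i)
    return np.asarray(keep) / fs


def detect_slope(trace: Trace, cfg: DetectorConfig | None = None) -> np.ndarray:
    """Slope-based candidate onsets (seconds) on an inward-polarity trace.

    Accumulation is a run-wise cumulative integral of the (smoothed)
    negative slope, reset whenever the slope turns non-negative; a run
    whose accumulated excursion exceeds ``slope_threshold_sd`` robust
    SDs of the accumulated trace yields one candidate at the run start.
    """
    cfg = cfg or DetectorConfig()
    cfg.validate()
    fs = trace.fs_hz
    y = trace.samples
    h = max(1, int(round(0.5 * cfg.slope_window_ms * 1e-3 * fs)))
    if y.size <= 2 * h + 2:
        raise ConfigError("slope_window_ms", "trace shorter than slope window")
    s = np.zeros_like(y)
    s[h:-h] = (y[2 * h:] - y[:-2 * h]) * (fs / (2 * h))
    k = max(1, int(round(cfg.slope_smooth_ms * 1e-3 * fs)))
    if k > 1:
        s = signal.convolve(s, np.ones(k) / k, mode="same")

    neg = s < 0
    contrib = np.where(neg, s / fs, 0.0)  # integrates to pA
    c = np.cumsum(contrib)
    idx = np.arange(y.size)
    last_reset = np.maximum.accumulate(np.where(~neg, idx, -1))
    base = np.where(last_reset >= 0, c[np.maximum(last_reset, 0)], 0.0)
    acc = c - base  # <= 0, run-wise accumulated negative slope

    # The accumulated descent is in signal units (pA), so its threshold
    # uses the robust SD of the baseline-removed trace itself; the MAD of
    # the accumulated trace would be dominated by the many small early-run
    # values and grossly underestimate the run-descent tail.
    sigma = _scale_or_fallback(y)
    if sigma <= 0:
        return np.empty(0)
    thr = cfg.slope_threshold_sd * sigma

    starts = np.flatnonzero(neg & ~np.concatenate([[False], neg[:-1]]))
    if starts.size == 0:
        return np.empty(0)
    run_min = np.minimum.reduceat(acc, starts)
    return starts[run_min <= -thr] / fs


def detect_highband(trace: Trace, cfg: DetectorConfig | None = None) -> np.ndarray:
    """High-pass amplitude-threshold candidates (seconds), inward polarity."""
    cfg = cfg or DetectorConfig()
    cfg.validate()
    fs = trace.fs_hz
    sos = signal.butter(4, cfg.highband_cut_hz, btype="highpass", fs=fs,
                        output="sos")
    yf = signal.sosfiltfilt(sos, trace.samples)
    # light smoothing so the hysteresis state is not toggled by
    # sample-scale noise flicker at high sampling rates
    k = max(1, int(round(cfg.slope_smooth_ms * 1e-3 * fs)))
    if k > 1:
        yf = signal.convolve(yf, np.ones(k) / k, mode="same")
    sd = _scale_or_fallback(yf)
    if sd == 0:
        return np.empty(0)
    return _crossing_onsets(yf, cfg.amp_threshold_sd * sd, fs, cfg.debounce_ms,
                            cfg.rearm_frac)


def detect_multiband(trace: Trace, cfg: DetectorConfig | None = None) -> np.ndarray:
    """Multi-band amplitude-threshold candidates (seconds), inward polarity.

    Each low cutoff in ``multiband_low_hz_set`` defines a band up to
    300 Hz; per-band crossings within the merge tolerance collapse to
    one candidate at the earliest time.
    """
    cfg = cfg or DetectorConfig()
    cfg.validate()
    fs = trace.fs_hz
    if cfg.multiband_high_hz >= fs / 2:
        raise ConfigError("multiband_high_hz", "band above Nyquist")
    all_cands = []
    for lo in cfg.multiband_low_hz_set:
        sos = signal.butter(4, [lo, cfg.multiband_high_hz], btype="bandpass",
                            fs=fs, output="sos")
        yf = signal.sosfiltfilt(sos, trace.samples)
        sd = _scale_or_fallback(yf)
        if sd == 0:
            continue
        all_cands.append(_crossing_onsets(yf, cfg.amp_threshold_sd * sd,
                                          fs, cfg.debounce_ms, cfg.rearm_frac))
    if not all_cands:
        return np.empty(0)
    merged, _ = _merge_times(np.sort(np.concatenate(all_cands)),
                             cfg.merge_tol_ms * 1e-3)
    return merged


def _merge_times(times: np.ndarray, tol_s: float,
                 tags: list[frozenset[str]] | None = None
                 ) -> tuple[np.ndarray, list[frozenset[str]]]:
    """Greedy dedup of sorted times: cluster within ``tol_s`` of the
    cluster's earliest member, keep the earliest, union the tags."""
    if times.size == 0:
        return times, []
    keep_t = [times[0]]
    keep_tag = [tags[0] if tags else frozenset()]
    for i in range(1, times.size):
        if times[i] - keep_t[-1] <= tol_s:
            if tags:
                keep_tag[-1] = keep_tag[-1] | tags[i]
        else:
            keep_t.append(times[i])
            keep_tag.append(tags[i] if tags else frozenset())
    return np.asarray(keep_t), keep_tag


def combine_candidates(per_method: Mapping[str, np.ndarray],
                       cfg: DetectorConfig | None = None
                       ) -> tuple[np.ndarray, list[frozenset[str]]]:
    """Union of the methods' candidates, deduplicated within the tolerance.

    Returns sorted onset times plus, per onset, the set of methods that
    proposed it.
    """
    cfg = cfg or DetectorConfig()
    pairs = [(t, frozenset([m])) for m, ts in per_method.items()
             for t in np.asarray(ts, dtype=float)]
    if not pairs:
        return np.empty(0), []
    pairs.sort(key=lambda p: p[0])
    times = np.asarray([p[0] for p in pairs])
    tags = [p[1] for p in pairs]
    return _merge_times(times, cfg.merge_tol_ms * 1e-3, tags)


# ---------------------------------------------------------------------------
# Event measurement
# ---------------------------------------------------------------------------

def _fit_decay_tau_ms(m: np.ndarray, fs: float, amp: float) -> float:
    """Single-exponential decay constant by log-linear least squares.

    ``m`` is the positive-going decay segment starting at the peak.
    Samples below 10% of the amplitude are excluded (log blows up in the
    noise floor).  Returns NaN when the segment is too short to fit.
    """
    if m.size < max(int(3e-3 * fs), 5):
        return float("nan")
    good = m > 0.1 * amp
    # use the contiguous stretch from the peak
    stop = int(np.argmin(good)) if not good.all() else m.size
    if stop < 5:
        return float("nan")
    t = np.arange(stop) / fs
    lg = np.log(m[:stop])
    slope, _ = np.polyfit(t, lg, 1)
    if slope >= 0:
        return float("nan")
    return float(-1.0 / slope * 1e3)


def measure_events(trace: Trace, onsets_s: np.ndarray,
                   provenance: list[frozenset[str]] | None = None,
                   search_window_ms: float = 10.0,
                   baseline_window_ms: float = 2.0) -> list[PscEvent]:
    """Measure amplitude and kinetics at given onsets (inward polarity).

    Per event: local baseline is the median over the 2 ms before onset;
    amplitude is |extremum - baseline| within a 10 ms post-onset window
    (truncated at the next onset, so overlapping events do not corrupt
    each other); the 20-80% rise time comes from interpolated threshold
    crossings of the rising phase; the decay constant from a
    single-exponential fit of the falling phase, reported as NaN when
    the decay is truncated or the fit fails.
    """
    fs = trace.fs_hz
    y = trace.samples
    n = y.size
    onsets = np.asarray(onsets_s, dtype=float)
    order = np.argsort(onsets)
    onsets = onsets[order]
    if provenance is not None:
        provenance = [provenance[i] for i in order]
    w_search = int(round(search_window_ms * 1e-3 * fs))
    w_base = int(round(baseline_window_ms * 1e-3 * fs))
    events: list[PscEvent] = []
    for j, t0 in enumerate(onsets):
        i0 = int(round((t0 - trace.t0_s) * fs))
        if i0 < 0 or i0 >= n:
            raise ValueError(f"onset {t0:.6f} s outside trace")
        pre = y[max(0, i0 - w_base):i0]
        baseline = float(np.median(pre)) if pre.size else float(y[i0])
        i_next = int(round((onsets[j + 1] - trace.t0_s) * fs)) if j + 1 < onsets.size else n
        i_end = min(i0 + w_search, i_next, n)
        if i_end <= i0 + 1:
            i_end = min(i0 + 2, n)
        seg = y[i0:i_end]
        i_pk = i0 + int(np.argmin(seg))
        amp = float(baseline - y[i_pk])  # inward: negative extremum
        m_rise = baseline - y[i0:i_pk + 1]
        rise = float("nan")
        if m_rise.size >= 2 and amp > 0:
            rise = _rise_20_80_ms(m_rise, amp, fs)
        decay = float("nan")
        if amp > 0:
            i_decay_end = min(i_next, i_pk + int(round(0.05 * fs)), n)
            m_decay = baseline - y[i_pk:i_decay_end]
            decay = _fit_decay_tau_ms(np.maximum(m_decay, 1e-12), fs, amp)
        events.append(PscEvent(
            onset_s=t0, peak_s=trace.t0_s + i_pk / fs,
            amplitude_pa=max(amp, 0.0), rise_20_80_ms=rise,
            decay_tau_ms=decay,
            detected_by=provenance[j] if provenance else frozenset()))
    return events


def _rise_20_80_ms(m: np.ndarray, amp: float, fs: float) -> float:
    lo, hi = 0.2 * amp, 0.8 * amp

    def first_cross(level):
        above = m >= level
        k = np.flatnonzero(above)
        if k.size == 0:
            return None
        i = k[0]
        if i == 0:
            return 0.0
        return (i - 1) + (level - m[i - 1]) / (m[i] - m[i - 1])
    a = first_cross(lo)
    b = first_cross(hi)
    if a is None or b is None or b < a:
        return float("nan")
    return float((b - a) / fs * 1e3)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def detect_psc_events(trace: Trace, modality: str = "sEPSC",
                      cfg: DetectorConfig | None = None,
                      baseline_window_s: float = 1.0,
                      baseline_removed: bool = False) -> list[PscEvent]:
    """Hybrid detection + measurement of spontaneous PSC events.

    ``modality`` sets the expected polarity: ``"sEPSC"`` events are
    inward (negative), ``"sIPSC"`` outward (positive; handled by sign
    flip, and the slope method is disabled because it cannot capture
    slow IPSC rise times).  Automated vetting drops candidates with
    implausible measured rise times (outside ``cfg.rise_bounds_ms``) or
    sub-threshold amplitudes, standing in for manual inspection.
    """
    if modality not in ("sEPSC", "sIPSC"):
        raise ConfigError("modality", "must be 'sEPSC' or 'sIPSC'")
    cfg = cfg or DetectorConfig()
    cfg.validate()
    work = trace if baseline_removed else remove_baseline(trace, baseline_window_s)
    if modality == "sIPSC":
        work = Trace(-work.samples, work.fs_hz, units=work.units,
                     t0_s=work.t0_s, meta=dict(work.meta))
    use_slope = cfg.use_slope_method and modality == "sEPSC"
    per_method: dict[str, np.ndarray] = {}
    if use_slope:
        per_method["slope"] = detect_slope(work, cfg)
    per_method["highband"] = detect_highband(work, cfg)
    per_method["multiband"] = detect_multiband(work, cfg)
    onsets, tags = combine_candidates(per_method, cfg)
    if onsets.size == 0:
        return []
    events = measure_events(work, onsets, tags)
    lo, hi = cfg.rise_bounds_ms
    # noise-relative amplitude floor: sub-noise "events" are either
    # threshold re-crossings riding a decay or chance extrema
    amp_floor = max(cfg.min_amplitude_pa,
                    cfg.min_amplitude_sd * _scale_or_fallback(work.samples))
    vetted = []
    for ev in events:
        if ev.amplitude_pa <= 0 or ev.amplitude_pa < amp_floor:
            continue
        if np.isfinite(ev.rise_20_80_ms) and not lo <= ev.rise_20_80_ms <= hi:
            continue
        vetted.append(ev)
    return vetted


def events_to_frame(events: list[PscEvent]) -> pd.DataFrame:
    """Event list as a DataFrame (CSV-ready)."""
    return pd.DataFrame([{
        "onset_s": e.onset_s, "peak_s": e.peak_s,
        "amplitude_pa": e.amplitude_pa, "rise_20_80_ms": e.rise_20_80_ms,
        "decay_tau_ms": e.decay_tau_ms,
        "detected_by": "+".join(sorted(e.detected_by)),
    } for e in events])


def event_frequency(events: Sequence, analyzed_duration_s: float) -> float:
    """Event count divided by analyzed duration, in Hz."""
    if analyzed_duration_s <= 0:
        raise ValueError("analyzed_duration_s must be > 0")
    return len(events) / analyzed_duration_s
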