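"""Synthetic electrophysiology generators with known ground truth.

Every downstream analysis stage in this package is exercised against
signals produced here: spontaneous postsynaptic-current (PSC) traces,
evoked 20 Hz stimulus trains with controlled short-term plasticity,
Poisson/bursty spike trains, narrow- vs wide-spike unit waveforms, and
1/f local field potentials with injected band-limited oscillatory
bursts.  Each generator returns the clean ground truth alongside the
noisy signal so that detector recall/precision and parameter recovery
can be measured exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .core import ConfigError, Trace
from .lfp import OscBurstEvent
from .spikes import SpikeUnit

__all__ = [
    "PscSynthConfig", "GroundTruthEvents", "gen_psc_trace", "psc_kernel",
    "StpSynthConfig", "stp_amplitudes", "gen_evoked_train",
    "SpikeSynthConfig", "gen_spike_train",
    "gen_unit_waveform", "gen_unit_population",
    "LfpSynthConfig", "BurstSpec", "gen_lfp",
]


# ---------------------------------------------------------------------------
# Spontaneous PSC traces
# ---------------------------------------------------------------------------

@dataclass
class PscSynthConfig:
    """Parameters of a synthetic spontaneous-PSC recording.

    Events are biexponential kernels at Poisson times with lognormal
    peak amplitudes, superimposed on a slowly drifting, noisy baseline.
    ``polarity`` follows the voltage-clamp convention: EPSCs recorded at
    -70 mV are inward (negative), IPSCs at 0 mV outward (positive).
    """

    duration_s: float = 300.0
    fs_hz: float = 25000.0
    event_rate_hz: float = 2.0
    amp_mean_pa: float = 30.0
    amp_cv: float = 0.3
    tau_rise_ms: float = 0.5
    tau_decay_ms: float = 5.0
    polarity: str = "inward"
    noise_sd_pa: float = 4.0
    drift_amp_pa: float = 10.0
    drift_period_s: float = 20.0
    drift_rw_sd_pa: float = 0.0
    seed: int = 0

    def validate(self):
        if self.duration_s <= 0:
            raise ConfigError("duration_s", "must be > 0")
        if self.fs_hz < 5000:
            raise ConfigError("fs_hz", "must be >= 5000 Hz")
        if not self.tau_rise_ms < self.tau_decay_ms:
            raise ConfigError("tau_rise_ms", "must be < tau_decay_ms")
        if self.amp_mean_pa <= 0:
            raise ConfigError("amp_mean_pa", "must be > 0")
        if self.event_rate_hz < 0:
            raise ConfigError("event_rate_hz", "must be >= 0")
        if self.polarity not in ("inward", "outward"):
            raise ConfigError("polarity", "must be 'inward' or 'outward'")
        if self.noise_sd_pa < 0:
            raise ConfigError("noise_sd_pa", "must be >= 0")


@dataclass
class GroundTruthEvents:
    """Injected events: onset times (s) and positive peak amplitudes (pA)."""

    onset_times_s: np.ndarray
    amplitudes_pa: np.ndarray

    def __post_init__(self):
        self.onset_times_s = np.asarray(self.onset_times_s, dtype=float)
        self.amplitudes_pa = np.asarray(self.amplitudes_pa, dtype=float)

    @property
    def n_events(self) -> int:
        return int(self.onset_times_s.size)


def psc_kernel(t_s: np.ndarray, tau_rise_ms: float, tau_decay_ms: float) -> np.ndarray:
    """Peak-normalized difference-of-exponentials PSC kernel.

    ``k(t) = (exp(-t/tau_d) - exp(-t/tau_r)) / k(t_peak)`` for ``t >= 0``,
    zero before onset.  Peak value is exactly 1.
    """
    tr = tau_rise_ms * 1e-3
    td = tau_decay_ms * 1e-3
    if not tr < td:
        raise ConfigError("tau_rise_ms", "must be < tau_decay_ms")
    t = np.asarray(t_s, dtype=float)
    g = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / td)
                 - np.exp(-np.clip(t, 0, None) / tr), 0.0)
    t_pk = tr * td / (td - tr) * np.log(td / tr)
    peak = np.exp(-t_pk / td) - np.exp(-t_pk / tr)
    return g / peak


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    if cv <= 0:
        return np.full(n, mean)
    s2 = np.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * s2
    return rng.lognormal(mu, np.sqrt(s2), n)


def gen_psc_trace(cfg: PscSynthConfig) -> tuple[Trace, GroundTruthEvents]:
    """Generate a spontaneous-PSC trace plus its ground-truth event list.

    The trace is ``drift + white noise + sum of events``; each event is a
    peak-normalized biexponential scaled to its drawn amplitude, with the
    configured polarity sign.  Onsets are snapped to the sample grid so
    timing recovery can be scored exactly.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs_hz))
    x = np.zeros(n)

    # baseline: slow sinusoid (+ optional random walk) and white noise
    if cfg.drift_amp_pa > 0:
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n) / cfg.fs_hz
        x += cfg.drift_amp_pa * np.sin(2 * np.pi * t / cfg.drift_period_s + phase)
    if cfg.drift_rw_sd_pa > 0:
        x += np.cumsum(rng.normal(0.0, cfg.drift_rw_sd_pa / np.sqrt(cfg.fs_hz), n))
    if cfg.noise_sd_pa > 0:
        x += rng.normal(0.0, cfg.noise_sd_pa, n)

    n_ev = rng.poisson(cfg.event_rate_hz * cfg.duration_s)
    onset_idx = np.unique(rng.integers(0, n, n_ev))
    amps = _lognormal(rng, cfg.amp_mean_pa, cfg.amp_cv, onset_idx.size)
    sign = -1.0 if cfg.polarity == "inward" else 1.0

    k_len = int(round(8 * cfg.tau_decay_ms * 1e-3 * cfg.fs_hz))
    kern = psc_kernel(np.arange(k_len) / cfg.fs_hz, cfg.tau_rise_ms, cfg.tau_decay_ms)
    for i0, a in zip(onset_idx, amps):
        seg = min(k_len, n - i0)
        x[i0:i0 + seg] += sign * a * kern[:seg]

    truth = GroundTruthEvents(onset_idx / cfg.fs_hz, amps)
    trace = Trace(x, cfg.fs_hz, units="pA",
                  meta={"generator": "gen_psc_trace", "polarity": cfg.polarity,
                        "seed": cfg.seed})
    return trace, truth


# ---------------------------------------------------------------------------
# Evoked trains (short-term plasticity)
# ---------------------------------------------------------------------------

@dataclass
class StpSynthConfig:
    """Deterministic resource-depletion/facilitation model of an evoked train.

    A Tsodyks-Markram-style recurrence: each pulse releases a fraction
    ``u`` of the available resource ``R``; ``R`` recovers toward 1 with
    time constant ``tau_rec_s`` and ``u`` decays back to ``release_prob``
    with ``tau_facil_s`` after being incremented by ``facil_incr``.
    Measurement noise is additive on the trace only; the returned true
    amplitudes are noise-free.
    """

    n_pulses: int = 8
    rate_hz: float = 20.0
    release_prob: float = 0.5
    tau_rec_s: float = 0.5
    facil_incr: float = 0.0
    tau_facil_s: float = 0.2
    amp1_pa: float = 100.0
    tau_rise_ms: float = 0.5
    tau_decay_ms: float = 5.0
    polarity: str = "inward"
    pre_s: float = 0.2
    post_s: float = 0.3
    noise_sd_pa: float = 1.0
    fs_hz: float = 25000.0
    seed: int = 0

    def validate(self):
        if not 0 < self.release_prob <= 1:
            raise ConfigError("release_prob", "must be in (0, 1]")
        if self.n_pulses < 2:
            raise ConfigError("n_pulses", "must be >= 2")
        if self.rate_hz <= 0:
            raise ConfigError("rate_hz", "must be > 0")
        if self.tau_rec_s <= 0:
            raise ConfigError("tau_rec_s", "must be > 0")
        if not 0 <= self.facil_incr < 1:
            raise ConfigError("facil_incr", "must be in [0, 1)")


def stp_amplitudes(cfg: StpSynthConfig) -> np.ndarray:
    """True per-pulse amplitudes from the resource recurrence (pA).

    The first pulse is scaled to exactly ``amp1_pa``; later pulses follow
    ``A_k ∝ u_k R_k``.
    """
    cfg.validate()
    dt = 1.0 / cfg.rate_hz
    u, r = cfg.release_prob, 1.0
    rel = []
    for _ in range(cfg.n_pulses):
        rel.append(u * r)
        r_after = r * (1.0 - u)
        u_after = u + cfg.facil_incr * (1.0 - u)
        r = 1.0 - (1.0 - r_after) * np.exp(-dt / cfg.tau_rec_s)
        u = cfg.release_prob + (u_after - cfg.release_prob) * np.exp(-dt / cfg.tau_facil_s)
    rel = np.asarray(rel)
    return cfg.amp1_pa * rel / rel[0]


def gen_evoked_train(cfg: StpSynthConfig) -> tuple[Trace, np.ndarray]:
    """Synthesize an evoked-train sweep; returns (trace, true amplitudes).

    Stimulus times are stored in ``trace.meta['stim_times_s']``.  PSC
    kernels from successive pulses superpose linearly, so at 20 Hz with
    slow decay kinetics the later pulses ride on residual current, as in
    real recordings.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    amps = stp_amplitudes(cfg)
    dt = 1.0 / cfg.rate_hz
    stim_times = cfg.pre_s + dt * np.arange(cfg.n_pulses)
    duration = cfg.pre_s + dt * cfg.n_pulses + cfg.post_s
    n = int(round(duration * cfg.fs_hz))
    x = rng.normal(0.0, cfg.noise_sd_pa, n) if cfg.noise_sd_pa > 0 else np.zeros(n)
    sign = -1.0 if cfg.polarity == "inward" else 1.0
    k_len = int(round(10 * cfg.tau_decay_ms * 1e-3 * cfg.fs_hz))
    kern = psc_kernel(np.arange(k_len) / cfg.fs_hz, cfg.tau_rise_ms, cfg.tau_decay_ms)
    for t0, a in zip(stim_times, amps):
        i0 = int(round(t0 * cfg.fs_hz))
        seg = min(k_len, n - i0)
        x[i0:i0 + seg] += sign * a * kern[:seg]
    trace = Trace(x, cfg.fs_hz, units="pA",
                  meta={"generator": "gen_evoked_train",
                        "stim_times_s": stim_times.tolist(),
                        "polarity": cfg.polarity, "seed": cfg.seed})
    return trace, amps


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

@dataclass
class SpikeSynthConfig:
    """Poisson or bursty spike-train parameters."""

    duration_s: float = 100.0
    mode: str = "poisson"
    rate_hz: float = 10.0
    burst_rate_hz: float = 0.5
    spikes_per_burst_mean: float = 4.0
    intra_burst_isi_ms: float = 5.0
    refractory_ms: float = 0.0
    seed: int = 0

    def validate(self):
        if self.duration_s < 0:
            raise ConfigError("duration_s", "must be >= 0")
        if self.rate_hz <= 0:
            raise ConfigError("rate_hz", "must be > 0")
        if self.refractory_ms < 0:
            raise ConfigError("refractory_ms", "must be >= 0")
        if self.mode not in ("poisson", "bursty"):
            raise ConfigError("mode", "must be 'poisson' or 'bursty'")


def gen_spike_train(cfg: SpikeSynthConfig) -> np.ndarray:
    """Sorted spike times in seconds.

    Poisson mode is a homogeneous process thinned by the absolute
    refractory period.  Bursty mode draws Poisson burst onsets at
    ``burst_rate_hz``, geometric spike counts (mean
    ``spikes_per_burst_mean``) and 10%-jittered intra-burst intervals.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if cfg.duration_s == 0:
        return np.empty(0)

    if cfg.mode == "poisson":
        n_exp = int(cfg.rate_hz * cfg.duration_s * 1.5 + 100)
        isis = rng.exponential(1.0 / cfg.rate_hz, n_exp)
        t = np.cumsum(isis)
        while t[-1] < cfg.duration_s:  # pragma: no cover - rare top-up
            isis = rng.exponential(1.0 / cfg.rate_hz, n_exp)
            t = np.concatenate([t, t[-1] + np.cumsum(isis)])
        t = t[t < cfg.duration_s]
    else:
        n_b = rng.poisson(cfg.burst_rate_hz * cfg.duration_s)
        onsets = rng.uniform(0, cfg.duration_s, n_b)
        spikes = []
        p = 1.0 / max(cfg.spikes_per_burst_mean, 1.0)
        for t0 in onsets:
            k = rng.geometric(p)
            isis = cfg.intra_burst_isi_ms * 1e-3 * (1 + 0.1 * rng.standard_normal(k - 1))
            spikes.append(t0 + np.concatenate([[0.0], np.cumsum(np.abs(isis))]))
        t = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
        t = t[t < cfg.duration_s]

    if cfg.refractory_ms > 0 and t.size:
        keep = [0]
        ref = cfg.refractory_ms * 1e-3
        for i in range(1, t.size):
            if t[i] - t[keep[-1]] >= ref:
                keep.append(i)
        t = t[keep]
    return np.unique(t)


# ---------------------------------------------------------------------------
# Unit waveforms
# ---------------------------------------------------------------------------

_WAVEFORM_CLASSES = {
    # trough-to-peak ms, trough width sigma ms, peak/trough ratio
    "narrow": (0.30, 0.08, 0.35),
    "wide": (0.80, 0.18, 0.50),
}


def gen_unit_waveform(kind: str, n: int, seed: int = 0, *,
                      noise_frac: float = 0.1, fs_hz: float = 30000.0,
                      trough_uv: float = 100.0) -> list[np.ndarray]:
    """Mean extracellular spike waveforms for a narrow- or wide-spike class.

    Narrow-spike templates have a trough-to-peak time of ~0.3 ms
    (putative fast-spiking interneurons), wide-spike ~0.8 ms (putative
    projection neurons).  White noise with SD ``noise_frac * trough_uv``
    is added per waveform.
    """
    if kind not in _WAVEFORM_CLASSES:
        raise ConfigError("kind", f"unknown waveform class {kind!r}")
    ttp_ms, sig_ms, ratio = _WAVEFORM_CLASSES[kind]
    rng = np.random.default_rng(seed)
    n_samp = int(round(3.0e-3 * fs_hz))
    t_ms = np.arange(n_samp) / fs_hz * 1e3
    t_tr = 1.0
    template = (-trough_uv * np.exp(-0.5 * ((t_ms - t_tr) / sig_ms) ** 2)
                + ratio * trough_uv
                * np.exp(-0.5 * ((t_ms - t_tr - ttp_ms) / (1.6 * sig_ms)) ** 2))
    out = []
    for _ in range(n):
        w = template.copy()
        if noise_frac > 0:
            w = w + rng.normal(0.0, noise_frac * trough_uv, n_samp)
        out.append(w)
    return out


def gen_unit_population(n_narrow: int, n_wide: int, *, duration_s: float = 120.0,
                        seed: int = 0, noise_frac: float = 0.1,
                        fs_hz: float = 30000.0) -> tuple[list[SpikeUnit], list[str]]:
    """Synthetic single units with class-typical waveforms and firing rates.

    Narrow-spike units fire fast (lognormal around 15 Hz), wide-spike
    units slowly (around 3 Hz), mirroring the rate difference used to
    assign putative cell classes.  Returns units plus true class labels
    (``"narrow"`` / ``"wide"``).
    """
    rng = np.random.default_rng(seed)
    units: list[SpikeUnit] = []
    labels: list[str] = []
    for kind, n_units, rate0 in (("narrow", n_narrow, 15.0), ("wide", n_wide, 3.0)):
        wfs = gen_unit_waveform(kind, n_units, seed=rng.integers(2**31),
                                noise_frac=noise_frac, fs_hz=fs_hz)
        for w in wfs:
            rate = float(np.exp(np.log(rate0) + 0.25 * rng.standard_normal()))
            st = gen_spike_train(SpikeSynthConfig(
                duration_s=duration_s, mode="poisson", rate_hz=rate,
                refractory_ms=2.0, seed=int(rng.integers(2**31))))
            units.append(SpikeUnit(spike_times_s=st, mean_waveform_uv=w,
                                   waveform_fs_hz=fs_hz,
                                   recording_duration_s=duration_s))
            labels.append(kind)
    return units, labels


# ---------------------------------------------------------------------------
# LFP with oscillatory bursts
# ---------------------------------------------------------------------------

@dataclass
class BurstSpec:
    """One class of injected band-limited bursts."""

    band_low_hz: float
    band_high_hz: float
    rate_per_min: float
    duration_ms_mean: float = 300.0
    amplitude_db: float = 10.0
    name: str = ""


@dataclass
class LfpSynthConfig:
    """1/f^alpha LFP background with injected oscillatory bursts.

    Burst amplitudes are calibrated in dB over the *median band envelope*
    of the background, the same scale on which the dual-threshold burst
    detector operates.  Ground-truth start/end times are where the
    injected envelope alone sits 2 dB above that background level (the
    conventional event-boundary threshold), so generator durations and
    detector durations share a convention.
    """

    duration_s: float = 600.0
    fs_hz: float = 1000.0
    background_exponent: float = 1.0
    background_sd_uv: float = 50.0
    burst_specs: Sequence[BurstSpec] = field(default_factory=list)
    line_noise_50hz_db: float | None = None
    edge_margin_s: float = 2.0
    seed: int = 0

    def validate(self):
        if self.duration_s <= 0:
            raise ConfigError("duration_s", "must be > 0")
        if self.fs_hz <= 0:
            raise ConfigError("fs_hz", "must be > 0")
        nyq = self.fs_hz / 2
        for spec in self.burst_specs:
            if not 0 < spec.band_low_hz < spec.band_high_hz < nyq:
                raise ConfigError("burst_specs",
                                  f"band ({spec.band_low_hz}, {spec.band_high_hz}) "
                                  f"outside (0, {nyq}) Hz")
            if spec.rate_per_min < 0:
                raise ConfigError("burst_specs", "rates must be >= 0")


def _spectral_background(rng, n, fs, exponent, sd):
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def gen_lfp(cfg: LfpSynthConfig) -> tuple[Trace, list[OscBurstEvent]]:
    """Generate an LFP trace and the ground-truth list of injected bursts.

    The background is synthesized in the frequency domain (amplitude
    ``f^(-alpha/2)``, random phases) which gives exact control of the
    1/f exponent.  Each burst is a Gaussian-envelope sinusoid whose
    carrier frequency is drawn uniformly within its band.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs_hz))
    x = _spectral_background(rng, n, cfg.fs_hz, cfg.background_exponent,
                             cfg.background_sd_uv)
    t = np.arange(n) / cfg.fs_hz
    truth: list[OscBurstEvent] = []

    for spec in cfg.burst_specs:
        # background level on the detector's scale: median analytic
        # envelope of the band-passed background
        sos = signal.butter(4, [spec.band_low_hz, spec.band_high_hz],
                            btype="bandpass", fs=cfg.fs_hz, output="sos")
        env_bg = np.abs(signal.hilbert(signal.sosfiltfilt(sos, x)))
        med_bg = float(np.median(env_bg))
        if med_bg == 0:
            med_bg = 1e-12

        n_b = rng.poisson(spec.rate_per_min * cfg.duration_s / 60.0)
        lo = cfg.edge_margin_s
        hi = max(cfg.duration_s - cfg.edge_margin_s, lo)
        peaks = np.sort(rng.uniform(lo, hi, n_b))
        for tp in peaks:
            dur = spec.duration_ms_mean * 1e-3 * float(
                np.exp(0.2 * rng.standard_normal() - 0.02))
            a_db = spec.amplitude_db
            f0 = rng.uniform(spec.band_low_hz, spec.band_high_hz)
            phi = rng.uniform(0, 2 * np.pi)
            peak_amp = med_bg * 10 ** (a_db / 20.0)
            # sigma such that the envelope crosses (background + 2 dB)
            # exactly dur/2 either side of the peak
            drop_db = max(a_db - 2.0, 0.5)
            sigma = dur / (2.0 * np.sqrt(2.0 * np.log(10) * drop_db / 20.0))
            half = 4.0 * sigma
            i0 = max(int((tp - half) * cfg.fs_hz), 0)
            i1 = min(int((tp + half) * cfg.fs_hz), n)
            tt = t[i0:i1] - tp
            x[i0:i1] += (peak_amp * np.exp(-0.5 * (tt / sigma) ** 2)
                         * np.cos(2 * np.pi * f0 * tt + phi))
            truth.append(OscBurstEvent(
                band=spec.name or f"{spec.band_low_hz:g}-{spec.band_high_hz:g}Hz",
                start_s=tp - dur / 2, peak_s=tp, end_s=tp + dur / 2,
                peak_freq_hz=f0, peak_db_over_background=a_db))

    if cfg.line_noise_50hz_db is not None:
        amp = cfg.background_sd_uv * 10 ** (cfg.line_noise_50hz_db / 20.0)
        x += amp * np.sin(2 * np.pi * 50.0 * t)

    trace = Trace(x, cfg.fs_hz, units="uV",
                  meta={"generator": "gen_lfp", "seed": cfg.seed})
    truth.sort(key=lambda e: e.peak_s)
    return trace, truth
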