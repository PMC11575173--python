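"""Single-unit spike-train metrics and putative cell-type classification.

Covers unit quality control, mean firing rate, spike autocorrelograms,
the head/tail burst index, waveform shape features, and the unsupervised
two-way split into putative fast-spiking interneurons (narrow spikes,
high rate) versus putative spiny projection neurons (wide spikes).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .core import robust_sd

__all__ = [
    "SpikeUnit", "QualityMetrics", "Autocorrelogram", "BurstIndexResult",
    "compute_quality", "quality_pass", "autocorrelogram", "burst_index",
    "mean_rate", "waveform_features", "classify_units", "classify_spike_units",
]

# Curation thresholds for accepting a sorted unit: spike amplitude above
# 50 uV, refractory-period ISI violations below 0.5%, amplitude-histogram
# noise cutoff below 0.5, and SNR above 2.5.
AMPLITUDE_MIN_UV = 50.0
ISI_VIOLATION_MAX_PCT = 0.5
NOISE_CUTOFF_MAX = 0.5
SNR_MIN = 2.5


@dataclass
class SpikeUnit:
    """A sorted single unit: spike times plus its mean waveform."""

    spike_times_s: np.ndarray
    mean_waveform_uv: np.ndarray
    waveform_fs_hz: float
    recording_duration_s: float
    spike_amplitudes_uv: np.ndarray | None = None
    unit_id: str = ""

    def __post_init__(self):
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        self.mean_waveform_uv = np.asarray(self.mean_waveform_uv, dtype=float)
        if self.spike_times_s.size and np.any(np.diff(self.spike_times_s) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if self.spike_times_s.size and (
                self.spike_times_s[0] < 0
                or self.spike_times_s[-1] > self.recording_duration_s):
            raise ValueError("spike times outside [0, recording_duration_s]")


@dataclass
class QualityMetrics:
    """Unit curation metrics; ``isi_violation`` is a percentage of ISIs."""

    amplitude_uv: float
    isi_violation: float
    noise_cutoff: float
    snr: float


def compute_quality(unit: SpikeUnit, refractory_ms: float = 2.0) -> QualityMetrics:
    """Quality metrics for one unit.

    amplitude: trough depth of the mean waveform relative to its edge
    baseline.  isi_violation: percentage of inter-spike intervals shorter
    than the refractory period.  snr: waveform peak-to-peak over the
    robust SD of the baseline (first/last 15% of samples).  noise_cutoff:
    height of the low edge of the spike-amplitude histogram relative to
    its mode — near zero when the amplitude distribution is fully above
    the detection floor, approaching 1 when it is truncated; 0.0 when
    per-spike amplitudes are unavailable.
    """
    w = unit.mean_waveform_uv
    n_edge = max(int(0.15 * w.size), 2)
    edges = np.concatenate([w[:n_edge], w[-n_edge:]])
    baseline = float(np.median(edges))
    amplitude = float(abs(w.min() - baseline))
    noise = robust_sd(edges - baseline)

    isis = np.diff(unit.spike_times_s)
    viol = 100.0 * float(np.mean(isis < refractory_ms * 1e-3)) if isis.size else 0.0

    snr = float((w.max() - w.min()) / noise) if noise > 0 else np.inf

    cutoff = 0.0
    if unit.spike_amplitudes_uv is not None and len(unit.spike_amplitudes_uv) >= 10:
        counts, _ = np.histogram(unit.spike_amplitudes_uv, bins=50)
        nz = np.flatnonzero(counts)
        if nz.size and counts.max() > 0:
            cutoff = float(counts[nz[0]] / counts.max())
    return QualityMetrics(amplitude, viol, cutoff, snr)


def quality_pass(qm: QualityMetrics) -> tuple[bool, list[str]]:
    """Apply the curation thresholds; returns (pass, failed criteria)."""
    failed = []
    if not qm.amplitude_uv > AMPLITUDE_MIN_UV:
        failed.append("amplitude")
    if not qm.isi_violation < ISI_VIOLATION_MAX_PCT:
        failed.append("isi_violation")
    if not qm.noise_cutoff < NOISE_CUTOFF_MAX:
        failed.append("noise_cutoff")
    if not qm.snr > SNR_MIN:
        failed.append("snr")
    return len(failed) == 0, failed


# ---------------------------------------------------------------------------
# Autocorrelogram and burst index
# ---------------------------------------------------------------------------

@dataclass
class Autocorrelogram:
    """One-sided spike autocorrelogram: pair counts at positive lags.

    Bin ``k`` counts ordered spike pairs with lag in
    ``(bin_edges_ms[k], bin_edges_ms[k+1]]``; zero-lag self pairs are
    excluded.
    """

    bin_edges_ms: np.ndarray
    counts: np.ndarray
    n_spikes: int


def autocorrelogram(spike_times_s: np.ndarray, bin_ms: float = 1.0,
                    max_lag_ms: float = 50.0) -> Autocorrelogram:
    """Pair-count autocorrelogram over lags in (0, max_lag_ms]."""
    t = np.asarray(spike_times_s, dtype=float)
    edges = np.arange(0.0, max_lag_ms + bin_ms / 2, bin_ms)
    counts = np.zeros(edges.size - 1, dtype=np.int64)
    if t.size < 2:
        return Autocorrelogram(edges, counts, int(t.size))
    max_lag = max_lag_ms * 1e-3
    hi = np.searchsorted(t, t + max_lag, side="right")
    dt_ms: list[np.ndarray] = []
    for i in range(t.size - 1):
        if hi[i] > i + 1:
            dt_ms.append((t[i + 1:hi[i]] - t[i]) * 1e3)
    if dt_ms:
        lags = np.concatenate(dt_ms)
        # right-closed bins so that an exact k-ms lag lands in (k-1, k]
        idx = np.digitize(lags, edges, right=True) - 1
        valid = (idx >= 0) & (idx < counts.size)
        np.add.at(counts, idx[valid], 1)
    return Autocorrelogram(edges, counts, int(t.size))


@dataclass
class BurstIndexResult:
    """Head/tail burst index from autocorrelogram counts.

    head = counts at 2-10 ms lags, tail = counts at 35-50 ms lags;
    index = (head - tail) / (head + tail), in [-1, 1], NaN when both
    windows are empty.  Positive values indicate bursty firing.
    """

    head_sum: int
    tail_sum: int
    index: float


def burst_index(acg: Autocorrelogram, head_ms: tuple[float, float] = (2.0, 10.0),
                tail_ms: tuple[float, float] = (35.0, 50.0)) -> BurstIndexResult:
    """Burst index from an autocorrelogram (raw count sums)."""
    centers_hi = acg.bin_edges_ms[1:]  # bin k covers (edge[k], edge[k+1]]
    head_mask = (centers_hi > head_ms[0]) & (centers_hi <= head_ms[1])
    tail_mask = (centers_hi > tail_ms[0]) & (centers_hi <= tail_ms[1])
    head = int(acg.counts[head_mask].sum())
    tail = int(acg.counts[tail_mask].sum())
    idx = (head - tail) / (head + tail) if head + tail > 0 else float("nan")
    return BurstIndexResult(head, tail, idx)


def mean_rate(unit: SpikeUnit) -> float:
    """Mean firing rate in Hz."""
    if unit.recording_duration_s <= 0:
        raise ValueError("recording_duration_s must be > 0")
    return unit.spike_times_s.size / unit.recording_duration_s


# ---------------------------------------------------------------------------
# Waveform features and classification
# ---------------------------------------------------------------------------

def waveform_features(mean_waveform_uv: np.ndarray, fs_hz: float) -> dict[str, float]:
    """Shape features of a biphasic (trough-then-peak) mean waveform.

    Returns trough-to-peak time (ms), half-width of the trough (ms), and
    the peak/trough amplitude ratio.  Raises on waveforms without a
    positive peak after the trough.
    """
    w = np.asarray(mean_waveform_uv, dtype=float)
    i_tr = int(np.argmin(w))
    if i_tr == 0 or i_tr >= w.size - 2 or w[i_tr] >= 0:
        raise ValueError("waveform is not biphasic")
    after = w[i_tr:]
    i_pk = i_tr + int(np.argmax(after))
    if w[i_pk] <= 0 or i_pk == i_tr:
        raise ValueError("waveform is not biphasic")
    ttp_ms = (i_pk - i_tr) / fs_hz * 1e3

    half = w[i_tr] / 2.0
    left = np.flatnonzero(w[:i_tr] > half)
    right = np.flatnonzero(w[i_tr:] > half)
    if left.size == 0 or right.size == 0:
        raise ValueError("waveform is not biphasic")
    iL, iR = left[-1], i_tr + right[0]

    def _cross(i_hi, i_lo):  # linear interp of crossing between samples
        return i_hi + (half - w[i_hi]) / (w[i_lo] - w[i_hi])

    xL = _cross(iL, iL + 1)
    xR = (iR - 1) + (half - w[iR - 1]) / (w[iR] - w[iR - 1])
    half_width_ms = (xR - xL) / fs_hz * 1e3
    return {
        "trough_to_peak_ms": float(ttp_ms),
        "half_width_ms": float(half_width_ms),
        "peak_trough_ratio": float(w[i_pk] / abs(w[i_tr])),
    }


def classify_units(features: pd.DataFrame, seed: int = 0) -> pd.Series:
    """Two-cluster split into putative PV interneurons vs putative SPNs.

    ``features`` needs columns ``trough_to_peak_ms``, ``half_width_ms``
    and ``log_rate``.  Features are standardized, embedded with PCA and
    split by 2-means; the cluster with the smaller mean trough-to-peak
    time is labeled ``putative_PV_IN``, the other ``putative_SPN``.
    """
    cols = ["trough_to_peak_ms", "half_width_ms", "log_rate"]
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    if len(features) < 4:
        raise ValueError("insufficient units: need >= 4 for classification")
    X = features[cols].to_numpy(dtype=float)
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("units are indistinguishable (zero feature variance); "
                         "refusing a two-cluster split")
    Xs = StandardScaler().fit_transform(X)
    emb = PCA(n_components=min(2, Xs.shape[1]), random_state=seed).fit_transform(Xs)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(emb)
    lab = km.labels_
    ttp = features["trough_to_peak_ms"].to_numpy(dtype=float)
    mean0 = ttp[lab == 0].mean()
    mean1 = ttp[lab == 1].mean()
    pv_cluster = 0 if mean0 < mean1 else 1
    names = np.where(lab == pv_cluster, "putative_PV_IN", "putative_SPN")
    return pd.Series(names, index=features.index, name="unit_class")


def classify_spike_units(units: list[SpikeUnit], seed: int = 0) -> pd.DataFrame:
    """Feature extraction + classification for a list of units.

    Returns a per-unit table with rate, burst index, waveform features,
    QC outcome and the putative class label.
    """
    rows = []
    for u in units:
        feats = waveform_features(u.mean_waveform_uv, u.waveform_fs_hz)
        rate = mean_rate(u)
        qm = compute_quality(u)
        ok, failed = quality_pass(qm)
        bi = burst_index(autocorrelogram(u.spike_times_s))
        rows.append({
            "unit_id": u.unit_id, "rate_hz": rate,
            "log_rate": np.log(max(rate, 1e-3)),
            "burst_index": bi.index, "qc_pass": ok,
            "qc_failed": ";".join(failed), **feats,
        })
    df = pd.DataFrame(rows)
    df["unit_class"] = classify_units(df, seed=seed)
    return df
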