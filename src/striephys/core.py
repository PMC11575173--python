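"""Core containers and file I/O.

A :class:`Trace` is the single in-memory representation of a uniformly
sampled signal used throughout the package: voltage-clamp current in pA
for synaptic analysis, extracellular voltage in uV for LFP work.  Traces
round-trip to disk as a ``.npy`` array plus a JSON sidecar carrying the
sampling rate, units and free-form metadata.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    """Invalid configuration value; ``field_name`` names the offender."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass
class Trace:
    """Uniformly sampled signal.

    Parameters
    ----------
    samples : ndarray
        Signal values (current in pA or voltage in uV).
    fs_hz : float
        Sampling rate in Hz.
    units : str
        Physical units of ``samples``.
    t0_s : float
        Time of the first sample, seconds.
    meta : dict
        Free-form recording metadata (stimulus times, ground truth, ...).
    """

    samples: np.ndarray
    fs_hz: float
    units: str = "pA"
    t0_s: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs_hz <= 0:
            raise ConfigError("fs_hz", "sampling rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ConfigError("samples", "need a 1-D signal of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ConfigError("samples", "signal contains non-finite values")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0_s + np.arange(self.n_samples) / self.fs_hz

    def index_at(self, t_s: float) -> int:
        """Nearest sample index for a time in seconds (clipped to range)."""
        i = int(round((t_s - self.t0_s) * self.fs_hz))
        return min(max(i, 0), self.n_samples - 1)


def save_trace(trace: Trace, path: str | Path) -> Path:
    """Write ``trace`` as ``<path>.npy`` + ``<path>.json`` sidecar."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".npy" else path
    np.save(base.with_suffix(".npy"), trace.samples)
    sidecar = {
        "fs_hz": trace.fs_hz,
        "units": trace.units,
        "t0_s": trace.t0_s,
        "meta": _jsonable(trace.meta),
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return base.with_suffix(".npy")


def load_trace(path: str | Path) -> Trace:
    """Load a trace written by :func:`save_trace`."""
    base = Path(path)
    if base.suffix == ".npy":
        base = base.with_suffix("")
    samples = np.load(base.with_suffix(".npy"))
    side = json.loads(base.with_suffix(".json").read_text())
    return Trace(samples, side["fs_hz"], side.get("units", "pA"),
                 side.get("t0_s", 0.0), side.get("meta", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_events_csv(df: pd.DataFrame, path: str | Path,
                     time_cols: tuple[str, ...] = ()) -> Path:
    """Write an event table with times rounded to 6 decimal places."""
    path = Path(path)
    out = df.copy()
    for c in time_cols:
        if c in out.columns:
            out[c] = out[c].round(6)
    out.to_csv(path, index=False)
    return path


def robust_sd(x: np.ndarray) -> float:
    """MAD-based robust standard deviation (1.4826 * MAD).

    Preferred over the naive SD for event-containing traces, where the
    events themselves inflate the scale estimate.
    """
    x = np.asarray(x)
    if x.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))
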