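"""Bootstrap resampling of group contrasts and E-I balance trajectories.

The estimator of a lesion-vs-sham contrast: in each iteration, 75% of
each group's cells are drawn (without replacement by default), group
means are computed, and their ratio (relative change) or difference is
recorded.  Across iterations this yields a point estimate, an SD
("noise level", displayed as a ±3 SD band), and a 95% percentile
interval.  A contrast is flagged significant when the null value (1 for
ratios, 0 for differences) falls outside the ±3 SD noise band; this
rule is calibrated to a ~5% false-positive rate under 75%
without-replacement subsampling, whereas the narrower percentile
interval of subsample statistics is not (see the methods note).
Chaining per-time-window excitatory and inhibitory contrasts produces
the E-I balance trajectory of a cell type after dopamine depletion.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ConfigError

__all__ = ["BootstrapConfig", "BootstrapResult", "EiTrajectoryPoint",
           "bootstrap_contrast", "relative_change_curve", "ei_trajectory",
           "trajectory_to_frame"]


@dataclass
class BootstrapConfig:
    """Resampling parameters for group contrasts.

    ``mode`` selects ratio (lesion mean / sham mean) or difference
    (lesion mean - sham mean).  ``replace=False`` draws 75% subsamples
    without replacement (the literal resampling procedure);
    ``replace=True`` gives the classical bootstrap.
    ``significance_rule`` is ``"band3sd"`` (null outside point ± 3 SD)
    or ``"ci"`` (null outside the 95% percentile interval).
    """

    subsample_frac: float = 0.75
    n_iter: int = 1000
    mode: str = "ratio"
    ci_level: float = 0.95
    replace: bool = False
    significance_rule: str = "band3sd"
    seed: int = 0

    def validate(self):
        if not 0 < self.subsample_frac <= 1:
            raise ConfigError("subsample_frac", "must be in (0, 1]")
        if self.n_iter < 100:
            raise ConfigError("n_iter", "must be >= 100")
        if self.mode not in ("ratio", "difference"):
            raise ConfigError("mode", "must be 'ratio' or 'difference'")
        if self.significance_rule not in ("band3sd", "ci"):
            raise ConfigError("significance_rule", "must be 'band3sd' or 'ci'")
        if not 0 < self.ci_level < 1:
            raise ConfigError("ci_level", "must be in (0, 1)")


@dataclass
class BootstrapResult:
    """Summary of the resampled contrast distribution."""

    point_estimate: float
    sd: float
    ci_low: float
    ci_high: float
    band_3sd_low: float
    band_3sd_high: float
    significant: bool
    n_rejected: int = 0


@dataclass
class EiTrajectoryPoint:
    """One step of the E-I balance trajectory of a cell type."""

    time_window: str
    delta_e: float
    delta_i: float
    cell_type: str = ""


def _subsample_means(values: np.ndarray, k: int, n_iter: int,
                     rng: np.random.Generator, replace: bool) -> np.ndarray:
    n = values.size
    if replace:
        idx = rng.integers(0, n, size=(n_iter, k))
    else:
        idx = np.argsort(rng.random((n_iter, n)), axis=1)[:, :k]
    return values[idx].mean(axis=1)


def bootstrap_contrast(group_sham: Sequence[float], group_lesion: Sequence[float],
                       cfg: BootstrapConfig | None = None) -> BootstrapResult:
    """Resampled contrast of ``group_lesion`` against ``group_sham``.

    Both groups are independently subsampled each iteration.  In ratio
    mode, iterations whose sham resample mean is exactly zero are
    rejected and redrawn; more than 10% rejections aborts.
    """
    cfg = cfg or BootstrapConfig()
    cfg.validate()
    a = np.asarray(group_sham, dtype=float)
    b = np.asarray(group_lesion, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ka = max(int(np.floor(cfg.subsample_frac * a.size)), 1)
    kb = max(int(np.floor(cfg.subsample_frac * b.size)), 1)
    rng = np.random.default_rng(cfg.seed)

    stats = np.empty(cfg.n_iter)
    filled = 0
    rejected = 0
    max_reject = max(int(0.1 * cfg.n_iter), 1)
    while filled < cfg.n_iter:
        todo = cfg.n_iter - filled
        ma = _subsample_means(a, ka, todo, rng, cfg.replace)
        mb = _subsample_means(b, kb, todo, rng, cfg.replace)
        if cfg.mode == "ratio":
            ok = ma != 0
            rejected += int((~ok).sum())
            if rejected > max_reject:
                raise ValueError("ratio mode: more than 10% of iterations had "
                                 "a zero sham resample mean")
            vals = mb[ok] / ma[ok]
        else:
            vals = mb - ma
        stats[filled:filled + vals.size] = vals
        filled += vals.size

    point = float(stats.mean())
    sd = float(stats.std(ddof=0))
    alpha = (1 - cfg.ci_level) / 2
    ci_low, ci_high = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    lo3, hi3 = point - 3 * sd, point + 3 * sd
    null = 1.0 if cfg.mode == "ratio" else 0.0
    if cfg.significance_rule == "band3sd":
        significant = not (lo3 <= null <= hi3)
    else:
        significant = not (ci_low <= null <= ci_high)
    return BootstrapResult(point, sd, float(ci_low), float(ci_high),
                           float(lo3), float(hi3), bool(significant),
                           n_rejected=rejected)


def relative_change_curve(windowed_data: Mapping[str, tuple[Sequence[float],
                                                            Sequence[float]]],
                          cfg: BootstrapConfig | None = None
                          ) -> list[tuple[str, BootstrapResult | None]]:
    """Ratio-mode bootstrap per time window, with an artificial reference.

    ``windowed_data`` maps window label -> (sham values, lesion values).
    The returned curve starts with a ``("reference", result)`` point
    pinned at 1 (zero spread, by construction not significant) that
    serves purely as a visual anchor; windows with an empty group are
    flagged with ``None``.
    """
    cfg = cfg or BootstrapConfig()
    if cfg.mode != "ratio":
        cfg = BootstrapConfig(**{**cfg.__dict__, "mode": "ratio"})
    curve: list[tuple[str, BootstrapResult | None]] = [
        ("reference", BootstrapResult(1.0, 0.0, 1.0, 1.0, 1.0, 1.0, False))]
    for i, (window, (sham, lesion)) in enumerate(windowed_data.items()):
        if len(sham) == 0 or len(lesion) == 0:
            curve.append((window, None))
            continue
        wcfg = BootstrapConfig(**{**cfg.__dict__, "seed": cfg.seed + i})
        curve.append((window, bootstrap_contrast(sham, lesion, wcfg)))
    return curve


def ei_trajectory(e_results: Mapping[str, BootstrapResult],
                  i_results: Mapping[str, BootstrapResult],
                  cell_type: str = "") -> list[EiTrajectoryPoint]:
    """Pair per-window excitatory and inhibitory contrasts into a trajectory.

    Windows must match exactly between the two mappings; the trajectory
    preserves the insertion order of ``e_results``.
    """
    if list(e_results.keys()) != list(i_results.keys()):
        raise ValueError("E and I contrasts cover different time windows")
    return [EiTrajectoryPoint(w, e_results[w].point_estimate,
                              i_results[w].point_estimate, cell_type)
            for w in e_results]


def trajectory_to_frame(points: list[EiTrajectoryPoint]) -> pd.DataFrame:
    return pd.DataFrame([{"cell_type": p.cell_type, "time_window": p.time_window,
                          "delta_e": p.delta_e, "delta_i": p.delta_i}
                         for p in points])
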