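"""End-to-end study pipeline: synthesis, detection, contrasts, report.

Runs a lesion-vs-sham study design over time windows and cell types:
spontaneous EPSC/IPSC traces are synthesized per cell (with any imposed
group effects), events are detected with the hybrid detector, evoked
trains are generated and profiled, bootstrap contrasts and E-I
trajectories are computed per window, group comparisons are tabulated,
and everything is written to a report directory with a machine-readable
manifest.  Reruns with the same config and seed reproduce every output
byte for byte.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootstrap import (BootstrapConfig, bootstrap_contrast, ei_trajectory,
                        trajectory_to_frame)
from .core import ConfigError
from .evoked import EvokedRecording, stp_profile
from .lfp import (BANDS, SpectralConfig, band_power, burst_statistics,
                  detect_osc_bursts, multitaper_psd, normalize_psd, segment_lfp)
from .psc import detect_psc_events, event_frequency
from .stats import bh_adjust, compare_groups, compare_train_profiles
from .synth import (BurstSpec, LfpSynthConfig, PscSynthConfig, StpSynthConfig,
                    gen_evoked_train, gen_lfp, gen_psc_trace)

__all__ = ["StudyDesign", "demo_config", "run_pipeline"]

log = logging.getLogger("striephys")

KNOWN_STAGES = ("synth_study", "detect_psc", "evoked", "bootstrap",
                "compare", "lfp", "report")


@dataclass
class StudyDesign:
    """Factorial design of a lesion study."""

    groups: list[str] = field(default_factory=lambda: ["sham", "lesion"])
    time_windows: list[str] = field(default_factory=lambda: ["week2", "week3",
                                                             "week_gt3"])
    cell_types: list[str] = field(default_factory=lambda: ["PV_IN", "D1_SPN"])
    n_cells: int = 6
    records: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    def cells(self):
        """Yield (cell_id, cell_type, window, group) in deterministic order."""
        for ct in self.cell_types:
            for w in self.time_windows:
                for g in self.groups:
                    for i in range(self.n_cells):
                        cid = f"{ct}_{w}_{g}_{i:02d}"
                        self.records[cid] = (g, w, ct)
                        yield cid, ct, w, g


def demo_config() -> dict:
    """A complete study configuration with three imposed group effects.

    The effects mirror the study's qualitative findings: increased
    inhibitory amplitude onto PV interneurons in week 3, decreased
    excitatory amplitude onto D1 SPNs beyond week 3, and a switch from
    facilitating to depressing evoked excitation onto PV interneurons
    in the lesion group.
    """
    return {
        "seed": 0,
        "stages": ["synth_study", "detect_psc", "evoked", "bootstrap",
                   "compare", "lfp", "report"],
        "study": {
            "groups": ["sham", "lesion"],
            "time_windows": ["week2", "week3", "week_gt3"],
            "cell_types": ["PV_IN", "D1_SPN"],
            "n_cells": 6,
            "psc": {
                "duration_s": 30.0, "fs_hz": 10000.0, "event_rate_hz": 2.0,
                "noise_sd_pa": 4.0, "epsc_amp_mean_pa": 30.0,
                "ipsc_amp_mean_pa": 40.0, "epsc_tau_decay_ms": 5.0,
                "ipsc_tau_decay_ms": 8.0, "amp_cv": 0.3,
                "cell_scale_cv": 0.08,
            },
            "effects": [
                {"cell_type": "PV_IN", "window": "week3",
                 "measure": "sIPSC_amplitude", "factor": 1.4},
                {"cell_type": "D1_SPN", "window": "week_gt3",
                 "measure": "sEPSC_amplitude", "factor": 0.65},
            ],
            "evoked": {
                "default": {"release_prob": 0.35, "tau_rec_s": 0.3,
                            "facil_incr": 0.10, "tau_facil_s": 0.3},
                "overrides": [
                    {"cell_type": "PV_IN", "group": "sham",
                     "params": {"release_prob": 0.15, "facil_incr": 0.25,
                                "tau_facil_s": 0.5, "tau_rec_s": 0.5}},
                    {"cell_type": "PV_IN", "group": "lesion",
                     "params": {"release_prob": 0.70, "facil_incr": 0.0,
                                "tau_rec_s": 0.8}},
                ],
            },
        },
        "bootstrap": {"n_iter": 1000, "subsample_frac": 0.75, "mode": "ratio"},
        "compare": {"test": "welch_t", "bh_adjust": False},
        "lfp": {
            "duration_s": 120.0, "n_per_group": 3,
            "beta_rate_per_min": {"sham": 12.0, "lesion": 5.0},
            "burst_amplitude_db": 9.0,
        },
        "report": {"plots": True},
    }


# ---------------------------------------------------------------------------

def _validate_config(cfg: dict):
    stages = cfg.get("stages", list(KNOWN_STAGES))
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ConfigError("stages", f"unknown stage(s): {unknown}")
    if "study" not in cfg and any(s in stages for s in
                                  ("synth_study", "detect_psc", "evoked")):
        raise ConfigError("study", "missing study section")
    return stages


def _effect_factor(effects, cell_type, window, group, measure) -> float:
    if group != "lesion":
        return 1.0
    f = 1.0
    for e in effects or []:
        if (e["cell_type"] == cell_type and e["window"] == window
                and e["measure"] == measure):
            f *= float(e["factor"])
    return f


def _evoked_params(evoked_cfg, cell_type, group) -> dict:
    params = dict(evoked_cfg.get("default", {}))
    for ov in evoked_cfg.get("overrides", []):
        if ov["cell_type"] == cell_type and ov["group"] == group:
            params.update(ov["params"])
    return params


def _child_seed(ss_pool, key):
    # ss_pool is (root seed, issued-keys dict); deterministic seed per key
    root, issued = ss_pool
    if key not in issued:
        issued[key] = len(issued)
    k = issued[key]
    return int(np.random.SeedSequence([root, k]).generate_state(1)[0] % (2**31))


def _stage_psc(cfg, design: StudyDesign, seed: int) -> pd.DataFrame:
    p = cfg["study"]["psc"]
    effects = cfg["study"].get("effects", [])
    pool = (seed, {})
    rows = []
    for cid, ct, w, g in design.cells():
        for modality, polarity in (("sEPSC", "inward"), ("sIPSC", "outward")):
            measure = f"{modality}_amplitude"
            base = p["epsc_amp_mean_pa"] if modality == "sEPSC" \
                else p["ipsc_amp_mean_pa"]
            factor = _effect_factor(effects, ct, w, g, measure)
            cell_rng = np.random.default_rng(
                _child_seed(pool, f"scale/{cid}/{modality}"))
            scale = float(np.exp(p.get("cell_scale_cv", 0.08)
                                 * cell_rng.standard_normal()))
            tau_d = p["epsc_tau_decay_ms"] if modality == "sEPSC" \
                else p["ipsc_tau_decay_ms"]
            scfg = PscSynthConfig(
                duration_s=p["duration_s"], fs_hz=p["fs_hz"],
                event_rate_hz=p["event_rate_hz"],
                amp_mean_pa=base * factor * scale,
                amp_cv=p.get("amp_cv", 0.3), tau_decay_ms=tau_d,
                polarity=polarity, noise_sd_pa=p["noise_sd_pa"],
                seed=_child_seed(pool, f"trace/{cid}/{modality}"))
            trace, _ = gen_psc_trace(scfg)
            events = detect_psc_events(trace, modality=modality)
            amps = [e.amplitude_pa for e in events]
            rows.append({"cell_id": cid, "cell_type": ct, "window": w,
                         "group": g, "measure": measure,
                         "value": float(np.mean(amps)) if amps else np.nan})
            rows.append({"cell_id": cid, "cell_type": ct, "window": w,
                         "group": g, "measure": f"{modality}_frequency",
                         "value": event_frequency(events, trace.duration_s)})
    return pd.DataFrame(rows)


def _stage_evoked(cfg, design: StudyDesign, seed: int) -> pd.DataFrame:
    ev = cfg["study"].get("evoked", {})
    pool = (seed + 1, {})
    rows = []
    for cid, ct, w, g in design.cells():
        params = _evoked_params(ev, ct, g)
        scfg = StpSynthConfig(noise_sd_pa=1.5,
                              seed=_child_seed(pool, f"evoked/{cid}"), **params)
        trace, _ = gen_evoked_train(scfg)
        prof = stp_profile(EvokedRecording.from_trace(trace))
        for pulse, v in enumerate(prof.normalized_amplitudes, start=1):
            rows.append({"cell_id": cid, "cell_type": ct, "window": w,
                         "group": g, "pulse": pulse,
                         "normalized_amplitude": float(v),
                         "classification": prof.classification})
    return pd.DataFrame(rows)


def _stage_bootstrap(cfg, cells: pd.DataFrame, seed: int
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    bcfg = cfg.get("bootstrap", {})
    rows = []
    diff_results: dict[tuple[str, str, str], dict] = {}
    amp_measures = ["sEPSC_amplitude", "sIPSC_amplitude"]
    i = 0
    for ct in sorted(cells["cell_type"].unique()):
        for measure in amp_measures:
            for w in cells[cells["cell_type"] == ct]["window"].unique():
                sel = cells[(cells["cell_type"] == ct)
                            & (cells["measure"] == measure)
                            & (cells["window"] == w)]
                sham = sel[sel["group"] == "sham"]["value"].dropna().to_numpy()
                lesion = sel[sel["group"] == "lesion"]["value"].dropna().to_numpy()
                if sham.size == 0 or lesion.size == 0:
                    continue
                for mode in ("ratio", "difference"):
                    i += 1
                    res = bootstrap_contrast(sham, lesion, BootstrapConfig(
                        n_iter=int(bcfg.get("n_iter", 1000)),
                        subsample_frac=float(bcfg.get("subsample_frac", 0.75)),
                        mode=mode, seed=seed + i))
                    rows.append({"cell_type": ct, "window": w,
                                 "measure": measure, "mode": mode,
                                 "point_estimate": res.point_estimate,
                                 "sd": res.sd, "ci_low": res.ci_low,
                                 "ci_high": res.ci_high,
                                 "band_3sd_low": res.band_3sd_low,
                                 "band_3sd_high": res.band_3sd_high,
                                 "significant": res.significant})
                    if mode == "difference":
                        diff_results[(ct, measure, w)] = res
    # E-I trajectories from difference-mode contrasts
    traj_frames = []
    for ct in sorted(cells["cell_type"].unique()):
        windows = [w for w in cells["window"].unique()
                   if (ct, "sEPSC_amplitude", w) in diff_results
                   and (ct, "sIPSC_amplitude", w) in diff_results]
        if not windows:
            continue
        e_res = {w: diff_results[(ct, "sEPSC_amplitude", w)] for w in windows}
        i_res = {w: diff_results[(ct, "sIPSC_amplitude", w)] for w in windows}
        traj_frames.append(trajectory_to_frame(ei_trajectory(e_res, i_res, ct)))
    traj = pd.concat(traj_frames, ignore_index=True) if traj_frames \
        else pd.DataFrame(columns=["cell_type", "time_window",
                                   "delta_e", "delta_i"])
    return pd.DataFrame(rows), traj


def _stage_compare(cfg, cells: pd.DataFrame, evoked: pd.DataFrame
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    ccfg = cfg.get("compare", {})
    test = ccfg.get("test", "welch_t")
    rows = []
    for (ct, measure, w), sel in cells.groupby(["cell_type", "measure",
                                                "window"]):
        sham = sel[sel["group"] == "sham"]["value"].dropna()
        lesion = sel[sel["group"] == "lesion"]["value"].dropna()
        if len(sham) < 2 or len(lesion) < 2:
            continue
        res = compare_groups(sham, lesion, test=test, measure=str(measure),
                             window=str(w))
        d = res.to_dict()
        d["cell_type"] = ct
        rows.append(d)
    comp = pd.DataFrame(rows)
    if ccfg.get("bh_adjust", False) and not comp.empty:
        comp["p_adjusted_bh"] = bh_adjust(comp["p_value"].to_numpy())
    anova_rows = []
    if not evoked.empty:
        for ct, sel in evoked.groupby("cell_type"):
            prof = sel.pivot_table(index=["cell_id", "group"], columns="pulse",
                                   values="normalized_amplitude")
            sham = prof.xs("sham", level="group").to_numpy()
            lesion = prof.xs("lesion", level="group").to_numpy()
            if sham.shape[0] < 2 or lesion.shape[0] < 2:
                continue
            res = compare_train_profiles(sham, lesion,
                                         measure="evoked_normalized_amplitude")
            d = res.to_dict()
            d["cell_type"] = ct
            anova_rows.append(d)
    return comp, pd.DataFrame(anova_rows)


def _stage_lfp(cfg, seed: int) -> pd.DataFrame:
    lcfg = cfg.get("lfp", {})
    beta = BANDS["beta"]
    scfg = SpectralConfig()
    rows = []
    i = 0
    for group, rate in lcfg.get("beta_rate_per_min",
                                {"sham": 12.0, "lesion": 5.0}).items():
        for rep in range(int(lcfg.get("n_per_group", 3))):
            i += 1
            gen_cfg = LfpSynthConfig(
                duration_s=float(lcfg.get("duration_s", 120.0)),
                burst_specs=[BurstSpec(beta.lo_hz, beta.hi_hz, rate,
                                       amplitude_db=float(
                                           lcfg.get("burst_amplitude_db", 9.0)),
                                       name="beta")],
                seed=seed + 1000 + i)
            trace, _ = gen_lfp(gen_cfg)
            segs = segment_lfp(trace)
            freqs, psd = multitaper_psd(segs, trace.fs_hz, scfg)
            npsd = normalize_psd(freqs, psd, scfg)
            events = detect_osc_bursts(trace, beta)
            stats_d = burst_statistics(events, trace.duration_s)
            row = {"group": group, "rep": rep,
                   "beta_power": band_power(freqs, npsd, beta),
                   "low_gamma_power": band_power(freqs, npsd,
                                                 BANDS["low_gamma"]),
                   "high_gamma_power": band_power(freqs, npsd,
                                                  BANDS["high_gamma"]),
                   "beta_burst_rate_per_min": stats_d["rate_per_min"],
                   "beta_burst_mean_duration_s": stats_d["mean_duration_s"]}
            rows.append(row)
    return pd.DataFrame(rows)


def _stage_report(out: Path, cells, evoked, lfp_df):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plots = out / "plots"
    plots.mkdir(exist_ok=True)
    if cells is not None and not cells.empty:
        amp = cells[cells["measure"].str.endswith("amplitude")]
        for measure, sel in amp.groupby("measure"):
            fig, axes = plt.subplots(1, len(sel["cell_type"].unique()),
                                     figsize=(8, 3), squeeze=False)
            for ax, (ct, s2) in zip(axes[0], sel.groupby("cell_type")):
                data, labels = [], []
                for (w, g), s3 in s2.groupby(["window", "group"]):
                    data.append(s3["value"].dropna().to_numpy())
                    labels.append(f"{w}\n{g}")
                ax.boxplot(data, tick_labels=labels)
                ax.set_title(f"{ct} {measure}")
                ax.tick_params(labelsize=6)
            fig.tight_layout()
            fig.savefig(plots / f"{measure}.png", dpi=100)
            plt.close(fig)
    if evoked is not None and not evoked.empty:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for (ct, g), sel in evoked.groupby(["cell_type", "group"]):
            m = sel.groupby("pulse")["normalized_amplitude"].agg(["mean", "sem"])
            ax.errorbar(m.index, m["mean"], yerr=m["sem"], label=f"{ct} {g}")
        ax.axhline(1.0, color="k", lw=0.5)
        ax.set_xlabel("pulse"), ax.set_ylabel("normalized amplitude")
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(plots / "evoked_trains.png", dpi=100)
        plt.close(fig)
    if lfp_df is not None and not lfp_df.empty:
        fig, ax = plt.subplots(figsize=(4, 3))
        for band in ("beta_power", "low_gamma_power", "high_gamma_power"):
            m = lfp_df.groupby("group")[band].mean()
            ax.plot(m.index, m.values, "o-", label=band)
        ax.set_ylabel("normalized power"), ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(plots / "lfp_band_power.png", dpi=100)
        plt.close(fig)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: int | None = None) -> Path:
    """Execute the configured stages and write a report directory.

    ``config`` is a dict or a path to a YAML file (see
    :func:`demo_config`).  ``seed`` overrides the config's seed.  The
    directory receives results CSVs, plots, a log, and ``manifest.json``
    with the config hash, seed, versions and per-output checksums.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    stages = _validate_config(config)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    outputs: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False, float_format="%.8g")
        outputs[name] = _sha256(path)

    try:
        design = StudyDesign(**{k: config["study"][k] for k in
                                ("groups", "time_windows", "cell_types",
                                 "n_cells") if k in config.get("study", {})}) \
            if "study" in config else StudyDesign()
        cells = evoked = lfp_df = None
        t_all = time.perf_counter()
        if "synth_study" in stages or "detect_psc" in stages:
            t0 = time.perf_counter()
            cells = _stage_psc(config, design, seed)
            save(cells, "cells.csv")
            log.info("stage detect_psc done in %.1f s", time.perf_counter() - t0)
        if "evoked" in stages:
            t0 = time.perf_counter()
            evoked = _stage_evoked(config, design, seed)
            save(evoked, "evoked_profiles.csv")
            log.info("stage evoked done in %.1f s", time.perf_counter() - t0)
        if "bootstrap" in stages and cells is not None:
            t0 = time.perf_counter()
            boot, traj = _stage_bootstrap(config, cells, seed)
            save(boot, "bootstrap_results.csv")
            save(traj, "ei_trajectory.csv")
            log.info("stage bootstrap done in %.1f s", time.perf_counter() - t0)
        if "compare" in stages and cells is not None:
            t0 = time.perf_counter()
            comp, anova = _stage_compare(config, cells,
                                         evoked if evoked is not None
                                         else pd.DataFrame())
            save(comp, "comparisons.csv")
            save(anova, "evoked_anova.csv")
            log.info("stage compare done in %.1f s", time.perf_counter() - t0)
        if "lfp" in stages:
            t0 = time.perf_counter()
            lfp_df = _stage_lfp(config, seed)
            save(lfp_df, "lfp_summary.csv")
            log.info("stage lfp done in %.1f s", time.perf_counter() - t0)
        if "report" in stages and config.get("report", {}).get("plots", True):
            _stage_report(out, cells, evoked, lfp_df)
        manifest = {
            "config_sha256": hashlib.sha256(
                json.dumps(config, sort_keys=True).encode()).hexdigest(),
            "seed": seed,
            "versions": {"striephys": __version__,
                         "numpy": np.__version__, "pandas": pd.__version__},
            "outputs": outputs,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        log.info("pipeline finished in %.1f s", time.perf_counter() - t_all)
    finally:
        log.removeHandler(fh)
        fh.close()
    return out
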