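"""End-to-end orchestration: simulate/load -> preprocess -> integrate -> test -> report.

A run is a directory of TSV/JSON artifacts produced by four stages, each
re-runnable in isolation:

* ``stage_data``    — subject condition-average ERPs (``erps.tsv``) and
  behavioral logs, either simulated or preprocessed from BrainVision files.
* ``stage_integrate`` — difference waves, ROI running t-tests, detected
  windows and the subject x ROI x window amplitude table.
* ``stage_anova``   — mixed ANOVA per analysis window, plus the
  age x intensity simple effects where that interaction is significant.
* ``stage_behavior`` — HT/FA/RT tables, their ANOVAs and a summary table.

``run`` executes all stages and writes a provenance log with parameter
values and SHA-256 hashes of every artifact; a fixed seed makes the whole
run byte-reproducible.  The default parameter profile is the analysis
standard: 0.01-60 Hz then 0.1-30 Hz filters, -100..400 ms epochs, -100..0 ms
baseline, +-100 uV rejection, 30-epoch inclusion, alpha 0.05, 12-sample run
criterion, the four windows and five ROIs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as behavior_mod
from . import synth
from .anova_stats import mixed_anova, simple_effects
from .integration import (DEFAULT_ROIS, DEFAULT_WINDOWS, DifferenceWave,
                          detect_windows, difference_waves, pointwise_ttest,
                          roi_average, window_amplitude_table)
from .io_formats import (ResultsTable, read_brainvision, read_trial_log,
                         write_results, write_trial_log)
from .preprocess import (SubjectERP, bandpass, baseline_correct, extract_epochs,
                         grand_average, reject_artifacts, rereference,
                         subject_average)

log = logging.getLogger("averp")

STANDARD_PARAMS = {
    "bandpass_continuous_hz": [0.01, 60.0],
    "bandpass_average_hz": [0.1, 30.0],
    "epoch_window_ms": [-100.0, 400.0],
    "baseline_window_ms": [-100.0, 0.0],
    "reject_threshold_uv": 100.0,
    "min_epochs": 30,
    "alpha": 0.05,
    "min_run": 12,
    "windows_ms": [list(w) for w in DEFAULT_WINDOWS],
    "rois": {k: list(v) for k, v in DEFAULT_ROIS.items()},
}


@dataclass
class RunConfig:
    mode: str = "simulate"                    # "simulate" | "real"
    sim_mode: str = "erp"                     # "erp" (fast averages) | "continuous"
    seed: int = 0
    sim: dict = field(default_factory=dict)   # SimConfig field overrides
    params: dict = field(default_factory=lambda: dict(STANDARD_PARAMS))
    real_inputs: list[dict] = field(default_factory=list)
    # each: {subject, group, vhdr, log}
    marker_map: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        merged = dict(STANDARD_PARAMS)
        merged.update(self.params)
        self.params = merged
        if self.mode not in ("simulate", "real"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def sim_config(self) -> synth.SimConfig:
        kw = dict(self.sim)
        effects = [synth.IntegrationEffectSpec(**e) if isinstance(e, dict) else e
                   for e in kw.pop("integration_effects", [])]
        for e in effects:
            if isinstance(e.window_ms, list):
                e.window_ms = tuple(e.window_ms)
        design = kw.pop("design", None)
        if isinstance(design, dict):
            design = synth.DesignSpec(**design)
        noise = kw.pop("noise", None)
        if isinstance(noise, dict):
            noise = synth.NoiseSpec(**noise)
        cfg = synth.SimConfig(seed=kw.pop("seed", self.seed),
                              integration_effects=effects,
                              **({"design": design} if design else {}),
                              **({"noise": noise} if noise else {}),
                              **kw)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def standard_profile(seed: int = 0, **overrides) -> RunConfig:
    """The frozen default profile: simulate-mode run at the study scale."""
    return RunConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# ERP (de)serialization

ERP_SCHEMA = {"subject": "string", "group": "string", "modality": "string",
              "intensity": "string", "n_epochs": "integer", "included": "integer",
              "channel": "string", "t_ms": "real", "uv": "real"}


def write_erps(erps: list[SubjectERP], path: Path) -> None:
    frames = []
    for e in erps:
        n_ch, n_t = e.mean_wave.shape
        frames.append(pd.DataFrame({
            "subject": np.repeat(e.subject_id, n_ch * n_t),
            "group": e.group, "modality": e.modality, "intensity": e.intensity,
            "n_epochs": e.n_epochs, "included": int(e.included),
            "channel": np.repeat(e.channel_labels, n_t),
            "t_ms": np.tile(e.times_ms, n_ch),
            "uv": e.mean_wave.ravel(),
        }))
    df = pd.concat(frames, ignore_index=True)
    df["n_epochs"] = df["n_epochs"].astype(int)
    df["included"] = df["included"].astype(int)
    write_results(ResultsTable(df, dict(ERP_SCHEMA)), path)


def read_erps(path: Path) -> list[SubjectERP]:
    df = pd.read_csv(path, sep="\t")
    out = []
    keys = ["subject", "group", "modality", "intensity"]
    for (sid, group, modality, intensity), sub in df.groupby(keys, sort=False):
        channels = list(pd.unique(sub["channel"]))
        times = np.sort(pd.unique(sub["t_ms"]))
        wave = (sub.pivot_table(index="channel", columns="t_ms", values="uv")
                .loc[channels, times].to_numpy())
        out.append(SubjectERP(
            subject_id=str(sid), group=group, modality=modality, intensity=intensity,
            mean_wave=wave, times_ms=times, channel_labels=channels,
            n_epochs=int(sub["n_epochs"].iloc[0]), included=bool(sub["included"].iloc[0]),
            history=[{"step": "read_erps"}]))
    return out


# ---------------------------------------------------------------------------
# stages

def _preprocess_recording(recording, params, min_epochs) -> list[SubjectERP]:
    lo, hi = params["bandpass_continuous_hz"]
    alo, ahi = params["bandpass_average_hz"]
    rec = rereference(recording)
    rec = bandpass(rec, lo, hi)
    t0, t1 = params["epoch_window_ms"]
    epoch_sets = extract_epochs(rec, tmin_ms=t0, tmax_ms=t1)
    erps = []
    for es in epoch_sets.values():
        es = baseline_correct(es, tuple(params["baseline_window_ms"]))
        es, _ = reject_artifacts(es, params["reject_threshold_uv"])
        erp = subject_average(es, min_epochs=min_epochs)
        erp = bandpass(erp, alo, ahi)
        erps.append(baseline_correct_erp(erp, tuple(params["baseline_window_ms"])))
    return erps


def stage_data(config: RunConfig, run_dir: Path) -> None:
    """Produce ``erps.tsv`` and per-subject behavioral logs."""
    run_dir.mkdir(parents=True, exist_ok=True)
    params = config.params
    erps: list[SubjectERP] = []
    if config.mode == "simulate":
        sim = config.sim_config()
        if config.sim_mode == "erp":
            bundle = synth.simulate_cohort(sim, out_dir=run_dir / "logs", mode="erp")
            alo, ahi = params["bandpass_average_hz"]
            for sid, group in bundle.subjects:
                for (modality, intensity), wave in bundle.erps[sid].items():
                    erp = SubjectERP(subject_id=sid, group=group, modality=modality,
                                     intensity=intensity, mean_wave=wave,
                                     times_ms=bundle.times_ms,
                                     channel_labels=list(sim.channel_labels),
                                     n_epochs=sim.design.standards_per_modality,
                                     included=True,
                                     history=[{"step": "simulate_erp"},
                                              {"step": "baseline_correct"}])
                    erp = baseline_correct_erp(erp, tuple(params["baseline_window_ms"]))
                    erp = bandpass(erp, alo, ahi)
                    # the near-DC high-pass rings on a 0.5 s segment; re-anchor
                    erps.append(baseline_correct_erp(erp, tuple(params["baseline_window_ms"])))
        elif config.sim_mode == "continuous":
            (run_dir / "logs").mkdir(exist_ok=True)
            for sid, group in sim.subjects():
                rec, events = synth.simulate_subject(sim, sid, group)
                write_trial_log(events, run_dir / "logs" / f"{sid}_log.tsv")
                erps.extend(_preprocess_recording(rec, params, params["min_epochs"]))
        else:
            raise ValueError(f"unknown sim_mode {config.sim_mode!r}")
    else:
        (run_dir / "logs").mkdir(exist_ok=True)
        marker_map = {k: tuple(v) for k, v in config.marker_map.items()}
        for item in config.real_inputs:
            rec = read_brainvision(item["vhdr"], marker_map,
                                   subject_id=item["subject"], group=item["group"])
            if "log" in item:
                events = read_trial_log(item["log"])
                write_trial_log(events, run_dir / "logs" / f"{item['subject']}_log.tsv")
            erps.extend(_preprocess_recording(rec, params, params["min_epochs"]))
    write_erps(erps, run_dir / "erps.tsv")
    log.info("stage_data: wrote %d subject ERPs", len(erps))


def baseline_correct_erp(erp: SubjectERP, window_ms: tuple[float, float]) -> SubjectERP:
    """Baseline-correct an already-averaged wave (used by the fast sim path)."""
    mask = (erp.times_ms >= window_ms[0]) & (erp.times_ms <= window_ms[1])
    out = dataclasses.replace(erp)
    out.mean_wave = erp.mean_wave - erp.mean_wave[:, mask].mean(axis=1, keepdims=True)
    return out


WINDOW_SCHEMA = {"group": "string", "intensity": "string", "roi": "string",
                 "start_ms": "real", "end_ms": "real", "n_samples": "integer",
                 "mean_t": "real", "direction": "string"}


def stage_integrate(config: RunConfig, run_dir: Path) -> None:
    """Difference waves, ROI running t-tests, windows, amplitude table."""
    erps = read_erps(run_dir / "erps.tsv")
    params = config.params
    rois = {k: list(v) for k, v in params["rois"].items()}
    windows = [tuple(w) for w in params["windows_ms"]]

    by_subject: dict[str, dict] = {}
    for e in erps:
        if e.included:
            by_subject.setdefault(e.subject_id, {})[(e.modality, e.intensity)] = e
    diffs: list[DifferenceWave] = []
    for sid, conds in by_subject.items():
        intensities = {k[1] for k in conds}
        complete = [i for i in intensities
                    if all((m, i) in conds for m in ("V", "A", "AV"))]
        for i in sorted(complete):
            diffs.append(difference_waves({k: v for k, v in conds.items() if k[1] == i})[i])

    # grand-average ROI difference waves per group x intensity (for the report)
    ga_rows = []
    win_rows = []
    for group in sorted({d.group for d in diffs}):
        for intensity in sorted({d.intensity for d in diffs}):
            cell = [roi_average(d, rois) for d in diffs
                    if d.group == group and d.intensity == intensity]
            if not cell:
                continue
            ga = np.mean([d.wave for d in cell], axis=0)
            for ri, roi in enumerate(rois):
                ga_rows.append(pd.DataFrame({
                    "group": group, "intensity": intensity, "roi": roi,
                    "t_ms": cell[0].times_ms, "uv": ga[ri]}))
            if len(cell) >= 2:
                for roi in rois:
                    series = pointwise_ttest(cell, roi)
                    for w in detect_windows(series, params["alpha"], params["min_run"]):
                        win_rows.append({"group": group, "intensity": intensity,
                                         "roi": roi, "start_ms": w.start_ms,
                                         "end_ms": w.end_ms, "n_samples": w.n_samples,
                                         "mean_t": w.mean_t, "direction": w.direction})
    ga = pd.concat(ga_rows, ignore_index=True) if ga_rows else \
        pd.DataFrame(columns=["group", "intensity", "roi", "t_ms", "uv"])
    write_results(ResultsTable(ga, {"group": "string", "intensity": "string",
                                    "roi": "string", "t_ms": "real", "uv": "real"}),
                  run_dir / "diffwaves.tsv")
    win = pd.DataFrame(win_rows, columns=list(WINDOW_SCHEMA))
    win["n_samples"] = win["n_samples"].astype(int) if len(win) else win["n_samples"]
    write_results(ResultsTable(win, dict(WINDOW_SCHEMA)), run_dir / "windows.tsv")

    amp = window_amplitude_table(diffs, rois, windows)
    write_results(ResultsTable(amp, {"subject": "string", "group": "string",
                                     "intensity": "string", "roi": "string",
                                     "window": "string", "amplitude_uv": "real"}),
                  run_dir / "amplitudes.tsv")
    log.info("stage_integrate: %d difference waves, %d windows", len(diffs), len(win))


ANOVA_SCHEMA = {"window": "string", "effect": "string", "df_num": "integer",
                "df_den": "integer", "F": "real", "p": "real", "eps_gg": "real",
                "p_gg": "real", "pes": "real"}


def stage_anova(config: RunConfig, run_dir: Path) -> None:
    """2 (age) x 2 (intensity) x 5 (ROI) mixed ANOVA per analysis window."""
    amp = pd.read_csv(run_dir / "amplitudes.tsv", sep="\t")
    frames = []
    simple_frames = []
    for window, sub in amp.groupby("window", sort=False):
        res = mixed_anova(sub, "amplitude_uv", "subject",
                          between=["group"], within=["intensity", "roi"])
        res.insert(0, "window", window)
        frames.append(res)
        inter = res.loc[res["effect"] == "group x intensity"]
        if len(inter) and inter["p_gg"].iloc[0] < config.params["alpha"]:
            se = simple_effects(sub, "amplitude_uv", "subject", target="group",
                                conditioning=["intensity"], between=["group"],
                                within=["roi"])
            se.insert(0, "window", window)
            simple_frames.append(se)
    out = pd.concat(frames, ignore_index=True)
    out["df_num"] = out["df_num"].astype(int)
    out["df_den"] = out["df_den"].astype(int)
    write_results(ResultsTable(out, dict(ANOVA_SCHEMA)), run_dir / "anova_erp.tsv")
    if simple_frames:
        se = pd.concat(simple_frames, ignore_index=True)
        se.to_csv(run_dir / "simple_effects_erp.tsv", sep="\t", index=False)
    log.info("stage_anova: %d windows analyzed", len(frames))


def stage_behavior(config: RunConfig, run_dir: Path) -> None:
    """Behavioral tables and their 2 x 2 x 3 mixed ANOVAs."""
    logs_dir = run_dir / "logs"
    logs, groups = {}, {}
    manifest_path = logs_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        meta = {s["id"]: s["group"] for s in manifest["subjects"]}
    else:
        meta = None
    for p in sorted(logs_dir.glob("*_log.tsv")):
        sid = p.name[:-len("_log.tsv")]
        logs[sid] = read_trial_log(p)
        groups[sid] = meta[sid] if meta else _infer_group(run_dir, sid)
    tables = behavior_mod.behavior_tables(logs, groups)
    frames = []
    for measure in ("ht", "fa", "rt"):
        t = tables[measure].dropna(subset=["value"])
        res = mixed_anova(t, "value", "subject",
                          between=["group"], within=["intensity", "modality"])
        res.insert(0, "window", measure)
        frames.append(res)
    out = pd.concat(frames, ignore_index=True)
    out["df_num"] = out["df_num"].astype(int)
    out["df_den"] = out["df_den"].astype(int)
    write_results(ResultsTable(out, dict(ANOVA_SCHEMA)), run_dir / "anova_behavior.tsv")
    summary = behavior_mod.summary_table(tables["cells"])
    summary.to_csv(run_dir / "behavior_summary.tsv", sep="\t", index=False, float_format="%.6g")
    tables["cells"].to_csv(run_dir / "behavior_cells.tsv", sep="\t", index=False,
                           float_format="%.6g")
    log.info("stage_behavior: %d subjects", len(logs))


def _infer_group(run_dir: Path, sid: str) -> str:
    erps = pd.read_csv(run_dir / "erps.tsv", sep="\t", usecols=["subject", "group"]).drop_duplicates()
    match = erps.loc[erps["subject"] == sid, "group"]
    if len(match):
        return match.iloc[0]
    raise ValueError(f"cannot determine group of subject {sid}")


def report(run_dir: str | Path) -> Path:
    """Render a human-readable Markdown summary with per-ROI figures."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    needed = ["diffwaves.tsv", "windows.tsv", "anova_erp.tsv",
              "anova_behavior.tsv", "behavior_summary.tsv"]
    missing = [f for f in needed if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run: missing {missing}")

    ga = pd.read_csv(run_dir / "diffwaves.tsv", sep="\t")
    win = pd.read_csv(run_dir / "windows.tsv", sep="\t")
    anova_erp = pd.read_csv(run_dir / "anova_erp.tsv", sep="\t")
    anova_beh = pd.read_csv(run_dir / "anova_behavior.tsv", sep="\t")
    summary = pd.read_csv(run_dir / "behavior_summary.tsv", sep="\t")

    fig_dir = run_dir / "figures"
    fig_dir.mkdir(exist_ok=True)
    for roi, sub in ga.groupby("roi"):
        fig, ax = plt.subplots(figsize=(6, 3.5))
        for (group, intensity), cell in sub.groupby(["group", "intensity"]):
            ax.plot(cell["t_ms"], cell["uv"], label=f"{group}/{intensity}")
        for _, w in win.loc[win["roi"] == roi].iterrows():
            ax.axvspan(w["start_ms"], w["end_ms"], alpha=0.15, color="gray")
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("AV - (A+V) (uV)")
        ax.set_title(roi)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(fig_dir / f"diff_{roi}.png", dpi=100)
        plt.close(fig)

    lines = ["# Run report", ""]
    groups_present = sorted(ga["group"].unique())
    lines.append(f"Groups analyzed: {', '.join(groups_present) or 'none'}")
    for g in ("older", "younger"):
        if g not in groups_present:
            lines.append(f"**Warning:** no included subjects in group '{g}'; "
                         f"group contrasts skipped.")
    lines += ["", "## Behavioral summary (mean (SD) over subjects)", "",
              summary.to_string(index=False), "",
              "## Behavioral mixed ANOVAs (HT / FA / RT)", "",
              anova_beh.to_string(index=False), "",
              "## Detected integration windows", "",
              win.to_string(index=False) if len(win) else "(none)", "",
              "## ERP amplitude mixed ANOVAs per analysis window", ""]
    for window, sub in anova_erp.groupby("window", sort=False):
        lines += [f"### Window {window} ms", "", sub.to_string(index=False), ""]
    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out


# ---------------------------------------------------------------------------

STAGES = [("data", stage_data), ("integrate", stage_integrate),
          ("anova", stage_anova), ("behavior", stage_behavior)]


def _hash_tree(run_dir: Path) -> dict[str, str]:
    out = {}
    for p in sorted(run_dir.rglob("*")):
        if p.is_file() and p.name != "provenance.json":
            out[str(p.relative_to(run_dir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def run(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute every stage and write ``provenance.json``; on stage failure a
    ``FAILED`` marker naming the stage is left next to the partial outputs."""
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.to_yaml(run_dir / "config.yaml")
    prov = {"stages": []}
    for name, fn in STAGES:
        t0 = time.time()
        try:
            fn(config, run_dir)
        except Exception as exc:
            (run_dir / "FAILED").write_text(f"stage {name}: {exc}\n")
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        prov["stages"].append({"stage": name, "seconds": round(time.time() - t0, 3)})
    report(run_dir)
    prov["params"] = config.params
    prov["seed"] = config.seed
    prov["hashes"] = _hash_tree(run_dir)
    (run_dir / "provenance.json").write_text(json.dumps(prov, indent=1))
    return run_dir
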