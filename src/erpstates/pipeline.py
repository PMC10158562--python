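"""End-to-end orchestration of the picture-naming ERP analysis.

Stages, in fixed order: simulate (or load) epochs -> behavioural RT/accuracy
filtering -> single-subject preprocessing and averaging (stimulus- and
response-locked) -> topographic consistency tests -> point-wise waveform
ANOVA with extent criteria -> tANOVA -> overlap-removal concatenation ->
TAAHC segmentation with model selection -> individual back-fitting ->
fitting statistics. Every stage writes its outputs under the run directory
and registers them in a JSON manifest with content hashes, so a re-run with
the same configuration and seed reproduces the numbers bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alignment, mass_univariate, microstates, preprocess, synth, tanova as tanova_mod
from .containers import CombinedErp, Erp
from .montage import make_hemisphere_montage, write_montage
from .topo import p1_peak_latency, tct

log = logging.getLogger("erpstates")

__all__ = ["PipelineConfig", "run_pipeline", "report"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis, with study defaults.

    Defaults are the study's reference analysis values: 0.2-30 Hz band-pass, +/-100
    microvolt artifact criterion, minimum 55 trials per average, 500-2000 ms
    RT bounds, alpha 0.01 with 10-frame/5-electrode extent for waveform
    ANOVA, 12-frame consecutive criterion for tANOVA, 12-frame minimum
    duration and 0.95 merge correlation for segmentation, 95% GEV model
    selection.
    """

    # data source: synthetic design overrides (see synth.SyntheticDesign)
    design: dict = field(default_factory=dict)
    # preprocessing
    hp_hz: float = 0.2
    lp_hz: float = 30.0
    artifact_threshold_uv: float = 100.0
    min_trials: int = 55
    baseline: bool = True
    bad_electrodes: dict = field(default_factory=dict)  # subject -> [labels]
    # behaviour
    rt_lo_ms: float = 500.0
    rt_hi_ms: float = 2000.0
    # waveform ANOVA
    alpha_waveform: float = 0.01
    min_consec_tf_waveform: int = 10
    min_adjacent_electrodes: int = 5
    # tANOVA / TCT
    alpha_tanova: float = 0.01
    min_consec_tf_tanova: int = 12
    n_perm_tanova: int = 5000
    n_perm_tct: int = 1000
    # segmentation & fitting
    k_range: list[int] = field(default_factory=lambda: list(range(2, 16)))
    gev_threshold: float = 0.95
    min_duration_tf: int = 12
    merge_correlation: float = 0.95
    min_presence_tf: int = 12
    p1_window_ms: list[float] = field(default_factory=lambda: [80.0, 160.0])
    fit_window1_tf: list[int] = field(default_factory=lambda: [35, 103])
    fit_window2_start_tf: int = 100
    # bookkeeping
    seed: int = 0
    out_dir: str = "runs/latest"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def make_design(self) -> synth.SyntheticDesign:
        base = dataclasses.asdict(synth.SyntheticDesign())
        base.pop("template_maps")
        overrides = dict(self.design)
        if "state_sequence" in overrides:
            overrides["state_sequence"] = tuple(
                synth.StateSpec(**s) for s in overrides["state_sequence"]
            )
        base.update(overrides)
        base["seed"] = self.seed
        for key in (
            "group_names", "condition_names", "group_latency_shift_ms",
            "group_amplitude_scale", "rt_mean_ms", "accuracy_logit_group",
            "accuracy_logit_condition", "condition_effect_window_ms",
        ):
            if isinstance(base.get(key), list):
                base[key] = tuple(base[key])
        base["state_sequence"] = tuple(
            synth.StateSpec(**s) if isinstance(s, dict) else s
            for s in base["state_sequence"]
        )
        return synth.SyntheticDesign(**base)


def _sha(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


class _Run:
    def __init__(self, out_dir: Path):
        self.dir = out_dir
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest = {"stages": {}, "files": {}}

    def record(self, stage: str, **info):
        self.manifest["stages"][stage] = info

    def save_array(self, name: str, arr: np.ndarray):
        path = self.dir / f"{name}.npy"
        path.parent.mkdir(parents=True, exist_ok=True)
        np.save(path, arr)
        self.manifest["files"][f"{name}.npy"] = _sha(path)

    def save_table(self, name: str, df: pd.DataFrame):
        path = self.dir / f"{name}.csv"
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False)
        self.manifest["files"][f"{name}.csv"] = _sha(path)

    def save_json(self, name: str, obj):
        path = self.dir / f"{name}.json"
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(obj, indent=2, default=_jsonify))
        self.manifest["files"][f"{name}.json"] = _sha(path)

    def finish(self):
        (self.dir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, default=_jsonify)
        )


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o).__name__)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Execute every analysis stage; returns the run directory."""
    out = Path(out_dir or config.out_dir)
    run = _Run(out)
    config.to_yaml(out / "config.yaml")
    design = config.make_design()
    fs = design.sampling_rate
    montage = make_hemisphere_montage(design.n_electrodes)
    write_montage(montage, out / "montage.txt")

    # --- stage 1: simulate -------------------------------------------------
    log.info("stage simulate: %d groups x %d subjects x %d electrodes",
             design.n_groups, design.n_subjects_per_group, design.n_electrodes)
    stim_epochs, behavior = synth.simulate_epochs(design, montage)
    resp_epochs, resp_dropped = synth.simulate_response_locked(
        design, montage, stim_epochs
    )
    run.save_table("behavior/trials", behavior)
    run.record("simulate", seed=design.seed,
               n_epoch_sets=len(stim_epochs),
               response_locked_dropped=resp_dropped)

    # --- stage 2: behaviour ------------------------------------------------
    kept, rep = alignment.rt_filter(behavior, config.rt_lo_ms, config.rt_hi_ms)
    rt_summary = (
        kept.groupby(["group", "condition"])["rt_ms"].agg(["mean", "std", "count"])
        .reset_index()
    )
    run.save_table("behavior/rt_summary", rt_summary)
    run.record("behavior", **dataclasses.asdict(rep))

    # --- stage 3: preprocessing & averaging --------------------------------
    erps: dict[str, list[Erp]] = {"stimulus": [], "response": []}
    exclusions = []
    resp_by_key = {(e.subject, e.condition): e for e in resp_epochs}
    for ep in stim_epochs:
        ep_r = resp_by_key[(ep.subject, ep.condition)]
        # RT-window filter on the trial table, common to both alignments
        ok_rt = (
            (ep.trial_meta["rt_ms"] >= config.rt_lo_ms)
            & (ep.trial_meta["rt_ms"] <= config.rt_hi_ms)
        ).to_numpy()
        ep_f = ep.with_data(ep.data[ok_rt], trial_mask=ok_rt)
        for lock, eset in (("stimulus", ep_f), ("response", ep_r)):
            bad = config.bad_electrodes.get(eset.subject, [])
            try:
                erp, rej = preprocess.preprocess_epochs(
                    eset,
                    montage=montage,
                    hp=config.hp_hz,
                    lp=config.lp_hz,
                    abs_threshold=config.artifact_threshold_uv,
                    bad=bad,
                    baseline=config.baseline,
                    min_trials=config.min_trials,
                )
            except preprocess.TooFewTrialsError as err:
                exclusions.append(
                    {"subject": eset.subject, "condition": eset.condition,
                     "lock": lock, "reason": str(err)}
                )
                continue
            erps[lock].append(erp)
    run.save_table("preprocess/exclusions", pd.DataFrame(exclusions))
    # keep only subjects with a complete condition set in both locks
    complete = _complete_subjects(erps, design)
    for lock in erps:
        erps[lock] = [e for e in erps[lock] if e.subject in complete]
    run.record("preprocess", n_excluded=len(exclusions),
               n_subjects_retained=len(complete))
    if not complete:
        raise RuntimeError("preprocessing excluded every subject")

    # --- stage 4: topographic consistency ----------------------------------
    rng = np.random.default_rng([config.seed, 11])
    tct_rows = []
    for lock in ("stimulus", "response"):
        for gname in design.group_names:
            maps = np.stack([
                e.data for e in erps[lock]
                if e.group == gname
            ])
            if maps.shape[0] < 5:
                continue
            res = tct(maps, n_perm=config.n_perm_tct, alpha=0.05,
                      seed=rng.integers(2**31))
            tct_rows.append({
                "lock": lock, "group": gname,
                "frac_significant": float(res.significant.mean()),
            })
    run.save_table("tct/summary", pd.DataFrame(tct_rows))
    run.record("tct", n_perm=config.n_perm_tct)

    # --- stage 5: waveform ANOVA -------------------------------------------
    for lock in ("stimulus", "response"):
        stat = mass_univariate.pointwise_anova(
            erps[lock], alpha=config.alpha_waveform
        )
        mass_univariate.extent_threshold(
            stat, montage,
            min_consec_tf=config.min_consec_tf_waveform,
            min_adjacent=config.min_adjacent_electrodes,
            alpha=config.alpha_waveform,
        )
        for eff in stat.mask:
            run.save_array(f"waveform/{lock}_{eff}_F", stat.F[eff])
            run.save_array(f"waveform/{lock}_{eff}_mask", stat.mask[eff])
    run.record("waveform_anova", alpha=config.alpha_waveform,
               criteria=[config.min_consec_tf_waveform,
                         config.min_adjacent_electrodes])

    # --- stage 6: tANOVA ---------------------------------------------------
    for lock in ("stimulus", "response"):
        res = tanova_mod.tanova(
            erps[lock],
            n_perm=config.n_perm_tanova,
            alpha=config.alpha_tanova,
            seed=int(rng.integers(2**31)),
            min_consec_tf=config.min_consec_tf_tanova,
        )
        for eff in res.p:
            run.save_array(f"tanova/{lock}_{eff}_p", res.p[eff])
            run.save_array(f"tanova/{lock}_{eff}_mask", res.mask[eff])
    run.record("tanova", n_perm=config.n_perm_tanova, alpha=config.alpha_tanova)

    # --- stage 7: P1 latency ----------------------------------------------
    p1_rows = [
        {"subject": e.subject, "group": e.group, "condition": e.condition,
         "p1_latency_ms": p1_peak_latency(e, tuple(config.p1_window_ms))}
        for e in erps["stimulus"]
    ]
    run.save_table("waveform/p1_latency", pd.DataFrame(p1_rows))

    # --- stage 8: overlap removal & grand averages -------------------------
    mean_rt = kept.groupby(["subject", "condition"])["rt_ms"].mean()
    group_rt = kept.groupby(["group", "condition"])["rt_ms"].mean()
    combined_gavg: list[CombinedErp] = []
    for gname in design.group_names:
        for cname in design.condition_names:
            stim_list = [e for e in erps["stimulus"]
                         if e.group == gname and e.condition == cname]
            resp_list = [e for e in erps["response"]
                         if e.group == gname and e.condition == cname]
            g_stim = _grand_average(stim_list)
            g_resp = _grand_average(resp_list)
            comb = alignment.remove_overlap_concatenate(
                g_stim, g_resp, float(group_rt.loc[(gname, cname)]),
                end_offset_tf=design.resp_end_offset_tf,
            )
            comb.group, comb.condition = gname, cname
            combined_gavg.append(comb)
            run.save_array(f"grand_averages/{gname}_{cname}", comb.data)
    combined_indiv: list[CombinedErp] = []
    stim_by_key = {(e.subject, e.condition): e for e in erps["stimulus"]}
    for e_resp in erps["response"]:
        key = (e_resp.subject, e_resp.condition)
        comb = alignment.remove_overlap_concatenate(
            stim_by_key[key], e_resp, float(mean_rt.loc[key]),
            end_offset_tf=design.resp_end_offset_tf,
        )
        combined_indiv.append(comb)
    run.record("alignment", n_combined_grand=len(combined_gavg),
               n_combined_individual=len(combined_indiv))

    # --- stage 9: segmentation ---------------------------------------------
    keys = [f"{c.group}_{c.condition}" for c in combined_gavg]
    ks = [k for k in config.k_range]
    segs = microstates.taahc_segment(
        [c.as_erp() for c in combined_gavg],
        k_range=ks,
        min_duration_tf=config.min_duration_tf,
        merge_correlation=config.merge_correlation,
        dataset_keys=keys,
    )
    best, curve = microstates.select_model(segs, config.gev_threshold)
    run.save_table("segmentation/gev_curve", curve)
    run.save_array("segmentation/templates", best.templates)
    for key, lab in best.labels.items():
        run.save_array(f"segmentation/labels_{key}", lab)
    run.record("segmentation", selected_k=best.k, total_gev=best.total_gev,
               n_templates=best.templates.shape[0])

    # --- stage 10: back-fitting --------------------------------------------
    fit_rows = []
    windows = _fitting_windows(config, best, combined_gavg)
    for comb in combined_indiv:
        for wname, (lo_frac, hi_frac, candidates) in windows.items():
            lo, hi = _window_tf(wname, comb, config)
            if hi - lo < 2 or not candidates:
                continue
            res = microstates.fit_templates(
                comb.as_erp(), best.templates, best.template_names,
                candidates=candidates, window_tf=(lo, hi),
                min_presence_tf=config.min_presence_tf,
                min_duration_tf=config.min_duration_tf,
            )
            t = res.table
            t.insert(3, "window", wname)
            fit_rows.append(t)
    fitting = pd.concat(fit_rows, ignore_index=True)
    run.save_table("fitting/results", fitting)

    # --- stage 11: fitting statistics --------------------------------------
    stats_rows = []
    for wname in windows:
        sub = fitting[fitting["window"] == wname]
        if sub.empty:
            continue
        try:
            res = microstates.compare_fitting(sub)
        except ValueError as err:
            run.record(f"fitting_stats_{wname}", error=str(err))
            continue
        t = res["anova"]
        t.insert(0, "window", wname)
        stats_rows.append(t)
    if stats_rows:
        run.save_table("fitting/statistics", pd.concat(stats_rows, ignore_index=True))
    run.record("fitting", n_rows=len(fitting), windows=list(windows))

    run.finish()
    return out


def _complete_subjects(erps, design) -> set[str]:
    need = 2 * len(design.condition_names)
    counts: dict[str, int] = {}
    for lock in erps:
        for e in erps[lock]:
            counts[e.subject] = counts.get(e.subject, 0) + 1
    return {s for s, n in counts.items() if n == need}


def _grand_average(erp_list: list[Erp]) -> Erp:
    if not erp_list:
        raise RuntimeError("no ERPs to grand-average in a design cell")
    first = erp_list[0]
    return Erp(
        data=np.mean([e.data for e in erp_list], axis=0),
        sampling_rate=first.sampling_rate,
        pre_lock_tf=first.pre_lock_tf,
        lock=first.lock,
        n_trials_averaged=len(erp_list),
        group=first.group,
        condition=first.condition,
    )


def _window_tf(wname: str, comb: CombinedErp, config: PipelineConfig):
    n = comb.n_times
    if wname == "P1":
        lo, hi = config.fit_window1_tf
    elif wname == "post_P1":
        lo, hi = config.fit_window2_start_tf, comb.boundary_tf
    else:  # response portion
        lo, hi = comb.boundary_tf, n
    return max(0, min(lo, n)), max(0, min(hi, n))


def _fitting_windows(config, seg, combined_gavg):
    """Candidate templates per fitting period, from grand-average labels."""
    windows = {"P1": None, "post_P1": None, "response": None}
    out = {}
    for wname in windows:
        cands: set[str] = set()
        for comb in combined_gavg:
            key = f"{comb.group}_{comb.condition}"
            lab = seg.labels[key]
            lo, hi = _window_tf(wname, comb, config)
            for v in np.unique(lab[lo:hi]):
                if v >= 0:
                    cands.add(seg.template_names[int(v)])
        out[wname] = (None, None, sorted(cands))
    return out


# ---------------------------------------------------------------------------
# reporting


def report(run_dir: str | Path) -> Path:
    """Render summary figures and tables for a completed run.

    Produces GFP curves of the grand averages, electrode x frame
    significance rasters, template-map topographies, segmentation timelines
    and the fitting summary. Returns the report directory.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    if not (run_dir / "manifest.json").exists():
        raise FileNotFoundError(f"{run_dir} is not a completed run (no manifest)")
    rep_dir = run_dir / "report"
    rep_dir.mkdir(exist_ok=True)

    gavg_files = sorted((run_dir / "grand_averages").glob("*.npy"))
    if gavg_files:
        fig, ax = plt.subplots(figsize=(8, 4))
        for f in gavg_files:
            data = np.load(f)
            g = np.sqrt(np.mean((data - data.mean(axis=0)) ** 2, axis=0))
            ax.plot(g, label=f.stem, lw=1)
        ax.set_xlabel("time-frame (from picture onset)")
        ax.set_ylabel("GFP (uV)")
        ax.legend(fontsize=6)
        fig.savefig(rep_dir / "gfp_curves.png", dpi=120)
        plt.close(fig)

    for mask_file in sorted((run_dir / "tanova").glob("*_mask.npy")) + sorted(
        (run_dir / "waveform").glob("*_mask.npy")
    ):
        m = np.load(mask_file)
        fig, ax = plt.subplots(figsize=(8, 2.5))
        if m.ndim == 1:
            m = m[None, :]
        ax.imshow(m, aspect="auto", cmap="Greys", interpolation="nearest")
        ax.set_title(mask_file.stem, fontsize=8)
        ax.set_xlabel("time-frame")
        fig.savefig(rep_dir / f"{mask_file.stem}.png", dpi=120)
        plt.close(fig)

    tmpl_file = run_dir / "segmentation" / "templates.npy"
    mont_file = run_dir / "montage.txt"
    if tmpl_file.exists() and mont_file.exists():
        from .montage import read_montage

        montage = read_montage(mont_file)
        templates = np.load(tmpl_file)
        k = templates.shape[0]
        fig, axes = plt.subplots(1, k, figsize=(2 * k, 2.2))
        axes = np.atleast_1d(axes)
        pos = montage.positions
        xy = pos[:, :2] / (1.0 + pos[:, 2])[:, None]
        for i, ax in enumerate(axes):
            sc = ax.scatter(xy[:, 0], xy[:, 1], c=templates[i], cmap="RdBu_r",
                            s=25, vmin=-abs(templates[i]).max(),
                            vmax=abs(templates[i]).max())
            ax.set_title(chr(ord("A") + i))
            ax.set_aspect("equal")
            ax.axis("off")
        fig.savefig(rep_dir / "template_maps.png", dpi=120)
        plt.close(fig)

        label_files = sorted((run_dir / "segmentation").glob("labels_*.npy"))
        if label_files:
            fig, ax = plt.subplots(figsize=(8, 0.4 * len(label_files) + 1))
            for row, f in enumerate(label_files):
                lab = np.load(f)
                ax.imshow(lab[None, :], aspect="auto", cmap="tab20",
                          extent=(0, lab.size, row, row + 1), vmin=-1,
                          vmax=max(19, k))
            ax.set_yticks(np.arange(len(label_files)) + 0.5)
            ax.set_yticklabels([f.stem.replace("labels_", "") for f in label_files],
                               fontsize=6)
            ax.set_xlabel("time-frame")
            fig.savefig(rep_dir / "segmentation_timeline.png", dpi=120)
            plt.close(fig)

    fit_file = run_dir / "fitting" / "results.csv"
    if fit_file.exists():
        fit = pd.read_csv(fit_file)
        summary = fit.groupby(["window", "template", "group"]).agg(
            presence=("presence", "mean"),
            gev=("gev", "mean"),
            duration_ms=("duration_ms", "mean"),
        ).reset_index()
        summary.to_csv(rep_dir / "fitting_summary.csv", index=False)
    return rep_dir
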