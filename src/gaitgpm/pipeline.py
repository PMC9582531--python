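"""End-to-end orchestration over a synthetic or on-disk study.

Per subject: gait detection from the foot accelerometers, EEG cleaning (two
states: common-average-referenced only, and fully artifact-attenuated),
time-frequency decomposition, cycle warping, ERSP/GPM construction, one
spectral-PCA model fitted on the all-condition average and re-applied to the
condition ERSPs, and footprint features for both cleaning states.  Group
level: stride-metric ANOVA, footprint distances, and the three cluster
permutation tests at the analysis channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gaitgpm import footprint as fp
from gaitgpm import gait, io, preprocess, spca, stats, synthetic, timefreq


@dataclass
class PipelineConfig:
    out_root: str = "results"
    seed: int = 0
    analysis_channel: str = "Cz"
    input_layout: str = "synthetic"      # "synthetic" | "bids-like"
    input_dir: str | None = None         # required for bids-like
    study: synthetic.SyntheticStudySpec = field(
        default_factory=synthetic.SyntheticStudySpec)
    gait_params: gait.GaitDetectionParams = field(
        default_factory=gait.GaitDetectionParams)
    preproc_params: preprocess.PreprocParams = field(
        default_factory=preprocess.PreprocParams)
    tf_params: timefreq.TFParams = field(default_factory=timefreq.TFParams)
    stats_params: stats.StatsParams = field(default_factory=stats.StatsParams)
    clean_eeg: bool = True               # run line-noise/ICA artifact attenuation
    baseline_min_s: float = 30.0

    REQUIRED_BLOCKS = ("out_root", "seed", "analysis_channel", "input_layout",
                       "study", "gait_params", "preproc_params", "tf_params",
                       "stats_params")

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        missing = [k for k in cls.REQUIRED_BLOCKS if k not in cfg]
        if missing:
            raise ValueError(f"config missing required block(s): {missing}")
        return cls(
            out_root=cfg["out_root"], seed=cfg["seed"],
            analysis_channel=cfg["analysis_channel"],
            input_layout=cfg["input_layout"], input_dir=cfg.get("input_dir"),
            study=synthetic.SyntheticStudySpec(**cfg["study"]),
            gait_params=gait.GaitDetectionParams(**cfg["gait_params"]),
            preproc_params=preprocess.PreprocParams(**cfg["preproc_params"]),
            tf_params=timefreq.TFParams(**cfg["tf_params"]),
            stats_params=stats.StatsParams(**cfg["stats_params"]),
            clean_eeg=cfg.get("clean_eeg", True),
            baseline_min_s=cfg.get("baseline_min_s", 30.0),
        )


def detect_condition_cycles(left: gait.AccelTrace, right: gait.AccelTrace,
                            params: gait.GaitDetectionParams,
                            step_threshold_g: float | None = None
                            ) -> list[gait.GaitCycle]:
    ev_l = gait.detect_foot_events(left, params, step_threshold_g)
    ev_r = gait.detect_foot_events(right, params, step_threshold_g)
    return gait.assemble_gait_cycles(ev_l, ev_r, params)


def preprocess_two_state(rec: preprocess.EEGRecording,
                         params: preprocess.PreprocParams, seed: int,
                         clean: bool = True
                         ) -> tuple[preprocess.EEGRecording,
                                    preprocess.EEGRecording, dict]:
    """(CAR-only state, fully cleaned state, provenance).

    The CAR-only state stops after resampling/filtering, bad-channel
    interpolation, and re-referencing -- the comparison state used for
    footprint distances.  The cleaned state adds line-noise removal and
    ICA eye rejection.
    """
    prov: dict = {"stages": []}
    rec1 = preprocess.resample_and_filter(rec, params)
    bads = preprocess.find_bad_channels(rec1, params)
    rec1 = preprocess.replace_bads(rec1, bads)
    prov["stages"].append({"stage": "find_bad_channels", "n_bads": len(bads),
                           "bads": sorted(bads)})
    rec_car = preprocess.rereference_car(preprocess.interpolate_bads(rec1))
    if not clean:
        prov["stages"].append({"stage": "artifact_attenuation", "skipped": True})
        return rec_car, rec_car, prov
    rec2 = preprocess.remove_line_noise(rec1, params)
    rec2 = preprocess.interpolate_bads(rec2)
    rec2 = preprocess.rereference_car(rec2)
    rec2, decomp = preprocess.ica_eye_removal(rec2, params, seed=seed)
    prov["stages"].append({
        "stage": "ica_eye_removal",
        "n_components": len(decomp.eye_scores),
        "n_removed": len(decomp.removed),
        "n_kept": len(decomp.eye_scores) - len(decomp.removed)})
    return rec_car, rec2, prov


@dataclass
class SubjectResult:
    subject: str
    stride: dict                       # condition -> StrideMetrics summary
    ersp_avg_raw: timefreq.GaitERSP
    ersp_avg_clean: timefreq.GaitERSP
    gpm_by_condition: dict             # condition -> GPM (sPCA-attenuated)
    footprint_raw: fp.FootprintVector
    footprint_clean: fp.FootprintVector
    provenance: dict


def _standing_baseline(rec: preprocess.EEGRecording, tf_params: timefreq.TFParams,
                       min_s: float) -> timefreq.BaselinePower:
    tfp = timefreq.morlet_power(rec, tf_params)
    t0 = rec.event_latency("standing_start")
    t1 = rec.event_latency("standing_end")
    return timefreq.standing_baseline_power(tfp, [(t0, t1)], min_duration_s=min_s)


def run_subject(cfg: PipelineConfig, subject_idx: int,
                recordings: dict | None = None) -> SubjectResult:
    """Process one subject from synthetic generation through footprints.

    ``recordings`` may pre-supply loaded data (used for bids-like input);
    otherwise data are generated from the study spec.
    """
    spec = cfg.study
    sub = f"sub-{subject_idx:02d}"
    prov: dict = {"subject": sub, "conditions": {}}

    if recordings is None:
        recordings = {}
        tl0 = synthetic.GaitTimeline([np.empty(0)], bouts=[])
        rest, _ = synthetic.generate_eeg(
            tl0, spec, "even_ST", seed=synthetic._mix([spec.seed, subject_idx], 99),
            standing_s=spec.standing_s)
        recordings["rest"] = rest
        for cond in synthetic.CONDITIONS:
            tl, left, right, rec, _truth = synthetic.generate_subject_condition(
                spec, subject_idx, cond, with_standing=False)
            recordings[cond] = {"eeg": rec, "left": left, "right": right}

    # standing baseline through the same cleaning chain
    rest_car, rest_clean, p0 = preprocess_two_state(
        recordings["rest"], cfg.preproc_params, seed=cfg.seed + subject_idx,
        clean=cfg.clean_eeg)
    prov["rest"] = p0
    base_raw = _standing_baseline(rest_car, cfg.tf_params, cfg.baseline_min_s)
    base_clean = _standing_baseline(rest_clean, cfg.tf_params, cfg.baseline_min_s)

    stride_summary: dict = {}
    segs_raw, segs_clean = {}, {}
    for cond in synthetic.CONDITIONS:
        entry = recordings[cond]
        cycles = detect_condition_cycles(entry["left"], entry["right"], cfg.gait_params)
        valid = [c for c in cycles if c.valid]
        sm = gait.stride_metrics(cycles) if valid else None
        stride_summary[cond] = {
            "n_cycles_detected": len(cycles),
            "n_cycles_valid": len(valid),
            "mean_stride_s": sm.mean_stride_s if sm else np.nan,
            "cv_pct": sm.cv_pct if sm else np.nan,
        }
        rec_car, rec_clean, pc = preprocess_two_state(
            entry["eeg"], cfg.preproc_params,
            seed=cfg.seed + 1000 * subject_idx + synthetic.CONDITIONS.index(cond),
            clean=cfg.clean_eeg)
        prov["conditions"][cond] = pc
        for state, rec_s in (("raw", rec_car), ("clean", rec_clean)):
            tfp = timefreq.morlet_power(rec_s, cfg.tf_params)
            segs, info = timefreq.extract_and_warp_cycles(tfp, rec_s, cycles,
                                                          cfg.tf_params)
            (segs_raw if state == "raw" else segs_clean)[cond] = segs
            prov["conditions"][cond][f"cycles_{state}"] = info

    ch_names = rest_car.layout.names

    def _avg_ersp(segs_by_cond: dict, baseline: timefreq.BaselinePower,
                  condition: str = "all") -> timefreq.GaitERSP:
        allsegs = np.concatenate([s for s in segs_by_cond.values() if len(s)], axis=0)
        return timefreq.average_to_ersp(allsegs, baseline, ch_names, condition)

    ersp_avg_raw = _avg_ersp(segs_raw, base_raw)
    ersp_avg_clean = _avg_ersp(segs_clean, base_clean)

    model = spca.fit_spca(ersp_avg_clean)
    ersp_avg_att = spca.apply_spca(model, ersp_avg_clean)
    gpm_by_cond = {}
    for cond in synthetic.CONDITIONS:
        ersp_c = timefreq.average_to_ersp(segs_clean[cond], base_clean, ch_names, cond)
        gpm_by_cond[cond] = timefreq.ersp_to_gpm(spca.apply_spca(model, ersp_c))
    prov["spca"] = {"explained_first": model.explained_fraction_first()}

    ds_mask = fp.double_support_bins(synthetic.DEFAULT_OFFSETS,
                                     cfg.tf_params.n_phase_bins)
    layout = rest_car.layout
    fpr = fp.compute_footprint(ersp_avg_raw, timefreq.ersp_to_gpm(ersp_avg_raw),
                               ds_mask, layout)
    fpc = fp.compute_footprint(ersp_avg_att, timefreq.ersp_to_gpm(ersp_avg_att),
                               ds_mask, layout)
    return SubjectResult(sub, stride_summary, ersp_avg_raw, ersp_avg_att,
                         gpm_by_cond, fpr, fpc, prov)


def group_analysis(results: list[SubjectResult], cfg: PipelineConfig) -> dict:
    """Behavioral ANOVA, footprint distances, and GPM cluster tests."""
    conds = list(synthetic.CONDITIONS)
    order = stats.CONDITION_ORDER

    stride_mat = np.array([[r.stride[c]["mean_stride_s"] for c in order]
                           for r in results])
    cv_mat = np.array([[r.stride[c]["cv_pct"] for c in order] for r in results])
    out: dict = {
        "stride_time_anova": stats.rm_anova_2x2(stride_mat),
        "stride_cv_anova": stats.rm_anova_2x2(cv_mat),
    }
    # effect sizes matching the ANOVA contrasts
    even = stride_mat[:, :2].mean(axis=1)
    uneven = stride_mat[:, 2:].mean(axis=1)
    out["stride_time_terrain_d"] = stats.cohens_d_paired(even, uneven).value

    scaled = fp.scale_footprints([v for r in results
                                  for v in (r.footprint_raw, r.footprint_clean)])
    dists = [fp.footprint_distance(scaled[2 * i], scaled[2 * i + 1])
             for i in range(len(results))]
    out["footprint_distances"] = dists
    if len(dists) >= 2 and any(d > 0 for d in dists):
        out["footprint_wilcoxon"] = stats.wilcoxon_signed_rank(
            np.asarray(dists), np.zeros(len(dists)))

    # cluster tests on the analysis channel within the stats band
    lo, hi = cfg.tf_params.stats_band_hz
    freqs = results[0].gpm_by_condition[conds[0]].freqs_hz
    fsel = (freqs >= lo) & (freqs <= hi)
    ch = results[0].gpm_by_condition[conds[0]].ch_names.index(cfg.analysis_channel)
    maps = {c: np.stack([r.gpm_by_condition[c].values_db[ch][fsel]
                         for r in results]) for c in conds}
    cmaps = stats.ConditionMaps(maps, freqs[fsel])
    out["clusters"] = {}
    for effect in stats.EFFECTS:
        pairs = stats.effect_maps(cmaps, effect)
        res = stats.cluster_permutation_test(pairs, cfg.stats_params)
        out["clusters"][effect] = {
            "min_p": res.min_p,
            "n_clusters": len(res.clusters),
            "significant": [
                {"mass": c.mass, "p": c.p_value, "d": c.cohens_d,
                 "freqs_hz": sorted(set(freqs[fsel][np.where(c.mask)[0]])),
                 "phase_bins": sorted(set(int(b) for b in np.where(c.mask)[1]))}
                for c in res.significant()],
        }
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; write the results bundle under ``cfg.out_root``."""
    out = Path(cfg.out_root)
    out.mkdir(parents=True, exist_ok=True)
    results = []
    for s in range(1, cfg.study.n_subjects + 1):
        recordings = None
        if cfg.input_layout == "bids-like":
            if not cfg.input_dir:
                raise ValueError("bids-like input requires input_dir")
            recordings = load_subject_recordings(Path(cfg.input_dir), s)
        results.append(run_subject(cfg, s, recordings))

    group = group_analysis(results, cfg)

    rows = []
    for r in results:
        for cond, sm in r.stride.items():
            terrain, task = cond.split("_")
            rows.append({"subject": r.subject, "terrain": terrain, "task": task,
                         **sm})
    pd.DataFrame(rows).to_csv(out / "stride_metrics.csv", index=False)

    fp_rows = []
    for r in results:
        for state, v in (("raw", r.footprint_raw), ("cleaned", r.footprint_clean)):
            fp_rows.append({"subject": r.subject, "state": state,
                            **dict(zip(fp.FEATURES, v.as_array()))})
    pd.DataFrame(fp_rows).to_csv(out / "footprint.csv", index=False)

    manifest = {
        "seed": cfg.seed,
        "analysis_channel": cfg.analysis_channel,
        "n_subjects": cfg.study.n_subjects,
        "group": group,
        "provenance": [r.provenance for r in results],
    }
    io.write_json(out / "results.json", manifest)
    return manifest


def load_subject_recordings(study_dir: Path, subject_idx: int) -> dict:
    """Load one subject's recordings from a generated study directory."""
    sub = f"sub-{subject_idx:02d}"
    sdir = study_dir / sub
    recordings: dict = {}
    from gaitgpm.montage import make_layout

    def _load(vhdr: Path) -> preprocess.EEGRecording:
        data, fs, names, events = io.read_brainvision(vhdr)
        return preprocess.EEGRecording(data, fs, make_layout(names), events)

    recordings["rest"] = _load(sdir / f"{sub}_task-rest_eeg.vhdr")
    for cond in synthetic.CONDITIONS:
        base = f"{sub}_task-{cond}"
        t, v, a = io.read_accel_table(sdir / f"{base}_accel-left.tsv")
        fs_a = 1.0 / float(np.median(np.diff(t)))
        left = gait.AccelTrace(v, a, fs_a, "left")
        t, v, a = io.read_accel_table(sdir / f"{base}_accel-right.tsv")
        right = gait.AccelTrace(v, a, fs_a, "right")
        recordings[cond] = {"eeg": _load(sdir / f"{base}_eeg.vhdr"),
                            "left": left, "right": right}
    return recordings
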