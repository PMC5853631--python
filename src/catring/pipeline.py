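"""End-to-end orchestration: simulate -> preprocess -> decode -> similarity
-> connectivity -> behavior, with CSV/JSON outputs and a report bundle.

Every stage reads its parameters from one :class:`PipelineConfig`, which is
serialized verbatim into the output directory; a fixed seed makes the whole
run byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import brain_behavior, connectivity, decoding, preprocess, similarity
from .geometry import Boundary, StimulusRing, geometry_json
from .synthetic import (
    Experiment,
    GCCoupling,
    ROISpec,
    SyntheticConfig,
    default_rois,
    generate_experiment,
    roi_run_series,
)

__all__ = [
    "PipelineConfig",
    "demo_config",
    "run_pipeline",
    "write_report",
    "validate_report",
    "config_to_dict",
    "config_from_dict",
]


@dataclass(frozen=True)
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    rfe: decoding.RFEConfig = field(default_factory=decoding.RFEConfig)
    timepoints: tuple[float, ...] = (6.0, 8.0, 10.0)
    separations: tuple[int, ...] = (1, 2, 3)
    scan_separation: int = 3
    decode_rfe: bool = True
    run_preprocess: bool = True
    preprocess_order: tuple[str, ...] = ("scale", "detrend")
    retrain: bool = False
    rt_window: int = 5
    seed: int = 0
    outdir: str = "catring_out"


def demo_config(seed: int = 0, outdir: str = "catring_out") -> PipelineConfig:
    """A small configuration that exercises every stage quickly: 3 subjects,
    5 runs, 1 task trial per position per run, 30-voxel ROIs."""
    rois = tuple(
        dataclasses.replace(r, n_voxels=30) for r in default_rois()
    )
    syn = SyntheticConfig(
        n_subjects=3, n_runs=5, task_trials_per_run=8, fixation_trials_per_run=8,
        rois=rois, seed=seed,
    )
    rfe = decoding.RFEConfig(min_features=12, patience=2)
    return PipelineConfig(
        synthetic=syn, rfe=rfe, timepoints=(6.0,), decode_rfe=True,
        rt_window=3, seed=seed, outdir=outdir,
    )


# ---------------------------------------------------------------- config io

def config_to_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return json.loads(json.dumps(d, default=list))


def config_from_dict(d: dict) -> PipelineConfig:
    syn = d.get("synthetic", {})
    syn = dict(syn)
    if "ring" in syn:
        syn["ring"] = StimulusRing(**syn["ring"])
    if "boundary" in syn:
        b = syn["boundary"]
        syn["boundary"] = Boundary(**b) if isinstance(b, dict) else Boundary(float(b))
    if "rois" in syn:
        syn["rois"] = tuple(
            ROISpec(**{**r, "category_amplitude": tuple(r["category_amplitude"])})
            for r in syn["rois"]
        )
    if "gc_coupling" in syn:
        gc = dict(syn["gc_coupling"])
        if "ar" in gc:
            gc["ar"] = tuple(gc["ar"])
        syn["gc_coupling"] = GCCoupling(**gc)
    out = dict(d)
    out["synthetic"] = SyntheticConfig(**syn)
    if "rfe" in d:
        out["rfe"] = decoding.RFEConfig(**d["rfe"])
    for key in ("timepoints", "separations", "preprocess_order"):
        if key in out:
            out[key] = tuple(out[key])
    return PipelineConfig(**out)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------- stages

def _preprocessed_datasets(cfg: PipelineConfig, exp: Experiment) -> None:
    """Replace each subject's datasets with versions rebuilt through the
    continuous-series path: raw run series -> global scaling -> run-wise
    detrending -> epoching (order configurable)."""
    syn = exp.config
    for sub in exp.subjects:
        for name, ds in list(sub.datasets.items()):
            values, run_labels = roi_run_series(
                syn, sub.subject, ds, sub.trials, exp.experiment_id
            )
            s = preprocess.RunSeries(values, run_labels)
            for step in cfg.preprocess_order:
                if step == "scale":
                    s = preprocess.global_scale(s)
                elif step == "detrend":
                    s = preprocess.detrend_runwise(s)
                else:
                    raise ValueError(f"unknown preprocessing step {step!r}")
            sub.datasets[name] = preprocess.epoch_trials(
                s, sub.trials, syn.tr, syn.trial_len, roi_name=name
            )


def _decode_stage(cfg: PipelineConfig, exp: Experiment):
    rows = []
    voxel_sets: dict[tuple[int, str, float], np.ndarray] = {}
    for sub in exp.subjects:
        for roi, ds in sub.datasets.items():
            for t in cfg.timepoints:
                res = decoding.decode_timepoint(
                    ds, t, cfg.rfe, rfe=cfg.decode_rfe
                )
                union = np.unique(np.concatenate(res.surviving_voxels))
                voxel_sets[(sub.subject, roi, t)] = union
                for split, acc in enumerate(res.split_accuracies):
                    rows.append(
                        dict(subject=sub.subject, roi=roi, timepoint=t,
                             split=split, accuracy=acc,
                             n_voxels=len(res.surviving_voxels[split]))
                    )
    return pd.DataFrame(rows), voxel_sets


def _similarity_stage(cfg: PipelineConfig, exp: Experiment, voxel_sets):
    syn = exp.config
    sim_rows, ci_rows, scan_rows = [], [], []
    tables: dict[tuple[int, str, float], similarity.SimilarityTable] = {}
    for sub in exp.subjects:
        for roi, ds in sub.datasets.items():
            for t in cfg.timepoints:
                vs = voxel_sets.get((sub.subject, roi, t))
                patterns = similarity.position_patterns(ds, t, voxel_set=vs)
                st = similarity.similarity_table(patterns, t=t, subject=sub.subject)
                tables[(sub.subject, roi, t)] = st
                df = st.to_frame()
                df.insert(0, "roi", roi)
                sim_rows.append(df)
                for steps in cfg.separations:
                    res = similarity.category_index(
                        st, syn.ring, exp.boundary, steps
                    )
                    ci_rows.append(
                        dict(subject=sub.subject, roi=roi, timepoint=t,
                             steps=steps, separation_dva=res.separation_dva,
                             boundary_axis=exp.boundary.axis_angle,
                             wcs=res.wcs, bcs=res.bcs, ci=res.ci)
                    )
                cis, best = similarity.boundary_scan(
                    st, syn.ring, cfg.scan_separation
                )
                for axis, ci in cis.items():
                    scan_rows.append(
                        dict(subject=sub.subject, roi=roi, timepoint=t,
                             steps=cfg.scan_separation, axis=axis, ci=ci,
                             is_best=axis == best.axis_angle)
                    )
    return (
        pd.concat(sim_rows, ignore_index=True),
        pd.DataFrame(ci_rows),
        pd.DataFrame(scan_rows),
        tables,
    )


def _connectivity_stage(cfg: PipelineConfig, exp: Experiment):
    frames = []
    for sub in exp.subjects:
        df = connectivity.condition_gc_table(sub.series)
        df.insert(0, "subject", sub.subject)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _behavior_stage(cfg: PipelineConfig, exp: Experiment, gc_df: pd.DataFrame):
    syn = exp.config
    top_down = f"{exp.subjects[0].series.name_x}->{exp.subjects[0].series.name_y}"
    std = (
        gc_df[gc_df.direction == top_down]
        .drop_duplicates(["subject", "run"])
        .pivot(index="subject", columns="run", values="standardized")
        .to_numpy()
    )
    rts = np.stack(
        [
            sub.trials[sub.trials.trial_type == "task"]
            .groupby("run")
            .rt.mean()
            .to_numpy()
            for sub in exp.subjects
        ]
    )
    res, table = brain_behavior.gc_rt_correlation(std, rts, window=cfg.rt_window)
    return res, table


# ---------------------------------------------------------------- report

REPORT_SCHEMA: dict = {
    "config_hash": str,
    "seed": int,
    "experiments": list,
    "files": list,
    "stage_seconds": dict,
    "gc_rt": dict,
}


def validate_report(report: dict) -> None:
    """Structural validation of the report against the shipped schema."""
    if not report:
        raise ValueError("empty report")
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} has wrong type")
    for f in report["files"]:
        if not isinstance(f, str):
            raise ValueError("file entries must be paths")


def write_report(report: dict, outdir: Path) -> None:
    if not report:
        raise ValueError("cannot write an empty report")
    validate_report(report)
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    lines = [
        "catring pipeline report",
        f"config hash: {report['config_hash']}  seed: {report['seed']}",
        "",
    ]
    for exp in report["experiments"]:
        lines.append(
            f"experiment {exp['experiment_id']} "
            f"(boundary {exp['boundary_axis']} deg):"
        )
        for roi, acc in exp["mean_accuracy"].items():
            lines.append(f"  decoding accuracy {roi}: {acc:.3f}")
        for roi, count in exp["boundary_optimal_count"].items():
            lines.append(
                f"  boundary scan {roi}: trained boundary optimal in "
                f"{count}/{exp['n_subjects']} subjects (binomial p = "
                f"{exp['boundary_binomial_p'][roi]:.3g})"
            )
    rho = report["gc_rt"]["rho"]
    p = report["gc_rt"]["p"]
    lines.append("")
    lines.append(f"GC-RT rank correlation: rho = {rho:.3f}, p = {p:.3g}")
    lines.append("")
    lines.append("files: " + ", ".join(report["files"]))
    (outdir / "report.txt").write_text("\n".join(lines))


# ---------------------------------------------------------------- pipeline

def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    syn = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(config_to_dict(dataclasses.replace(cfg, synthetic=syn)))
    )
    (outdir / "geometry.json").write_text(
        geometry_json(syn.ring, syn.boundary)
    )
    files = ["config.yaml", "geometry.json"]
    stage_seconds: dict[str, float] = {}
    experiments = []
    exp_ids = (1, 2) if cfg.retrain else (1,)
    exp_tables: dict[int, dict] = {}
    for exp_id in exp_ids:
        t0 = time.perf_counter()
        exp = generate_experiment(syn, experiment=exp_id)
        if cfg.run_preprocess:
            _preprocessed_datasets(cfg, exp)
        stage_seconds[f"simulate_exp{exp_id}"] = time.perf_counter() - t0

        trials = pd.concat(
            [s.trials.assign(subject=s.subject) for s in exp.subjects],
            ignore_index=True,
        )
        trials.to_csv(outdir / f"trials_exp{exp_id}.csv", index=False)
        files.append(f"trials_exp{exp_id}.csv")

        t0 = time.perf_counter()
        dec_df, voxel_sets = _decode_stage(cfg, exp)
        stage_seconds[f"decode_exp{exp_id}"] = time.perf_counter() - t0
        dec_df.to_csv(outdir / f"decoding_exp{exp_id}.csv", index=False)
        files.append(f"decoding_exp{exp_id}.csv")

        t0 = time.perf_counter()
        sim_df, ci_df, scan_df, tables = _similarity_stage(cfg, exp, voxel_sets)
        stage_seconds[f"similarity_exp{exp_id}"] = time.perf_counter() - t0
        for name, df in (
            (f"similarity_exp{exp_id}.csv", sim_df),
            (f"category_index_exp{exp_id}.csv", ci_df),
            (f"boundary_scan_exp{exp_id}.csv", scan_df),
        ):
            df.to_csv(outdir / name, index=False)
            files.append(name)

        t0 = time.perf_counter()
        gc_df = _connectivity_stage(cfg, exp)
        stage_seconds[f"gc_exp{exp_id}"] = time.perf_counter() - t0
        gc_df.to_csv(outdir / f"gc_exp{exp_id}.csv", index=False)
        files.append(f"gc_exp{exp_id}.csv")

        res, table = _behavior_stage(cfg, exp, gc_df)
        table.to_csv(outdir / f"gc_rt_groups_exp{exp_id}.csv", index=False)
        files.append(f"gc_rt_groups_exp{exp_id}.csv")

        scan_best = scan_df[scan_df.is_best]
        summary = {
            "experiment_id": exp_id,
            "boundary_axis": exp.boundary.axis_angle,
            "n_subjects": syn.n_subjects,
            "mean_accuracy": dec_df.groupby("roi").accuracy.mean().to_dict(),
            "boundary_optimal_count": {},
            "boundary_binomial_p": {},
            "gc_rt": {"rho": res.statistic, "p": res.p},
        }
        for roi in scan_best.roi.unique():
            sel = scan_best[
                (scan_best.roi == roi) & (scan_best.timepoint == cfg.timepoints[0])
            ]
            matches = (sel.axis == exp.boundary.axis_angle).to_numpy()
            test = similarity.boundary_scan_group(matches)
            summary["boundary_optimal_count"][roi] = int(test.statistic)
            summary["boundary_binomial_p"][roi] = test.p
        experiments.append(summary)
        exp_tables[exp_id] = dict(tables=tables)

    report = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "experiments": experiments,
        "files": files,
        "stage_seconds": stage_seconds,
        "gc_rt": experiments[0]["gc_rt"],
    }
    write_report(report, outdir)
    return report
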