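"""Run orchestration: simulate → segment → qc → quantify → mobility → frap →
report, with a manifest hashing every output for reproducibility checks."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import frap as frap_mod
from . import mobility as mob
from . import quant, segmentation
from ._validation import ValidationError
from .config import RunConfig, save_config
from .synthetic_data import (
    calibrate_papa_near,
    simulate_frap_movie,
    simulate_papa_experiment,
    write_frap_movie,
    write_papa_run,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "segment", "qc", "quantify", "mobility", "frap", "report")

CONDITIONS = ("interacting", "control")


def _child_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: RunConfig, out_dir: str | Path, stages: tuple[str, ...] = STAGES
) -> dict:
    """Execute the requested prefix of the pipeline DAG; return the manifest.

    The same (config, seed) pair reproduces byte-identical outputs.  Each
    stage draws its randomness from a child seed spawned from the master seed
    and recorded in the manifest.
    """
    for s in stages:
        if s not in STAGES:
            raise ValidationError(f"unknown stage {s!r}")
    idx = max(STAGES.index(s) for s in stages)
    stages = STAGES[: idx + 1]  # prefix-closed

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(STAGES, _child_seeds(config.seed, len(STAGES))))
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": list(stages),
        "outputs": {},
        "warnings": [],
    }
    save_config(config, out / "config.yaml")
    manifest["outputs"]["config.yaml"] = _hash_file(out / "config.yaml")

    state: dict = {}
    for stage in stages:
        fn = globals()[f"_stage_{stage}"]
        fn(config, out, seeds[stage], state, manifest)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _record(manifest: dict, out: Path, paths) -> None:
    for p in paths if not isinstance(paths, dict) else paths.values():
        p = Path(p)
        manifest["outputs"][str(p.relative_to(out))] = _hash_file(p)


def _stage_simulate(config, out, seed, state, manifest):
    photo = config.photophysics
    if config.simulation.interacting_enrichment is not None:
        photo = calibrate_papa_near(
            config.schedule, photo, config.simulation.interacting_enrichment
        )
    layout = config.layout()
    for i, condition in enumerate(CONDITIONS):
        det, traj, images, mask, gt = simulate_papa_experiment(
            config.schedule,
            photo,
            config.motion,
            layout,
            interacting=(condition == "interacting"),
            seed=seed + i,
        )
        paths = write_papa_run(out / condition, det, traj, images, mask, gt)
        _record(manifest, out, paths)
        state[condition] = {
            "detections": det,
            "trajectories": traj,
            "images": images,
            "mask": mask,
            "ground_truth": gt,
        }


def _stage_segment(config, out, seed, state, manifest):
    import tifffile

    for condition in CONDITIONS:
        cdata = state[condition]
        labeled = segmentation.segment_nuclei_threshold(
            cdata["images"]["560"], smoothing_sigma=10.0,
            min_area=int(config.qc.min_area or 0),
        )
        cdata["segmented_mask"] = labeled
        p = out / condition / "segmented_mask.tif"
        tifffile.imwrite(p, labeled)
        _record(manifest, out, [p])


def _stage_qc(config, out, seed, state, manifest):
    for condition in CONDITIONS:
        cdata = state[condition]
        mask = cdata.get("segmented_mask", cdata["mask"])
        assigned, assign_report = segmentation.assign_detections(
            cdata["detections"], mask
        )
        records = segmentation.records_from_mask(mask, cdata["images"]["642"])
        segmentation.count_detections_per_nucleus(assigned, records)
        retained, report = segmentation.apply_qc(records, config.qc)
        report["assignment"] = assign_report
        cdata["assigned"] = assigned
        cdata["retained"] = retained
        p = out / condition / "qc_report.json"
        p.write_text(json.dumps(report, indent=2, default=str))
        _record(manifest, out, [p])


def _stage_quantify(config, out, seed, state, manifest):
    cells = {}
    for condition in CONDITIONS:
        cdata = state[condition]
        labels = [r.label for r in cdata["retained"]]
        counts = quant.window_counts(cdata["assigned"], config.schedule, labels)
        cells[condition] = counts
    result = quant.quantify_condition(
        list(cells["interacting"].values()),
        list(cells["control"].values()),
        config.schedule,
        condition="interacting",
        n_boot=config.bootstrap.n_boot_proximity,
        percentiles=config.bootstrap.percentiles,
        seed=seed,
    )
    control_result = quant.quantify_condition(
        list(cells["control"].values()),
        list(cells["control"].values()),
        config.schedule,
        condition="control",
        n_boot=config.bootstrap.n_boot_proximity,
        percentiles=config.bootstrap.percentiles,
        seed=seed + 1,
    )
    rows = []
    for res in (result, control_result):
        rows.append(
            {
                "condition": res.condition,
                "papa_total": res.papa_total,
                "dr_total": res.dr_total,
                "gv_ratio": res.gv_ratio,
                "proximity_index": res.proximity_index,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n_cells": res.n_cells,
                "seed": res.seed,
            }
        )
    df = pd.DataFrame(rows)
    p = out / "proximity_results.csv"
    df.to_csv(p, index=False)
    _record(manifest, out, [p])
    state["proximity"] = {"interacting": result, "control": control_result}

    points = quant.cell_scatter_points(cells["interacting"], config.schedule)
    state["scatter_points"] = points
    sp = pd.DataFrame(
        [
            {
                "label": pt.label,
                "dr_corrected": pt.dr_corrected,
                "papa_corrected": pt.papa_corrected,
                "total_detections": pt.total_detections,
                "included": pt.included,
                "exclusion_reason": pt.exclusion_reason,
            }
            for pt in points
        ]
    )
    p2 = out / "scatter_points.csv"
    sp.to_csv(p2, index=False)
    _record(manifest, out, [p2])
    try:
        fit = quant.cell_scatter_regression(
            points, n_boot=config.bootstrap.n_boot_scatter, seed=seed + 2
        )
    except ValidationError as exc:
        manifest["warnings"].append(f"scatter regression skipped: {exc}")
        fit = None
    state["scatter_fit"] = fit
    if fit is not None:
        p3 = out / "scatter_fit.json"
        p3.write_text(json.dumps(fit, indent=2))
        _record(manifest, out, [p3])


def _stage_mobility(config, out, seed, state, manifest):
    grid = mob.default_grid(
        config.mobility.grid_points, config.mobility.d_min, config.mobility.d_max
    )
    rows = []
    state["spectra"] = {}
    for condition in CONDITIONS:
        cdata = state[condition]
        trajs = mob.TrajectorySet(
            data=cdata["trajectories"],
            frame_interval=config.schedule.frame_interval,
            pixel_size=config.motion.pixel_size,
            loc_error=config.motion.loc_error,
        )
        papa_set, dr_set, n_dropped = mob.split_by_reactivation(
            trajs, config.schedule
        )
        for tset in (papa_set, dr_set):
            if len(tset.data) == 0:
                manifest["warnings"].append(
                    f"{condition}/{tset.channel}: no trajectories; spectrum skipped"
                )
                continue
            spec = mob.fit_spectrum(
                tset,
                grid=grid,
                max_iter=config.mobility.max_iter,
                tol=config.mobility.tol,
                slow_threshold=config.mobility.slow_threshold,
            )
            state["spectra"][(condition, tset.channel)] = spec
            p = out / condition / f"spectrum_{tset.channel}.csv"
            spec.to_frame().to_csv(p, index=False)
            _record(manifest, out, [p])
            rows.append(
                {
                    "condition": condition,
                    "channel": tset.channel,
                    "slow_fraction": spec.slow_fraction,
                    "n_jumps": spec.n_jumps,
                    "n_dropped_baseline": n_dropped,
                }
            )
    df = pd.DataFrame(rows)
    p = out / "slow_fractions.csv"
    df.to_csv(p, index=False)
    _record(manifest, out, [p])
    state["slow_fractions"] = df


def _stage_frap(config, out, seed, state, manifest):
    fp = config.frap
    traces = []
    rows = []
    for m in range(fp.n_movies):
        movie, sidecar, gt = simulate_frap_movie(
            n_frames=fp.n_frames,
            bleach_frame=fp.bleach_frame,
            mobile_fraction=fp.mobile_fraction,
            tau=fp.tau,
            depth=fp.depth,
            spot_radius=fp.spot_radius,
            frame_interval=fp.frame_interval,
            seed=seed + m,
        )
        paths = write_frap_movie(out / "frap", movie, sidecar, gt, stem=f"movie_{m}")
        _record(manifest, out, paths)
        trace = frap_mod.frap_trace(
            movie,
            spot_center=tuple(sidecar["spot_center_yx"]),
            spot_radius=sidecar["spot_radius_px"],
            bleach_frame=sidecar["bleach_frame"],
            frame_interval=sidecar["frame_interval_s"],
        )
        traces.append(trace)
        for f, v in enumerate(trace.values, start=1):
            rows.append(
                {"movie": m, "frame": f, "time_s": (f - 1) * fp.frame_interval,
                 "value": v}
            )
    df = pd.DataFrame(rows)
    p = out / "frap_traces.csv"
    df.to_csv(p, index=False)
    _record(manifest, out, [p])
    mean, sem = frap_mod.average_traces(traces)
    mdf = pd.DataFrame(
        {
            "frame": np.arange(1, mean.size + 1),
            "time_s": (np.arange(1, mean.size + 1) - 1) * fp.frame_interval,
            "mean": mean,
            "sem": sem,
        }
    )
    p2 = out / "frap_mean.csv"
    mdf.to_csv(p2, index=False)
    _record(manifest, out, [p2])
    state["frap_traces"] = traces
    state["frap_mean"] = mdf


def _stage_report(config, out, seed, state, manifest):
    paths = make_report(state, out / "report")
    _record(manifest, out, paths)


def make_report(state: dict, out_dir: str | Path) -> list[Path]:
    """Figure panel: proximity bars, DR-vs-PAPA scatter with no-intercept fit
    band, paired slow-fraction bars, FRAP mean curve.  Missing inputs skip
    the corresponding figure with a warning."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    prox = state.get("proximity")
    if prox:
        fig, ax = plt.subplots(figsize=(4, 4))
        names = [c for c in prox if c != "control"]
        vals = [prox[c].proximity_index for c in names]
        err = np.array(
            [
                [prox[c].proximity_index - prox[c].ci_low for c in names],
                [prox[c].ci_high - prox[c].proximity_index for c in names],
            ]
        )
        ax.bar(names, vals, yerr=err, capsize=4, color="seagreen")
        ctrl = prox.get("control")
        ax.axhline(1.0, ls="--", color="gray")
        if ctrl is not None:
            ax.errorbar(
                [len(names) - 0.4],
                [1.0],
                yerr=[[1.0 - ctrl.ci_low], [ctrl.ci_high - 1.0]],
                fmt="none",
                ecolor="gray",
                capsize=4,
            )
        ax.set_ylabel("proximity index (PAPA/DR, control-normalized)")
        fig.tight_layout()
        p = out / "proximity_index.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        logger.warning("report: no proximity results; bar plot skipped")

    points, fit = state.get("scatter_points"), state.get("scatter_fit")
    if points and fit:
        inc = [p for p in points if p.included]
        x = np.array([p.dr_corrected for p in inc])
        y = np.array([p.papa_corrected for p in inc])
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(x, y, s=14, color="k")
        xs = np.linspace(0, max(x.max(), 1.0), 50)
        ax.plot(xs, fit["slope"] * xs, color="seagreen",
                label=f"slope = {fit['slope']:.3f}")
        ax.fill_between(
            xs, fit["ci_low"] * xs, fit["ci_high"] * xs, alpha=0.25,
            color="seagreen",
        )
        ax.set_xlabel("corrected DR detections per cell")
        ax.set_ylabel("corrected PAPA detections per cell")
        ax.legend()
        fig.tight_layout()
        p = out / "cell_scatter.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        logger.warning("report: no scatter fit; scatter figure skipped")

    sf = state.get("slow_fractions")
    if sf is not None and len(sf):
        fig, ax = plt.subplots(figsize=(4, 4))
        conditions = sf["condition"].unique()
        width = 0.35
        for i, channel in enumerate(("papa", "dr")):
            sub = sf[sf["channel"] == channel].set_index("condition")
            vals = [sub["slow_fraction"].get(c, np.nan) for c in conditions]
            ax.bar(
                np.arange(len(conditions)) + (i - 0.5) * width,
                vals,
                width,
                label=channel.upper(),
                color="seagreen" if channel == "papa" else "mediumpurple",
            )
        ax.set_xticks(range(len(conditions)), conditions)
        ax.set_ylabel("slow fraction (D < 0.1 μm²/s)")
        ax.legend()
        fig.tight_layout()
        p = out / "slow_fractions.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        logger.warning("report: no slow fractions; figure skipped")

    fm = state.get("frap_mean")
    if fm is not None:
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        ax.plot(fm["time_s"], fm["mean"], color="seagreen")
        ax.fill_between(
            fm["time_s"], fm["mean"] - fm["sem"], fm["mean"] + fm["sem"],
            alpha=0.3, color="seagreen",
        )
        ax.axhline(1.0, ls=":", color="gray")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("normalized recovery")
        fig.tight_layout()
        p = out / "frap_recovery.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        logger.warning("report: no FRAP traces; figure skipped")

    return written
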