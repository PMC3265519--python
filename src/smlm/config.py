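"""Pipeline orchestration with reproducible configuration.

A single YAML-serializable dict configures every stage; ``run_pipeline``
executes the requested stages in order (simulate, localize, drift, colors,
crosstalk, render, resolution), writes each stage's artifacts next to a
manifest recording the resolved config, seeds and per-stage localization
counts. Identical config + seed gives identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import analyze, io, localize as loc_mod, postprocess, simulate
from .calibrate import CalibrationCurve, build_calibration, default_astigmatic_curve
from .localize import LocalizeParams, fit_peak_3d, localize_movie
from .postprocess import DriftTrace
from .simulate import (ActivationSchedule, BlinkModel, CameraModel,
                       StructureSpec, make_structure, render_frames,
                       schedule_blinking)
from .tables import LocalizationTable, read_molecule_list, write_molecule_list

__all__ = ["run_pipeline", "calibration_from_bead_stack", "PipelineError"]

log = logging.getLogger("smlm")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage. Partial outputs remain."""


def calibration_from_bead_stack(stack, z_positions_nm,
                                params: LocalizeParams | None = None) -> CalibrationCurve:
    """Build a z-calibration from a stepped z-scan of isolated emitters.

    ``z_positions_nm`` gives the known stage z of each frame. All candidate
    spots in a frame are fit with the elliptical Gaussian and their widths
    averaged per z plane.
    """
    params = params or LocalizeParams(mode="2d")
    half = params.window // 2
    samples = []
    for f, z in enumerate(z_positions_nm):
        frame = np.asarray(stack.frames[f], dtype=float)
        filt = loc_mod.filter_frame(frame, params.filter_sigmas)
        sigma = loc_mod._robust_sigma(filt) or float(filt.std()) or 1e-12
        peaks = loc_mod.find_peaks(filt, params.threshold_k * sigma,
                                   min_separation=params.window)
        wxs, wys = [], []
        for r, c in peaks:
            if (r < half or c < half or r >= frame.shape[0] - half
                    or c >= frame.shape[1] - half):
                continue
            roi = frame[r - half:r + half + 1, c - half:c + half + 1]
            fit = fit_peak_3d(roi, (half + 0.5, half + 0.5),
                              pixel_size_nm=stack.pixel_size_nm)
            if fit.success:
                wxs.append(fit.wx_nm)
                wys.append(fit.wy_nm)
        if wxs:
            samples.append((float(z), float(np.mean(wxs)), float(np.mean(wys))))
    return build_calibration(samples)


def _build_schedule(cfg: dict) -> ActivationSchedule:
    if "cycle" in cfg:
        return ActivationSchedule(tuple(cfg["cycle"]),
                                  cfg.get("frame_rate_hz", 60.0))
    channels = cfg.get("channels", ["ch405"])
    if len(channels) == 1:
        return ActivationSchedule.single_color(
            channels[0], cfg.get("n_activation", 1), cfg.get("n_imaging", 3),
            cfg.get("frame_rate_hz", 60.0))
    return ActivationSchedule.multicolor(
        channels, cfg.get("n_activation", 2), cfg.get("n_imaging", 3),
        cfg.get("frame_rate_hz", 60.0))


def _linear_drift_trace(total_nm, n_frames: int, n_bins: int = 50) -> DriftTrace:
    edges = np.linspace(0, n_frames, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    fx = (centers - centers[0]) / n_frames
    return DriftTrace(edges, total_nm[0] * fx, total_nm[1] * fx)


def _stage_simulate(cfg: dict, outdir: Path, seed: int, manifest: dict):
    struct = cfg.get("structure", {})
    spec = StructureSpec(
        kind=struct.get("kind", "tube"),
        tube_radius=struct.get("tube_radius_nm", 75.0),
        axis=tuple(tuple(p) for p in struct.get(
            "axis_nm", [[500.0, 1000.0, 0.0], [4500.0, 1000.0, 0.0]])),
        label_density=struct.get("label_density", 2500.0),
        z_separation=struct.get("z_separation_nm", 0.0))
    schedule = _build_schedule(cfg.get("schedule", {}))
    blink = BlinkModel(**cfg.get("blink", {}))
    camera = CameraModel(**cfg.get("camera", {}))
    n_frames = int(cfg.get("n_frames", 2000))
    shape = tuple(cfg.get("shape_px", [32, 32]))
    curve = default_astigmatic_curve(**cfg.get("psf", {}))

    emitters = make_structure(spec, seed=seed,
                              channel=cfg.get("channel", "ch405"),
                              channel_weights=cfg.get("channel_weights"))
    events = schedule_blinking(emitters, schedule, blink, n_frames, seed=seed + 1)
    drift = None
    if "drift_total_nm" in cfg:
        drift = _linear_drift_trace(cfg["drift_total_nm"], n_frames)
    stack = simulate.render_frames(events, emitters, curve, camera, n_frames,
                                   shape, drift=drift, seed=seed + 2,
                                   schedule=schedule)
    io.write_stack(stack, outdir / "movie.tif",
                   manifest_extra={"seed": seed, "ground_truth": "ground_truth.csv"})
    io.write_ground_truth(emitters, outdir / "ground_truth.csv")
    manifest["simulate"] = {"n_emitters": len(emitters), "n_events": len(events),
                            "n_frames": n_frames, "seed": seed}
    log.info("simulate: %d emitters, %d events", len(emitters), len(events))
    return {"stack": stack, "emitters": emitters, "events": events,
            "schedule": schedule, "curve": curve, "drift": drift}


def run_pipeline(config: dict, outdir, seed: int | None = None) -> dict:
    """Execute the configured stages end to end.

    Returns a dict of in-memory artifacts; files and ``manifest.yaml`` are
    written under ``outdir``. A stage failure raises :class:`PipelineError`
    naming the stage, leaving earlier outputs in place.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    manifest: dict = {"seed": seed, "config": config, "stages": {}}
    state: dict = {}
    stages = config.get("stages", [k for k in (
        "simulate", "localize", "drift", "colors", "crosstalk", "render",
        "resolution") if k in config])

    # fail early on inconsistent config
    loc_cfg = config.get("localize", {})
    if loc_cfg.get("mode", "3d") == "3d" and "simulate" not in stages \
            and "calibration" not in loc_cfg and "localize" in stages:
        raise PipelineError(
            "stage localize: 3D mode requires a calibration "
            "(localize.calibration) when no simulation provides one")

    for stage in stages:
        try:
            if stage == "simulate":
                state.update(_stage_simulate(config.get("simulate", {}),
                                             outdir, seed, manifest["stages"]))
            elif stage == "localize":
                cfg = dict(config.get("localize", {}))
                if "stack_path" in cfg:
                    state["stack"] = io.read_stack(cfg.pop("stack_path"))
                curve = state.get("curve")
                if "calibration" in cfg:
                    curve = io.read_calibration(cfg.pop("calibration"))
                params = LocalizeParams(**{k: v for k, v in cfg.items()
                                           if k in LocalizeParams.__dataclass_fields__})
                table = localize_movie(state["stack"], curve, params)
                state["table"] = table
                write_molecule_list(table, outdir / "locs.csv")
                manifest["stages"]["localize"] = {
                    "n_localizations": len(table),
                    "candidates": table.metadata.get("candidates"),
                    "rejections": table.metadata.get("rejections")}
                log.info("localize: %d localizations", len(table))
            elif stage == "drift":
                cfg = config.get("drift", {})
                trace = postprocess.estimate_drift(
                    state["table"], bin_size=cfg.get("bin_size", 500),
                    render_pixel=cfg.get("render_pixel_nm", 25.0))
                state["table"] = postprocess.apply_drift(state["table"], trace)
                state["drift_trace"] = trace
                import pandas as pd
                pd.DataFrame({
                    "bin_start": trace.frame_edges[:-1].astype(int),
                    "bin_end": trace.frame_edges[1:].astype(int),
                    "dx_nm": trace.dx, "dy_nm": trace.dy,
                }).to_csv(outdir / "drift.csv", index=False)
                write_molecule_list(state["table"], outdir / "locs_driftcorr.csv")
                manifest["stages"]["drift"] = {
                    "n_bins": trace.n_bins,
                    "max_offset_nm": float(np.max(np.hypot(trace.dx, trace.dy)))}
            elif stage == "colors":
                state["table"] = postprocess.assign_colors(
                    state["table"], state["schedule"])
                write_molecule_list(state["table"], outdir / "locs_colored.csv")
                counts = state["table"].df["channel"].value_counts().to_dict()
                manifest["stages"]["colors"] = {
                    "per_channel": {str(k): int(v) for k, v in counts.items()}}
            elif stage == "crosstalk":
                cfg = config.get("crosstalk", {})
                est = postprocess.estimate_crosstalk(
                    state["table"], state["schedule"],
                    cross_activation={tuple(k.split(">")): v for k, v in
                                      cfg.get("cross_activation", {}).items()})
                state["table"], report = postprocess.subtract_crosstalk(
                    state["table"], est, seed=cfg.get("seed", seed + 3))
                write_molecule_list(state["table"], outdir / "locs_corrected.csv")
                io.write_yaml({
                    "apparent_specific": est.apparent_specific,
                    "nonspecific_per_frame": est.nonspecific_per_frame,
                    "actual_specific": est.actual_specific,
                    "pre_counts": report.pre_counts,
                    "post_counts": report.post_counts,
                    "removed": report.removed,
                    "seed": report.seed,
                }, outdir / "crosstalk.yaml")
                manifest["stages"]["crosstalk"] = {
                    "removed": report.removed, "post_counts": report.post_counts}
            elif stage == "render":
                cfg = config.get("render", {})
                img = analyze.render(state["table"],
                                     pitch=cfg.get("pitch_nm", 25.0),
                                     mode=cfg.get("mode", "2d"),
                                     width_mode=cfg.get("width_mode", "theoretical"),
                                     psf_sigma_nm=cfg.get("psf_sigma_nm", 150.0))
                import tifffile
                arr = img.data
                scale = 65535.0 / arr.max() if arr.max() > 0 else 1.0
                tifffile.imwrite(outdir / "render.tif",
                                 (arr * scale).astype(np.uint16))
                state["render"] = img
                manifest["stages"]["render"] = {"shape": list(arr.shape)}
            elif stage == "resolution":
                cfg = config.get("resolution", {})
                d = int(cfg.get("d", 2))
                n_per = float(cfg.get("n_locs_per_label", 4.0))
                regions = []
                for r in cfg.get("regions", []):
                    lo_x, hi_x = r["x_nm"]
                    lo_y, hi_y = r["y_nm"]
                    mask = ((state["table"].df["x_nm"] >= lo_x)
                            & (state["table"].df["x_nm"] < hi_x)
                            & (state["table"].df["y_nm"] >= lo_y)
                            & (state["table"].df["y_nm"] < hi_y)).to_numpy()
                    regions.append((mask, float(r["measure_um"])))
                a_mean, a_sd, _ = analyze.label_density(
                    state["table"], regions, d=d, n_locs_per_label=n_per)
                report = analyze.resolution_report(
                    a_mean, d, cfg.get("precision_xy_nm", 18.0),
                    cfg.get("precision_z_nm"), n_locs_per_label=n_per)
                io.write_yaml({**report.to_dict(), "density_sd": a_sd},
                              outdir / "resolution.yaml")
                state["resolution"] = report
                manifest["stages"]["resolution"] = report.to_dict()
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except PipelineError:
            io.write_yaml(manifest, outdir / "manifest.yaml")
            raise
        except Exception as exc:
            io.write_yaml(manifest, outdir / "manifest.yaml")
            raise PipelineError(f"stage {stage}: {exc}") from exc

    io.write_yaml(manifest, outdir / "manifest.yaml")
    state["manifest"] = manifest
    return state
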