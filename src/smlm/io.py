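"""File formats: TIFF stacks with YAML sidecar manifests, calibration YAML,
ground-truth and offset CSVs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibrate import CalibrationCurve
from .simulate import ActivationSchedule, EmitterSet, FrameStack

__all__ = [
    "write_stack", "read_stack", "write_calibration", "read_calibration",
    "write_ground_truth", "read_ground_truth", "write_offsets_csv",
    "read_offsets_csv", "write_yaml", "read_yaml",
]


def write_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_stack(stack: FrameStack, path, manifest_extra: dict | None = None) -> None:
    """Multi-page TIFF plus a ``<name>.yaml`` sidecar manifest."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.float32),
                     photometric="minisblack")
    manifest = {
        "pixel_size_nm": float(stack.pixel_size_nm),
        "focal_z_nm": float(stack.focal_z_nm),
        "fov_id": int(stack.fov_id),
        "pass_id": int(stack.pass_id),
        "n_frames": int(stack.n_frames),
        "schedule": stack.schedule.to_dict() if stack.schedule else None,
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    write_yaml(manifest, path.with_suffix(".yaml"))


def read_stack(path) -> FrameStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    manifest = read_yaml(path.with_suffix(".yaml"))
    sched = manifest.get("schedule")
    return FrameStack(
        frames=frames,
        pixel_size_nm=manifest["pixel_size_nm"],
        focal_z_nm=manifest.get("focal_z_nm", 0.0),
        fov_id=manifest.get("fov_id", 0),
        pass_id=manifest.get("pass_id", 0),
        schedule=ActivationSchedule.from_dict(sched) if sched else None)


def write_calibration(curve: CalibrationCurve, path) -> None:
    write_yaml(curve.to_dict(), path)


def read_calibration(path) -> CalibrationCurve:
    return CalibrationCurve.from_dict(read_yaml(path))


def write_ground_truth(emitters: EmitterSet, path) -> None:
    pd.DataFrame({
        "emitter_id": np.arange(len(emitters)),
        "x_nm": emitters.positions[:, 0],
        "y_nm": emitters.positions[:, 1],
        "z_nm": emitters.positions[:, 2],
        "channel": emitters.channel,
        "structure_id": emitters.structure_id,
    }).to_csv(path, index=False)


def read_ground_truth(path) -> EmitterSet:
    df = pd.read_csv(path)
    return EmitterSet(df[["x_nm", "y_nm", "z_nm"]].to_numpy(),
                      df["channel"].to_numpy(dtype=object),
                      df["structure_id"].to_numpy())


def write_offsets_csv(offsets, path) -> None:
    pd.DataFrame([{
        "fov_i": o.i, "fov_j": o.j, "dx_nm": o.dx, "dy_nm": o.dy,
        "dz_nm": o.dz, "confidence": o.confidence, "source": o.source,
        "flagged": o.flagged,
    } for o in offsets]).to_csv(path, index=False)


def read_offsets_csv(path):
    from .mosaic import TileOffset

    df = pd.read_csv(path)
    return [TileOffset(int(r.fov_i), int(r.fov_j), r.dx_nm, r.dy_nm, r.dz_nm,
                       (np.inf if not np.isfinite(r.confidence) else r.confidence),
                       str(r.source), bool(getattr(r, "flagged", False)))
            for r in df.itertuples()]
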