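"""Synthetic STORM data: structures, blinking schedules, raw frame stacks.

The simulator emulates membrane-labeled neural processes: fluorescent
labels are placed by a Poisson point process on the *surface* of tubular
structures (membrane labeling), each label produces a small number of
switching events tied to the activation/imaging frame cycle, and events are
rendered as astigmatic elliptical Gaussian spots with EMCCD-like noise.

Every operation takes an explicit seed; identical seeds give identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from .calibrate import CalibrationCurve
from .psf import add_spot
from .tables import LocalizationTable

__all__ = [
    "StructureSpec", "EmitterSet", "ActivationSchedule", "BlinkModel",
    "CameraModel", "FrameStack",
    "make_structure", "schedule_blinking", "render_frames", "events_to_table",
]

NM_PER_UM = 1000.0


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class StructureSpec:
    """Geometric description of a labeled membrane structure.

    ``label_density`` is the areal density of labels on the membrane
    surface, in labels per um^2 (the quantity the Nyquist criterion
    consumes). For junction kinds, ``z_separation`` is the axial distance
    between the two tube axes where they cross.
    """

    kind: str  # tube | x_junction | y_junction | flat_patch
    tube_radius: float  # nm
    axis: tuple  # polyline of 3D points, nm
    label_density: float  # labels / um^2 of membrane surface
    z_separation: float = 0.0  # nm, junctions only

    def __post_init__(self):
        if self.kind not in ("tube", "x_junction", "y_junction", "flat_patch"):
            raise ValueError(f"unknown structure kind {self.kind!r}")
        if self.tube_radius <= 0:
            raise ValueError("tube_radius must be > 0")
        if self.label_density < 0:
            raise ValueError("label_density must be >= 0")
        if self.z_separation < 0:
            raise ValueError("z_separation must be >= 0")


@dataclass
class EmitterSet:
    """Ground-truth label positions (nm) with channel and structure ids."""

    positions: np.ndarray  # (N, 3) nm
    channel: np.ndarray  # (N,) str
    structure_id: np.ndarray  # (N,) int

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 3)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("emitter positions must be finite")
        self.channel = np.asarray(self.channel, dtype=object)
        self.structure_id = np.asarray(self.structure_id, dtype=int)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def concatenate(cls, parts) -> "EmitterSet":
        parts = list(parts)
        return cls(
            np.vstack([p.positions for p in parts]) if parts else np.zeros((0, 3)),
            np.concatenate([p.channel for p in parts]) if parts else [],
            np.concatenate([p.structure_id for p in parts]) if parts else [],
        )


@dataclass(frozen=True)
class ActivationSchedule:
    """Repeating frame cycle of activation and imaging frames.

    ``cycle`` entries are either ``"activation:<channel>"`` or
    ``"imaging"``. An event is *specific* to a channel when it falls in the
    first imaging frame directly after that channel's activation frames.
    """

    cycle: tuple
    frame_rate_hz: float = 60.0

    def __post_init__(self):
        if not self.cycle:
            raise ValueError("cycle must be non-empty")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate must be > 0")
        for role in self.cycle:
            if role != "imaging" and not role.startswith("activation:"):
                raise ValueError(f"bad cycle entry {role!r}")
        if "imaging" not in self.cycle:
            raise ValueError("cycle must contain imaging frames")
        object.__setattr__(self, "cycle", tuple(self.cycle))

    @classmethod
    def single_color(cls, channel: str = "ch405", n_activation: int = 1,
                     n_imaging: int = 3, frame_rate_hz: float = 60.0):
        """One activator: n_activation activation + n_imaging imaging frames."""
        cycle = (f"activation:{channel}",) * n_activation + ("imaging",) * n_imaging
        return cls(cycle, frame_rate_hz)

    @classmethod
    def multicolor(cls, channels=("ch405", "ch457", "ch532"), n_activation: int = 2,
                   n_imaging: int = 3, frame_rate_hz: float = 60.0):
        """Interleaved activator blocks, e.g. 2 activation + 3 imaging frames each."""
        cycle = []
        for ch in channels:
            cycle += [f"activation:{ch}"] * n_activation + ["imaging"] * n_imaging
        return cls(tuple(cycle), frame_rate_hz)

    @property
    def cycle_len(self) -> int:
        return len(self.cycle)

    @cached_property
    def channels(self) -> tuple:
        out = []
        for role in self.cycle:
            if role.startswith("activation:"):
                ch = role.split(":", 1)[1]
                if ch not in out:
                    out.append(ch)
        return tuple(out)

    @cached_property
    def post_activation_slot(self) -> dict:
        """channel -> cycle slot of the first imaging frame after its activation."""
        slots = {}
        n = self.cycle_len
        for i, role in enumerate(self.cycle):
            if role == "imaging" and self.cycle[i - 1].startswith("activation:"):
                ch = self.cycle[i - 1].split(":", 1)[1]
                slots.setdefault(ch, i % n)
        return slots

    @cached_property
    def imaging_slots(self) -> tuple:
        return tuple(i for i, r in enumerate(self.cycle) if r == "imaging")

    @cached_property
    def other_imaging_slots(self) -> tuple:
        """Imaging slots that are not post-activation for any channel."""
        post = set(self.post_activation_slot.values())
        return tuple(i for i in self.imaging_slots if i not in post)

    def slot_of(self, frame):
        return np.asarray(frame, dtype=int) % self.cycle_len

    def channel_of_frame(self, frame):
        """Specific channel for post-activation frames, else None (scalar)."""
        slot = int(frame) % self.cycle_len
        for ch, s in self.post_activation_slot.items():
            if s == slot:
                return ch
        return None

    def to_dict(self) -> dict:
        return {"cycle": list(self.cycle), "frame_rate_hz": self.frame_rate_hz}

    @classmethod
    def from_dict(cls, d) -> "ActivationSchedule":
        return cls(tuple(d["cycle"]), d.get("frame_rate_hz", 60.0))


@dataclass(frozen=True)
class BlinkModel:
    """Photophysics of the activator-reporter pairs, per switching event.

    ``mean_localizations_per_label`` is the average number of switching
    events one label contributes over the whole movie (default 4, the
    conservative divisor the resolution calculus also uses).
    ``specific_activation_prob``, if given, overrides the per-cycle
    activation probability derived from that mean. ``nonspecific_rate`` is
    the per-imaging-frame probability that a label switches on without its
    activation pulse (imaging-laser induced). ``cross_activation`` maps
    (activating_channel, emitter_channel) to a per-cycle false-activation
    probability (wrong-laser crosstalk).
    """

    mean_localizations_per_label: float = 4.0
    specific_activation_prob: float | None = None
    nonspecific_rate: float = 0.0
    cross_activation: dict = field(default_factory=dict)
    photons_mean: float = 5000.0
    photons_distribution: str = "constant"  # constant | exponential

    def __post_init__(self):
        if self.mean_localizations_per_label <= 0:
            raise ValueError("mean_localizations_per_label must be > 0")
        if self.photons_mean <= 0:
            raise ValueError("photons_mean must be > 0")
        if self.specific_activation_prob is not None and not (
            0.0 <= self.specific_activation_prob <= 1.0
        ):
            raise ValueError("specific_activation_prob must be in [0, 1]")
        if not 0.0 <= self.nonspecific_rate <= 1.0:
            raise ValueError("nonspecific_rate must be in [0, 1]")
        for v in self.cross_activation.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("cross_activation probabilities must be in [0, 1]")
        if self.photons_distribution not in ("constant", "exponential"):
            raise ValueError("photons_distribution must be constant or exponential")

    def draw_photons(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.photons_distribution == "constant":
            return np.full(n, float(self.photons_mean))
        return np.maximum(rng.exponential(self.photons_mean, size=n), 50.0)


@dataclass(frozen=True)
class CameraModel:
    """EMCCD-like camera: Poisson shot noise, Gaussian read noise, offset."""

    pixel_size_nm: float = 160.0
    background: float = 10.0  # photons / pixel / frame, shares shot noise
    offset: float = 100.0  # constant baseline, counts
    read_noise: float = 2.0  # Gaussian sigma, counts
    gain: float = 1.0
    shot_noise: bool = True

    def __post_init__(self):
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.gain <= 0 or self.read_noise < 0:
            raise ValueError("negative camera gain/read noise rejected")
        if self.background < 0 or self.offset < 0:
            raise ValueError("background and offset must be >= 0")


@dataclass
class FrameStack:
    """Raw movie: (T, H, W) intensities plus acquisition geometry."""

    frames: np.ndarray
    pixel_size_nm: float
    focal_z_nm: float = 0.0
    fov_id: int = 0
    pass_id: int = 0
    schedule: ActivationSchedule | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be >= 0")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# structure generation

def _polyline_geometry(axis: np.ndarray):
    axis = np.atleast_2d(np.asarray(axis, dtype=float))
    if axis.shape[0] < 2:
        raise ValueError("axis polyline needs at least 2 points")
    seg = np.diff(axis, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    if seg_len.sum() <= 0:
        raise ValueError("degenerate polyline: zero total length")
    return axis, seg, seg_len


def _frames_along(seg: np.ndarray):
    """Orthonormal (normal, binormal) per segment."""
    t = seg / np.linalg.norm(seg, axis=1, keepdims=True)
    ref = np.tile([0.0, 0.0, 1.0], (len(t), 1))
    nearly_vertical = np.abs(t @ [0.0, 0.0, 1.0]) > 0.9
    ref[nearly_vertical] = [1.0, 0.0, 0.0]
    n = np.cross(ref, t)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    b = np.cross(t, n)
    return n, b


def _sample_tube_surface(axis, radius: float, density: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Poisson point process on a tube's membrane surface, positions in nm."""
    axis, seg, seg_len = _polyline_geometry(axis)
    total_len = seg_len.sum()
    area_um2 = 2.0 * np.pi * radius * total_len / NM_PER_UM**2
    n = rng.poisson(density * area_um2)
    if n == 0:
        return np.zeros((0, 3))
    s = rng.uniform(0.0, total_len, n)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[idx]) / seg_len[idx]
    base = axis[idx] + frac[:, None] * seg[idx]
    normal, binormal = _frames_along(seg)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    offset = radius * (np.cos(theta)[:, None] * normal[idx]
                       + np.sin(theta)[:, None] * binormal[idx])
    return base + offset


def _sample_patch(axis, half_width: float, density: float,
                  rng: np.random.Generator) -> np.ndarray:
    axis, seg, seg_len = _polyline_geometry(axis)
    total_len = seg_len.sum()
    area_um2 = total_len * 2.0 * half_width / NM_PER_UM**2
    n = rng.poisson(density * area_um2)
    if n == 0:
        return np.zeros((0, 3))
    s = rng.uniform(0.0, total_len, n)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[idx]) / seg_len[idx]
    base = axis[idx] + frac[:, None] * seg[idx]
    normal, _ = _frames_along(seg)
    u = rng.uniform(-half_width, half_width, n)
    return base + u[:, None] * normal[idx]


def _rotate_about_z(points: np.ndarray, center: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    rel = points - center
    out = rel.copy()
    out[:, 0] = c * rel[:, 0] - s * rel[:, 1]
    out[:, 1] = s * rel[:, 0] + c * rel[:, 1]
    return out + center


def _junction_axes(spec: StructureSpec):
    """Two tube axes crossing with the requested axial separation."""
    axis, _, _ = _polyline_geometry(spec.axis)
    center = 0.5 * (axis.min(axis=0) + axis.max(axis=0))
    angle = np.pi / 2 if spec.kind == "x_junction" else np.pi / 4
    second = _rotate_about_z(axis, center, angle)
    second[:, 2] += spec.z_separation
    return axis, second


def make_structure(spec: StructureSpec, seed, channel: str = "ch405",
                   channel_weights: dict | None = None) -> EmitterSet:
    """Place labels on a structure's membrane by a Poisson point process.

    The expected count is ``label_density`` times the membrane surface area
    (2*pi*r*L for tubes, L*2r for flat patches). ``channel_weights`` maps
    channel names to mixing fractions for multicolor labeling; by default
    every label belongs to ``channel``.
    """
    rng = np.random.default_rng(seed)
    if spec.kind in ("x_junction", "y_junction"):
        ax1, ax2 = _junction_axes(spec)
        pts1 = _sample_tube_surface(ax1, spec.tube_radius, spec.label_density, rng)
        pts2 = _sample_tube_surface(ax2, spec.tube_radius, spec.label_density, rng)
        positions = np.vstack([pts1, pts2])
        structure_id = np.concatenate([
            np.zeros(len(pts1), dtype=int), np.ones(len(pts2), dtype=int)])
    elif spec.kind == "tube":
        positions = _sample_tube_surface(spec.axis, spec.tube_radius,
                                         spec.label_density, rng)
        structure_id = np.zeros(len(positions), dtype=int)
    else:  # flat_patch
        positions = _sample_patch(spec.axis, spec.tube_radius,
                                  spec.label_density, rng)
        structure_id = np.zeros(len(positions), dtype=int)

    n = len(positions)
    if channel_weights:
        names = list(channel_weights)
        w = np.array([channel_weights[k] for k in names], dtype=float)
        w = w / w.sum()
        channels = rng.choice(np.asarray(names, dtype=object), size=n, p=w)
    else:
        channels = np.full(n, channel, dtype=object)
    return EmitterSet(positions, channels, structure_id)


# ---------------------------------------------------------------------------
# blinking

EVENT_COLUMNS = ["emitter_id", "frame", "photons", "laser", "kind"]


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame({
        "emitter_id": pd.Series(dtype=int), "frame": pd.Series(dtype=int),
        "photons": pd.Series(dtype=float), "laser": pd.Series(dtype=object),
        "kind": pd.Series(dtype=object)})


def schedule_blinking(emitters: EmitterSet, schedule: ActivationSchedule,
                      blink: BlinkModel, n_frames: int, seed) -> pd.DataFrame:
    """Draw switching events for every label over an ``n_frames`` movie.

    Returns a DataFrame (emitter_id, frame, photons, laser, kind) where kind
    is "specific", "nonspecific" or "cross". Specific events land in the
    first imaging frame after their own channel's activation block;
    nonspecific events are uniform over all imaging frames; wrong-laser
    (cross) events land in the *activating* channel's post-activation frame.
    """
    if n_frames < schedule.cycle_len:
        raise ValueError("movie shorter than one activation cycle")
    rng = np.random.default_rng(seed)
    L = schedule.cycle_len
    n_cycles = n_frames // L
    parts = []

    # specific events
    for ch, slot in schedule.post_activation_slot.items():
        sel = np.flatnonzero(emitters.channel == ch)
        if sel.size == 0 or n_cycles == 0:
            continue
        if blink.specific_activation_prob is not None:
            p = blink.specific_activation_prob
        else:
            p = min(1.0, blink.mean_localizations_per_label / n_cycles)
        if p <= 0:
            continue
        counts = rng.binomial(n_cycles, p, size=sel.size)
        total = int(counts.sum())
        if total == 0:
            continue
        eid = np.repeat(sel, counts)
        cycles = np.concatenate([
            rng.choice(n_cycles, size=c, replace=False) for c in counts if c > 0
        ]) if total else np.zeros(0, dtype=int)
        parts.append(pd.DataFrame({
            "emitter_id": eid, "frame": cycles * L + slot,
            "photons": blink.draw_photons(total, rng),
            "laser": ch, "kind": "specific"}))

    # nonspecific (imaging-laser) events: uniform over imaging frames
    if blink.nonspecific_rate > 0 and len(emitters):
        img_slots = np.asarray(schedule.imaging_slots)
        n_img = n_cycles * img_slots.size
        counts = rng.binomial(n_img, blink.nonspecific_rate, size=len(emitters))
        total = int(counts.sum())
        if total:
            eid = np.repeat(np.arange(len(emitters)), counts)
            pick = rng.integers(0, n_img, size=total)
            frames = (pick // img_slots.size) * L + img_slots[pick % img_slots.size]
            parts.append(pd.DataFrame({
                "emitter_id": eid, "frame": frames,
                "photons": blink.draw_photons(total, rng),
                "laser": "imaging", "kind": "nonspecific"}))

    # wrong-laser (cross) activations
    for (laser_ch, victim_ch), p in blink.cross_activation.items():
        slot = schedule.post_activation_slot.get(laser_ch)
        if slot is None or p <= 0:
            continue
        sel = np.flatnonzero(emitters.channel == victim_ch)
        if sel.size == 0:
            continue
        counts = rng.binomial(n_cycles, p, size=sel.size)
        total = int(counts.sum())
        if total == 0:
            continue
        eid = np.repeat(sel, counts)
        cycles = np.concatenate([
            rng.choice(n_cycles, size=c, replace=False) for c in counts if c > 0])
        parts.append(pd.DataFrame({
            "emitter_id": eid, "frame": cycles * L + slot,
            "photons": blink.draw_photons(total, rng),
            "laser": laser_ch, "kind": "cross"}))

    if not parts:
        return _empty_events()
    events = pd.concat(parts, ignore_index=True)
    return events.sort_values("frame", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# frame rendering

def render_frames(events: pd.DataFrame, emitters: EmitterSet,
                  curve: CalibrationCurve, camera: CameraModel,
                  n_frames: int, shape: tuple, focal_z: float = 0.0,
                  drift=None, seed=0, schedule: ActivationSchedule | None = None,
                  fov_id: int = 0, pass_id: int = 0) -> FrameStack:
    """Render switching events into a raw movie.

    Each event becomes an elliptical Gaussian spot of integrated signal
    ``photons`` with widths wx(z - focal_z), wy(z - focal_z) from the same
    calibration curve the analysis uses. Events whose axial offset falls
    outside the curve's valid range (the detectable window around the focal
    plane) are silently dropped. ``drift`` is an optional
    :class:`~smlm.postprocess.DriftTrace` that displaces spot centers
    per frame.
    """
    rng = np.random.default_rng(seed)
    H, W = shape
    px = camera.pixel_size_nm
    signal = np.zeros((n_frames, H, W), dtype=np.float32)

    if len(events):
        eid = events["emitter_id"].to_numpy()
        pos = emitters.positions[eid]
        zrel = pos[:, 2] - focal_z
        keep = curve.contains(zrel)
        frames_idx = events["frame"].to_numpy()[keep]
        photons = events["photons"].to_numpy()[keep]
        pos = pos[keep]
        zrel = zrel[keep]
        wx, wy = curve.widths_at(zrel)
        dx = dy = np.zeros(len(pos))
        if drift is not None:
            dx, dy, _ = drift.offsets_at(frames_idx)
        x_px = (pos[:, 0] + dx) / px
        y_px = (pos[:, 1] + dy) / px
        sx_px, sy_px = wx / px, wy / px
        for f, x0, y0, sx, sy, n_ph in zip(frames_idx, x_px, y_px, sx_px, sy_px, photons):
            if 0 <= f < n_frames:
                add_spot(signal[f], x0, y0, sx, sy, n_ph)

    signal += camera.background
    if camera.shot_noise:
        out = rng.poisson(signal).astype(np.float32)
    else:
        out = signal
    out *= camera.gain
    out += camera.offset
    if camera.read_noise > 0:
        out += rng.normal(0.0, camera.read_noise, size=out.shape).astype(np.float32)
    np.clip(out, 0.0, None, out=out)
    return FrameStack(out.astype(np.float32), pixel_size_nm=px,
                      focal_z_nm=focal_z, fov_id=fov_id, pass_id=pass_id,
                      schedule=schedule)


def events_to_table(events: pd.DataFrame, emitters: EmitterSet,
                    pixel_size_nm: float = 160.0, n_frames: int = 0,
                    drift=None, scatter_sigma=None, seed=0,
                    fov_id: int = 0, pass_id: int = 0) -> LocalizationTable:
    """Idealized molecule list straight from ground truth.

    Bypasses rendering and fitting: each event is localized at its
    emitter's true position, optionally displaced by a drift trace and by
    per-axis Gaussian scatter ``scatter_sigma = (sx, sy, sz)`` nm emulating
    photon-limited localization error. The true channel and event kind are
    kept in extra columns (``true_channel``, ``kind``) for validation.
    """
    rng = np.random.default_rng(seed)
    eid = events["emitter_id"].to_numpy() if len(events) else np.zeros(0, dtype=int)
    pos = emitters.positions[eid] if len(events) else np.zeros((0, 3))
    frames = events["frame"].to_numpy() if len(events) else np.zeros(0, dtype=int)
    x, y, z = pos[:, 0].copy(), pos[:, 1].copy(), pos[:, 2].copy()
    if drift is not None and len(frames):
        dx, dy, dz = drift.offsets_at(frames)
        x += dx
        y += dy
        z += dz
    if scatter_sigma is not None and len(frames):
        sx, sy, sz = scatter_sigma
        x += rng.normal(0.0, sx, len(frames))
        y += rng.normal(0.0, sy, len(frames))
        z += rng.normal(0.0, sz, len(frames))
    table = LocalizationTable.from_arrays(
        x, y, frames, z_nm=z,
        photons=events["photons"].to_numpy() if len(events) else 1000.0,
        fov_id=fov_id, pass_id=pass_id,
        pixel_size_nm=pixel_size_nm, n_frames=n_frames)
    table.df["true_channel"] = emitters.channel[eid] if len(events) else np.zeros(0, dtype=object)
    table.df["kind"] = events["kind"].to_numpy() if len(events) else np.zeros(0, dtype=object)
    table.df["emitter_id"] = eid
    return table
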