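"""Drift correction, activation-frame color coding, crosstalk subtraction.

Drift is estimated by reconstructing images from temporal subsets of the
localizations (bins of frames) and cross-correlating each sub-image against
the one from the initial time segment. Color coding tags each localization
with the activator channel whose pulse immediately preceded its frame;
everything else is "nonspecific". Crosstalk is removed statistically: the
constant nonspecific rate measured in the non-post-activation imaging
frames predicts how many of each channel's apparent-specific localizations
are false, and that many are removed by seeded random thinning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .registration import hist2d, xcorr_shift
from .simulate import ActivationSchedule
from .tables import LocalizationTable

__all__ = [
    "DriftTrace", "CrosstalkEstimate", "CrosstalkReport", "DriftEstimationError",
    "estimate_drift", "apply_drift", "assign_colors",
    "estimate_crosstalk", "subtract_crosstalk",
]


class DriftEstimationError(RuntimeError):
    pass


@dataclass
class DriftTrace:
    """Per-time-bin lateral offsets with a fixed interpolation contract.

    ``frame_edges`` (length B+1) tile the movie; bin b covers
    [edges[b], edges[b+1]). Offsets are the displacement of that bin's
    localizations relative to the reference bin (offset (0,0) there).
    ``offsets_at`` interpolates piecewise-linearly between bin centers and
    extrapolates as a constant beyond the first/last center.
    """

    frame_edges: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    dz: np.ndarray | None = None
    reference_bin: int = 0
    confidence: np.ndarray | None = None

    def __post_init__(self):
        self.frame_edges = np.asarray(self.frame_edges, dtype=float)
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        b = len(self.frame_edges) - 1
        if not (len(self.dx) == len(self.dy) == b) or b < 1:
            raise ValueError("offset arrays must match the number of bins")
        if self.dz is None:
            self.dz = np.zeros(b)
        if abs(self.dx[self.reference_bin]) > 1e-9 or abs(self.dy[self.reference_bin]) > 1e-9:
            raise ValueError("reference bin offset must be (0, 0)")

    @property
    def n_bins(self) -> int:
        return len(self.frame_edges) - 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.frame_edges[:-1] + self.frame_edges[1:])

    def covers(self, frames) -> bool:
        f = np.asarray(frames)
        return bool(np.all((f >= self.frame_edges[0]) & (f < self.frame_edges[-1])))

    def offsets_at(self, frames):
        """(dx, dy, dz) nm at the given frame indices."""
        f = np.asarray(frames, dtype=float)
        c = self.bin_centers
        return (np.interp(f, c, self.dx), np.interp(f, c, self.dy),
                np.interp(f, c, self.dz))

    @classmethod
    def zero(cls, n_frames: int, n_bins: int = 1) -> "DriftTrace":
        edges = np.linspace(0, n_frames, n_bins + 1)
        return cls(edges, np.zeros(n_bins), np.zeros(n_bins))


def estimate_drift(table: LocalizationTable, bin_size: int = 1000,
                   render_pixel: float = 25.0, reference_bin: int = 0,
                   min_confidence: float = 6.0) -> DriftTrace:
    """Estimate lateral stage drift from the molecule list itself.

    The movie is split into bins of ``bin_size`` frames; each bin's 2D
    render (``render_pixel`` nm histogram, lightly smoothed) is
    cross-correlated against the reference bin's render, and the negated
    alignment shift is that bin's drift offset.
    """
    n_frames = table.n_frames or int(table.df["frame"].max()) + 1
    n_bins = max(int(np.ceil(n_frames / bin_size)), 1)
    if n_bins < 2:
        raise ValueError("need at least 2 bins to estimate drift; "
                         "decrease bin_size or provide a longer movie")
    edges = np.arange(n_bins + 1, dtype=float) * bin_size
    edges[-1] = max(edges[-1], n_frames)

    df = table.df
    x, y, fr = (df["x_nm"].to_numpy(), df["y_nm"].to_numpy(),
                df["frame"].to_numpy())
    bounds = (x.min(), x.max() + render_pixel, y.min(), y.max() + render_pixel)
    renders = []
    for b in range(n_bins):
        sel = (fr >= edges[b]) & (fr < edges[b + 1])
        if sel.sum() < 1000:
            warnings.warn(
                f"drift bin {b} has only {int(sel.sum())} localizations; "
                "estimates may be noisy", stacklevel=2)
        renders.append(hist2d(x[sel], y[sel], render_pixel, bounds))

    dx = np.zeros(n_bins)
    dy = np.zeros(n_bins)
    conf = np.zeros(n_bins)
    ref = renders[reference_bin]
    for b in range(n_bins):
        if b == reference_bin:
            conf[b] = np.inf
            continue
        (sy, sx), c = xcorr_shift(ref, renders[b])
        if c < min_confidence:
            raise DriftEstimationError(
                f"correlation peak for bin {b} below confidence floor "
                f"({c:.1f} < {min_confidence}); use larger bins")
        # shifting the bin render by (sy, sx) aligns it to the reference, so
        # the bin drifted by the opposite amount
        dx[b] = -sx * render_pixel
        dy[b] = -sy * render_pixel
        conf[b] = c
    return DriftTrace(edges, dx, dy, reference_bin=reference_bin,
                      confidence=conf)


def apply_drift(table: LocalizationTable, trace: DriftTrace) -> LocalizationTable:
    """Subtract the interpolated drift offset from every localization.

    Leaves counts, photons and z untouched; a zero trace is the identity.
    """
    frames = table.df["frame"].to_numpy()
    if len(frames) and not trace.covers(frames):
        raise ValueError("drift trace does not cover the table's frame range")
    out = table.copy()
    if len(frames):
        dx, dy, dz = trace.offsets_at(frames)
        out.df["x_nm"] = out.df["x_nm"].to_numpy() - dx
        out.df["y_nm"] = out.df["y_nm"].to_numpy() - dy
        if np.any(dz != 0):
            out.df["z_nm"] = out.df["z_nm"].to_numpy() - dz
    return out


def assign_colors(table: LocalizationTable,
                  schedule: ActivationSchedule) -> LocalizationTable:
    """Color code localizations by the preceding activation pulse.

    A localization in the first imaging frame after a channel's activation
    block gets that channel; localizations in any other frame are coded
    "nonspecific". Pure function of frame index and schedule.
    """
    if table.n_frames and table.n_frames < schedule.cycle_len:
        raise ValueError("movie shorter than one schedule cycle")
    out = table.copy()
    if not len(out.df):
        return out
    slots = schedule.slot_of(out.df["frame"].to_numpy())
    channel = np.full(len(out.df), "nonspecific", dtype=object)
    for ch, s in schedule.post_activation_slot.items():
        channel[slots == s] = ch
    out.df["channel"] = channel
    return out


@dataclass
class CrosstalkEstimate:
    """Per-channel activation statistics behind the statistical subtraction."""

    apparent_specific: dict  # channel -> count in post-activation frames
    nonspecific_per_frame: float  # mean count per non-post-activation imaging frame
    actual_specific: dict  # channel -> apparent - nonspecific expectation, >= 0
    expected_crosstalk: dict  # channel -> expected false count among apparent
    cross_activation: dict = field(default_factory=dict)  # (src, dst) -> rate

    def __post_init__(self):
        for ch, app in self.apparent_specific.items():
            if self.actual_specific[ch] > app + 1e-9:
                raise ValueError("actual_specific cannot exceed apparent_specific")


def _frame_slot_counts(schedule: ActivationSchedule, n_frames: int):
    """Occurrences of each cycle slot over an n_frames movie."""
    L = schedule.cycle_len
    full, rem = divmod(n_frames, L)
    return {s: full + (1 if s < rem else 0) for s in range(L)}


def estimate_crosstalk(table: LocalizationTable, schedule: ActivationSchedule,
                       cross_activation: dict | None = None) -> CrosstalkEstimate:
    """Measure apparent-specific vs nonspecific activation counts.

    Assumes nonspecific activations occur at a constant per-frame rate:
    the rate measured in imaging frames that do not follow an activation
    pulse predicts the nonspecific contribution hiding inside each
    channel's post-activation (apparent specific) count.
    """
    other = schedule.other_imaging_slots
    if not other:
        raise ValueError(
            "cycle has no imaging frames outside the post-activation ones; "
            "the nonspecific rate cannot be estimated")
    n_frames = table.n_frames or int(table.df["frame"].max()) + 1
    slot_counts = _frame_slot_counts(schedule, n_frames)
    slots = schedule.slot_of(table.df["frame"].to_numpy())

    n_other_frames = sum(slot_counts[s] for s in other)
    n_other_locs = int(np.isin(slots, other).sum())
    rate = n_other_locs / n_other_frames if n_other_frames else 0.0

    apparent, actual, expected = {}, {}, {}
    for ch, s in schedule.post_activation_slot.items():
        app = int((slots == s).sum())
        exp_false = rate * slot_counts[s]
        apparent[ch] = app
        expected[ch] = min(exp_false, app)
        actual[ch] = max(app - exp_false, 0.0)
    return CrosstalkEstimate(apparent, rate, actual, expected,
                             dict(cross_activation or {}))


@dataclass
class CrosstalkReport:
    pre_counts: dict
    post_counts: dict
    removed: dict
    residual_fraction: dict
    seed: int


def subtract_crosstalk(table: LocalizationTable, estimate: CrosstalkEstimate,
                       seed: int = 0):
    """Statistically remove crosstalk localizations by seeded thinning.

    For each channel the expected number of false localizations (the
    nonspecific contribution to its post-activation frames, plus any
    configured wrong-laser contribution from ``estimate.cross_activation``)
    is drawn uniformly at random, without replacement, from that channel's
    localizations and removed. The expected corrected count therefore
    equals the actual-specific estimate. Returns (corrected_table, report).
    """
    rng = np.random.default_rng(seed)
    df = table.df
    drop = np.zeros(len(df), dtype=bool)
    pre, removed, resid = {}, {}, {}
    channels = df["channel"].to_numpy()
    for ch, apparent in estimate.apparent_specific.items():
        idx = np.flatnonzero(channels == ch)
        expected = estimate.expected_crosstalk.get(ch, 0.0)
        for (src, dst), rate in estimate.cross_activation.items():
            if dst == ch:
                expected += rate * estimate.actual_specific.get(src, 0.0)
        # stochastic rounding keeps the correction unbiased over seeds
        n_remove = int(np.floor(expected))
        if rng.random() < expected - n_remove:
            n_remove += 1
        if n_remove > idx.size:
            warnings.warn(
                f"channel {ch}: expected removals ({n_remove}) exceed available "
                f"localizations ({idx.size}); removing all", stacklevel=2)
            n_remove = idx.size
        if n_remove:
            drop[rng.choice(idx, size=n_remove, replace=False)] = True
        pre[ch] = int(idx.size)
        removed[ch] = int(n_remove)
        post = idx.size - n_remove
        resid[ch] = (max(expected - n_remove, 0.0) / post) if post else 0.0
    out = table.copy()
    out.df = out.df.loc[~drop].reset_index(drop=True)
    report = CrosstalkReport(
        pre_counts=pre,
        post_counts={ch: pre[ch] - removed[ch] for ch in pre},
        removed=removed, residual_fraction=resid, seed=seed)
    return out, report
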