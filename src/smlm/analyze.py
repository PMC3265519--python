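"""Rendering and the resolution calculus.

The image resolution of a localization-microscopy image combines two
independent error sources:

* localization precision — the FWHM scatter of repeated localizations of
  one emitter, set by photon statistics;
* the Nyquist sampling limit of the finite label density ``a`` (labels per
  um^d in dimension d): resolution equals twice the mean distance between
  neighboring labels,

      alpha_Nyquist = 2 / a**(1/d)            (micrometers in, nm out)

and the two are combined in quadrature:

      resolution = sqrt(alpha_Nyquist**2 + precision_FWHM**2).

Label density itself comes from localization counts divided by the region
measure and by the mean number of localizations each label contributes
(default n = 4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .psf import add_spot
from .tables import LocalizationTable

__all__ = [
    "RenderedImage", "ResolutionReport", "PrecisionEstimate",
    "render", "line_profile", "fwhm", "localization_precision",
    "label_density", "nyquist_resolution", "combined_resolution",
    "density_fold_change", "voxel_dwell_time", "channel_ratio",
    "resolution_report",
]

NM_PER_UM = 1000.0
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


class UndefinedFWHMError(ValueError):
    """Raised when a profile has no well-defined half-maximum crossings."""


@dataclass
class RenderedImage:
    """Super-resolution render: unit-volume Gaussian per localization.

    Total intensity equals the number of rendered localizations (up to
    border truncation of the Gaussian tails). ``pitch`` is (x, y) or
    (x, y, z-slice thickness) in nm; ``origin`` the nm coordinate of the
    array corner.
    """

    data: np.ndarray
    pitch: tuple
    origin: tuple
    slice_thickness_nm: float | None = None


@dataclass
class PrecisionEstimate:
    """Localization precision as FWHM per axis, from pooled cluster scatter."""

    fwhm_x_nm: float
    fwhm_y_nm: float
    fwhm_z_nm: float
    n_clusters: int

    def __post_init__(self):
        if min(self.fwhm_x_nm, self.fwhm_y_nm) < 0:
            raise ValueError("FWHM must be >= 0")
        if self.n_clusters < 10:
            raise ValueError("need >= 10 clusters for a reportable estimate")

    @property
    def fwhm_xy_nm(self) -> float:
        return 0.5 * (self.fwhm_x_nm + self.fwhm_y_nm)


@dataclass
class ResolutionReport:
    """Label density, Nyquist limit, precision, and their quadrature sum."""

    label_density: float  # labels / um^d
    dimension: int
    n_locs_per_label: float
    nyquist_nm: float
    precision_xy_nm: float
    precision_z_nm: float | None
    resolution_xy_nm: float
    resolution_z_nm: float | None

    def to_dict(self) -> dict:
        return {k: (None if v is None else float(v) if not isinstance(v, int) else v)
                for k, v in vars(self).items()}


# ---------------------------------------------------------------------------
# rendering

def render(table: LocalizationTable, pitch: float, mode: str = "2d",
           width_mode: str = "theoretical", fixed_sigma_nm: float = 10.0,
           psf_sigma_nm: float = 150.0, slice_thickness_nm: float = 100.0,
           bounds=None) -> RenderedImage:
    """Render a molecule list as a sum of unit-volume Gaussians.

    width_mode "theoretical" uses the first-order photon-limited estimate
    sigma = psf_sigma / sqrt(photons) per localization; "fixed" uses
    ``fixed_sigma_nm`` for all. In "3d" mode z is binned into slices of
    ``slice_thickness_nm`` and each slice rendered in 2D.
    """
    if pitch <= 0:
        raise ValueError("pitch must be > 0")
    df = table.df
    if not len(df):
        raise ValueError("cannot render an empty table")
    x = df["x_nm"].to_numpy()
    y = df["y_nm"].to_numpy()
    if bounds is None:
        pad = 5 * max(fixed_sigma_nm, pitch)
        bounds = (x.min() - pad, x.max() + pad, y.min() - pad, y.max() + pad)
    xmin, xmax, ymin, ymax = bounds
    nx = max(int(np.ceil((xmax - xmin) / pitch)), 1)
    ny = max(int(np.ceil((ymax - ymin) / pitch)), 1)

    if width_mode == "theoretical":
        ph = np.maximum(df["photons"].to_numpy(), 1.0)
        sig = psf_sigma_nm / np.sqrt(ph)
    elif width_mode == "fixed":
        sig = np.full(len(df), float(fixed_sigma_nm))
    else:
        raise ValueError("width_mode must be 'theoretical' or 'fixed'")
    sig_px = np.maximum(sig / pitch, 0.35)  # floor keeps kernels resolvable

    if mode == "2d":
        img = np.zeros((ny, nx))
        for xi, yi, si in zip((x - xmin) / pitch, (y - ymin) / pitch, sig_px):
            add_spot(img, xi, yi, si, si, 1.0, radius_sigmas=5.0)
        return RenderedImage(img, (pitch, pitch), (xmin, ymin))
    if mode != "3d":
        raise ValueError("mode must be '2d' or '3d'")

    z = df["z_nm"].to_numpy()
    if np.any(np.isnan(z)):
        raise ValueError("3D rendering requires z for every localization")
    zmin = np.floor(z.min() / slice_thickness_nm) * slice_thickness_nm
    nz = max(int(np.ceil((z.max() - zmin) / slice_thickness_nm)), 1)
    vol = np.zeros((nz, ny, nx))
    kz = np.minimum(((z - zmin) / slice_thickness_nm).astype(int), nz - 1)
    for xi, yi, si, zi in zip((x - xmin) / pitch, (y - ymin) / pitch, sig_px, kz):
        add_spot(vol[zi], xi, yi, si, si, 1.0, radius_sigmas=5.0)
    return RenderedImage(vol, (pitch, pitch, slice_thickness_nm),
                         (xmin, ymin, zmin), slice_thickness_nm)


# ---------------------------------------------------------------------------
# profiles

def line_profile(image: RenderedImage, start, end, width_nm: float = 0.0,
                 n_samples: int | None = None):
    """Intensity profile along a segment, averaged across ``width_nm``.

    ``start``/``end`` are (x, y) nm in the image's coordinate frame.
    Returns (distance_nm, values).
    """
    from scipy.ndimage import map_coordinates

    data = image.data
    if data.ndim != 2:
        raise ValueError("line_profile expects a 2D render")
    px, py = image.pitch[0], image.pitch[1]
    x0, y0 = start
    x1, y1 = end
    length = float(np.hypot(x1 - x0, y1 - y0))
    if length <= 0:
        raise ValueError("zero-length segment")
    if n_samples is None:
        n_samples = max(int(np.ceil(length / min(px, py))) + 1, 2)
    t = np.linspace(0.0, 1.0, n_samples)
    xs = x0 + t * (x1 - x0)
    ys = y0 + t * (y1 - y0)
    ux, uy = (x1 - x0) / length, (y1 - y0) / length
    nxv, nyv = -uy, ux  # unit normal
    if width_nm > 0:
        n_lines = max(int(np.ceil(width_nm / min(px, py))) + 1, 2)
        offs = np.linspace(-width_nm / 2, width_nm / 2, n_lines)
    else:
        offs = np.array([0.0])
    acc = np.zeros(n_samples)
    for o in offs:
        cx = (xs + o * nxv - image.origin[0]) / px - 0.5
        cy = (ys + o * nyv - image.origin[1]) / py - 0.5
        acc += map_coordinates(data, [cy, cx], order=1, mode="constant")
    # segment inside image check: corners of sampling footprint
    for o in (offs[0], offs[-1]):
        cx = (np.array([xs[0], xs[-1]]) + o * nxv - image.origin[0]) / px
        cy = (np.array([ys[0], ys[-1]]) + o * nyv - image.origin[1]) / py
        if np.any(cx < -0.5) or np.any(cx > data.shape[1] + 0.5) \
                or np.any(cy < -0.5) or np.any(cy > data.shape[0] + 0.5):
            raise ValueError("profile segment extends outside the image")
    return t * length, acc / len(offs)


def fwhm(distance, values) -> float:
    """Full width at half maximum by linear interpolation at half max.

    Raises :class:`UndefinedFWHMError` for flat/all-zero profiles or when a
    half-max crossing is missing on either side of the peak.
    """
    d = np.asarray(distance, dtype=float)
    v = np.asarray(values, dtype=float)
    vmax = v.max()
    if vmax <= 0 or np.all(v == v[0]):
        raise UndefinedFWHMError("profile has no peak; FWHM undefined")
    half = vmax / 2.0
    k = int(np.argmax(v))
    left = None
    for i in range(k, 0, -1):
        if v[i - 1] <= half <= v[i]:
            frac = (half - v[i - 1]) / (v[i] - v[i - 1])
            left = d[i - 1] + frac * (d[i] - d[i - 1])
            break
    right = None
    for i in range(k, len(v) - 1):
        if v[i + 1] <= half <= v[i]:
            frac = (v[i] - half) / (v[i] - v[i + 1])
            right = d[i] + frac * (d[i + 1] - d[i])
            break
    if left is None or right is None:
        raise UndefinedFWHMError("half-maximum crossing not found")
    return float(right - left)


# ---------------------------------------------------------------------------
# precision from single-emitter clusters

def _gaussian_fwhm_1d(samples: np.ndarray) -> float:
    """FWHM from a Gaussian fit to the histogram of centered samples."""
    if np.allclose(samples, 0.0):
        return 0.0
    sd = samples.std()
    if sd == 0:
        return 0.0
    hist, edges = np.histogram(samples, bins=max(int(np.sqrt(len(samples))), 10))
    centers = 0.5 * (edges[:-1] + edges[1:])

    def g(xv, amp, mu, sigma):
        return amp * np.exp(-0.5 * ((xv - mu) / sigma) ** 2)

    try:
        popt, _ = curve_fit(g, centers, hist, p0=[hist.max(), 0.0, sd],
                            maxfev=5000)
        sigma = abs(popt[2])
    except RuntimeError:
        sigma = sd
    return FWHM_PER_SIGMA * sigma


def localization_precision(clusters) -> PrecisionEstimate:
    """Pooled localization scatter of isolated-emitter clusters.

    ``clusters`` is a sequence of DataFrames (or LocalizationTables), one
    per isolated emitter, each with >= 5 localizations. Every cluster is
    recentered to its centroid; the pooled per-axis distributions are fit
    with Gaussians and reported as FWHM.
    """
    dfs = [c.df if isinstance(c, LocalizationTable) else c for c in clusters]
    dfs = [d for d in dfs if len(d) >= 5]
    if len(dfs) < 10:
        raise ValueError("need >= 10 clusters with >= 5 localizations each")
    cx, cy, cz = [], [], []
    for d in dfs:
        cx.append(d["x_nm"].to_numpy() - d["x_nm"].mean())
        cy.append(d["y_nm"].to_numpy() - d["y_nm"].mean())
        z = d["z_nm"].to_numpy()
        if not np.any(np.isnan(z)):
            cz.append(z - z.mean())
    x = np.concatenate(cx)
    y = np.concatenate(cy)
    fz = _gaussian_fwhm_1d(np.concatenate(cz)) if len(cz) == len(dfs) else np.nan
    return PrecisionEstimate(_gaussian_fwhm_1d(x), _gaussian_fwhm_1d(y), fz,
                             n_clusters=len(dfs))


# ---------------------------------------------------------------------------
# density / resolution calculus

def label_density(table: LocalizationTable, regions, d: int = 2,
                  n_locs_per_label: float = 4.0):
    """Label density (labels per um^d) from localization counts.

    ``regions`` is a list of (selector, measure_um) pairs: ``selector`` is
    a boolean mask over the table rows (or a callable df -> mask) and
    ``measure_um`` the region's area (um^2, d=2, data projected) or volume
    (um^3, d=3). Density per region = count / measure / n_locs_per_label.
    Returns (mean, sd, per_region) — sd is 0 for a single region.
    """
    if d not in (2, 3):
        raise ValueError("d must be 2 or 3")
    if n_locs_per_label <= 0:
        raise ValueError("n_locs_per_label must be > 0")
    regions = list(regions)
    if not regions:
        raise ValueError("empty region list")
    densities = []
    for selector, measure in regions:
        if measure <= 0:
            raise ValueError("region measure must be > 0")
        mask = selector(table.df) if callable(selector) else np.asarray(selector)
        count = int(np.sum(mask))
        densities.append(count / measure / n_locs_per_label)
    densities = np.asarray(densities, dtype=float)
    return float(densities.mean()), float(densities.std(ddof=0)), densities


def nyquist_resolution(a: float, d: int = 2) -> float:
    """Nyquist resolution limit (nm): twice the mean neighbor spacing.

    ``a`` in labels per um^d. alpha = 2 / a**(1/d) um = 2000 / a**(1/d) nm.
    """
    if a <= 0:
        raise ValueError("label density must be > 0")
    if d not in (2, 3):
        raise ValueError("d must be 2 or 3")
    return 2.0 * NM_PER_UM / a ** (1.0 / d)


def combined_resolution(nyquist_nm: float, precision_fwhm_nm: float) -> float:
    """Quadrature combination of the Nyquist limit and localization precision."""
    if nyquist_nm < 0 or precision_fwhm_nm < 0:
        raise ValueError("resolution components must be >= 0")
    return float(np.hypot(nyquist_nm, precision_fwhm_nm))


def density_fold_change(a1: float, a2: float, d: int = 2):
    """(density fold, Nyquist-resolution fold) between two label densities."""
    if a1 <= 0 or a2 <= 0:
        raise ValueError("densities must be > 0")
    fold = a1 / a2
    return fold, fold ** (1.0 / d)


def voxel_dwell_time(volume_um, voxel_pitch_um: float,
                     dwell_per_voxel_s: float) -> float:
    """Serial scan time: (number of voxels at the given pitch) x dwell.

    ``volume_um`` is (Lx, Ly, Lz) in um. Used to compare localization
    imaging against a point-scanning modality at matched resolution.
    """
    if voxel_pitch_um <= 0 or dwell_per_voxel_s <= 0:
        raise ValueError("pitch and dwell must be > 0")
    lx, ly, lz = volume_um
    if min(lx, ly, lz) < 0:
        raise ValueError("volume dimensions must be >= 0")
    n_vox = (lx / voxel_pitch_um) * (ly / voxel_pitch_um) * (lz / voxel_pitch_um)
    return float(n_vox * dwell_per_voxel_s)


def channel_ratio(table: LocalizationTable, region=None,
                  channels=("ch405", "ch457", "ch532")) -> dict:
    """Per-channel localization fractions over the specific channels.

    Nonspecific/unassigned localizations are excluded; fractions sum to 1.
    ``region`` is an optional boolean mask or callable df -> mask.
    """
    df = table.df
    if region is not None:
        mask = region(df) if callable(region) else np.asarray(region)
        df = df.loc[mask]
    counts = {ch: int((df["channel"] == ch).sum()) for ch in channels}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no specific-channel localizations in region; "
                         "channel ratio undefined")
    return {ch: c / total for ch, c in counts.items()}


def resolution_report(a: float, d: int, precision_xy_nm: float,
                      precision_z_nm: float | None = None,
                      n_locs_per_label: float = 4.0) -> ResolutionReport:
    """Assemble the full resolution report for a measured label density."""
    nyq = nyquist_resolution(a, d)
    return ResolutionReport(
        label_density=a, dimension=d, n_locs_per_label=n_locs_per_label,
        nyquist_nm=nyq,
        precision_xy_nm=precision_xy_nm, precision_z_nm=precision_z_nm,
        resolution_xy_nm=combined_resolution(nyq, precision_xy_nm),
        resolution_z_nm=(combined_resolution(nyq, precision_z_nm)
                         if precision_z_nm is not None else None))
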