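"""Raw frames -> molecule lists.

Per frame: band-pass filter (difference of Gaussians), threshold at a
robust multiple of the background noise, detect strict local maxima, fit
each candidate with a pixel-integrated Gaussian (symmetric in 2D mode,
elliptical in 3D mode), and in 3D mode look the fitted width pair up in the
astigmatism calibration to assign z.

Candidates whose fit windows overlap are both dropped: the fitter assumes
non-overlapping single-molecule images. Every dropped candidate is counted
by reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares

from .calibrate import CalibrationCurve
from .psf import pixel_integrated_gaussian
from .simulate import FrameStack
from .tables import LocalizationTable

__all__ = [
    "LocalizeParams", "FitResult",
    "filter_frame", "find_peaks", "fit_peak_2d", "fit_peak_3d",
    "assign_z", "localize_movie",
]


@dataclass(frozen=True)
class LocalizeParams:
    """Tunable knobs of the localization chain.

    ``filter_sigmas`` are the small/large Gaussian scales (px) of the
    band-pass; ``threshold_k`` multiplies the robust (MAD-based) noise sigma
    of the filtered frame; ``window`` is the square fit-window side in px
    (7 px covers about +/-3 sigma of the in-focus spot at 160 nm pixels);
    ``z_gate`` is the maximum allowed distance from the calibration curve in
    sqrt-width space (sqrt-nm units) before a 3D localization is rejected.
    """

    mode: str = "2d"  # 2d | 3d
    filter_sigmas: tuple = (1.0, 4.0)
    threshold_k: float = 5.0
    window: int = 7
    z_gate: float = 1.0
    min_photons: float = 1.0

    def __post_init__(self):
        if self.mode not in ("2d", "3d"):
            raise ValueError("mode must be '2d' or '3d'")
        if not self.filter_sigmas[0] < self.filter_sigmas[1]:
            raise ValueError("filter scales must be strictly increasing")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")


@dataclass
class FitResult:
    """One candidate's fit: positions/widths in nm relative to the ROI corner."""

    success: bool
    reason: str = ""
    x_nm: float = np.nan
    y_nm: float = np.nan
    photons: float = np.nan
    wx_nm: float = np.nan
    wy_nm: float = np.nan
    background: float = np.nan
    residual: float = np.nan


def filter_frame(frame: np.ndarray, kernel_scales=(1.0, 4.0)) -> np.ndarray:
    """Difference-of-Gaussians band-pass.

    Small-scale smoothing suppresses pixel noise; subtracting the
    large-scale blur removes slowly varying background. On a constant input
    the output is ~0 everywhere.
    """
    small, large = kernel_scales
    if not small < large:
        raise ValueError("kernel scales must be strictly increasing")
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D")
    if np.any(frame < 0):
        raise ValueError("frame must be non-negative")
    return (gaussian_filter(frame, small, mode="nearest")
            - gaussian_filter(frame, large, mode="nearest"))


def find_peaks(filtered: np.ndarray, threshold: float,
               min_separation: int = 0) -> list:
    """Strict 8-neighborhood local maxima above ``threshold``.

    Candidates closer than ``min_separation`` px (Chebyshev distance) are
    merged, keeping the brighter one. Returns [(row, col), ...].
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    a = np.asarray(filtered, dtype=float)
    pad = np.pad(a, 1, mode="constant", constant_values=-np.inf)
    center = pad[1:-1, 1:-1]
    is_max = center > threshold
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            is_max &= center > pad[1 + di:pad.shape[0] - 1 + di,
                                   1 + dj:pad.shape[1] - 1 + dj]
    rows, cols = np.nonzero(is_max)
    if rows.size == 0:
        return []
    order = np.argsort(a[rows, cols])[::-1]
    kept: list[tuple[int, int]] = []
    for k in order:
        r, c = int(rows[k]), int(cols[k])
        if min_separation > 0 and any(
            max(abs(r - r2), abs(c - c2)) < min_separation for r2, c2 in kept
        ):
            continue
        kept.append((r, c))
    kept.sort()
    return kept


def _prepare_roi(roi: np.ndarray) -> np.ndarray:
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2 or roi.shape[0] != roi.shape[1]:
        raise ValueError("ROI must be square")
    return roi


def _fit_gaussian(roi, x0, y0, pixel_size_nm, elliptical, sigma_init_px=1.2):
    ny, nx = roi.shape
    bg0 = float(np.percentile(roi, 20))
    amp0 = max(float(roi.sum() - bg0 * roi.size), 1.0)
    if elliptical:
        p0 = [x0, y0, amp0, sigma_init_px, sigma_init_px, bg0]
        lo = [-1.0, -1.0, 0.0, 0.25, 0.25, -np.inf]
        hi = [nx + 1.0, ny + 1.0, np.inf, nx, ny, np.inf]
    else:
        p0 = [x0, y0, amp0, sigma_init_px, bg0]
        lo = [-1.0, -1.0, 0.0, 0.25, -np.inf]
        hi = [nx + 1.0, ny + 1.0, np.inf, nx, np.inf]

    def model(p):
        if elliptical:
            cx, cy, amp, sx, sy, bg = p
        else:
            cx, cy, amp, sx, bg = p
            sy = sx
        return bg + amp * pixel_integrated_gaussian(ny, nx, cx, cy, sx, sy)

    res = least_squares(lambda p: (model(p) - roi).ravel(), p0,
                        bounds=(lo, hi), xtol=1e-10, ftol=1e-10)
    resid = float(np.sqrt(np.mean((model(res.x) - roi) ** 2)))
    return res, resid


def fit_peak_2d(roi: np.ndarray, initial_center=None,
                pixel_size_nm: float = 1.0, min_photons: float = 1.0) -> FitResult:
    """Symmetric Gaussian + constant background least-squares fit.

    ``initial_center`` is (x, y) in px within the ROI; the result's
    positions and width are in nm relative to the ROI corner (pass
    ``pixel_size_nm=1`` to work in pixels). Flat or non-convergent ROIs are
    rejected with a reason.
    """
    roi = _prepare_roi(roi)
    if roi.max() - roi.min() <= 0:
        return FitResult(False, "flat_roi")
    if initial_center is None:
        initial_center = (roi.shape[1] / 2.0, roi.shape[0] / 2.0)
    res, resid = _fit_gaussian(roi, *initial_center, pixel_size_nm, elliptical=False)
    if not res.success:
        return FitResult(False, "non_convergent")
    cx, cy, amp, sx, bg = res.x
    if amp < min_photons:
        return FitResult(False, "no_signal")
    return FitResult(True, "", cx * pixel_size_nm, cy * pixel_size_nm,
                     amp, sx * pixel_size_nm, sx * pixel_size_nm, bg, resid)


def fit_peak_3d(roi: np.ndarray, initial_center=None,
                pixel_size_nm: float = 1.0, min_photons: float = 1.0,
                width_bounds_nm: tuple | None = None) -> FitResult:
    """Elliptical Gaussian fit with independent x/y widths (camera axes).

    ``width_bounds_nm`` is the calibration's (min, max) width range; fits
    whose widths fall outside [0.3*min, 3*max] are rejected (ellipticity
    gate).
    """
    roi = _prepare_roi(roi)
    if roi.max() - roi.min() <= 0:
        return FitResult(False, "flat_roi")
    if initial_center is None:
        initial_center = (roi.shape[1] / 2.0, roi.shape[0] / 2.0)
    res, resid = _fit_gaussian(roi, *initial_center, pixel_size_nm, elliptical=True)
    if not res.success:
        return FitResult(False, "non_convergent")
    cx, cy, amp, sx, sy, bg = res.x
    if amp < min_photons:
        return FitResult(False, "no_signal")
    wx, wy = sx * pixel_size_nm, sy * pixel_size_nm
    if width_bounds_nm is not None:
        wmin, wmax = width_bounds_nm
        if not (0.3 * wmin <= wx <= 3.0 * wmax and 0.3 * wmin <= wy <= 3.0 * wmax):
            return FitResult(False, "ellipticity_gate")
    return FitResult(True, "", cx * pixel_size_nm, cy * pixel_size_nm,
                     amp, wx, wy, bg, resid)


def assign_z(wx, wy, curve: CalibrationCurve, gate: float = 1.0,
             grid_nm: float = 1.0):
    """Invert fitted widths into z via the calibration curve.

    Finds the z in the valid range minimizing the Euclidean distance
    between (sqrt(wx), sqrt(wy)) and (sqrt(wx(z)), sqrt(wy(z))) on a
    ``grid_nm`` grid with quadratic refinement. Returns (z, distance) for
    scalars, or arrays; off-curve pairs (distance > ``gate``) get z = NaN.
    """
    wx = np.asarray(wx, dtype=float)
    wy = np.asarray(wy, dtype=float)
    scalar = wx.ndim == 0
    wx, wy = np.atleast_1d(wx), np.atleast_1d(wy)
    if np.any(wx <= 0) or np.any(wy <= 0):
        raise ValueError("widths must be positive")
    lo, hi = curve.z_range
    zg = np.arange(lo, hi + grid_nm / 2, grid_nm)
    cwx, cwy = curve.widths_at(zg)
    swx, swy = np.sqrt(cwx), np.sqrt(cwy)
    d2 = (np.sqrt(wx)[:, None] - swx[None, :]) ** 2 \
        + (np.sqrt(wy)[:, None] - swy[None, :]) ** 2
    k = np.argmin(d2, axis=1)
    z = zg[k].astype(float)
    # quadratic refinement of the distance minimum
    interior = (k > 0) & (k < len(zg) - 1)
    if np.any(interior):
        ki = k[interior]
        idx = np.flatnonzero(interior)
        ym = d2[idx, ki - 1]
        y0 = d2[idx, ki]
        yp = d2[idx, ki + 1]
        denom = ym - 2 * y0 + yp
        shift = np.where(np.abs(denom) > 1e-30, 0.5 * (ym - yp) / np.where(denom == 0, 1, denom), 0.0)
        z[interior] += np.clip(shift, -1, 1) * grid_nm
    dist = np.sqrt(d2[np.arange(len(k)), k])
    z = np.where(dist <= gate, z, np.nan)
    if scalar:
        return float(z[0]), float(dist[0])
    return z, dist


def _robust_sigma(a: np.ndarray) -> float:
    med = np.median(a)
    return 1.4826 * float(np.median(np.abs(a - med)))


def localize_movie(stack: FrameStack, curve: CalibrationCurve | None = None,
                   params: LocalizeParams = LocalizeParams()) -> LocalizationTable:
    """Run the full per-frame chain over a movie.

    Deterministic given its inputs. The returned table's metadata carries
    per-reason rejection counts under ``"rejections"`` and the candidate
    count under ``"candidates"``.
    """
    if params.mode == "3d" and curve is None:
        raise ValueError("3D mode requires an astigmatism calibration curve")
    px = stack.pixel_size_nm
    half = params.window // 2
    width_bounds = curve.width_bounds if curve is not None else None
    rej = {"non_convergent": 0, "no_signal": 0, "flat_roi": 0,
           "ellipticity_gate": 0, "off_curve_z": 0, "border": 0, "overlap": 0}
    rows = []
    n_candidates = 0
    for f in range(stack.n_frames):
        frame = np.asarray(stack.frames[f], dtype=float)
        filt = filter_frame(frame, params.filter_sigmas)
        sigma = _robust_sigma(filt)
        if sigma <= 0:
            sigma = float(filt.std()) or 1e-12
        threshold = params.threshold_k * sigma
        peaks = find_peaks(filt, threshold, min_separation=2)
        n_candidates += len(peaks)
        # drop overlapping fit windows (both members)
        keep = []
        for i, (r, c) in enumerate(peaks):
            clash = any(
                max(abs(r - r2), abs(c - c2)) < params.window
                for j, (r2, c2) in enumerate(peaks) if j != i)
            if clash:
                rej["overlap"] += 1
            else:
                keep.append((r, c))
        for r, c in keep:
            if (r < half or c < half or r >= frame.shape[0] - half
                    or c >= frame.shape[1] - half):
                rej["border"] += 1
                continue
            roi = frame[r - half:r + half + 1, c - half:c + half + 1]
            center0 = (half + 0.5, half + 0.5)
            if params.mode == "2d":
                fit = fit_peak_2d(roi, center0, pixel_size_nm=1.0,
                                  min_photons=params.min_photons)
            else:
                fit = fit_peak_3d(roi, center0, pixel_size_nm=1.0,
                                  min_photons=params.min_photons,
                                  width_bounds_nm=(
                                      (width_bounds[0] / px, width_bounds[1] / px)
                                      if width_bounds else None))
            if not fit.success:
                rej[fit.reason] += 1
                continue
            x_nm = (c - half + fit.x_nm) * px
            y_nm = (r - half + fit.y_nm) * px
            wx_nm, wy_nm = fit.wx_nm * px, fit.wy_nm * px
            z_nm = np.nan
            if params.mode == "3d":
                z_nm, _ = assign_z(wx_nm, wy_nm, curve, gate=params.z_gate)
                if np.isnan(z_nm):
                    rej["off_curve_z"] += 1
                    continue
                z_nm += stack.focal_z_nm
            rows.append((f, x_nm, y_nm, z_nm, fit.photons, wx_nm, wy_nm,
                         fit.residual, "unassigned", stack.fov_id, stack.pass_id))

    df = pd.DataFrame(rows, columns=[
        "frame", "x_nm", "y_nm", "z_nm", "photons", "wx_nm", "wy_nm",
        "residual", "channel", "fov_id", "pass_id"])
    table = LocalizationTable(df, pixel_size_nm=px, n_frames=stack.n_frames)
    table.metadata["rejections"] = rej
    table.metadata["candidates"] = n_candidates
    table.metadata["mode"] = params.mode
    return table
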