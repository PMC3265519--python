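"""Histogram rendering and cross-correlation offset estimation.

Shared by drift correction (temporal sub-renders) and mosaic alignment
(focal planes and adjacent fields of view). Offsets are found at the
cross-correlation peak with 3-point quadratic sub-pixel interpolation per
axis; the confidence score is the peak's prominence over the correlation
background in robust-sigma units.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

__all__ = ["hist2d", "hist3d", "xcorr_shift", "xcorr_shift_1d"]


def hist2d(x, y, pixel: float, bounds) -> np.ndarray:
    """2D count histogram. ``bounds`` = (xmin, xmax, ymin, ymax) nm."""
    xmin, xmax, ymin, ymax = bounds
    nx = max(int(np.ceil((xmax - xmin) / pixel)), 1)
    ny = max(int(np.ceil((ymax - ymin) / pixel)), 1)
    h, _, _ = np.histogram2d(
        np.asarray(y, float), np.asarray(x, float), bins=(ny, nx),
        range=((ymin, ymin + ny * pixel), (xmin, xmin + nx * pixel)))
    return h


def hist3d(x, y, z, pixel_xy: float, pixel_z: float, bounds) -> np.ndarray:
    """3D count histogram (z, y, x); ``bounds`` = (xmin,xmax,ymin,ymax,zmin,zmax)."""
    xmin, xmax, ymin, ymax, zmin, zmax = bounds
    nx = max(int(np.ceil((xmax - xmin) / pixel_xy)), 1)
    ny = max(int(np.ceil((ymax - ymin) / pixel_xy)), 1)
    nz = max(int(np.ceil((zmax - zmin) / pixel_z)), 1)
    h, _ = np.histogramdd(
        np.column_stack([np.asarray(z, float), np.asarray(y, float),
                         np.asarray(x, float)]),
        bins=(nz, ny, nx),
        range=((zmin, zmin + nz * pixel_z), (ymin, ymin + ny * pixel_xy),
               (xmin, xmin + nx * pixel_xy)))
    return h


def _quadratic_peak(ym: float, y0: float, yp: float) -> float:
    denom = ym - 2.0 * y0 + yp
    if abs(denom) < 1e-30:
        return 0.0
    return float(np.clip(0.5 * (ym - yp) / denom, -1.0, 1.0))


def _confidence(c: np.ndarray, peak_val: float) -> float:
    med = np.median(c)
    mad = np.median(np.abs(c - med))
    sigma = 1.4826 * mad if mad > 0 else (c.std() or 1.0)
    return float((peak_val - med) / sigma)


def xcorr_shift(ref: np.ndarray, img: np.ndarray, smooth: float = 1.0,
                max_shift: int | None = None):
    """Sub-pixel shift (dy, dx) that moves ``img`` onto ``ref``.

    Both inputs are count histograms on the same grid. Returns
    ((dy, dx), confidence) in pixels, with the convention
    ``shift = position_in_ref - position_in_img``: translating ``img`` by
    (dy, dx) superimposes it on ``ref``.
    """
    a = np.asarray(ref, float)
    b = np.asarray(img, float)
    if smooth > 0:
        a = gaussian_filter(a, smooth)
        b = gaussian_filter(b, smooth)
    a = a - a.mean()
    b = b - b.mean()
    c = fftconvolve(a, b[::-1, ::-1], mode="full")
    if max_shift is not None:
        cy, cx = b.shape[0] - 1, b.shape[1] - 1
        mask = np.full(c.shape, -np.inf)
        y0, y1 = max(cy - max_shift, 0), min(cy + max_shift + 1, c.shape[0])
        x0, x1 = max(cx - max_shift, 0), min(cx + max_shift + 1, c.shape[1])
        mask[y0:y1, x0:x1] = 0.0
        c = c + mask
    iy, ix = np.unravel_index(np.argmax(c), c.shape)
    conf = _confidence(c[np.isfinite(c)], c[iy, ix])
    dy = float(iy - (b.shape[0] - 1))
    dx = float(ix - (b.shape[1] - 1))
    if 0 < iy < c.shape[0] - 1 and np.isfinite(c[iy - 1, ix]) and np.isfinite(c[iy + 1, ix]):
        dy += _quadratic_peak(c[iy - 1, ix], c[iy, ix], c[iy + 1, ix])
    if 0 < ix < c.shape[1] - 1 and np.isfinite(c[iy, ix - 1]) and np.isfinite(c[iy, ix + 1]):
        dx += _quadratic_peak(c[iy, ix - 1], c[iy, ix], c[iy, ix + 1])
    # peak at lag L maximizes sum(ref[n] * img[n - L]): img + L matches ref
    return (dy, dx), conf


def xcorr_shift_1d(ref: np.ndarray, sig: np.ndarray, smooth: float = 1.0):
    """Sub-pixel 1D shift moving ``sig`` onto ``ref``; see :func:`xcorr_shift`."""
    a = np.asarray(ref, float)
    b = np.asarray(sig, float)
    if smooth > 0:
        a = gaussian_filter(a, smooth)
        b = gaussian_filter(b, smooth)
    a = a - a.mean()
    b = b - b.mean()
    c = np.correlate(a, b, mode="full")
    i = int(np.argmax(c))
    conf = _confidence(c, c[i])
    d = float(i - (len(b) - 1))
    if 0 < i < len(c) - 1:
        d += _quadratic_peak(c[i - 1], c[i], c[i + 1])
    return d, conf
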