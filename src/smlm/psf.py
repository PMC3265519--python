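"""Pixel-integrated Gaussian spot model shared by simulator, fitter, renderer."""

from __future__ import annotations

import numpy as np
from scipy.special import erf

_SQRT2 = np.sqrt(2.0)

__all__ = ["pixel_integrated_gaussian", "add_spot"]


def pixel_integrated_gaussian(ny: int, nx: int, x0: float, y0: float,
                              sx: float, sy: float) -> np.ndarray:
    """Unit-volume elliptical Gaussian integrated over unit pixels.

    ``(x0, y0)`` in pixel units with pixel (0,0) spanning [0,1)x[0,1); the
    returned (ny, nx) array sums to 1 up to tail truncation at the border.
    """
    xe = np.arange(nx + 1, dtype=float)
    ye = np.arange(ny + 1, dtype=float)
    cx = 0.5 * (erf((xe - x0) / (_SQRT2 * sx)))
    cy = 0.5 * (erf((ye - y0) / (_SQRT2 * sy)))
    return np.outer(np.diff(cy), np.diff(cx))


def add_spot(frame: np.ndarray, x0: float, y0: float, sx: float, sy: float,
             photons: float, radius_sigmas: float = 4.0) -> None:
    """Accumulate ``photons`` * pixel-integrated Gaussian into ``frame`` in place.

    Only a window of +/- ``radius_sigmas`` * max(sx, sy) pixels around the
    center is touched, clipped to the frame.
    """
    ny, nx = frame.shape
    r = radius_sigmas * max(sx, sy)
    j0, j1 = max(0, int(np.floor(x0 - r))), min(nx, int(np.ceil(x0 + r)) + 1)
    i0, i1 = max(0, int(np.floor(y0 - r))), min(ny, int(np.ceil(y0 + r)) + 1)
    if j1 <= j0 or i1 <= i0:
        return
    patch = pixel_integrated_gaussian(i1 - i0, j1 - j0, x0 - j0, y0 - i0, sx, sy)
    frame[i0:i1, j0:j1] += photons * patch
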