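"""Astigmatism z-calibration.

A cylindrical lens in the emission path makes the image of a point emitter
elliptical, with the x and y Gaussian widths depending on the axial offset z
from the focal plane. Calibrating width-versus-z curves on isolated emitters
lets the localizer invert fitted widths into a z coordinate.

Widths throughout this package are Gaussian standard deviations in nm.

The default parameterization per axis is the astigmatic defocusing
polynomial

    w(z) = w0 * sqrt(1 + u**2 + A*u**3 + B*u**4),   u = (z - c) / d

where ``w0`` is the minimum width, ``c`` the axial position of that minimum,
``d`` the depth-of-focus scale, and ``A``, ``B`` higher-order corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "AxisWidthModel",
    "CalibrationCurve",
    "CalibrationError",
    "UninvertibleCalibrationError",
    "build_calibration",
    "widths_at",
    "default_astigmatic_curve",
]


class CalibrationError(ValueError):
    """Raised when a calibration cannot be built or evaluated."""


class UninvertibleCalibrationError(CalibrationError):
    """Raised when wx(z) - wy(z) is not strictly monotonic (no unique z)."""


@dataclass(frozen=True)
class AxisWidthModel:
    """Width (sigma, nm) of one camera axis as a function of z (nm)."""

    w0: float
    c: float
    d: float
    A: float = 0.0
    B: float = 0.0

    def __call__(self, z):
        u = (np.asarray(z, dtype=float) - self.c) / self.d
        arg = 1.0 + u**2 + self.A * u**3 + self.B * u**4
        return self.w0 * np.sqrt(np.maximum(arg, 1e-12))


@dataclass(frozen=True)
class CalibrationCurve:
    """Paired wx(z), wy(z) models valid over ``z_range`` (nm).

    ``z0`` is the focal crossing point where wx = wy. The signed difference
    wx(z) - wy(z) is strictly monotonic over the valid range, which
    guarantees that the width pair determines z uniquely.
    """

    wx_model: AxisWidthModel
    wy_model: AxisWidthModel
    z_range: tuple[float, float]
    z0: float
    fit_residual_nm: float = 0.0

    def __post_init__(self):
        lo, hi = self.z_range
        if not hi > lo:
            raise CalibrationError("z_range must be increasing")
        _check_invertible(self.wx_model, self.wy_model, (lo, hi))

    def widths_at(self, z):
        """Evaluate (wx, wy) in nm at axial offset ``z`` nm.

        Raises :class:`CalibrationError` if z lies outside the valid range.
        """
        z = np.asarray(z, dtype=float)
        lo, hi = self.z_range
        if np.any(z < lo) or np.any(z > hi):
            raise CalibrationError(
                f"z outside calibration valid range [{lo}, {hi}] nm"
            )
        return self.wx_model(z), self.wy_model(z)

    def contains(self, z) -> np.ndarray:
        lo, hi = self.z_range
        z = np.asarray(z, dtype=float)
        return (z >= lo) & (z <= hi)

    @property
    def width_bounds(self) -> tuple[float, float]:
        """(min, max) width over the valid range, both axes pooled."""
        z = np.linspace(*self.z_range, 257)
        w = np.concatenate([self.wx_model(z), self.wy_model(z)])
        return float(w.min()), float(w.max())

    def to_dict(self) -> dict:
        return {
            "wx": vars(self.wx_model).copy(),
            "wy": vars(self.wy_model).copy(),
            "z_range_nm": [float(self.z_range[0]), float(self.z_range[1])],
            "z0_nm": float(self.z0),
            "fit_residual_nm": float(self.fit_residual_nm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            wx_model=AxisWidthModel(**d["wx"]),
            wy_model=AxisWidthModel(**d["wy"]),
            z_range=tuple(d["z_range_nm"]),
            z0=d["z0_nm"],
            fit_residual_nm=d.get("fit_residual_nm", 0.0),
        )


def widths_at(curve: CalibrationCurve, z):
    """Module-level alias for :meth:`CalibrationCurve.widths_at`."""
    return curve.widths_at(z)


def _check_invertible(wx_model, wy_model, z_range, n=513):
    z = np.linspace(*z_range, n)
    diff = wx_model(z) - wy_model(z)
    if np.max(np.abs(diff)) < 1e-3:
        raise UninvertibleCalibrationError(
            "wx(z) = wy(z) over the whole range: no astigmatism, "
            "z-lookup is uninvertible"
        )
    ddiff = np.diff(diff)
    if not (np.all(ddiff > 0) or np.all(ddiff < 0)):
        raise UninvertibleCalibrationError(
            "wx(z) - wy(z) is not strictly monotonic over the valid range"
        )


def _crossing_point(wx_model, wy_model, z_range) -> float:
    lo, hi = z_range
    f = lambda z: float(wx_model(z) - wy_model(z))
    if f(lo) * f(hi) < 0:
        return float(brentq(f, lo, hi))
    # no sign change inside the range: closest approach
    z = np.linspace(lo, hi, 2049)
    return float(z[np.argmin(np.abs(wx_model(z) - wy_model(z)))])


def _fit_axis(z: np.ndarray, w: np.ndarray) -> AxisWidthModel:
    w0_init = float(w.min())
    c_init = float(z[np.argmin(w)])
    d_init = max((z.max() - z.min()) / 2.0, 50.0)

    def resid(p):
        return AxisWidthModel(*p)(z) - w

    res = least_squares(
        resid,
        x0=[w0_init, c_init, d_init, 0.0, 0.0],
        bounds=([1e-3, -np.inf, 1e-3, -2.0, -2.0], [np.inf, np.inf, np.inf, 2.0, 2.0]),
    )
    if not res.success:
        raise CalibrationError("axis width fit did not converge")
    return AxisWidthModel(*res.x)


def build_calibration(width_samples) -> CalibrationCurve:
    """Fit a :class:`CalibrationCurve` to measured (z, wx, wy) samples.

    Parameters
    ----------
    width_samples
        Sequence of (z_nm, wx_nm, wy_nm) triples from a z-scan of isolated
        emitters; at least 5 distinct z positions spanning more than 200 nm.

    Returns
    -------
    CalibrationCurve
        Valid range set to the sampled z interval; raises
        :class:`UninvertibleCalibrationError` when the fitted width
        difference is not strictly monotonic.
    """
    samples = np.asarray(list(width_samples), dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise CalibrationError("width_samples must be (z, wx, wy) triples")
    z, wx, wy = samples.T
    if np.unique(z).size < 5:
        raise CalibrationError("need at least 5 distinct z samples")
    span = z.max() - z.min()
    if span <= 200.0:
        raise CalibrationError(
            f"z samples span {span:.0f} nm; need > 200 nm for a usable curve"
        )
    if np.any(wx <= 0) or np.any(wy <= 0):
        raise CalibrationError("widths must be positive")

    wx_model = _fit_axis(z, wx)
    wy_model = _fit_axis(z, wy)
    z_range = (float(z.min()), float(z.max()))
    _check_invertible(wx_model, wy_model, z_range)
    z0 = _crossing_point(wx_model, wy_model, z_range)
    resid = np.concatenate([wx_model(z) - wx, wy_model(z) - wy])
    return CalibrationCurve(
        wx_model=wx_model,
        wy_model=wy_model,
        z_range=z_range,
        z0=z0,
        fit_residual_nm=float(np.sqrt(np.mean(resid**2))),
    )


def default_astigmatic_curve(
    w0: float = 150.0,
    astig_offset: float = 200.0,
    depth: float = 400.0,
    z_range: tuple[float, float] = (-400.0, 400.0),
) -> CalibrationCurve:
    """Analytic curve for a typical cylindrical-lens setup.

    The wx and wy focal planes sit at -/+ ``astig_offset`` nm so the widths
    cross at z = 0; the +/-400 nm default range matches the axial window in
    which single molecules remain detectable with this degree of
    astigmatism.
    """
    wx = AxisWidthModel(w0=w0, c=-astig_offset, d=depth)
    wy = AxisWidthModel(w0=w0, c=+astig_offset, d=depth)
    return CalibrationCurve(wx_model=wx, wy_model=wy, z_range=z_range, z0=0.0)
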