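"""Localization chain: filtering, peak finding, Gaussian fits, z lookup.

The fitters are checked against exhaustive grid-search least-squares
oracles that share nothing with the optimizer path except the spot model.
"""

import numpy as np
import pandas as pd
import pytest

from smlm.calibrate import UninvertibleCalibrationError
from smlm.localize import (LocalizeParams, assign_z, filter_frame, find_peaks,
                           fit_peak_2d, fit_peak_3d, localize_movie)
from smlm.psf import pixel_integrated_gaussian
from smlm.simulate import (ActivationSchedule, CameraModel, EmitterSet,
                           render_frames)


# ---------------------------------------------------------------------------
# oracles

def dog_oracle(frame, small, large, truncate=4.0):
    """Two-pass direct-summation difference of Gaussians with edge padding."""
    def kernel(sigma):
        r = int(truncate * sigma + 0.5)
        x = np.arange(-r, r + 1, dtype=float)
        k = np.exp(-0.5 * (x / sigma) ** 2)
        return k / k.sum()

    def conv2(img, k):
        r = len(k) // 2
        pad = np.pad(img, ((0, 0), (r, r)), mode="edge")
        rows = np.array([[np.dot(pad[i, j:j + len(k)], k)
                          for j in range(img.shape[1])]
                         for i in range(img.shape[0])])
        pad = np.pad(rows, ((r, r), (0, 0)), mode="edge")
        return np.array([[np.dot(pad[i:i + len(k), j], k)
                          for j in range(img.shape[1])]
                         for i in range(img.shape[0])])

    return conv2(frame, kernel(small)) - conv2(frame, kernel(large))


def peak_scan_oracle(filtered, threshold):
    """Exhaustive strict-8-neighborhood local-maximum scan."""
    out = []
    a = filtered
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            if a[i, j] <= threshold:
                continue
            ok = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < a.shape[0] and 0 <= jj < a.shape[1] \
                            and a[i, j] <= a[ii, jj]:
                        ok = False
            if ok:
                out.append((i, j))
    return out


def grid_search_fit_oracle(roi, x_grid, y_grid, sx_grid, sy_grid=None):
    """Least-squares optimum of the spot model on an explicit parameter grid.

    For each (x, y, sx[, sy]) the amplitude and constant background are
    solved in closed form; returns the grid point with the smallest SSE.
    Separable erf sums keep the scan fast.
    """
    d = np.asarray(roi, dtype=float)
    ny, nx = d.shape
    Sd, Sdd, n = d.sum(), (d * d).sum(), d.size
    if sy_grid is None:
        pairs = [(s, s) for s in sx_grid]
    else:
        pairs = [(sx, sy) for sx in sx_grid for sy in sy_grid]
    from scipy.special import erf
    sq2 = np.sqrt(2.0)
    xe = np.arange(nx + 1, dtype=float)
    ye = np.arange(ny + 1, dtype=float)
    best = (np.inf, None)
    for sx, sy in pairs:
        Gx = np.diff(0.5 * erf((xe[None, :] - x_grid[:, None]) / (sq2 * sx)), axis=1)
        Gy = np.diff(0.5 * erf((ye[None, :] - y_grid[:, None]) / (sq2 * sy)), axis=1)
        sgx, sgy = Gx.sum(axis=1), Gy.sum(axis=1)
        sgx2, sgy2 = (Gx**2).sum(axis=1), (Gy**2).sum(axis=1)
        Sg = np.outer(sgy, sgx)
        Sgg = np.outer(sgy2, sgx2)
        Sgd = Gy @ d @ Gx.T
        det = Sgg * n - Sg**2
        amp = (Sgd * n - Sg * Sd) / det
        bg = (Sgg * Sd - Sg * Sgd) / det
        sse = Sdd - amp * Sgd - bg * (Sd * np.ones_like(amp)) \
            - amp * bg * Sg - amp**2 * Sgg + amp**2 * Sgg  # expand below
        # SSE = Sdd - 2 amp Sgd - 2 bg Sd + amp^2 Sgg + 2 amp bg Sg + bg^2 n
        sse = (Sdd - 2 * amp * Sgd - 2 * bg * Sd + amp**2 * Sgg
               + 2 * amp * bg * Sg + bg**2 * n)
        k = np.unravel_index(np.argmin(sse), sse.shape)
        if sse[k] < best[0]:
            best = (float(sse[k]), (float(x_grid[k[1]]), float(y_grid[k[0]]),
                                    sx, sy))
    return best[1]


def make_spot(ny, nx, x0, y0, sx, sy, photons, bg):
    return bg + photons * pixel_integrated_gaussian(ny, nx, x0, y0, sx, sy)


# ---------------------------------------------------------------------------

class TestFilterFrame:
    def test_constant_image_maps_to_zero(self):
        out = filter_frame(np.full((32, 32), 500.0))
        assert np.max(np.abs(out)) < 1e-9 * 500.0

    def test_delta_spot_peaks_at_spot(self):
        img = np.zeros((32, 32))
        img[12, 20] = 100.0
        out = filter_frame(img)
        assert np.unravel_index(np.argmax(out), out.shape) == (12, 20)

    def test_matches_direct_convolution_oracle(self, rng):
        img = rng.uniform(0, 100, (32, 32))
        got = filter_frame(img, (1.0, 4.0))
        want = dog_oracle(img, 1.0, 4.0)
        assert np.max(np.abs(got - want)) < 1e-6

    def test_scales_must_increase(self):
        with pytest.raises(ValueError):
            filter_frame(np.ones((8, 8)), (3.0, 1.0))


class TestFindPeaks:
    def test_blank_frame_empty(self):
        assert find_peaks(np.zeros((16, 16)), 1.0) == []

    def test_two_separated_spots_found(self):
        img = np.zeros((32, 32))
        img[10, 10] = 5.0
        img[10, 20] = 7.0
        assert len(find_peaks(img, 1.0, min_separation=7)) == 2

    def test_close_candidates_merge_to_brighter(self):
        img = np.zeros((32, 32))
        img[10, 10] = 5.0
        img[10, 14] = 7.0
        assert find_peaks(img, 1.0, min_separation=7) == [(10, 14)]

    def test_matches_exhaustive_scan_oracle(self, rng):
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(rng.uniform(0, 10, (64, 64)), 1.5)
        thr = float(np.percentile(img, 90))
        assert find_peaks(img, thr) == sorted(peak_scan_oracle(img, thr))


class TestFit2D:
    def test_noiseless_subpixel_centroid(self):
        roi = make_spot(15, 15, 5.30, 6.70, 1.3, 1.3, 2000.0, 10.0)
        fit = fit_peak_2d(roi)
        assert fit.success
        assert fit.x_nm == pytest.approx(5.30, abs=1e-3)
        assert fit.y_nm == pytest.approx(6.70, abs=1e-3)
        assert fit.photons == pytest.approx(2000.0, rel=1e-3)

    def test_matches_grid_search_oracle_under_noise(self, rng):
        roi = rng.poisson(make_spot(16, 16, 7.8, 8.4, 1.3, 1.3, 3000.0, 20.0))
        fit = fit_peak_2d(roi.astype(float))
        step = 0.01
        ox, oy, _, _ = grid_search_fit_oracle(
            roi, np.arange(7.0, 9.0, step), np.arange(7.5, 9.5, step),
            np.arange(1.0, 1.7, 0.005))
        assert abs(fit.x_nm - ox) <= step + 1e-9
        assert abs(fit.y_nm - oy) <= step + 1e-9

    def test_zero_signal_rejected(self):
        fit = fit_peak_2d(np.full((15, 15), 7.0))
        assert not fit.success and fit.reason == "flat_roi"

    def test_reports_nm_with_pixel_size(self):
        roi = make_spot(15, 15, 7.5, 7.5, 1.3, 1.3, 2000.0, 0.0)
        fit = fit_peak_2d(roi, pixel_size_nm=160.0)
        assert fit.x_nm == pytest.approx(7.5 * 160.0, abs=0.5)
        assert fit.wx_nm == pytest.approx(1.3 * 160.0, abs=0.5)


class TestFit3D:
    def test_noiseless_width_ratio(self):
        roi = make_spot(15, 15, 7.2, 7.6, 1.4 * 1.0, 1.0, 3000.0, 5.0)
        fit = fit_peak_3d(roi)
        assert fit.success
        assert fit.wx_nm / fit.wy_nm == pytest.approx(1.4, abs=1e-3)

    def test_matches_grid_search_oracle_under_noise(self, rng):
        roi = rng.poisson(make_spot(16, 16, 8.2, 7.6, 1.5, 1.1, 4000.0, 15.0))
        fit = fit_peak_3d(roi.astype(float))
        step = 0.01
        ox, oy, _, _ = grid_search_fit_oracle(
            roi, np.arange(7.4, 9.0, step), np.arange(6.8, 8.4, step),
            np.arange(1.2, 1.8, 0.01), np.arange(0.85, 1.4, 0.01))
        assert abs(fit.x_nm - ox) <= step + 1e-9
        assert abs(fit.y_nm - oy) <= step + 1e-9

    def test_widths_outside_calibration_gate_rejected(self, curve):
        roi = make_spot(15, 15, 7.5, 7.5, 6.5, 6.5, 50000.0, 5.0)
        wmin, wmax = curve.width_bounds
        fit = fit_peak_3d(roi, pixel_size_nm=160.0,
                          width_bounds_nm=(wmin, wmax))
        assert not fit.success and fit.reason == "ellipticity_gate"


class TestAssignZ:
    def test_crossing_widths_give_z0(self, curve):
        wx, wy = curve.widths_at(curve.z0)
        z, dist = assign_z(float(wx), float(wy), curve)
        assert z == pytest.approx(curve.z0, abs=1.0)

    def test_round_trip_at_200nm(self, curve):
        wx, wy = curve.widths_at(200.0)
        z, _ = assign_z(float(wx), float(wy), curve)
        assert z == pytest.approx(200.0, abs=1.0)

    def test_far_off_curve_rejected(self, curve):
        z, dist = assign_z(600.0, 600.0, curve, gate=1.0)
        assert np.isnan(z) and dist > 1.0

    def test_uninvertible_curve_errors_at_build(self):
        from smlm.calibrate import default_astigmatic_curve

        with pytest.raises(UninvertibleCalibrationError):
            default_astigmatic_curve(astig_offset=0.0)


class TestLocalizeMovie:
    def _movie(self, curve, quiet, n_events=100, photons=5000.0, z=0.0,
               noisy=False, seed=0):
        em = EmitterSet(np.array([[1280.0, 1280.0, z]]), ["ch405"], [0])
        ev = pd.DataFrame({
            "emitter_id": np.zeros(n_events, dtype=int),
            "frame": np.arange(n_events),
            "photons": np.full(n_events, photons),
            "laser": ["ch405"] * n_events, "kind": ["specific"] * n_events})
        cam = CameraModel(background=10.0, offset=100.0, read_noise=2.0) \
            if noisy else quiet
        return render_frames(ev, em, curve, cam, n_events, (16, 16), seed=seed)

    def test_empty_movie_gives_empty_table(self, curve, quiet_camera):
        from smlm.simulate import _empty_events

        stack = render_frames(_empty_events(), EmitterSet(np.zeros((0, 3)), [], []),
                              curve, quiet_camera, 4, (16, 16), seed=0)
        table = localize_movie(stack, curve, LocalizeParams(mode="3d"))
        assert len(table) == 0

    def test_missing_calibration_in_3d_mode(self, curve, quiet_camera):
        stack = self._movie(curve, quiet_camera, n_events=2)
        with pytest.raises(ValueError, match="calibration"):
            localize_movie(stack, None, LocalizeParams(mode="3d"))

    def test_single_emitter_event_recovery_and_scatter(self, curve, quiet_camera):
        stack = self._movie(curve, quiet_camera, n_events=100, noisy=True, seed=5)
        table = localize_movie(stack, curve, LocalizeParams(mode="3d"))
        assert len(table) >= 90
        # scatter consistent with photon statistics: the shot-noise floor
        # s/sqrt(N), inflated (< ~2.5x) by background and readout noise
        sx = table.df["x_nm"].std()
        floor = float(curve.widths_at(0.0)[0]) / np.sqrt(5000.0)
        assert floor < sx < 2.5 * floor
        assert table.df["z_nm"].std() < 40.0

    def test_two_z_levels_separated(self, curve, quiet_camera):
        s1 = self._movie(curve, quiet_camera, n_events=40, z=-150.0, noisy=True, seed=1)
        s2 = self._movie(curve, quiet_camera, n_events=40, z=+150.0, noisy=True, seed=2)
        t1 = localize_movie(s1, curve, LocalizeParams(mode="3d"))
        t2 = localize_movie(s2, curve, LocalizeParams(mode="3d"))
        gap = t2.df["z_nm"].mean() - t1.df["z_nm"].mean()
        assert gap == pytest.approx(300.0, abs=30.0)


class TestFitterInvariants:
    @pytest.mark.parametrize("frac", [(0.13, 0.41), (0.5, 0.5), (0.87, 0.09),
                                      (0.31, 0.72)])
    def test_noiseless_bias_below_half_nm(self, frac):
        """Sub-pixel bias of the fitter itself, photon statistics removed."""
        x0, y0 = 7.0 + frac[0], 7.0 + frac[1]
        roi = make_spot(15, 15, x0, y0, 1.3, 1.3, 5000.0, 10.0)
        fit = fit_peak_2d(roi, pixel_size_nm=160.0)
        assert abs(fit.x_nm - x0 * 160.0) < 0.5
        assert abs(fit.y_nm - y0 * 160.0) < 0.5

    def test_precision_improves_with_photons(self, rng):
        """Localization scatter scales as 1/sqrt(N) over 500/2000/8000."""
        sigmas = []
        for photons in (500.0, 2000.0, 8000.0):
            xs = []
            for _ in range(150):
                roi = rng.poisson(
                    make_spot(15, 15, 7.5, 7.5, 1.3, 1.3, photons, 2.0))
                fit = fit_peak_2d(roi.astype(float))
                if fit.success:
                    xs.append(fit.x_nm)
            sigmas.append(np.std(xs))
        assert sigmas[0] > sigmas[1] > sigmas[2]
        assert sigmas[0] / sigmas[1] == pytest.approx(2.0, rel=0.2)
        assert sigmas[1] / sigmas[2] == pytest.approx(2.0, rel=0.2)
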