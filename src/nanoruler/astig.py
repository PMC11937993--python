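"""Astigmatic 3D calibration, spot fitting and localization-precision
estimation.

A cylindrical lens makes the PSF width along x and y depend on defocus in
opposite directions; the calibration maps z to the width pair
(wx(z), wy(z)) via the standard defocus curve

    w(z) = w0 * sqrt(1 + u^2 + A u^3 + B u^4),   u = (z - c) / d,

and z is recovered from a measured width pair by minimising the distance
in sqrt-width space (common practice for astigmatic SMLM).  Precision is
estimated by Monte Carlo: render noisy camera images of a molecule from a
spline-interpolated PSF width model at the stated photon/background
level, fit each with an elliptical Gaussian, and report the SD of the
fitted x, y and looked-up z as functions of z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq, curve_fit, minimize_scalar

__all__ = [
    "AxisParams",
    "CalibrationCurve",
    "SpotFit",
    "PrecisionProfile",
    "CameraParams",
    "defocus_width",
    "fit_calibration",
    "render_spot",
    "fit_spot",
    "z_from_widths",
    "estimate_precision",
    "default_calibration",
    "write_frames",
    "read_frames",
]


@dataclass(frozen=True)
class AxisParams:
    """Defocus-curve parameters of one lateral axis (nm)."""

    w0: float = 150.0     # focal width
    c: float = 0.0        # focal offset along z
    d: float = 400.0      # depth scale
    A: float = 0.0        # cubic correction
    B: float = 0.0        # quartic correction


def defocus_width(z, p: AxisParams):
    """Width of one PSF axis at defocus z (standard astigmatic curve)."""
    u = (np.asarray(z, dtype=float) - p.c) / p.d
    val = 1.0 + u**2 + p.A * u**3 + p.B * u**4
    return p.w0 * np.sqrt(np.clip(val, 1e-12, None))


@dataclass
class CalibrationCurve:
    """wx/wy defocus parameters with the valid z range."""

    x: AxisParams
    y: AxisParams
    z_range: tuple = (-500.0, 500.0)
    rms_residual_nm: float = 0.0

    def widths(self, z):
        return defocus_width(z, self.x), defocus_width(z, self.y)

    def crossing(self) -> float:
        """The single focus crossing wx(z) = wy(z) inside the range."""
        f = lambda z: defocus_width(z, self.x) - defocus_width(z, self.y)
        return float(brentq(f, *self.z_range))


def default_calibration(offset_nm: float = 250.0) -> CalibrationCurve:
    """Typical astigmatic calibration: the two axes focus ±offset from the
    nominal plane."""
    return CalibrationCurve(x=AxisParams(c=-offset_nm),
                            y=AxisParams(c=+offset_nm))


def fit_calibration(bead_scan, z_range_pad: float = 0.0) -> CalibrationCurve:
    """Least-squares defocus-curve fit of a bead z-scan.

    ``bead_scan``: array-like of (z, wx, wy) rows, at least 10 points.
    Raises if the scan does not bracket the focus crossing.
    """
    scan = np.asarray(bead_scan, dtype=float)
    if scan.shape[0] < 10:
        raise ValueError("bead scan needs at least 10 points")
    z, wx, wy = scan[:, 0], scan[:, 1], scan[:, 2]
    diff = wx - wy
    if diff.min() > 0 or diff.max() < 0:
        raise ValueError("bead scan does not bracket the focus crossing "
                         "(wx - wy does not change sign)")

    def model(zz, w0, c, d, A, B):
        return defocus_width(zz, AxisParams(w0, c, d, A, B))

    params = []
    resid = 0.0
    for w in (wx, wy):
        i0 = int(np.argmin(w))
        p0 = [float(w.min()), float(z[i0]), (z.max() - z.min()) / 2.0,
              0.0, 0.0]
        popt, _ = curve_fit(model, z, w, p0=p0, maxfev=20000)
        params.append(AxisParams(*popt))
        resid += float(((model(z, *popt) - w) ** 2).sum())
    rms = float(np.sqrt(resid / (2 * len(z))))
    return CalibrationCurve(x=params[0], y=params[1],
                            z_range=(float(z.min()) - z_range_pad,
                                     float(z.max()) + z_range_pad),
                            rms_residual_nm=rms)


@dataclass(frozen=True)
class CameraParams:
    """Simple camera model (pixel size in nm, photons per count = 1)."""

    pixel_nm: float = 100.0
    patch_px: int = 15
    em_excess_noise: bool = False   # EM gain ≈ doubled Poisson variance


@dataclass
class SpotFit:
    """Elliptical-Gaussian fit of one molecule image (axes fixed to the
    astigmatism axes)."""

    x_nm: float
    y_nm: float
    wx_nm: float
    wy_nm: float
    amplitude: float
    background: float
    photons: float
    residual: float
    converged: bool


def _pixel_gauss(edges, mu, sigma):
    """Integral of a 1D Gaussian over pixel bins given bin edges."""
    from scipy.special import erf
    u = (edges - mu) / (np.sqrt(2.0) * sigma)
    e = 0.5 * (1.0 + erf(u))
    return np.diff(e)


def render_spot(x_nm, y_nm, wx_nm, wy_nm, photons, background,
                camera: CameraParams, rng=None):
    """Render a pixelated molecule image; Poisson noise if rng given."""
    n = camera.patch_px
    edges = np.arange(n + 1) * camera.pixel_nm
    px = _pixel_gauss(edges, x_nm, wx_nm)
    py = _pixel_gauss(edges, y_nm, wy_nm)
    img = photons * np.outer(px, py) + background
    if rng is not None:
        if camera.em_excess_noise:
            img = 2.0 * rng.poisson(img / 2.0)
        else:
            img = rng.poisson(img).astype(float)
    return img


def fit_spot(image_patch, camera: CameraParams) -> SpotFit:
    """Least-squares elliptical-Gaussian fit of a single spot.

    Returns a flagged (non-converged) fit rather than raising when the
    optimizer fails or the patch has no usable peak.
    """
    img = np.asarray(image_patch, dtype=float)
    n = img.shape[0]
    px = camera.pixel_nm
    # image axis 0 is x (render uses outer(px_x, py_y))
    xx, yy = np.meshgrid((np.arange(n) + 0.5) * px,
                         (np.arange(n) + 0.5) * px, indexing="ij")

    bg0 = float(np.median(img))
    amp0 = float(img.max() - bg0)
    if amp0 <= 0:
        return SpotFit(np.nan, np.nan, np.nan, np.nan, 0.0, bg0, 0.0,
                       np.inf, False)
    i0, j0 = np.unravel_index(np.argmax(img), img.shape)

    def model(_, x0, y0, wx, wy, amp, bg):
        g = amp * np.exp(-((xx - x0) ** 2) / (2 * wx**2)
                         - ((yy - y0) ** 2) / (2 * wy**2)) + bg
        return g.ravel()

    p0 = [(i0 + 0.5) * px, (j0 + 0.5) * px, 1.5 * px, 1.5 * px, amp0, bg0]
    lo = [0.0, 0.0, 0.3 * px, 0.3 * px, 0.0, 0.0]
    hi = [n * px, n * px, n * px, n * px, 10 * amp0 + 10, img.max() + 1]
    try:
        popt, _ = curve_fit(model, None, img.ravel(), p0=p0,
                            bounds=(lo, hi), maxfev=5000)
    except (RuntimeError, ValueError):
        return SpotFit(np.nan, np.nan, np.nan, np.nan, amp0, bg0, 0.0,
                       np.inf, False)
    x0, y0, wx, wy, amp, bg = popt
    res = float(np.sqrt(np.mean((model(None, *popt) - img.ravel()) ** 2)))
    photons = float(2 * np.pi * amp * wx * wy / px**2)
    return SpotFit(x0, y0, wx, wy, amp, bg, photons, res, True)


def z_from_widths(wx, wy, calibration: CalibrationCurve,
                  boundary_tol_nm: float = 1.0):
    """z minimising (√wx−√wx(z))² + (√wy−√wy(z))² over the valid range.

    Returns ``(z, flagged)``; flagged means the minimum sits at the range
    boundary (the width pair is outside the calibrated regime).
    """
    swx, swy = np.sqrt(wx), np.sqrt(wy)

    def cost(z):
        mx, my = calibration.widths(z)
        return (swx - np.sqrt(mx)) ** 2 + (swy - np.sqrt(my)) ** 2

    res = minimize_scalar(cost, bounds=calibration.z_range,
                          method="bounded", options={"xatol": 1e-4})
    z = float(res.x)
    flagged = (min(z - calibration.z_range[0],
                   calibration.z_range[1] - z) < boundary_tol_nm)
    return z, flagged


def write_frames(frames, path) -> None:
    """Write synthetic camera frames as a TIFF stack (float32)."""
    import tifffile

    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32))


def read_frames(path) -> np.ndarray:
    """Read a TIFF frame stack."""
    import tifffile

    return tifffile.imread(path)


@dataclass
class PrecisionProfile:
    """Monte-Carlo localization precision vs z."""

    z_nm: np.ndarray
    sigma_x_nm: np.ndarray
    sigma_y_nm: np.ndarray
    sigma_z_nm: np.ndarray
    photons: float
    background: float
    n_repeats: int


def estimate_precision(
    calibration: CalibrationCurve,
    photons: float = 53_000.0,
    background: float = 300.0,
    z_grid=None,
    n_repeats: int = 200,
    seed=None,
    camera: Optional[CameraParams] = None,
) -> PrecisionProfile:
    """Monte-Carlo localization precision at the stated photon/background
    level.

    The PSF width model is a cubic spline through the calibration curve
    (mirroring spline-PSF practice); for each z, ``n_repeats`` noisy
    images are rendered and fitted, and the SDs of fitted x, y and of the
    width-lookup z are returned.
    """
    if n_repeats < 100:
        raise ValueError("n_repeats must be >= 100 for stable SDs")
    if camera is None:
        camera = CameraParams()
    if z_grid is None:
        z_grid = np.linspace(-300.0, 300.0, 7)
    z_grid = np.asarray(z_grid, dtype=float)
    rng = np.random.default_rng(seed)

    zs = np.linspace(*calibration.z_range, 81)
    spline_x = CubicSpline(zs, defocus_width(zs, calibration.x))
    spline_y = CubicSpline(zs, defocus_width(zs, calibration.y))

    centre = camera.patch_px * camera.pixel_nm / 2.0
    sx, sy, sz = [], [], []
    for z in z_grid:
        wx, wy = float(spline_x(z)), float(spline_y(z))
        xs, ys, zfit = [], [], []
        for _ in range(n_repeats):
            off = rng.uniform(-0.5, 0.5, 2) * camera.pixel_nm
            img = render_spot(centre + off[0], centre + off[1], wx, wy,
                              photons, background, camera, rng)
            fit = fit_spot(img, camera)
            if not fit.converged:
                continue
            xs.append(fit.x_nm - off[0])
            ys.append(fit.y_nm - off[1])
            zf, flag = z_from_widths(fit.wx_nm, fit.wy_nm, calibration)
            if not flag:
                zfit.append(zf)
        sx.append(np.std(xs, ddof=1) if len(xs) > 10 else np.nan)
        sy.append(np.std(ys, ddof=1) if len(ys) > 10 else np.nan)
        sz.append(np.std(zfit, ddof=1) if len(zfit) > 10 else np.nan)
    return PrecisionProfile(z_nm=z_grid, sigma_x_nm=np.asarray(sx),
                            sigma_y_nm=np.asarray(sy),
                            sigma_z_nm=np.asarray(sz),
                            photons=photons, background=background,
                            n_repeats=n_repeats)
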