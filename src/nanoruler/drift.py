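"""Drift estimation by redundant cross-correlation of time-windowed
reconstructions.

The acquisition is split into time windows, each window is rendered as a
histogram image (6 nm default bins), and the relative shift of every
window pair is estimated from the cross-correlation peak with sub-pixel
(quadratic) interpolation.  The per-window offsets are then solved from
the redundant pair set by weighted least squares, anchored at zero for the
first window, and interpolated linearly across frames.  Correlations are
evaluated on the xy and xz projections of the render (the marginals of the
3D correlation), which is standard SMLM practice and far cheaper than the
full 3D volume.  A fiducial-based alternative (smoothed mean path of
marked clusters) is provided for data with beacons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DriftTrajectory", "estimate_drift", "apply_drift",
           "fiducial_drift"]


@dataclass
class DriftTrajectory:
    """Per-window drift offsets (nm) with a per-frame linear interpolant."""

    window_centers: np.ndarray     # frame index of each window centre
    offsets: np.ndarray            # (n_windows, 3) nm, window 1 anchored at 0
    n_frames: int

    def at(self, frames) -> np.ndarray:
        f = np.asarray(frames, dtype=float)
        return np.column_stack([
            np.interp(f, self.window_centers, self.offsets[:, k])
            for k in range(3)])


def _render2d(u, v, bin_nm, extent):
    (u0, u1), (v0, v1) = extent
    eu = np.arange(u0, u1 + bin_nm, bin_nm)
    ev = np.arange(v0, v1 + bin_nm, bin_nm)
    h, _, _ = np.histogram2d(u, v, bins=(eu, ev))
    return h.astype(np.float32)


def _corr_shift(a, b, max_shift_bins):
    """Shift of b relative to a from the cross-correlation peak, with
    quadratic sub-pixel interpolation, searched within ±max_shift_bins."""
    fa = np.fft.rfft2(a)
    fb = np.fft.rfft2(b)
    c = np.fft.irfft2(fa * np.conj(fb), s=a.shape)
    c = np.fft.fftshift(c)
    cy, cx = np.array(c.shape) // 2
    m = max_shift_bins
    win = c[cy - m:cy + m + 1, cx - m:cx + m + 1]
    iy, ix = np.unravel_index(np.argmax(win), win.shape)

    def subpix(w, i, j, axis):
        if axis == 0:
            y0, y1, y2 = w[i - 1, j], w[i, j], w[i + 1, j]
        else:
            y0, y1, y2 = w[i, j - 1], w[i, j], w[i, j + 1]
        # log-parabola: exact for a Gaussian peak, suppresses pixel locking
        if min(y0, y1, y2) > 0:
            y0, y1, y2 = np.log(y0), np.log(y1), np.log(y2)
        denom = y0 - 2 * y1 + y2
        return 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom

    dy = iy - m + (subpix(win, iy, ix, 0)
                   if 0 < iy < 2 * m else 0.0)
    dx = ix - m + (subpix(win, iy, ix, 1)
                   if 0 < ix < 2 * m else 0.0)
    peak = float(win[iy, ix])
    return dy, dx, peak


def estimate_drift(
    table: pd.DataFrame,
    n_windows: int = 20,
    bin_nm: float = 6.0,
    max_shift_nm: float = 150.0,
    min_locs_per_window: int = 100,
    max_pair_lag: int | None = None,
    seed=None,
) -> DriftTrajectory:
    """Estimate the drift trajectory of a localization table.

    ``max_pair_lag`` limits the pair set to |i−j| ≤ lag (default: all
    pairs).  Windows with fewer than ``min_locs_per_window`` localizations
    are down-weighted with a warning.  The first window is the zero
    anchor.
    """
    frames = table["frame"].to_numpy()
    f_lo, f_hi = int(frames.min()), int(frames.max())
    if f_hi - f_lo + 1 < 2 * n_windows:
        raise ValueError(
            f"table spans {f_hi - f_lo + 1} frames; need at least "
            f"{2 * n_windows} for {n_windows} windows")
    edges = np.linspace(f_lo, f_hi + 1, n_windows + 1)
    widx = np.clip(np.searchsorted(edges, frames, side="right") - 1,
                   0, n_windows - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    x = table["x_nm"].to_numpy()
    y = table["y_nm"].to_numpy()
    z = table["z_nm"].to_numpy()
    pad = max_shift_nm
    ext_x = (x.min() - pad, x.max() + pad)
    ext_y = (y.min() - pad, y.max() + pad)
    ext_z = (z.min() - pad, z.max() + pad)

    imgs_xy, imgs_xz, counts = [], [], []
    for w in range(n_windows):
        sel = widx == w
        counts.append(int(sel.sum()))
        imgs_xy.append(_render2d(x[sel], y[sel], bin_nm, (ext_x, ext_y)))
        imgs_xz.append(_render2d(x[sel], z[sel], bin_nm, (ext_x, ext_z)))
    counts = np.array(counts)
    low = counts < min_locs_per_window
    if low.any():
        warnings.warn(f"{low.sum()} window(s) have fewer than "
                      f"{min_locs_per_window} localizations; down-weighted")

    m = int(np.ceil(max_shift_nm / bin_nm))
    rows, rhs, wts = [], [], []
    for i in range(n_windows):
        for j in range(i + 1, n_windows):
            if max_pair_lag is not None and j - i > max_pair_lag:
                continue
            dxi, dxj, pk1 = _corr_shift(imgs_xy[i], imgs_xy[j], m)
            dzy, dzx, pk2 = _corr_shift(imgs_xz[i], imgs_xz[j], m)
            # shift of window j relative to i, in nm
            shift = np.array([
                0.5 * (dxi + dzy) * bin_nm,    # x appears in both renders
                dxj * bin_nm,
                dzx * bin_nm,
            ])
            row = np.zeros(n_windows)
            row[j], row[i] = 1.0, -1.0
            w_pair = np.sqrt(min(counts[i], counts[j]))
            if low[i] or low[j]:
                w_pair *= 0.1
            rows.append(row)
            rhs.append(shift)
            wts.append(w_pair)
    A = np.asarray(rows)
    b = np.asarray(rhs)
    w = np.asarray(wts)[:, None]
    # anchor: drop the first column (offset_0 = 0)
    sol, *_ = np.linalg.lstsq(A[:, 1:] * w, b * w, rcond=None)
    offsets = np.vstack([np.zeros(3), sol])
    # the shift of window j relative to i measures -(drift_j - drift_i)
    # for structures rendered at drifted positions; see apply_drift
    return DriftTrajectory(window_centers=centers, offsets=-offsets,
                           n_frames=f_hi + 1)


def apply_drift(table: pd.DataFrame, trajectory: DriftTrajectory,
                sign: float = -1.0) -> pd.DataFrame:
    """Return a copy of the table with the drift removed
    (coordinates + sign·drift(frame); row count unchanged)."""
    out = table.copy()
    d = trajectory.at(out["frame"].to_numpy())
    out[["x_nm", "y_nm", "z_nm"]] = (
        out[["x_nm", "y_nm", "z_nm"]].to_numpy() + sign * d)
    return out


def fiducial_drift(table: pd.DataFrame, cluster_centers,
                   radius_nm: float = 150.0, n_windows: int = 50,
                   smooth: int = 3) -> DriftTrajectory:
    """Fiducial-mode drift: the smoothed mean path of user-marked
    clusters (e.g. gold beads), averaged over markers."""
    frames = table["frame"].to_numpy()
    f_lo, f_hi = int(frames.min()), int(frames.max())
    edges = np.linspace(f_lo, f_hi + 1, n_windows + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    xyz = table[["x_nm", "y_nm", "z_nm"]].to_numpy()
    paths = []
    for c in np.atleast_2d(np.asarray(cluster_centers, dtype=float)):
        near = np.linalg.norm(xyz[:, :2] - c[:2], axis=1) < radius_nm
        if near.sum() < n_windows:
            continue
        path = np.full((n_windows, 3), np.nan)
        widx = np.clip(np.searchsorted(edges, frames[near], "right") - 1,
                       0, n_windows - 1)
        for wi in range(n_windows):
            sel = widx == wi
            if sel.any():
                path[wi] = xyz[near][sel].mean(axis=0)
        # fill gaps, reference to the first window
        for k in range(3):
            good = np.isfinite(path[:, k])
            path[:, k] = np.interp(centers, centers[good], path[good, k])
        paths.append(path - path[0])
    if not paths:
        raise ValueError("no usable fiducial clusters")
    mean_path = np.mean(paths, axis=0)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        for k in range(3):
            mean_path[:, k] = np.convolve(
                np.pad(mean_path[:, k], smooth // 2, mode="edge"),
                kernel, mode="valid")[:n_windows]
    return DriftTrajectory(window_centers=centers, offsets=mean_path,
                           n_frames=f_hi + 1)
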