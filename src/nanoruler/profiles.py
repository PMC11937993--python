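"""Cross-section profiles, two-Gaussian peak fitting and distance tables.

The measurement chain follows standard SMLM morphometry practice: select a
slab (projection depth) and a stripe through the structure, histogram the
localizations along the measurement axis (6 nm default bins), fit two
Gaussian peaks plus a constant baseline by bounded quasi-Newton least
squares (L-BFGS-B), and report the peak-to-peak distance.  Ensembles are
cleaned by excluding flagged (artifact) fits and filtering outliers with
the modified Z-score (Iglewicz-Hoban constant 0.6745, threshold 3.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize
from scipy.signal import find_peaks
from sklearn.cluster import DBSCAN

from .geometry import CapsidModel, VirusGeometry, capsid_edges

__all__ = [
    "Profile",
    "TwoGaussianFit",
    "MeasurementResult",
    "profile_1d",
    "fit_two_gaussians",
    "modified_zscore_filter",
    "measure_ensemble",
    "gp24_triangle_distances",
    "capsid_center_estimate",
    "align_principal_axis",
    "tail_frame",
    "width_profile_xy",
    "width_profile_xz",
    "length_profile_xz",
    "tail_width_profile",
    "basal_width_profile",
    "tail_length_profile",
    "measure_tail_length",
]


@dataclass
class Profile:
    """1D localization histogram of a slab ∩ stripe region."""

    centers: np.ndarray
    counts: np.ndarray
    bin_nm: float
    axis: str = "x"
    slab_nm: Optional[float] = None
    stripe_nm: Optional[float] = None

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class TwoGaussianFit:
    """Two Gaussian peaks + constant baseline fitted to a profile."""

    c1: float
    c2: float
    w1: float
    w2: float
    a1: float
    a2: float
    baseline: float
    residual: float
    converged: bool
    artifact: bool = False
    note: str = ""

    @property
    def distance(self) -> float:
        return self.c2 - self.c1


@dataclass
class MeasurementResult:
    """Ensemble distance measurement with filter provenance."""

    raw: np.ndarray                 # all non-artifact per-particle distances
    kept: np.ndarray                # after modified Z-score filtering
    mean: float
    sd: float
    n: int
    n_artifact: int = 0
    dropped_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))


_AXIS = {"x": 0, "y": 1, "z": 2}


def profile_1d(
    points: np.ndarray,
    measure_axis: str = "x",
    bin_nm: float = 6.0,
    slab_axis: Optional[str] = None,
    slab_center: float = 0.0,
    slab_nm: Optional[float] = None,
    stripe_axis: Optional[str] = None,
    stripe_center: float = 0.0,
    stripe_nm: Optional[float] = None,
    extent: Optional[tuple] = None,
    pad_bins: int = 3,
) -> Profile:
    """Histogram localizations along ``measure_axis`` within an optional
    slab and stripe.  ``pad_bins`` empty bins are appended on each side so
    peaks at the data boundary remain fittable.  Raises if the selected
    region is empty."""
    pts = np.asarray(points, dtype=float)
    sel = np.ones(len(pts), dtype=bool)
    if slab_nm is not None and slab_axis is not None:
        sel &= np.abs(pts[:, _AXIS[slab_axis]] - slab_center) <= slab_nm / 2.0
    if stripe_nm is not None and stripe_axis is not None:
        sel &= np.abs(pts[:, _AXIS[stripe_axis]] - stripe_center) <= stripe_nm / 2.0
    v = pts[sel, _AXIS[measure_axis]]
    if extent is not None:
        v = v[(v >= extent[0]) & (v <= extent[1])]
    if v.size == 0:
        raise ValueError(
            f"empty profile region (axis={measure_axis}, slab={slab_axis}"
            f"@{slab_center:.0f}±{(slab_nm or 0) / 2:.0f}, "
            f"stripe={stripe_axis}@{stripe_center:.0f}"
            f"±{(stripe_nm or 0) / 2:.0f})")
    lo = (np.floor(v.min() / bin_nm) - pad_bins) * bin_nm
    edges = np.arange(lo, v.max() + (pad_bins + 1) * bin_nm, bin_nm)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_nm])
    counts, edges = np.histogram(v, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Profile(centers=centers, counts=counts.astype(float), bin_nm=bin_nm,
                   axis=measure_axis, slab_nm=slab_nm, stripe_nm=stripe_nm)


def _two_gauss(p, x):
    a1, c1, w1, a2, c2, w2, b = p
    return (b + a1 * np.exp(-0.5 * ((x - c1) / w1) ** 2)
            + a2 * np.exp(-0.5 * ((x - c2) / w2) ** 2))


def _local_moments(x, y, i, half=3):
    """Gaussian init (amplitude, centre, width) from the bins around peak i."""
    lo, hi = max(i - half, 0), min(i + half + 1, len(x))
    xs, ys = x[lo:hi], y[lo:hi]
    w = np.clip(ys - ys.min(), 0, None) + 1e-12
    c = float((xs * w).sum() / w.sum())
    var = float((w * (xs - c) ** 2).sum() / w.sum())
    return float(y[i]), c, max(np.sqrt(var), (x[1] - x[0]) / 2.0)


def _initial_params(profile: Profile) -> list:
    """Candidate parameter starts: local moments of the two highest
    well-separated maxima, plus a quantile-lobe fallback."""
    x, y = profile.centers, profile.counts
    b = profile.bin_nm
    inits = []
    smooth = gaussian_filter1d(y, 1.0)
    peaks, props = find_peaks(smooth, distance=2, height=0.05 * smooth.max())
    if len(peaks) >= 2:
        order = peaks[np.argsort(props["peak_heights"])[::-1]]
        i1 = order[0]
        for i2 in order[1:]:
            if abs(x[i2] - x[i1]) >= 2 * b:
                m1, m2 = _local_moments(x, y, i1), _local_moments(x, y, i2)
                inits.append((*m1, *m2))
                break
    cum = np.cumsum(y) / y.sum()
    ilo = int(np.searchsorted(cum, 0.12))
    ihi = int(min(np.searchsorted(cum, 0.88), len(x) - 1))
    if x[ihi] - x[ilo] >= 2 * b:
        m1, m2 = _local_moments(x, y, ilo), _local_moments(x, y, ihi)
        inits.append((*m1, *m2))
    if not inits:
        span = x[-1] - x[0]
        a = float(y.max())
        inits.append((a, x[0] + span / 4, b, a, x[-1] - span / 4, b))
    return inits


def _objective_grad(p, x, y):
    a1, c1, w1, a2, c2, w2, b = p
    u1 = (x - c1) / w1
    u2 = (x - c2) / w2
    g1 = np.exp(-0.5 * u1**2)
    g2 = np.exp(-0.5 * u2**2)
    r = b + a1 * g1 + a2 * g2 - y
    grad = np.array([
        2 * (r * g1).sum(),
        2 * (r * a1 * g1 * u1 / w1).sum(),
        2 * (r * a1 * g1 * u1**2 / w1).sum(),
        2 * (r * g2).sum(),
        2 * (r * a2 * g2 * u2 / w2).sum(),
        2 * (r * a2 * g2 * u2**2 / w2).sum(),
        2 * r.sum(),
    ])
    return float(r @ r), grad


def fit_two_gaussians(
    profile: Profile,
    bounds: Optional[Sequence] = None,
    init: Optional[Sequence] = None,
) -> TwoGaussianFit:
    """Fit two Gaussians + constant baseline by L-BFGS-B least squares.

    Initialisation uses local moments of the two dominant well-separated
    peaks (several starts; the best final objective wins).  Fits that do
    not converge, whose centers collide (closer than two bin widths) or
    that pin a center at the histogram boundary are flagged as artifacts
    and are excluded by ensemble measurements.
    """
    x, y = profile.centers, profile.counts
    if np.count_nonzero(y) < 6:
        return TwoGaussianFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                              np.nan, np.inf, False, True,
                              "fewer than 6 non-empty bins")
    b = profile.bin_nm
    span = x[-1] - x[0]
    ymax = float(y.max())
    if bounds is None:
        bounds = [(0.0, 3 * ymax), (x[0], x[-1]), (b / 3.0, span),
                  (0.0, 3 * ymax), (x[0], x[-1]), (b / 3.0, span),
                  (0.0, ymax)]

    if init is not None and len(init) == 2:
        # centers only: fill in moment-free defaults
        starts = [(ymax, float(init[0]), b, ymax, float(init[1]), b)]
    elif init is not None:
        starts = [tuple(init)]
    else:
        starts = _initial_params(profile)

    base0 = float(np.median(y))
    best = None
    for (a1, c1, w1, a2, c2, w2) in starts:
        for wscale in (1.0, 2.0):
            p0 = np.array([max(a1 - base0, 1.0), c1, w1 * wscale,
                           max(a2 - base0, 1.0), c2, w2 * wscale, base0])
            p0 = np.clip(p0, [lo for lo, _ in bounds], [hi for _, hi in bounds])
            res = minimize(_objective_grad, p0, args=(x, y), jac=True,
                           method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
    p = best.x
    if p[1] > p[4]:
        p = np.array([p[3], p[4], p[5], p[0], p[1], p[2], p[6]])
    fit = TwoGaussianFit(
        c1=float(p[1]), c2=float(p[4]), w1=float(abs(p[2])),
        w2=float(abs(p[5])), a1=float(p[0]), a2=float(p[3]),
        baseline=float(p[6]), residual=float(np.sqrt(best.fun / len(x))),
        converged=bool(best.success))
    edge = 0.51 * b
    if not fit.converged:
        fit.artifact, fit.note = True, "optimizer did not converge"
    elif fit.c2 - fit.c1 < 2 * b:
        fit.artifact, fit.note = True, "center collision"
    elif (min(fit.c1 - x[0], x[-1] - fit.c2) < edge):
        fit.artifact, fit.note = True, "center at histogram boundary"
    return fit


def modified_zscore_filter(values, threshold: float = 3.5):
    """Iglewicz-Hoban modified Z-score outlier filter.

    M_i = 0.6745 (x_i - median) / MAD; values with |M_i| > threshold are
    dropped.  If MAD = 0 all values are kept with a warning.  Returns
    ``(kept_values, kept_indices, dropped_indices)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("modified Z-score filter needs at least 3 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        warnings.warn("MAD is zero; keeping all values")
        return x.copy(), np.arange(x.size), np.empty(0, dtype=int)
    m = 0.6745 * (x - med) / mad
    keep = np.abs(m) <= threshold
    return x[keep], np.flatnonzero(keep), np.flatnonzero(~keep)


def measure_ensemble(
    clouds: Sequence[np.ndarray],
    measure_fn: Callable[[np.ndarray], TwoGaussianFit],
    zscore_threshold: float = 3.5,
    min_particles: int = 10,
) -> MeasurementResult:
    """Per-particle profile measurement over an ensemble.

    ``measure_fn`` maps one particle's localization coordinates to a
    :class:`TwoGaussianFit`; artifact fits are excluded, the surviving
    peak-to-peak distances are filtered by modified Z-score and summarised
    as mean ± SD with the retained n.
    """
    if len(clouds) < min_particles:
        raise ValueError(f"need at least {min_particles} particles, "
                         f"got {len(clouds)}")
    distances, n_artifact = [], 0
    for pts in clouds:
        try:
            fit = measure_fn(np.asarray(pts, dtype=float))
        except ValueError:
            n_artifact += 1
            continue
        if fit.artifact or not np.isfinite(fit.distance):
            n_artifact += 1
            continue
        distances.append(fit.distance)
    raw = np.asarray(distances)
    if raw.size < 3:
        raise ValueError(
            f"fewer than 3 surviving measurements ({raw.size}); "
            f"{n_artifact} artifact fits excluded")
    kept, kept_idx, dropped = modified_zscore_filter(raw, zscore_threshold)
    return MeasurementResult(
        raw=raw, kept=kept, mean=float(kept.mean()),
        sd=float(kept.std(ddof=1)), n=int(kept.size),
        n_artifact=n_artifact, dropped_indices=dropped)


# ---------------------------------------------------------------------------
# capsid / tail measurement recipes (standing particles, lab frame)


def capsid_center_estimate(points: np.ndarray,
                           capsid_length_nm: float = 120.0) -> np.ndarray:
    """Capsid-centre estimate for a standing particle: the capsid is the
    topmost ``capsid_length_nm`` of the cloud."""
    pts = np.asarray(points, dtype=float)
    z = pts[:, 2]
    L = capsid_length_nm
    # rough capsid region from the top quantile
    z0 = np.quantile(z, 0.995)
    sel = z > z0 - L
    cxy = pts[sel, :2].mean(axis=0)
    # the capsid side wall (large radius) spans the capsid z-range nearly
    # symmetrically, so its mean z is a robust centre; the tail never
    # reaches these radii and cannot drag the estimate down
    rho = np.linalg.norm(pts[:, :2] - cxy, axis=1)
    wall = sel & (rho > 20.0)
    cz = float(z[wall].mean()) if wall.sum() >= 20 else float(z[sel].mean())
    # refine with a window wide enough to cover the full wall on both
    # sides (half-length + linkage/noise margin) so no systematic cut
    # biases the mean
    for _ in range(3):
        win = (np.abs(z - cz) < L / 2.0 + 10.0) & (rho > 20.0)
        if win.sum() < 20:
            break
        cz = float(z[win].mean())
    cap = pts[np.abs(z - cz) < L / 2.0]
    # means, not medians: the x/y marginals of a hollow ring are bimodal
    # and their median is high-variance
    return np.array([cap[:, 0].mean(), cap[:, 1].mean(), cz])


def width_profile_xy(points, center=None, slab_nm=100.0, bin_nm=6.0,
                     stripe_nm=17.0) -> Profile:
    """Capsid width in the x,y projection: central z-slab (100 nm
    projection depth), cross-section stripe through the centre, histogram
    along x."""
    c = capsid_center_estimate(points) if center is None else center
    return profile_1d(points - c, "x", bin_nm, slab_axis="z", slab_nm=slab_nm,
                      stripe_axis="y" if stripe_nm else None,
                      stripe_nm=stripe_nm)


def width_profile_xz(points, center=None, slab_nm=70.0, stripe_nm=17.0,
                     bin_nm=6.0) -> Profile:
    """Capsid width in the x,z projection: central y-stripe, histogram
    along x within the central (widest) capsid z-range."""
    c = capsid_center_estimate(points) if center is None else center
    return profile_1d(points - c, "x", bin_nm, slab_axis="z", slab_nm=slab_nm,
                      stripe_axis="y", stripe_nm=stripe_nm)


def length_profile_xz(points, center=None, core_nm=17.0, bin_nm=6.0,
                      margin_nm=55.0) -> Profile:
    """Capsid length along z: central x/y core stripe, histogram along z
    across both pole walls (margin keeps the tail plateau out)."""
    c = capsid_center_estimate(points) if center is None else center
    p = np.asarray(points, dtype=float) - c
    sel = (np.abs(p[:, 0]) <= core_nm / 2.0) & (np.abs(p[:, 1]) <= core_nm / 2.0)
    return profile_1d(p[sel], "z", bin_nm, extent=(-margin_nm - 30, margin_nm + 30))


def align_principal_axis(points: np.ndarray) -> np.ndarray:
    """Rotate a particle cloud about its centroid so its principal axis is
    +z, signed so the fatter (capsid) end points up.

    A 17 nm stripe walked along a 140 nm tail is spoiled by even a few
    degrees of tilt, so tail measurements align particles first (standing
    capsid measurements stay in the lab frame).
    """
    pts = np.asarray(points, dtype=float)
    cen = pts.mean(axis=0)
    q = pts - cen
    _, vecs = np.linalg.eigh(np.cov(q.T))
    axis = vecs[:, -1]
    a = q @ axis
    perp = q - np.outer(a, axis)
    rho2 = np.einsum("ij,ij->i", perp, perp)
    hi = a > np.median(a)
    if rho2[hi].mean() < rho2[~hi].mean():   # capsid (fat) end must be +
        axis = -axis
        a = -a
    v = np.cross(axis, [0.0, 0.0, 1.0])
    s, c = np.linalg.norm(v), float(axis @ [0.0, 0.0, 1.0])
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + K + K @ K * ((1 - c) / s**2)
    return q @ R.T + cen


def tail_frame(points: np.ndarray, geometry: VirusGeometry) -> np.ndarray:
    """Axis-aligned particle coordinates with the tail on [0, tail_length]
    and the axis through (0, 0): capsid junction at z = tail_length."""
    aligned = align_principal_axis(points)
    c = capsid_center_estimate(aligned, geometry.capsid.length_nm)
    off = np.array([c[0], c[1],
                    c[2] - geometry.capsid.length_nm / 2.0
                    - geometry.tail.length_nm])
    return aligned - off


def tail_width_profile(points, geometry: VirusGeometry, stripe_nm=17.0,
                       bin_nm=6.0) -> Profile:
    """Tail tube width: central third of the tail in z, y-stripe,
    histogram along x (axis-aligned frame)."""
    L = geometry.tail.length_nm
    p = tail_frame(points, geometry)
    return profile_1d(p, "x", bin_nm, slab_axis="z", slab_center=L / 2.0,
                      slab_nm=L / 3.0, stripe_axis="y", stripe_nm=stripe_nm)


def basal_width_profile(points, geometry: VirusGeometry, stripe_nm=17.0,
                        bin_nm=6.0) -> Profile:
    """Basal-plate width: the basal tail segment, y-stripe cross-section,
    histogram along x (axis-aligned frame)."""
    t = geometry.tail
    hb = t.basal_height_nm
    p = tail_frame(points, geometry)
    return profile_1d(p, "x", bin_nm, slab_axis="z", slab_center=hb / 2.0,
                      slab_nm=hb, stripe_axis="y", stripe_nm=stripe_nm)


def tail_length_profile(points, geometry: VirusGeometry, bin_nm=6.0,
                        margin_nm=4.0) -> Profile:
    """z histogram of the tail region (axis-aligned frame).

    The radial gate follows the tail's own envelope — basal-plate radius
    over the basal segment, tube radius above — plus a margin, so the
    basal ring is included while the curved capsid bottom contributes only
    right at the junction."""
    t = geometry.tail
    L = t.length_nm
    p = tail_frame(points, geometry)
    rho = np.hypot(p[:, 0], p[:, 1])
    r_env = np.where(p[:, 2] <= t.basal_height_nm + margin_nm,
                     t.basal_width_nm / 2.0, t.width_nm / 2.0)
    sel = rho <= r_env + margin_nm
    return profile_1d(p[sel], "z", bin_nm, extent=(-36.0, L + 30.0))


def measure_tail_length(points, geometry: VirusGeometry, bin_nm=6.0,
                        margin_nm=4.0) -> TwoGaussianFit:
    """Tail length from the z-profile endpoints.

    The tail-region z-profile is a top-hat (the tube plateau dominates and
    the ends are edges, not peaks), so the two endpoint Gaussians are
    fitted to the absolute derivative of the smoothed profile — each edge
    becomes a peak at the edge centre — one constrained to the basal
    (substrate) window, one to the capsid-junction window."""
    prof = tail_length_profile(points, geometry, bin_nm, margin_nm)
    y = gaussian_filter1d(prof.counts, 1.0)
    dprof = Profile(centers=prof.centers, counts=np.abs(np.gradient(y)),
                    bin_nm=prof.bin_nm, axis="z")
    x = dprof.centers
    L = geometry.tail.length_nm
    ymax = float(dprof.counts.max())
    span = x[-1] - x[0]
    b = dprof.bin_nm
    # windows isolate the outermost edges: the basal onset (rise) and the
    # capsid-junction drop (fall); the interior edges of the basal bump
    # and the tube are excluded
    bounds = [(0.0, 3 * ymax), (x[0], 2.0), (b / 3.0, span / 4),
              (0.0, 3 * ymax), (L - 5.0, x[-1]), (b / 3.0, span / 4),
              (0.0, ymax)]
    return fit_two_gaussians(dprof, bounds=bounds)


# ---------------------------------------------------------------------------
# gp24 triangle distances


def gp24_triangle_distances(
    gp24_points: np.ndarray,
    geometry: VirusGeometry,
    rotation: Optional[np.ndarray] = None,
    translation: Optional[np.ndarray] = None,
    eps_nm: float = 20.0,
    min_samples: int = 5,
) -> dict:
    """3D centre-of-mass distances between clustered gp24 vertex clouds.

    gp24 localizations are clustered (DBSCAN, 20 nm default radius), each
    cluster's centre of mass is matched to the nearest model vertex under
    the particle's registration transform (body -> lab), and the pairwise
    3D distances are reported per edge family: ``equilateral`` (end-cap
    edges) and ``scalene_long`` (cross-ring edges of the mid-section
    triangles).
    """
    pts = np.asarray(gp24_points, dtype=float)
    labels = DBSCAN(eps=eps_nm, min_samples=min_samples).fit_predict(pts)
    coms, sizes = [], []
    for k in sorted(set(labels) - {-1}):
        sel = labels == k
        if sel.sum() >= min_samples:
            coms.append(pts[sel].mean(axis=0))
            sizes.append(int(sel.sum()))
    coms = np.asarray(coms)
    if len(coms) < 3:
        raise ValueError(f"only {len(coms)} gp24 clusters resolved (need >= 3)")

    R = np.eye(3) if rotation is None else np.asarray(rotation)
    t = np.zeros(3) if translation is None else np.asarray(translation)
    cap = geometry.capsid
    verts_body = geometry.capsid_vertices_body()
    verts_lab = verts_body @ R.T + t

    # match each cluster to its nearest model vertex; a vertex claimed by
    # two clusters means the clustering did not resolve the pentamers
    d = np.linalg.norm(coms[:, None, :] - verts_lab[None, :, :], axis=2)
    assign = d.argmin(axis=1)
    if len(set(assign.tolist())) != len(assign):
        raise ValueError("two gp24 clusters matched the same model vertex")
    vertex_of = {int(v): i for i, v in enumerate(assign)}

    edges = capsid_edges(cap)
    out = {"equilateral": [], "scalene_long": []}
    for fam, key in (("equilateral", "equilateral"), ("cross", "scalene_long")):
        for a, b in edges[fam]:
            if int(a) in vertex_of and int(b) in vertex_of:
                out[key].append(float(np.linalg.norm(
                    coms[vertex_of[int(a)]] - coms[vertex_of[int(b)]])))
    return out
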