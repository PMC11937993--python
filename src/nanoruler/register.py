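"""Rigid point-cloud registration and particle fusion.

Global registration: RANSAC over descriptor correspondences.  Each point
of the voxel-downsampled clouds gets a rotation-invariant shape-context
descriptor (the histogram of its distances to all other points); 3-point
correspondence hypotheses are screened by pairwise-distance consistency
and scored by inlier fraction after a Kabsch solve.  Local refinement:
point-to-point ICP (nearest neighbours via a k-d tree, Kabsch update),
whose RMS is non-increasing by construction of the least-squares step.

Fusion pools many registered copies of the same structure into one
high-density average, either template-free (align to an evolving average)
or model-guided (align every particle to the geometric reference cloud).
The gp24 routine augments the particle set with synthetic model particles
(removed again before pooling), mirroring guided-averaging practice for
sparse vertex labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import VirusGeometry, make_site_set, model_point_cloud, symmetry_rotations

__all__ = [
    "RigidTransform",
    "AverageParticle",
    "voxel_downsample",
    "ransac_global_registration",
    "icp_refine",
    "register",
    "fuse_particles",
    "guided_average_gp24",
    "average_measurements",
    "rotation_angle_deg",
    "symmetry_reduced_rotation_error",
]


@dataclass
class RigidTransform:
    """Rigid map x -> R @ x + t with registration quality metrics."""

    R: np.ndarray
    t: np.ndarray
    fitness: float = np.nan          # inlier fraction
    inlier_rms: float = np.nan       # nm
    success: bool = True
    rms_history: list = field(default_factory=list)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.R.T + self.t

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(R=self.R @ other.R,
                              t=self.R @ other.t + self.t)


@dataclass
class AverageParticle:
    """Pooled localization cloud of registered particles."""

    points: np.ndarray
    n_particles: int
    transforms: List[RigidTransform]
    provenance: str = "template_free"
    n_failed: int = 0


def voxel_downsample(points: np.ndarray, voxel_nm: float) -> np.ndarray:
    """Average points within cubic voxels of side ``voxel_nm``."""
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        return pts
    keys = np.floor(pts / voxel_nm).astype(np.int64)
    _, inv, counts = np.unique(keys, axis=0, return_inverse=True,
                               return_counts=True)
    sums = np.zeros((len(counts), 3))
    np.add.at(sums, inv, pts)
    return sums / counts[:, None]


def _shape_context(points: np.ndarray, n_bins: int = 12) -> np.ndarray:
    """Rotation-invariant per-point descriptor: normalized histogram of
    distances to all other points."""
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    rmax = d.max()
    edges = np.linspace(0.0, rmax + 1e-9, n_bins + 1)
    desc = np.empty((len(points), n_bins))
    for i in range(len(points)):
        h, _ = np.histogram(d[i], bins=edges)
        h[0] -= 1  # self
        desc[i] = h / max(len(points) - 1, 1)
    return desc


def _kabsch(src: np.ndarray, dst: np.ndarray):
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    S = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ S @ U.T
    return R, cd - R @ cs


def ransac_global_registration(
    source: np.ndarray,
    target: np.ndarray,
    voxel_nm: float = 8.0,
    n_iters: int = 4000,
    seed=None,
    k_candidates: int = 4,
    fitness_floor: float = 0.25,
    early_stop_fitness: float = 0.85,
) -> RigidTransform:
    """RANSAC global registration on voxel-downsampled clouds.

    Returns a transform with ``success=False`` when the best inlier
    fraction stays below ``fitness_floor`` (caller may retry with a new
    seed).
    """
    src_full = np.asarray(source, dtype=float)
    tgt_full = np.asarray(target, dtype=float)
    if len(src_full) < 50 or len(tgt_full) < 50:
        raise ValueError("registration needs at least 50 points per cloud")
    rng = np.random.default_rng(seed)
    src = voxel_downsample(src_full, voxel_nm)
    tgt = voxel_downsample(tgt_full, voxel_nm)
    dsrc = _shape_context(src)
    dtgt = _shape_context(tgt)
    # candidate correspondences: k nearest descriptors
    desc_tree = cKDTree(dtgt)
    _, cand = desc_tree.query(dsrc, k=k_candidates)
    cand = np.atleast_2d(cand)
    tgt_tree = cKDTree(tgt)
    inlier_thresh = 2.0 * voxel_nm
    n = len(src)
    best = None
    best_fit = -1.0
    for _ in range(n_iters):
        ids = rng.choice(n, 3, replace=False)
        picks = cand[ids, rng.integers(0, cand.shape[1], 3)]
        if len(set(picks.tolist())) < 3:
            continue
        a = src[ids]
        b = tgt[picks]
        ok = True
        for u, v in ((0, 1), (1, 2), (0, 2)):
            da = np.linalg.norm(a[u] - a[v])
            db = np.linalg.norm(b[u] - b[v])
            if da < 2 * voxel_nm or abs(da - db) > 1.5 * voxel_nm:
                ok = False
                break
        if not ok:
            continue
        R, t = _kabsch(a, b)
        d, _ = tgt_tree.query(src @ R.T + t, k=1,
                              distance_upper_bound=inlier_thresh)
        inl = np.isfinite(d)
        fit = inl.mean()
        if fit > best_fit:
            best_fit = fit
            rms = float(np.sqrt((d[inl] ** 2).mean())) if inl.any() else np.inf
            best = RigidTransform(R=R, t=t, fitness=fit, inlier_rms=rms)
            if fit >= early_stop_fitness:
                break
    if best is None or best_fit < fitness_floor:
        if best is None:
            best = RigidTransform(R=np.eye(3), t=np.zeros(3), fitness=0.0)
        best.success = False
    return best


def icp_refine(
    source: np.ndarray,
    target: np.ndarray,
    init: Optional[RigidTransform] = None,
    max_corr_nm: float = 20.0,
    tol: float = 1e-6,
    max_iter: int = 60,
) -> RigidTransform:
    """Point-to-point ICP from an initial transform.

    Iterates correspondence + Kabsch until the relative RMS change drops
    below ``tol``; the RMS history is recorded and is non-increasing up to
    correspondence changes (asserted in tests on synthetic data).
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    T = init if init is not None else RigidTransform(np.eye(3), np.zeros(3))
    R, t = T.R.copy(), T.t.copy()
    tree = cKDTree(tgt)
    history = []
    prev = np.inf
    for _ in range(max_iter):
        moved = src @ R.T + t
        d, idx = tree.query(moved, k=1, distance_upper_bound=max_corr_nm)
        ok = np.isfinite(d)
        if ok.sum() < 3:
            raise ValueError(
                f"ICP: no correspondences within {max_corr_nm} nm")
        rms = float(np.sqrt((d[ok] ** 2).mean()))
        history.append(rms)
        if prev - rms < tol * max(prev, 1e-12):
            break
        prev = rms
        dR, dt = _kabsch(moved[ok], tgt[idx[ok]])
        R = dR @ R
        t = dR @ t + dt
    out = RigidTransform(R=R, t=t, inlier_rms=history[-1],
                         fitness=float(ok.mean()), rms_history=history)
    return out


def register(source, target, voxel_nm=8.0, n_iters=2000, seed=None,
             max_corr_nm=None, n_starts: int = 12,
             good_rms_nm: float = 2.0) -> RigidTransform:
    """RANSAC global + ICP local registration.

    A near-symmetric particle offers many high-fitness but wrong RANSAC
    consensi, so several independent RANSAC starts are each refined by
    ICP and the result with the lowest terminal RMS wins (stopping early
    once the RMS reaches ``good_rms_nm``).
    """
    rng = np.random.default_rng(seed)
    if max_corr_nm is None:
        max_corr_nm = 3.0 * voxel_nm
    best = None
    any_success = False
    for _ in range(n_starts):
        g = ransac_global_registration(source, target, voxel_nm=voxel_nm,
                                       n_iters=n_iters,
                                       seed=int(rng.integers(2**31)))
        any_success = any_success or g.success
        if not g.success:
            continue
        try:
            refined = icp_refine(source, target, init=g,
                                 max_corr_nm=max_corr_nm)
        except ValueError:
            continue
        if best is None or refined.inlier_rms < best.inlier_rms:
            best = refined
        if best.inlier_rms <= good_rms_nm:
            break
    if best is None:
        best = RigidTransform(np.eye(3), np.zeros(3), fitness=0.0,
                              success=False)
    else:
        best.success = any_success
    return best


def rotation_angle_deg(R: np.ndarray) -> float:
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


def symmetry_reduced_rotation_error(
    R_est: np.ndarray,
    R_true: np.ndarray,
    symmetry: Optional[Sequence[np.ndarray]] = None,
) -> float:
    """Smallest rotation angle between estimate and truth over the model
    symmetry group (5-fold about the virus axis by default): transforms
    differing by a symmetry rotation are physically equivalent."""
    if symmetry is None:
        symmetry = symmetry_rotations(5)
    best = np.inf
    for S in symmetry:
        best = min(best, rotation_angle_deg(R_est @ S @ R_true.T))
    return best


def fuse_particles(
    clouds: Sequence[np.ndarray],
    reference: str = "evolving_average",
    model_cloud: Optional[np.ndarray] = None,
    n_rounds: int = 2,
    voxel_nm: float = 8.0,
    n_iters: int = 3000,
    seed=None,
    max_fail_frac: float = 0.5,
    n_starts: int = 6,
    good_rms_nm: float = 7.5,
) -> AverageParticle:
    """Particle fusion: register every cloud into a common frame and pool.

    ``reference="evolving_average"``: template-free — initialize with the
    first cloud, align all, pool, then re-align everyone to the (down-
    sampled) pooled average for ``n_rounds`` rounds.
    ``reference="model"``: align every cloud to ``model_cloud``.
    Aborts when more than ``max_fail_frac`` of alignments fail.
    """
    if len(clouds) < 10:
        raise ValueError("fusion needs at least 10 particle clouds")
    rng = np.random.default_rng(seed)
    clouds = [np.asarray(c, dtype=float) for c in clouds]

    if reference == "model":
        if model_cloud is None:
            raise ValueError("model mode needs model_cloud")
        ref = np.asarray(model_cloud, dtype=float)
        rounds = 1
    elif reference == "evolving_average":
        ref = clouds[0] - clouds[0].mean(axis=0)
        rounds = max(1, n_rounds)
    else:
        raise ValueError(f"unknown reference mode {reference!r}")

    transforms: List[RigidTransform] = []
    for _ in range(rounds):
        transforms = []
        moved = []
        n_failed = 0
        for c in clouds:
            try:
                T = register(c, ref, voxel_nm=voxel_nm, n_iters=n_iters,
                             seed=int(rng.integers(2**31)),
                             n_starts=n_starts, good_rms_nm=good_rms_nm)
            except ValueError:
                T = RigidTransform(np.eye(3), np.zeros(3), success=False)
            if not T.success:
                n_failed += 1
                transforms.append(T)
                continue
            transforms.append(T)
            moved.append(T.apply(c))
        if n_failed > max_fail_frac * len(clouds):
            raise RuntimeError(
                f"fusion aborted: {n_failed}/{len(clouds)} alignments failed")
        pooled = np.vstack(moved)
        if reference == "evolving_average":
            ref = voxel_downsample(pooled, voxel_nm / 2.0)
    return AverageParticle(points=pooled, n_particles=len(clouds) - n_failed,
                           transforms=transforms,
                           provenance=("model_guided" if reference == "model"
                                       else "template_free"),
                           n_failed=n_failed)


def guided_average_gp24(
    gp24_clouds: Sequence[np.ndarray],
    capsid_clouds: Sequence[np.ndarray],
    geometry: VirusGeometry,
    augment_frac: float = 0.1,
    model_points: int = 1500,
    gp24_model_locs_per_site: int = 15,
    jitter_nm: float = 3.0,
    voxel_nm: float = 8.0,
    n_iters: int = 3000,
    seed=None,
) -> AverageParticle:
    """Model-guided averaging of paired (gp24, whole-capsid) channels.

    The particle set is augmented with ``ceil(augment_frac · n)`` synthetic
    model particles (capsid surface + gp24 vertex clouds) that stabilise
    the guided alignment of sparse gp24 labels; capsid channels drive the
    registration to the geometric model, the transforms are applied to the
    gp24 channels, and the model particles are removed before pooling.
    """
    if len(gp24_clouds) != len(capsid_clouds):
        raise ValueError("gp24 and capsid channels must be paired")
    n = len(gp24_clouds)
    rng = np.random.default_rng(seed)
    n_aug = int(np.ceil(augment_frac * n)) if augment_frac > 0 else 0

    cap_list = [np.asarray(c, dtype=float) for c in capsid_clouds]
    gp_list = [np.asarray(c, dtype=float) for c in gp24_clouds]
    gp24_sites = make_site_set(geometry, "gp24").positions
    for k in range(n_aug):
        mc = model_point_cloud(geometry, model_points, include_tail=False,
                               seed=int(rng.integers(2**31)))
        gp = np.repeat(gp24_sites, gp24_model_locs_per_site, axis=0)
        gp = gp + rng.normal(0.0, jitter_nm, gp.shape)
        cap_list.append(mc)
        gp_list.append(gp)

    ref = model_point_cloud(geometry, 4000, include_tail=False, seed=0)
    fused = fuse_particles(cap_list, reference="model", model_cloud=ref,
                           voxel_nm=voxel_nm, n_iters=n_iters, seed=seed)
    pooled_gp = []
    kept = 0
    for i in range(n):                      # real particles only
        T = fused.transforms[i]
        if not T.success:
            continue
        pooled_gp.append(T.apply(gp_list[i]))
        kept += 1
    if not pooled_gp:
        raise RuntimeError("guided gp24 averaging: no particle aligned")
    return AverageParticle(points=np.vstack(pooled_gp), n_particles=kept,
                           transforms=fused.transforms[:n],
                           provenance="model_guided+augmented",
                           n_failed=n - kept)


def average_measurements(average: AverageParticle,
                         bin_nm: float = 6.0,
                         slice_nm: float = 17.0) -> dict:
    """Width and length of an averaged capsid cloud by the 17 nm slice /
    17 nm stripe two-Gaussian procedure (xy for width, xz for length)."""
    from .profiles import fit_two_gaussians, profile_1d

    pts = np.asarray(average.points, dtype=float)
    c = pts.mean(axis=0)
    p = pts - c
    width_prof = profile_1d(p, "x", bin_nm, slab_axis="z", slab_nm=slice_nm,
                            stripe_axis="y", stripe_nm=slice_nm)
    length_prof = profile_1d(p, "z", bin_nm, slab_axis="y", slab_nm=slice_nm,
                             stripe_axis="x", stripe_nm=slice_nm)
    return {"width": fit_two_gaussians(width_prof),
            "length": fit_two_gaussians(length_prof)}
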