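"""Parametric 3D model of the T4 bacteriophage.

The capsid is modelled at two levels that share one parameter set:

* a 12-vertex prolate icosahedral *frame* (two poles plus two skewed
  pentagonal rings) whose 20 triangular faces split into ten equilateral
  end-cap triangles and ten scalene mid-section triangles.  The frame
  carries the protein site sets (gp24 pentamers at eleven vertices, the
  Hoc/Soc face lattices) and the triangle-edge measurements.
* a rounded *envelope* — a surface of revolution with the same width and
  length: a cylinder spanning the inter-ring mid-section capped by
  ellipsoidal end caps reaching the poles — used for surface (whole-virus)
  labelling and for registration reference clouds.  Cryo-EM shows the
  capsid edges are rounded; sampling the faceted frame instead is
  available via ``envelope="faceted"``.

The tail is a coaxial cylinder with a wider basal-plate segment at the
substrate end.  Coordinate convention: the virus axis is +z, the tail
points towards -z, the substrate is the plane z = 0.  A standing particle
therefore has its tail on [0, tail_length] and its capsid centre at
``tail_length + capsid_length / 2`` (≈ 200 nm for the default T4
parameters).  All lengths are in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "GeometryError",
    "CapsidModel",
    "TailModel",
    "SiteSet",
    "VirusGeometry",
    "build_capsid",
    "build_tail",
    "default_geometry",
    "make_site_set",
    "model_point_cloud",
    "capsid_edges",
    "symmetry_rotations",
    "write_xyz",
    "read_xyz",
]

SIN36 = np.sin(np.deg2rad(36.0))


class GeometryError(ValueError):
    """Raised when a requested virus geometry cannot be constructed."""


@dataclass(frozen=True)
class CapsidModel:
    """Prolate icosahedral capsid frame.

    ``vertices`` are in a capsid-centred frame (axis = z, centre = origin);
    vertex 0 is the top pole, 1-5 the upper ring, 6-10 the lower ring and
    11 the bottom (tail) pole.
    """

    vertices: np.ndarray          # (12, 3)
    faces: np.ndarray             # (20, 3) int indices
    width_nm: float               # target transverse diameter
    length_nm: float              # pole-to-pole distance
    edge_eq_nm: float             # equilateral end-cap edge
    edge_cross_nm: tuple          # the two cross-ring edge targets
    skew_deg: float               # inter-ring skew angle
    solve_residual_nm: float      # LSQ residual of the cross-chord solve
    tail_vertex_index: int = 11

    @property
    def ring_radius_nm(self) -> float:
        return float(np.hypot(self.vertices[1, 0], self.vertices[1, 1]))

    @property
    def ring_z_nm(self) -> float:
        """Axial position of the upper vertex ring (= envelope cylinder
        half-height)."""
        return float(self.vertices[1, 2])

    @property
    def cap_height_nm(self) -> float:
        """Axial height of an envelope end cap (ring to pole)."""
        return self.length_nm / 2.0 - self.ring_z_nm

    def envelope_radius(self, z) -> np.ndarray:
        """Transverse radius of the rounded envelope at axial position z
        (capsid-centred frame): constant over the mid-section, ellipsoidal
        over the end caps."""
        z = np.asarray(z, dtype=float)
        a = self.width_nm / 2.0
        c = self.ring_z_nm
        h = self.cap_height_nm
        u = np.clip((np.abs(z) - c) / h, 0.0, 1.0)
        return a * np.sqrt(1.0 - u**2)

    def envelope_normal(self, points: np.ndarray) -> np.ndarray:
        """Outward unit normal of the rounded envelope.

        For points on or near the frame surface this is the direction an
        antibody label protrudes along: cylindrical at the mid-section
        (and at the vertex rings), turning axial towards the poles.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        a = self.width_nm / 2.0
        c = self.ring_z_nm
        h = self.cap_height_nm
        rho = np.hypot(p[:, 0], p[:, 1])
        # gradient of the implicit surface (rho/a)^2 + ((|z|-c)_+/h)^2 = 1
        n = np.column_stack([p[:, 0], p[:, 1], np.zeros(len(p))]) / a**2
        on_cap = np.abs(p[:, 2]) > c
        zc = np.where(p[:, 2] > 0, c, -c)
        n[on_cap, 2] = (p[on_cap, 2] - zc[on_cap]) / h**2
        degenerate = (rho == 0) & ~on_cap
        n[degenerate] = [0.0, 0.0, 1.0]
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        n = n / norm
        return n if np.asarray(points).ndim == 2 else n[0]


@dataclass(frozen=True)
class TailModel:
    """Tail (neck + tube + basal plate) as coaxial cylinders."""

    length_nm: float          # full tail length including the neck
    width_nm: float           # central tube diameter
    basal_width_nm: float     # basal plate diameter
    basal_fraction: float     # axial fraction occupied by the basal plate
    attachment: np.ndarray    # capsid pole point the tail hangs from (body frame)

    @property
    def basal_height_nm(self) -> float:
        return self.basal_fraction * self.length_nm


@dataclass
class SiteSet:
    """A set of labelled-protein positions (body frame) with outward normals."""

    name: str
    positions: np.ndarray                    # (n, 3)
    normals: np.ndarray                      # (n, 3) unit vectors
    group_labels: Optional[np.ndarray] = None  # e.g. face or vertex index

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class VirusGeometry:
    """Capsid + tail assembled in the body frame (substrate z = 0)."""

    capsid: CapsidModel
    tail: TailModel

    @property
    def capsid_center_z(self) -> float:
        return self.tail.length_nm + self.capsid.length_nm / 2.0

    @property
    def total_length_nm(self) -> float:
        return self.tail.length_nm + self.capsid.length_nm

    def capsid_vertices_body(self) -> np.ndarray:
        v = self.capsid.vertices.copy()
        v[:, 2] += self.capsid_center_z
        return v


def _chord(dphi_deg: float, ring_sep: float, ring_radius: float) -> float:
    """Length of the chord between ring vertices separated axially by
    ``ring_sep`` and azimuthally by ``dphi_deg``."""
    dphi = np.deg2rad(dphi_deg)
    return float(np.sqrt(ring_sep**2 + 2.0 * ring_radius**2 * (1.0 - np.cos(dphi))))


def build_capsid(
    width_nm: float = 86.0,
    length_nm: float = 120.0,
    edge_eq_nm: float = 50.0,
    edge_cross_nm: tuple = (70.0, 73.0),
    width_tol_nm: float = 1.0,
) -> CapsidModel:
    """Construct the 12-vertex prolate icosahedral capsid frame.

    The end-cap geometry is fixed exactly by ``edge_eq_nm`` (ring radius
    R = edge/(2 sin 36°), pole height h = sqrt(edge² - R²)); the inter-ring
    skew angle is then solved numerically so the two families of cross-ring
    chords best match ``edge_cross_nm`` in least squares.  ``width_nm`` is
    treated as a target: construction fails if the resulting vertex
    diameter 2R differs from it by more than ``width_tol_nm`` (published
    cryo-EM roundings of the edge lengths and the width are independent).
    """
    if min(width_nm, length_nm, edge_eq_nm, *edge_cross_nm) <= 0:
        raise GeometryError("all capsid dimensions must be positive")
    if edge_eq_nm >= width_nm:
        raise GeometryError(
            f"equilateral edge ({edge_eq_nm} nm) must be smaller than the "
            f"capsid width ({width_nm} nm)"
        )
    R = edge_eq_nm / (2.0 * SIN36)
    if abs(2.0 * R - width_nm) > width_tol_nm:
        raise GeometryError(
            f"vertex diameter 2R = {2 * R:.2f} nm from edge_eq = {edge_eq_nm} nm "
            f"is incompatible with the target width {width_nm} nm "
            f"(tolerance {width_tol_nm} nm)"
        )
    h2 = edge_eq_nm**2 - R**2
    if h2 <= 0:
        raise GeometryError(
            f"equilateral edge {edge_eq_nm} nm does not exceed the ring "
            f"radius {R:.2f} nm; end caps are unsolvable"
        )
    h = float(np.sqrt(h2))
    d = length_nm - 2.0 * h
    if d <= 0:
        raise GeometryError(
            f"ring separation {d:.2f} nm ≤ 0: capsid too short for the "
            f"requested end caps (2h = {2 * h:.2f} nm)"
        )

    e1, e2 = float(edge_cross_nm[0]), float(edge_cross_nm[1])

    def objective(alpha: float) -> float:
        return (_chord(alpha, d, R) - e1) ** 2 + (_chord(72.0 - alpha, d, R) - e2) ** 2

    res = minimize_scalar(objective, bounds=(1e-6, 72.0 - 1e-6), method="bounded",
                          options={"xatol": 1e-10})
    alpha = float(res.x)
    residual = float(np.sqrt(res.fun))

    # vertices: top pole, upper ring, lower ring, bottom (tail) pole
    phi_u = np.deg2rad(72.0 * np.arange(5))
    phi_l = np.deg2rad(72.0 * np.arange(5) + alpha)
    verts = np.zeros((12, 3))
    verts[0] = (0.0, 0.0, length_nm / 2.0)
    verts[1:6, 0] = R * np.cos(phi_u)
    verts[1:6, 1] = R * np.sin(phi_u)
    verts[1:6, 2] = d / 2.0
    verts[6:11, 0] = R * np.cos(phi_l)
    verts[6:11, 1] = R * np.sin(phi_l)
    verts[6:11, 2] = -d / 2.0
    verts[11] = (0.0, 0.0, -length_nm / 2.0)

    faces = []
    for i in range(5):
        j = (i + 1) % 5
        faces.append((0, 1 + i, 1 + j))        # top cap
        faces.append((11, 6 + i, 6 + j))       # bottom cap
    for i in range(5):
        j = (i + 1) % 5
        # mid-section: each face has one ring edge and two cross-ring edges
        faces.append((1 + i, 1 + j, 6 + i))
        faces.append((6 + i, 6 + j, 1 + j))

    return CapsidModel(
        vertices=verts,
        faces=np.asarray(faces, dtype=int),
        width_nm=float(width_nm),
        length_nm=float(length_nm),
        edge_eq_nm=float(edge_eq_nm),
        edge_cross_nm=(e1, e2),
        skew_deg=alpha,
        solve_residual_nm=residual,
    )


def build_tail(
    length_nm: float = 140.0,
    width_nm: float = 24.0,
    basal_width_nm: float = 50.0,
    basal_fraction: float = 0.15,
    attachment: Optional[np.ndarray] = None,
) -> TailModel:
    """Construct the tail model (tube + basal plate, axis collinear with +z)."""
    if min(length_nm, width_nm, basal_width_nm) <= 0:
        raise GeometryError("all tail dimensions must be positive")
    if basal_width_nm < width_nm:
        raise GeometryError(
            f"basal plate diameter ({basal_width_nm} nm) cannot be smaller "
            f"than the tube diameter ({width_nm} nm)"
        )
    if not 0.0 < basal_fraction < 1.0:
        raise GeometryError("basal_fraction must lie in (0, 1)")
    if attachment is None:
        attachment = np.array([0.0, 0.0, length_nm])
    return TailModel(
        length_nm=float(length_nm),
        width_nm=float(width_nm),
        basal_width_nm=float(basal_width_nm),
        basal_fraction=float(basal_fraction),
        attachment=np.asarray(attachment, dtype=float),
    )


def default_geometry() -> VirusGeometry:
    """The default T4 geometry: 86 x 120 nm capsid with 50/70/73 nm edges,
    140 x 24 nm tail with a 50 nm basal plate."""
    return VirusGeometry(capsid=build_capsid(), tail=build_tail())


# ---------------------------------------------------------------------------
# topology helpers


def capsid_edges(model: CapsidModel) -> dict:
    """Classify the unique frame edges.

    Returns index-pair arrays: ``equilateral`` — the 20 end-cap edges (pole
    to ring and within-ring chords, all equal to edge_eq); ``cross`` — the
    20 inter-ring edges of the scalene mid-section triangles (the "long"
    scalene sides, alternating between the two cross-chord lengths).
    """
    eq, cross = set(), set()
    ring = set(range(1, 11))
    for f in model.faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            e = (min(a, b), max(a, b))
            if a in ring and b in ring and (a <= 5) != (b <= 5):
                cross.add(e)
            elif a in (0, 11) or b in (0, 11) or (a in ring and b in ring):
                eq.add(e)
    # within-ring chords that only bound mid faces are still equilateral edges
    return {
        "equilateral": np.array(sorted(eq), dtype=int),
        "cross": np.array(sorted(cross), dtype=int),
    }


def symmetry_rotations(n: int = 5, include_flip: bool = False) -> list:
    """Rotation matrices of the capsid symmetry group about the body z axis.

    ``include_flip`` adds the axis-flip elements (the capsid envelope alone
    is also invariant under z -> -z composed with an in-plane rotation; the
    tail breaks that symmetry, so the default is the C5 subgroup).
    """
    mats = []
    for k in range(n):
        c, s = np.cos(2 * np.pi * k / n), np.sin(2 * np.pi * k / n)
        mats.append(np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]]))
    if include_flip:
        flip = np.diag([1.0, -1.0, -1.0])
        mats += [m @ flip for m in list(mats)]
    return mats


# ---------------------------------------------------------------------------
# surface sampling

_ENVELOPE_GRID = 4096


def _envelope_z_density(model: CapsidModel):
    """z grid and surface-area weights dA = 2 pi r sqrt(1 + r'^2) dz of the
    rounded envelope (surface of revolution)."""
    L = model.length_nm
    z = np.linspace(-L / 2, L / 2, _ENVELOPE_GRID + 1)
    zm = 0.5 * (z[:-1] + z[1:])
    r = model.envelope_radius(zm)
    dr = np.gradient(model.envelope_radius(z), z)
    drm = 0.5 * (dr[:-1] + dr[1:])
    w = 2 * np.pi * r * np.sqrt(1.0 + drm**2) * np.diff(z)
    return zm, np.diff(z), w


def _capsid_surface_area(model: CapsidModel) -> float:
    _, _, w = _envelope_z_density(model)
    return float(w.sum())


def _sample_capsid_rounded(model: CapsidModel, n: int, rng) -> tuple:
    """Uniform samples (+ outward normals) on the rounded envelope,
    capsid-centred frame."""
    zm, dz, w = _envelope_z_density(model)
    idx = rng.choice(len(zm), size=n, p=w / w.sum())
    z = zm[idx] + rng.uniform(-0.5, 0.5, n) * dz[idx]
    r = model.envelope_radius(z)
    phi = rng.uniform(0, 2 * np.pi, n)
    p = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return p, model.envelope_normal(p)


def _triangle_areas(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    p0, p1, p2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)


def _sample_capsid_faceted(model: CapsidModel, n: int, rng) -> tuple:
    """Uniform samples (+ face normals) on the polyhedral frame surface."""
    verts, faces = model.vertices, model.faces
    areas = _triangle_areas(verts, faces)
    counts = rng.multinomial(n, areas / areas.sum())
    pts, nrm = [], []
    for f, m in zip(faces, counts):
        if m == 0:
            continue
        p0, p1, p2 = verts[f[0]], verts[f[1]], verts[f[2]]
        u, v = rng.uniform(size=m), rng.uniform(size=m)
        flip = u + v > 1
        u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
        pts.append(p0 + np.outer(u, p1 - p0) + np.outer(v, p2 - p0))
        nvec = np.cross(p1 - p0, p2 - p0)
        centroid = (p0 + p1 + p2) / 3.0
        if np.dot(nvec, centroid) < 0:
            nvec = -nvec
        nvec = nvec / np.linalg.norm(nvec)
        nrm.append(np.tile(nvec, (m, 1)))
    return np.vstack(pts), np.vstack(nrm)


def _tail_components(tail: TailModel) -> list:
    """(area, sampler) pairs for the tail surface, body frame."""
    rt, rb = tail.width_nm / 2.0, tail.basal_width_nm / 2.0
    hb, L = tail.basal_height_nm, tail.length_nm
    comps = []

    def cyl(radius, z0, z1):
        def f(m, rng):
            phi = rng.uniform(0, 2 * np.pi, m)
            z = rng.uniform(z0, z1, m)
            p = np.column_stack([radius * np.cos(phi), radius * np.sin(phi), z])
            nv = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(m)])
            return p, nv
        return f

    comps.append((2 * np.pi * rt * (L - hb), cyl(rt, hb, L)))       # tube side
    comps.append((2 * np.pi * rb * hb, cyl(rb, 0.0, hb)))           # basal side

    if rb > rt:
        # baseplate top face: rim annulus (the hub is occupied by the tube
        # exit).  The substrate face is not labelable: it is pressed
        # against the coverslip for a standing particle.
        def annulus(m, rng):
            phi = rng.uniform(0, 2 * np.pi, m)
            r = np.sqrt(rng.uniform(rt**2, rb**2, m))
            p = np.column_stack([r * np.cos(phi), r * np.sin(phi),
                                 np.full(m, float(hb))])
            return p, np.tile([0.0, 0.0, 1.0], (m, 1))
        comps.append((np.pi * (rb**2 - rt**2), annulus))
    return comps


def sample_surface(
    geometry: VirusGeometry,
    n: int,
    rng,
    include_tail: bool = True,
    envelope: str = "rounded",
) -> tuple:
    """``n`` uniform surface samples (+ outward normals) in the body frame."""
    cap = geometry.capsid
    if envelope == "faceted":
        A_capsid = float(_triangle_areas(cap.vertices, cap.faces).sum())
    elif envelope == "rounded":
        A_capsid = _capsid_surface_area(cap)
    else:
        raise GeometryError(f"unknown envelope {envelope!r}")
    comps = [(A_capsid, None)]
    if include_tail:
        comps += _tail_components(geometry.tail)
    areas = np.array([a for a, _ in comps])
    counts = rng.multinomial(n, areas / areas.sum())
    pts, nrm = [], []
    m = counts[0]
    if m:
        if envelope == "rounded":
            p, nv = _sample_capsid_rounded(cap, m, rng)
        else:
            p, nv = _sample_capsid_faceted(cap, m, rng)
        p = p + np.array([0.0, 0.0, geometry.capsid_center_z])
        pts.append(p)
        nrm.append(nv)
    for (area, sampler), m in zip(comps[1:], counts[1:]):
        if m:
            p, nv = sampler(m, rng)
            pts.append(p)
            nrm.append(nv)
    if not pts:
        return np.empty((0, 3)), np.empty((0, 3))
    return np.vstack(pts), np.vstack(nrm)


# ---------------------------------------------------------------------------
# site sets


def _hex_lattice_on_face(p0, p1, p2, spacing) -> np.ndarray:
    """Triangular lattice with nearest-neighbour distance ``spacing``,
    centred on the face centroid and clipped to the face."""
    e1 = p1 - p0
    e2 = p2 - p0
    u = e1 / np.linalg.norm(e1)
    nvec = np.cross(e1, e2)
    w = np.cross(nvec / np.linalg.norm(nvec), u)
    centroid = (p0 + p1 + p2) / 3.0
    a1 = spacing * u
    a2 = spacing * (0.5 * u + (np.sqrt(3) / 2.0) * w)
    extent = int(np.ceil(max(np.linalg.norm(e1), np.linalg.norm(e2)) / spacing)) + 2
    ij = np.mgrid[-extent:extent + 1, -extent:extent + 1].reshape(2, -1).T
    cand = centroid + ij[:, :1] * a1 + ij[:, 1:2] * a2
    # barycentric clip
    v0, v1 = e2, e1
    v2 = cand - p0
    d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
    d20, d21 = v2 @ v0, v2 @ v1
    denom = d00 * d11 - d01 * d01
    a = (d11 * d20 - d01 * d21) / denom
    b = (d00 * d21 - d01 * d20) / denom
    keep = (a >= -1e-9) & (b >= -1e-9) & (a + b <= 1 + 1e-9)
    return cand[keep]


def make_site_set(
    geometry: VirusGeometry,
    name: str,
    params: Optional[dict] = None,
    seed: Optional[int] = None,
) -> SiteSet:
    """Build a labelled-protein site set on the virus (body frame).

    Supported names: ``gp24`` (11 vertex pentamer sites — absent at the
    tail vertex), ``hoc`` / ``soc`` (idealised per-face triangular lattice,
    default 14 nm spacing), ``fibritin`` (6 whisker anchors on the neck
    circle) and ``whole_virus`` (uniform surface samples at an areal
    density, emulating polyclonal whole-phage labelling).
    """
    params = dict(params or {})
    cap = geometry.capsid
    z0 = geometry.capsid_center_z
    shift = np.array([0.0, 0.0, z0])

    if name == "gp24":
        idx = np.array([i for i in range(12) if i != cap.tail_vertex_index])
        pos_cap = cap.vertices[idx]
        normals = cap.envelope_normal(pos_cap)
        return SiteSet(name, pos_cap + shift, normals, group_labels=idx)

    if name in ("hoc", "soc"):
        spacing = float(params.get("spacing_nm", 14.0))
        pts, labels = [], []
        for fi, f in enumerate(cap.faces):
            p = _hex_lattice_on_face(cap.vertices[f[0]], cap.vertices[f[1]],
                                     cap.vertices[f[2]], spacing)
            pts.append(p)
            labels.append(np.full(len(p), fi))
        pos = np.vstack(pts)
        normals = cap.envelope_normal(pos)
        return SiteSet(name, pos + shift, normals,
                       group_labels=np.concatenate(labels))

    if name == "fibritin":
        r = geometry.tail.width_nm / 2.0
        ang = np.deg2rad(60.0 * np.arange(6))
        pos = np.column_stack([r * np.cos(ang), r * np.sin(ang),
                               np.full(6, geometry.tail.length_nm)])
        normals = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)])
        return SiteSet(name, pos, normals, group_labels=np.arange(6))

    if name == "whole_virus":
        density = float(params.get("density_per_nm2", 0.01))
        tail_density = float(params.get("tail_density_per_nm2", density))
        include_tail = bool(params.get("include_tail", True))
        envelope = params.get("envelope", "rounded")
        rng = np.random.default_rng(seed)
        area_capsid = _capsid_surface_area(cap)
        n_capsid = int(round(density * area_capsid))
        pos_list, nrm_list = [], []
        if n_capsid:
            p, nv = sample_surface(geometry, n_capsid, rng,
                                   include_tail=False, envelope=envelope)
            pos_list.append(p)
            nrm_list.append(nv)
        if include_tail:
            comps = _tail_components(geometry.tail)
            areas = np.array([a for a, _ in comps])
            n_tail = int(round(tail_density * areas.sum()))
            if n_tail:
                counts = rng.multinomial(n_tail, areas / areas.sum())
                for (a, sampler), m in zip(comps, counts):
                    if m:
                        p, nv = sampler(m, rng)
                        pos_list.append(p)
                        nrm_list.append(nv)
        if not pos_list:
            return SiteSet(name, np.empty((0, 3)), np.empty((0, 3)))
        return SiteSet(name, np.vstack(pos_list), np.vstack(nrm_list))

    raise GeometryError(f"unknown site-set name {name!r}")


def model_point_cloud(
    geometry: VirusGeometry,
    n_points: int,
    include_tail: bool = True,
    seed: Optional[int] = None,
    envelope: str = "rounded",
) -> np.ndarray:
    """Reference point cloud: ``n_points`` uniform samples on the model
    surface (body frame).  Deterministic for a fixed seed."""
    if n_points <= 0:
        raise GeometryError("n_points must be positive")
    rng = np.random.default_rng(seed)
    pts, _ = sample_surface(geometry, n_points, rng,
                            include_tail=include_tail, envelope=envelope)
    return pts


# ---------------------------------------------------------------------------
# XYZ import/export (hook for externally derived reference clouds)


def write_xyz(points: np.ndarray, path) -> None:
    """Write a point cloud as whitespace-delimited x y z text (nm)."""
    np.savetxt(path, np.asarray(points, dtype=float), fmt="%.4f",
               header="x_nm y_nm z_nm")


def read_xyz(path) -> np.ndarray:
    """Read a delimited XYZ text file (nm); comment lines start with '#'."""
    pts = np.loadtxt(path, comments="#", ndmin=2)
    if pts.shape[1] < 3:
        raise GeometryError(f"{path}: expected at least three columns (x y z)")
    return pts[:, :3]
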