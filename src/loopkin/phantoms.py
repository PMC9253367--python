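"""Synthetic bent-tube heart phantoms with known geometry, cells and deformation.

The phantom emulates a C-looping heart tube over four pseudo-time points: a
bilayer myocardial shell swept along a circular-arc centerline whose bend,
twist and global growth increase with time.  Because the deforming map is
analytic, every downstream quantity has a known ground truth: surface point
clouds, template/true meshes, packed ellipsoidal cells with prescribed volume
and anisotropy distributions (including a spatial volume gradient toward the
outer curvature), deformation gradients and their Jacobians.

Material coordinates are (theta, s, rho): circumferential angle, centerline
arc position in [0, L] and radial position within the wall, all at the
reference (time-point-1) scale.  The time-t map applies a global growth
factor, bends the centerline into an arc, and twists the circumferential
coordinate linearly along the tube.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fitting import PointCloud, tube_mesh_from_rings
from .hermite import HermiteMesh

__all__ = [
    "PhantomSpec",
    "PhantomTimePoint",
    "map_material",
    "inverse_map",
    "true_mesh",
    "landmark_points",
    "azimuth_landmark",
    "local_frame",
    "template_from_landmarks",
    "fit_time_point",
    "estimate_tube_radius",
    "sample_point_cloud",
    "generate_cells",
    "cell_table_at_time",
    "rasterize",
    "true_deformation_gradient",
    "true_jacobian",
    "bin_material_points",
    "generate_series",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions of the synthetic looping-heart series.

    Defaults mirror the scale of an HH10-12 chick heart tube: ~1 mm long,
    ~150 um outer radius, a two-cell-thick wall, thousands of myocardial
    cells with volumes in the 10-700 um^3 range and anisotropy 0.5-0.95,
    imaged at 0.24 um isotropic voxels.  Bends/twists/growth per time point
    drive the known deformation between the four stages.
    """

    seed: int = 0
    radius: float = 150.0          # outer radius, um
    wall_thickness: float = 25.0   # um
    length: float = 1000.0         # centerline arc length, um
    bend_angles: tuple = (0.0, 30.0, 60.0, 90.0)   # deg per time point
    twist_angles: tuple = (0.0, 10.0, 20.0, 30.0)  # deg per time point
    growth_scales: tuple = (1.0, 1.05, 1.10, 1.15)
    n_cells: int = 2000
    cell_volume_median: float = 80.0   # um^3, lognormal median
    cell_volume_sigma: float = 0.8     # lognormal sigma (log scale)
    cell_volume_range: tuple = (10.0, 700.0)
    anisotropy_range: tuple = (0.5, 0.95)
    volume_gradient: float = 0.3   # log-amplitude of the outer-curvature volume gradient
    voxel_size: float = 0.24       # um
    n_cloud_points: int = 5000
    cloud_noise_sigma: float = 0.5  # um

    @property
    def r_inner(self) -> float:
        return self.radius - self.wall_thickness

    @property
    def n_time_points(self) -> int:
        return len(self.bend_angles)

    @classmethod
    def desk(cls, **overrides) -> "PhantomSpec":
        """Reduced-scale phantom for voxel-level work (fits small grids)."""
        base = dict(
            radius=18.0, wall_thickness=8.0, length=90.0, n_cells=260,
            cell_volume_median=30.0, cell_volume_sigma=0.45,
            cell_volume_range=(8.0, 120.0), voxel_size=0.5,
            n_cloud_points=2000,
        )
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# The deforming map
# ---------------------------------------------------------------------------

def _bend_params(spec: PhantomSpec, t: int):
    g = spec.growth_scales[t]
    B = np.deg2rad(spec.bend_angles[t])
    T = np.deg2rad(spec.twist_angles[t])
    return g, B, T


def map_material(spec: PhantomSpec, t: int, m: np.ndarray) -> np.ndarray:
    """World position of material points m = (theta, s, rho), vectorized."""
    m = np.atleast_2d(np.asarray(m, dtype=float))
    theta, s, rho = m[:, 0], m[:, 1], m[:, 2]
    g, B, T = _bend_params(spec, t)
    thetap = theta + T * s / spec.length
    rp = g * rho
    if abs(B) < 1e-12:
        x = np.column_stack([rp * np.cos(thetap), rp * np.sin(thetap), g * s])
        return x
    Rc = g * spec.length / B
    phi = B * s / spec.length
    cx, cz = Rc * (1.0 - np.cos(phi)), Rc * np.sin(phi)
    # in-plane radial frame vector n1 and out-of-plane n2 = +y
    n1x, n1z = np.cos(phi), -np.sin(phi)
    px = cx + rp * np.cos(thetap) * n1x
    py = rp * np.sin(thetap)
    pz = cz + rp * np.cos(thetap) * n1z
    return np.column_stack([px, py, pz])


def inverse_map(spec: PhantomSpec, t: int, x: np.ndarray) -> np.ndarray:
    """Material coordinates (theta, s, rho) of world points at time t."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    g, B, T = _bend_params(spec, t)
    if abs(B) < 1e-12:
        s = x[:, 2] / g
        rho = np.hypot(x[:, 0], x[:, 1]) / g
        thetap = np.arctan2(x[:, 1], x[:, 0])
    else:
        Rc = g * spec.length / B
        phi = np.arctan2(x[:, 2], Rc - x[:, 0])
        s = phi * spec.length / B
        cx, cz = Rc * (1.0 - np.cos(phi)), Rc * np.sin(phi)
        n1x, n1z = np.cos(phi), -np.sin(phi)
        d = x - np.column_stack([cx, np.zeros(len(x)), cz])
        comp1 = d[:, 0] * n1x + d[:, 2] * n1z
        comp2 = d[:, 1]
        rho = np.hypot(comp1, comp2) / g
        thetap = np.arctan2(comp2, comp1)
    theta = np.mod(thetap - T * s / spec.length, 2.0 * np.pi)
    return np.column_stack([theta, s, rho])


def _map_jacobian(spec: PhantomSpec, t: int, m: np.ndarray,
                  h=(1e-6, 1e-4, 1e-4)) -> np.ndarray:
    """d(world)/d(material) by central differences, (N, 3, 3)."""
    m = np.atleast_2d(np.asarray(m, dtype=float))
    J = np.empty((len(m), 3, 3))
    for k in range(3):
        dm = np.zeros(3)
        dm[k] = h[k]
        J[:, :, k] = (map_material(spec, t, m + dm) -
                      map_material(spec, t, m - dm)) / (2 * h[k])
    return J


def true_deformation_gradient(spec: PhantomSpec, t_ref: int, t_def: int,
                              m: np.ndarray) -> np.ndarray:
    """Analytic F of the t_ref -> t_def map at material points, (N, 3, 3)."""
    J0 = _map_jacobian(spec, t_ref, m)
    J1 = _map_jacobian(spec, t_def, m)
    return J1 @ np.linalg.inv(J0)


def true_jacobian(spec: PhantomSpec, t_ref: int, t_def: int,
                  m: np.ndarray) -> np.ndarray:
    return np.linalg.det(true_deformation_gradient(spec, t_ref, t_def, m))


def local_frame(spec: PhantomSpec, t: int, theta, s):
    """Orthonormal (circumferential, longitudinal, radial) frame, (N, 3, 3).

    Columns are unit vectors; computed from the map Jacobian at mid-wall so
    cell orientations co-rotate with the tissue.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    s = np.atleast_1d(np.asarray(s, dtype=float))
    rho = np.full_like(theta, 0.5 * (spec.radius + spec.r_inner))
    m = np.column_stack([theta, s, rho])
    J = _map_jacobian(spec, t, m)
    circ = J[:, :, 0] / np.linalg.norm(J[:, :, 0], axis=1, keepdims=True)
    rad = J[:, :, 2] / np.linalg.norm(J[:, :, 2], axis=1, keepdims=True)
    lon = np.cross(rad, circ)
    lon /= np.linalg.norm(lon, axis=1, keepdims=True)
    # re-orthogonalize circ against rad
    circ = np.cross(lon, rad)
    return np.stack([circ, lon, rad], axis=2)


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

def _ring_frames(spec: PhantomSpec, t: int, n_rings: int):
    s = np.linspace(0.0, spec.length, n_rings)
    g, B, T = _bend_params(spec, t)
    if abs(B) < 1e-12:
        centers = np.column_stack([np.zeros(n_rings), np.zeros(n_rings), g * s])
        tangents = np.tile([0.0, 0.0, 1.0], (n_rings, 1))
        normals = np.tile([1.0, 0.0, 0.0], (n_rings, 1))
    else:
        Rc = g * spec.length / B
        phi = B * s / spec.length
        centers = np.column_stack(
            [Rc * (1 - np.cos(phi)), np.zeros(n_rings), Rc * np.sin(phi)])
        tangents = np.column_stack([np.sin(phi), np.zeros(n_rings), np.cos(phi)])
        normals = np.column_stack([np.cos(phi), np.zeros(n_rings), -np.sin(phi)])
    twist = T * s / spec.length
    return centers, tangents, normals, twist, g


def true_mesh(spec: PhantomSpec, t: int, n_circ: int = 4,
              n_long: int = 6) -> HermiteMesh:
    """Ground-truth mesh: node rings on the material lattice mapped by time t.

    Element/node numbering is identical at all time points, so material
    correspondence between meshes is by shared (element, xi).
    """
    centers, tangents, normals, twist, g = _ring_frames(spec, t, n_long + 1)
    return tube_mesh_from_rings(centers, tangents, normals,
                                g * spec.radius, g * spec.r_inner,
                                n_circ, twist=twist)


def landmark_points(spec: PhantomSpec, t: int, n: int = 3) -> np.ndarray:
    """Centerline landmark points (cranial, interior, caudal attachments)."""
    s = np.linspace(0.0, spec.length, n)
    m = np.column_stack([np.zeros(n), s, np.zeros(n)])
    return map_material(spec, t, m)


def azimuth_landmark(spec: PhantomSpec, t: int) -> np.ndarray:
    """Surface landmark marking material theta = 0 at the caudal end."""
    return map_material(spec, t, np.array([[0.0, 0.0, spec.radius]]))[0]


def fit_time_point(spec: PhantomSpec, t: int, cloud: "PointCloud" = None,
                   cfg=None, n_circ: int = 4, n_long: int = 6,
                   cloud_seed: int = None):
    """Landmark-initialized template fit of one phantom time point.

    Convenience wrapper for the standard pipeline: sample (or take) the
    surface cloud, build the template from the centerline and azimuth
    landmarks with the cloud-estimated radius, and run the regularized fit.
    Returns the :class:`~loopkin.fitting.MeshFitResult`.
    """
    from .fitting import FitConfig, fit_mesh

    if cloud is None:
        cloud = sample_point_cloud(
            spec, t, seed=spec.seed + 100 + t if cloud_seed is None else cloud_seed)
    lm = landmark_points(spec, t)
    r = estimate_tube_radius(cloud, lm)
    tmpl = template_from_landmarks(
        lm, r, spec.wall_thickness * spec.growth_scales[t],
        n_circ=n_circ, n_long=n_long,
        azimuth_point=azimuth_landmark(spec, t))
    return fit_mesh(cloud, tmpl, cfg or FitConfig())


def _circle_through_3pts(p0, p1, p2):
    """Center, radius and plane basis of the circle through three 3D points."""
    v1, v2 = p1 - p0, p2 - p0
    nrm = np.cross(v1, v2)
    n_norm = np.linalg.norm(nrm)
    if n_norm < 1e-9 * max(np.linalg.norm(v1), 1.0):
        return None  # collinear
    nrm = nrm / n_norm
    # solve |c - p0|^2 = |c - p1|^2 = |c - p2|^2 with c in the plane
    A = np.array([2 * v1, 2 * v2, nrm])
    b = np.array([v1 @ v1, v2 @ v2, 0.0])
    c = p0 + np.linalg.solve(A, b)
    return c, float(np.linalg.norm(p0 - c)), nrm


def template_from_landmarks(landmarks: np.ndarray, radius: float,
                            wall_thickness: float, n_circ: int = 4,
                            n_long: int = 6,
                            azimuth_point=None) -> HermiteMesh:
    """Initial template swept along the arc through three centerline landmarks.

    This stands in for the anatomically guided template placement: the
    cranial/caudal attachment points and one interior landmark determine a
    circular-arc centerline; a constant-radius tube is swept along it.
    Collinear landmarks give a straight tube.  ``azimuth_point`` (a surface
    landmark near the caudal ring) anchors the circumferential origin so that
    xi1 = 0 marks the same material line at every time point — without it the
    node azimuths are an arbitrary convention of the arc construction.
    """
    p0, p1, p2 = np.asarray(landmarks, dtype=float)
    circ = _circle_through_3pts(p0, p1, p2)
    n_rings = n_long + 1
    if circ is None:
        d = (p2 - p0) / np.linalg.norm(p2 - p0)
        centers = p0 + np.outer(np.linspace(0, np.linalg.norm(p2 - p0), n_rings), d)
        tangents = np.tile(d, (n_rings, 1))
        ref = np.array([1.0, 0.0, 0.0])
        if abs(d @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        normals = np.tile(ref - (ref @ d) * d, (n_rings, 1))
    else:
        c, Rc, nrm = circ
        e1 = (p0 - c) / Rc
        e2 = np.cross(nrm, e1)
        a2 = np.arctan2((p2 - c) @ e2, (p2 - c) @ e1)
        if a2 < 0:
            a2 += 2 * np.pi
        ang = np.linspace(0.0, a2, n_rings)
        centers = c + Rc * (np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2))
        tangents = -np.outer(np.sin(ang), e1) + np.outer(np.cos(ang), e2)
        normals = np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2)
    twist = None
    if azimuth_point is not None:
        t0v = tangents[0] / np.linalg.norm(tangents[0])
        n1 = normals[0] - (normals[0] @ t0v) * t0v
        n1 /= np.linalg.norm(n1)
        n2 = np.cross(t0v, n1)
        v = np.asarray(azimuth_point, dtype=float) - centers[0]
        twist = np.full(n_rings, float(np.arctan2(v @ n2, v @ n1)))
    return tube_mesh_from_rings(centers, tangents, normals, radius,
                                radius - wall_thickness, n_circ, twist=twist)


def estimate_tube_radius(cloud: PointCloud, landmarks: np.ndarray) -> float:
    """Median point distance to the landmark arc centerline."""
    p0, p1, p2 = np.asarray(landmarks, dtype=float)
    circ = _circle_through_3pts(p0, p1, p2)
    pts = cloud.points
    if circ is None:
        d = (p2 - p0) / np.linalg.norm(p2 - p0)
        v = pts - p0
        perp = v - np.outer(v @ d, d)
        return float(np.median(np.linalg.norm(perp, axis=1)))
    c, Rc, nrm = circ
    v = pts - c
    in_plane = v - np.outer(v @ nrm, nrm)
    on_circle = c + Rc * in_plane / np.linalg.norm(in_plane, axis=1, keepdims=True)
    return float(np.median(np.linalg.norm(pts - on_circle, axis=1)))


# ---------------------------------------------------------------------------
# Point clouds
# ---------------------------------------------------------------------------

def sample_point_cloud(spec: PhantomSpec, t: int, n: int = None,
                       noise_sigma: float = None, seed: int = None) -> PointCloud:
    """Uniform-area sample of the outer surface with isotropic Gaussian noise.

    Rejection sampling against the numerically computed surface area element
    keeps the density uniform in physical area even where bending compresses
    the inner-curvature side.
    """
    n = spec.n_cloud_points if n is None else int(n)
    if n < 100:
        raise ValueError("need at least 100 points")
    noise_sigma = spec.cloud_noise_sigma if noise_sigma is None else noise_sigma
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    def area_weight(theta, s):
        m = np.column_stack([theta, s, np.full_like(theta, spec.radius)])
        J = _map_jacobian(spec, t, m)
        return np.linalg.norm(np.cross(J[:, :, 0], J[:, :, 1]), axis=1)

    tg = np.linspace(0, 2 * np.pi, 24)
    sg = np.linspace(0, spec.length, 24)
    TT, SS = np.meshgrid(tg, sg)
    wmax = 1.05 * area_weight(TT.ravel(), SS.ravel()).max()

    acc_theta, acc_s = [], []
    got = 0
    while got < n:
        k = int(1.5 * (n - got)) + 16
        th = rng.uniform(0, 2 * np.pi, k)
        ss = rng.uniform(0, spec.length, k)
        u = rng.uniform(0, wmax, k)
        keep = u < area_weight(th, ss)
        acc_theta.append(th[keep])
        acc_s.append(ss[keep])
        got += int(keep.sum())
    theta = np.concatenate(acc_theta)[:n]
    s = np.concatenate(acc_s)[:n]
    m = np.column_stack([theta, s, np.full(n, spec.radius)])
    pts = map_material(spec, t, m)
    if noise_sigma > 0:
        pts = pts + rng.normal(0.0, noise_sigma, pts.shape)
    return PointCloud(pts)


# ---------------------------------------------------------------------------
# Cells
# ---------------------------------------------------------------------------

def generate_cells(spec: PhantomSpec) -> pd.DataFrame:
    """Pack non-overlapping ellipsoidal cells into the wall (material frame).

    Cells are flat myocardial-like ellipsoids: long axis circumferential,
    middle axis longitudinal, short axis radial.  Volumes are lognormal with
    a multiplicative gradient increasing toward the outer curvature
    (theta = pi side); anisotropy is uniform in ``anisotropy_range``.
    Greedy rejection packing; if the target count is infeasible the achieved
    count is reported with a warning.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    n = spec.n_cells
    accepted_m, mats, semi_axes, volumes, anisos = [], [], [], [], []
    bound_r = []
    max_attempts = 40 * n
    attempts = 0
    while len(accepted_m) < n and attempts < max_attempts:
        attempts += 1
        theta = rng.uniform(0, 2 * np.pi)
        s = rng.uniform(0.03 * spec.length, 0.97 * spec.length)
        V = spec.cell_volume_median * np.exp(
            rng.normal(0.0, spec.cell_volume_sigma)
            + spec.volume_gradient * (-np.cos(theta)))
        V = float(np.clip(V, *spec.cell_volume_range))
        A = rng.uniform(*spec.anisotropy_range)
        ca = np.sqrt(1.0 - A)          # c/a from anisotropy = 1 - (c/a)^2
        a = (3.0 * V / (4.0 * np.pi)) ** (1 / 3) * ca ** -0.5
        c = ca * a
        b = np.sqrt(a * c)
        if 2 * c > 0.9 * spec.wall_thickness:
            continue  # cell too thick for the wall
        rho = rng.uniform(spec.r_inner + c, spec.radius - c)
        mpt = np.array([theta, s, rho])
        x = map_material(spec, 0, mpt[None])[0]
        r_bound = a
        ok = True
        for xj, rj in zip(accepted_m, bound_r):
            if np.linalg.norm(x - xj) < 0.75 * (r_bound + rj):
                ok = False
                break
        if ok:
            accepted_m.append(x)  # world position at the reference time
            bound_r.append(r_bound)
            semi_axes.append((a, b, c))
            volumes.append(V)
            anisos.append(A)
            mats.append(mpt)
    if len(accepted_m) < n:
        warnings.warn(
            f"cell packing achieved {len(accepted_m)} of {n} requested cells")
    mats = np.array(mats) if accepted_m else np.zeros((0, 3))
    df = pd.DataFrame({
        "label": np.arange(1, len(accepted_m) + 1),
        "theta": mats[:, 0], "s": mats[:, 1], "rho": mats[:, 2],
        "a": [sa[0] for sa in semi_axes],
        "b": [sa[1] for sa in semi_axes],
        "c": [sa[2] for sa in semi_axes],
        "volume": volumes,
        "anisotropy": anisos,
    })
    return df


def cell_table_at_time(spec: PhantomSpec, cells: pd.DataFrame,
                       t: int) -> pd.DataFrame:
    """Ground-truth cell feature table at time t (world frame).

    Centroids and orientations follow the tissue map; volumes and axis
    lengths carry the global growth factor.  Eigenvalues are the principal
    standard deviations of a solid ellipsoid (semi-axis / sqrt(5)).
    """
    g = spec.growth_scales[t]
    m = cells[["theta", "s", "rho"]].to_numpy()
    x = map_material(spec, t, m)
    frames = local_frame(spec, t, m[:, 0], m[:, 1])  # columns circ, lon, rad
    a = cells["a"].to_numpy() * g
    b = cells["b"].to_numpy() * g
    c = cells["c"].to_numpy() * g
    out = pd.DataFrame({
        "label": cells["label"].to_numpy(),
        "cx": x[:, 0], "cy": x[:, 1], "cz": x[:, 2],
        "volume_um3": cells["volume"].to_numpy() * g**3,
        "ev1": a / np.sqrt(5.0), "ev2": b / np.sqrt(5.0), "ev3": c / np.sqrt(5.0),
        "anisotropy": cells["anisotropy"].to_numpy(),
    })
    for k, name in enumerate(("vec1", "vec2", "vec3")):
        vec = frames[:, :, k]  # circ/lon/rad -> principal axes a, b, c
        for d, ax in enumerate("xyz"):
            out[f"{name}{ax}"] = vec[:, d]
    return out


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize(spec: PhantomSpec, cells: pd.DataFrame, t: int = 0,
              bbox=None, voxel_size: float = None, max_voxels: int = 3e8):
    """Voxelize the cells and the myocardial shell in a bounding box.

    Returns (labels, myocardium_mask, origin).  ``bbox`` is ((xmin, ymin,
    zmin), (xmax, ymax, zmax)) in um; default covers the whole tube, which is
    only feasible for reduced-scale specs — full-scale phantoms should pass a
    tile-sized bbox, exactly as large confocal volumes are handled in tiles.
    Arrays are indexed (z, y, x); world = origin + index * voxel_size
    (voxel-center convention).
    """
    voxel = spec.voxel_size if voxel_size is None else float(voxel_size)
    tab = cell_table_at_time(spec, cells, t)
    cent = tab[["cx", "cy", "cz"]].to_numpy()
    if bbox is None:
        g = spec.growth_scales[t]
        pad = 2.0 * voxel
        ring = sample_point_cloud(spec, t, n=1500, noise_sigma=0.0,
                                  seed=spec.seed + 7).points
        lo = ring.min(axis=0) - g * spec.radius * 0.05 - pad
        hi = ring.max(axis=0) + g * spec.radius * 0.05 + pad
        bbox = (lo, hi)
    lo = np.asarray(bbox[0], dtype=float)
    hi = np.asarray(bbox[1], dtype=float)
    shape_xyz = np.maximum(np.ceil((hi - lo) / voxel).astype(int), 1)
    if np.prod(shape_xyz.astype(float)) > max_voxels:
        raise ValueError(
            f"requested grid {tuple(shape_xyz[::-1])} exceeds {max_voxels:.0f} "
            "voxels; pass a smaller bbox or a coarser voxel_size")
    nz, ny, nx = int(shape_xyz[2]), int(shape_xyz[1]), int(shape_xyz[0])
    labels = np.zeros((nz, ny, nx), dtype=np.int32)

    axes = np.stack([
        tab[[f"vec{k}x", f"vec{k}y", f"vec{k}z"]].to_numpy()
        for k in (1, 2, 3)], axis=2)  # (n, 3, 3), columns are axes
    g = spec.growth_scales[t]
    semi = np.column_stack([cells["a"], cells["b"], cells["c"]]) * g

    for i in range(len(tab)):
        cmax = semi[i, 0]
        c0 = cent[i]
        ilo = np.floor((c0 - cmax - lo) / voxel).astype(int)
        ihi = np.ceil((c0 + cmax - lo) / voxel).astype(int) + 1
        ilo = np.maximum(ilo, 0)
        ihi = np.minimum(ihi, shape_xyz)
        if np.any(ihi <= ilo):
            continue
        gx = lo[0] + voxel * np.arange(ilo[0], ihi[0])
        gy = lo[1] + voxel * np.arange(ilo[1], ihi[1])
        gz = lo[2] + voxel * np.arange(ilo[2], ihi[2])
        ZZ, YY, XX = np.meshgrid(gz, gy, gx, indexing="ij")
        d = np.stack([XX - c0[0], YY - c0[1], ZZ - c0[2]], axis=-1)
        proj = d @ axes[i]  # components along the principal axes
        inside = ((proj / semi[i]) ** 2).sum(axis=-1) <= 1.0
        sub = labels[ilo[2]:ihi[2], ilo[1]:ihi[1], ilo[0]:ihi[0]]
        sub[inside & (sub == 0)] = int(tab["label"].iloc[i])

    # myocardium mask from the inverse map
    gx = lo[0] + voxel * np.arange(nx)
    gy = lo[1] + voxel * np.arange(ny)
    gz = lo[2] + voxel * np.arange(nz)
    ZZ, YY, XX = np.meshgrid(gz, gy, gx, indexing="ij")
    pts = np.column_stack([XX.ravel(), YY.ravel(), ZZ.ravel()])
    mat = inverse_map(spec, t, pts)
    mask = ((mat[:, 2] >= spec.r_inner) & (mat[:, 2] <= spec.radius)
            & (mat[:, 1] >= 0.0) & (mat[:, 1] <= spec.length))
    mask = mask.reshape(nz, ny, nx)
    return labels, mask, lo


# ---------------------------------------------------------------------------
# Series
# ---------------------------------------------------------------------------

@dataclass
class PhantomTimePoint:
    t: int
    point_cloud: PointCloud
    mesh: HermiteMesh
    cell_table: pd.DataFrame
    landmarks: np.ndarray
    wall_thickness: float
    growth_scale: float


def generate_series(spec: PhantomSpec, n_circ: int = 4, n_long: int = 6):
    """All per-time-point phantom artifacts with their ground truths.

    Returns (time_points, cells): a list of :class:`PhantomTimePoint` and the
    material-frame cell packing shared by all time points.  Labeled volumes
    are produced on demand with :func:`rasterize`.  Identical spec and seed
    give identical outputs.
    """
    cells = generate_cells(spec)
    out = []
    for t in range(spec.n_time_points):
        ss = np.random.SeedSequence([spec.seed, 7, t])
        cloud = sample_point_cloud(
            spec, t, seed=int(ss.generate_state(1)[0] % (2**31)))
        out.append(PhantomTimePoint(
            t=t,
            point_cloud=cloud,
            mesh=true_mesh(spec, t, n_circ, n_long),
            cell_table=cell_table_at_time(spec, cells, t),
            landmarks=landmark_points(spec, t),
            wall_thickness=spec.wall_thickness * spec.growth_scales[t],
            growth_scale=spec.growth_scales[t],
        ))
    return out, cells


def bin_material_points(spec: PhantomSpec, n_circ: int = 4, n_long: int = 6,
                        n_bins: int = 5) -> np.ndarray:
    """Material points of the 5x5 bin centers (mid-wall), mesh-lattice order.

    Ordering matches the deformation-gradient records: element-major
    (elements numbered ring-row by ring-row), then i (xi1), then j (xi2).
    """
    rho = 0.5 * (spec.radius + spec.r_inner)
    pts = []
    for e in range(n_circ * n_long):
        c, jrow = e % n_circ, e // n_circ
        for i in range(n_bins):
            for j in range(n_bins):
                xi1, xi2 = (i + 0.5) / n_bins, (j + 0.5) / n_bins
                theta = 2.0 * np.pi * (c + xi1) / n_circ
                s = spec.length * (jrow + xi2) / n_long
                pts.append((theta, s, rho))
    return np.array(pts)
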