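"""Geometric fitting of the tube template to surface point clouds.

The fit is a linear least-squares problem in the nodal mesh parameters,
solved iteratively: data points are projected onto the current outer surface,
the normal equations are assembled with projections and arc-length scale
factors frozen, the linear system (data term + Sobolev smoothing penalty) is
solved, scale factors are recomputed, and the loop repeats until the RMS
projection error stops changing.  Landmark nodes can be held fixed, which is
how anatomically identified attachment points constrain the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .hermite import (
    HermiteElement,
    HermiteMesh,
    MeshNode,
    surface_normal,
    surface_params,
    surface_weights,
    update_scale_factors,
    _gauss01,
)

__all__ = [
    "PointCloud",
    "Projection",
    "Projections",
    "FitConfig",
    "MeshFitResult",
    "FitSingularError",
    "build_template_tube",
    "tube_mesh_from_rings",
    "project_points",
    "compute_rms",
    "fit_mesh",
    "refine_and_bin",
    "BinIndex",
]


class FitSingularError(RuntimeError):
    """The assembled fitting system could not be solved."""


@dataclass
class PointCloud:
    """Surface data points z_d (um) with per-point weights gamma_d."""

    points: np.ndarray
    weights: np.ndarray = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 1 or self.points.shape[1] != 3:
            raise ValueError("points must be an N x 3 array with N >= 1")
        if self.weights is None:
            self.weights = np.ones(len(self.points))
        self.weights = np.asarray(self.weights, dtype=float).reshape(len(self.points))
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def from_csv(cls, path) -> "PointCloud":
        import pandas as pd

        df = pd.read_csv(path)
        pts = df[["x", "y", "z"]].to_numpy(float)
        w = df["w"].to_numpy(float) if "w" in df.columns else None
        return cls(pts, w)

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.points, columns=["x", "y", "z"])
        df["w"] = self.weights
        df.to_csv(path, index=False)


@dataclass
class Projection:
    element_id: int
    xi: tuple
    distance: float


class Projections:
    """Array-backed result of projecting a cloud onto the mesh outer surface."""

    def __init__(self, element_id, xi, distance):
        self.element_id = np.asarray(element_id, dtype=int)
        self.xi = np.asarray(xi, dtype=float)
        self.distance = np.asarray(distance, dtype=float)

    def __len__(self):
        return len(self.element_id)

    def __getitem__(self, i) -> Projection:
        return Projection(int(self.element_id[i]), tuple(self.xi[i]), float(self.distance[i]))

    def __iter__(self):
        return (self[i] for i in range(len(self)))


@dataclass
class FitConfig:
    """Fitting controls: Sobolev weights, iteration limits, landmark nodes.

    ``alpha`` penalizes surface tension (first parametric derivatives),
    ``beta`` penalizes curvature (second derivatives).  ``fixed_node_ids``
    are global node ids whose positions are held (hard constraints).
    """

    alpha: float = 1e-3
    beta: float = 1e-4
    max_iters: int = 10
    rms_tol: float = 1e-3  # um change between iterations
    fixed_node_ids: tuple = ()
    exclude_elements: tuple = ()

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("Sobolev weights must be non-negative")


@dataclass
class MeshFitResult:
    """Fitted mesh plus the RMS trajectory of the iterative fit."""

    mesh: HermiteMesh
    rms_history: list
    n_iterations: int
    converged: bool
    projections: Projections = None

    @property
    def rms(self) -> float:
        return self.rms_history[-1]

    def summary(self) -> str:
        lines = [
            "Mesh fit result",
            f"  nodes: {self.mesh.n_nodes}, elements: {self.mesh.n_elements}",
            f"  iterations: {self.n_iterations} (converged: {self.converged})",
            f"  initial RMS: {self.rms_history[0]:.6g} um",
            f"  final RMS:   {self.rms_history[-1]:.6g} um",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------

def tube_mesh_from_rings(centers, tangents, normals, radius_outer, radius_inner,
                         n_circ: int, twist=None) -> HermiteMesh:
    """Build a bicubic-linear tube mesh from per-ring frames.

    ``centers``/``tangents``/``normals`` are (n_rings, 3) arrays giving the
    centerline point, the unit longitudinal direction and a unit reference
    direction (first circumferential axis) of each node ring.  Radii may be
    scalars or per-ring arrays.  ``twist`` optionally rotates ring node
    placement about the tangent (radians per ring).
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    tangents = np.atleast_2d(np.asarray(tangents, dtype=float))
    normals = np.atleast_2d(np.asarray(normals, dtype=float))
    n_rings = len(centers)
    n_long = n_rings - 1
    if n_circ < 3 or n_long < 1:
        raise ValueError("need n_circ >= 3 and at least 2 rings")
    r_out = np.broadcast_to(np.asarray(radius_outer, dtype=float), (n_rings,))
    r_in = np.broadcast_to(np.asarray(radius_inner, dtype=float), (n_rings,))
    tw = np.zeros(n_rings) if twist is None else np.asarray(twist, dtype=float)

    n_per = n_circ * n_rings
    nodes = [None] * (2 * n_per)
    for layer, radii in ((0, r_in), (1, r_out)):
        for j in range(n_rings):
            t = tangents[j] / np.linalg.norm(tangents[j])
            n1 = normals[j] - np.dot(normals[j], t) * t
            n1 /= np.linalg.norm(n1)
            n2 = np.cross(t, n1)
            for c in range(n_circ):
                theta = 2.0 * np.pi * c / n_circ + tw[j]
                radial = np.cos(theta) * n1 + np.sin(theta) * n2
                circ = -np.sin(theta) * n1 + np.cos(theta) * n2
                x = centers[j] + radii[j] * radial
                nid = layer * n_per + j * n_circ + c
                nodes[nid] = MeshNode(x, circ, t, np.zeros(3))

    elements = []
    for j in range(n_long):
        for c in range(n_circ):
            c1 = (c + 1) % n_circ
            corners = [
                j * n_circ + c, j * n_circ + c1,
                (j + 1) * n_circ + c, (j + 1) * n_circ + c1,
            ]
            elements.append(HermiteElement(
                tuple(corners) + tuple(np.array(corners) + n_per)))
    mesh = HermiteMesh(nodes, elements, topology_tag="tube",
                       tube_shape=(n_circ, n_long))
    return update_scale_factors(mesh)


def build_template_tube(n_circ: int = 4, n_long: int = 6, radius: float = 150.0,
                        length: float = 1000.0,
                        wall_thickness: float = 25.0) -> HermiteMesh:
    """Cylindrical bicubic-linear template, open at both ends.

    Defaults give the coarse 56-node / 24-element tube (28 nodes on each of
    the inner and outer transmural layers).
    """
    if n_circ < 3 or n_long < 1:
        raise ValueError("need n_circ >= 3 and n_long >= 1")
    z = np.linspace(0.0, length, n_long + 1)
    centers = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    tangents = np.tile([0.0, 0.0, 1.0], (n_long + 1, 1))
    normals = np.tile([1.0, 0.0, 0.0], (n_long + 1, 1))
    return tube_mesh_from_rings(centers, tangents, normals, radius,
                                radius - wall_thickness, n_circ)


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------

def _scaled_surface_weight_matrix(mesh, eid, xi1, xi2, d1=0, d2=0):
    """(..., 16) weights expressed against raw nodal parameters.

    Like :func:`surface_weights` but with the nodal scale factors folded into
    the derivative-parameter columns, so the dot product with the raw
    (x, d1, d2, d12) node parameters reproduces the interpolation.
    """
    w = surface_weights(xi1, xi2, d1, d2).copy()
    elem = mesh.elements[eid]
    for a, nid in enumerate(elem.layer_nodes(1)):
        S1, S2 = mesh.scale_factors[nid]
        w[..., 4 * a + 1] *= S1
        w[..., 4 * a + 2] *= S2
        w[..., 4 * a + 3] *= S1 * S2
    return w


def _batch_project_element(mesh, eid, pts, seeds, n_iter=30):
    """Projected-Newton closest-point search on one element face.

    ``pts`` (m, 3), ``seeds`` (m, 2).  Returns (xi (m, 2), dist (m,)).
    """
    P = surface_params(mesh, eid, layer=1)
    xi = np.clip(np.asarray(seeds, dtype=float).copy(), 0.0, 1.0)
    for _ in range(n_iter):
        u = surface_weights(xi[:, 0], xi[:, 1]) @ P
        t1 = surface_weights(xi[:, 0], xi[:, 1], d1=1) @ P
        t2 = surface_weights(xi[:, 0], xi[:, 1], d2=1) @ P
        r = u - pts
        # Gauss-Newton on D(xi) = ||u(xi) - z||^2
        g1 = np.einsum("ij,ij->i", t1, r)
        g2 = np.einsum("ij,ij->i", t2, r)
        a11 = np.einsum("ij,ij->i", t1, t1)
        a12 = np.einsum("ij,ij->i", t1, t2)
        a22 = np.einsum("ij,ij->i", t2, t2)
        det = a11 * a22 - a12 * a12
        det = np.where(np.abs(det) < 1e-30, 1e-30, det)
        dx1 = -(a22 * g1 - a12 * g2) / det
        dx2 = -(a11 * g2 - a12 * g1) / det
        step = np.clip(np.column_stack([dx1, dx2]), -0.5, 0.5)
        new_xi = np.clip(xi + step, 0.0, 1.0)
        if np.max(np.abs(new_xi - xi)) < 1e-12:
            xi = new_xi
            break
        xi = new_xi
    u = surface_weights(xi[:, 0], xi[:, 1]) @ P
    return xi, np.linalg.norm(u - pts, axis=1)


def project_points(cloud: PointCloud, mesh: HermiteMesh,
                   exclude_elements=(), grid_n: int = 9,
                   n_candidates: int = 4) -> Projections:
    """Closest-point projection of every data point onto the outer surface.

    Each element face is densely sampled on a xi grid; a KD-tree over the
    samples supplies per-point candidate elements and Newton seeds, and a
    projected Gauss-Newton iteration refines each candidate.  The smallest
    distance wins; exact ties go to the lowest element id.
    """
    if len(cloud) == 0:
        raise ValueError("empty point cloud")
    excl = set(int(e) for e in exclude_elements)
    eids = [e for e in range(mesh.n_elements) if e not in excl]
    if not eids:
        raise ValueError("all elements excluded")
    g = np.linspace(0.0, 1.0, grid_n)
    g1, g2 = np.meshgrid(g, g, indexing="ij")
    gxi = np.column_stack([g1.ravel(), g2.ravel()])
    samples, sample_eid, sample_xi = [], [], []
    for e in eids:
        P = surface_params(mesh, e, layer=1)
        samples.append(surface_weights(gxi[:, 0], gxi[:, 1]) @ P)
        sample_eid.append(np.full(len(gxi), e))
        sample_xi.append(gxi)
    samples = np.vstack(samples)
    sample_eid = np.concatenate(sample_eid)
    sample_xi = np.vstack(sample_xi)

    tree = cKDTree(samples)
    k = min(len(samples), max(n_candidates * grid_n, 8))
    _, idx = tree.query(cloud.points, k=k)
    idx = np.atleast_2d(idx)

    # distinct candidate elements per point (up to n_candidates), keeping the
    # nearest sample of each as the Newton seed
    tasks_pt, tasks_eid, tasks_seed = [], [], []
    for i in range(len(cloud)):
        seen = {}
        for j in idx[i]:
            e = int(sample_eid[j])
            if e not in seen:
                seen[e] = j
                if len(seen) >= n_candidates:
                    break
        for e, j in seen.items():
            tasks_pt.append(i)
            tasks_eid.append(e)
            tasks_seed.append(sample_xi[j])
    tasks_pt = np.array(tasks_pt)
    tasks_eid = np.array(tasks_eid)
    tasks_seed = np.array(tasks_seed)

    res_xi = np.zeros((len(tasks_pt), 2))
    res_d = np.full(len(tasks_pt), np.inf)
    for e in np.unique(tasks_eid):
        m = tasks_eid == e
        xi, d = _batch_project_element(mesh, int(e), cloud.points[tasks_pt[m]],
                                       tasks_seed[m])
        res_xi[m] = xi
        res_d[m] = d

    # pick best candidate per point; quantized distance for stable tie-breaks
    dq = np.round(res_d / 1e-9)
    order = np.lexsort((tasks_eid, dq, tasks_pt))
    best = np.zeros(len(cloud), dtype=int)
    seen_pt = np.zeros(len(cloud), dtype=bool)
    for t in order:
        p = tasks_pt[t]
        if not seen_pt[p]:
            seen_pt[p] = True
            best[p] = t
    return Projections(tasks_eid[best], res_xi[best], res_d[best])


def compute_rms(projections) -> float:
    """Root-mean-square projection distance, sqrt(sum d^2 / N)."""
    if isinstance(projections, Projections):
        d = projections.distance
    else:
        d = np.asarray([p.distance if isinstance(p, Projection) else p
                        for p in projections], dtype=float)
    if d.size == 0:
        raise ValueError("no projections")
    return float(np.sqrt(np.mean(d**2)))


# ---------------------------------------------------------------------------
# Sobolev-regularized linear fit
# ---------------------------------------------------------------------------

def _sobolev_matrix(mesh, eids, dof_of_elem, n_dof, alpha, beta, n_gauss=4):
    """Assemble the Sobolev penalty integral over the listed element faces."""
    G = np.zeros((n_dof, n_dof))
    if alpha == 0 and beta == 0:
        return G
    xg, wg = _gauss01(n_gauss)
    q1, q2 = np.meshgrid(xg, xg, indexing="ij")
    w1, w2 = np.meshgrid(wg, wg, indexing="ij")
    q1, q2, wq = q1.ravel(), q2.ravel(), (w1 * w2).ravel()
    terms = [((1, 0), alpha), ((0, 1), alpha),
             ((2, 0), beta), ((0, 2), beta), ((1, 1), 2.0 * beta)]
    for e in eids:
        idx = dof_of_elem[e]
        Ge = np.zeros((16, 16))
        for (d1, d2), coef in terms:
            if coef == 0:
                continue
            W = _scaled_surface_weight_matrix(mesh, e, q1, q2, d1, d2)
            Ge += coef * (W.T * wq) @ W
        G[np.ix_(idx, idx)] += Ge
    return G


def fit_mesh(cloud: PointCloud, template: HermiteMesh,
             cfg: FitConfig = None) -> MeshFitResult:
    """Iterative Sobolev-regularized least-squares fit of the outer surface.

    The unknowns are the outer-layer nodal parameters (position, the two
    arc-length derivatives and the mixed derivative).  Each iteration freezes
    projections and scale factors, solves the linear normal equations (one
    right-hand side per coordinate), re-places the inner layer at the
    template's per-node wall thickness along the inward surface normal, and
    reconverges the scale factors.  Nodes listed in ``cfg.fixed_node_ids``
    keep their positions (their derivative parameters stay free).
    """
    cfg = cfg or FitConfig()
    mesh = template.copy()
    n_per = mesh.n_per_layer
    n_dof = 4 * n_per

    # per-node wall vectors of the template, re-applied along fitted normals
    wall = np.array([
        np.linalg.norm(mesh.nodes[k + n_per].x - mesh.nodes[k].x)
        for k in range(n_per)
    ])

    dof_of_elem = {}
    for e, elem in enumerate(mesh.elements):
        idx = []
        for nid in elem.layer_nodes(1):
            slot = nid - n_per
            idx.extend(range(4 * slot, 4 * slot + 4))
        dof_of_elem[e] = np.array(idx)

    fixed_dof = []
    for nid in cfg.fixed_node_ids:
        slot = int(nid) - n_per if int(nid) >= n_per else int(nid)
        fixed_dof.append(4 * slot)  # the position parameter block index
    fit_eids = [e for e in range(mesh.n_elements)
                if e not in set(cfg.exclude_elements)]

    proj = project_points(cloud, mesh, cfg.exclude_elements)
    history = [compute_rms(proj)]
    converged = False
    it = 0
    for it in range(1, cfg.max_iters + 1):
        A = np.zeros((n_dof, n_dof))
        b = np.zeros((n_dof, 3))
        for e in np.unique(proj.element_id):
            m = proj.element_id == e
            W = _scaled_surface_weight_matrix(
                mesh, int(e), proj.xi[m, 0], proj.xi[m, 1])
            gam = cloud.weights[m]
            idx = dof_of_elem[int(e)]
            A[np.ix_(idx, idx)] += (W.T * gam) @ W
            b[idx] += (W.T * gam) @ cloud.points[m]
        A += _sobolev_matrix(mesh, fit_eids, dof_of_elem, n_dof,
                             cfg.alpha, cfg.beta)
        # relative Tikhonov jitter keeps the system well-posed without
        # biasing well-constrained parameters
        diag = np.diag(A)
        A[np.diag_indices_from(A)] += 1e-10 * np.maximum(diag, 1e-2)

        params = np.empty((n_dof, 3))
        for k in range(n_per):
            node = mesh.nodes[k + n_per]
            params[4 * k + 0] = node.x
            params[4 * k + 1] = node.d1
            params[4 * k + 2] = node.d2
            params[4 * k + 3] = node.d12
        free = np.setdiff1d(np.arange(n_dof), np.array(fixed_dof, dtype=int))
        rhs = b[free] - A[np.ix_(free, np.array(fixed_dof, dtype=int))] @ \
            params[np.array(fixed_dof, dtype=int)] if fixed_dof else b[free]
        try:
            Aff = A[np.ix_(free, free)]
            # symmetric Jacobi equilibration: position and derivative DoF
            # differ by the scale-factor magnitude, so condition the system
            d = np.sqrt(np.maximum(np.diag(Aff), 1e-30))
            sol = np.linalg.solve(Aff / np.outer(d, d), rhs / d[:, None]) / d[:, None]
        except np.linalg.LinAlgError as exc:
            raise FitSingularError(
                "fitting system is singular; increase alpha/beta or add "
                "fixed landmark nodes"
            ) from exc
        if not np.all(np.isfinite(sol)):
            raise FitSingularError(
                "fitting system produced non-finite solution; increase "
                "alpha/beta")
        params[free] = sol

        for k in range(n_per):
            node = mesh.nodes[k + n_per]
            node.x = params[4 * k + 0].copy()
            node.d1 = params[4 * k + 1].copy()
            node.d2 = params[4 * k + 2].copy()
            node.d12 = params[4 * k + 3].copy()
        # inner layer follows the outer surface at the template wall thickness
        for k in range(n_per):
            out = mesh.nodes[k + n_per]
            nrm = np.cross(out.d1, out.d2)
            nn = np.linalg.norm(nrm)
            nrm = nrm / nn if nn > 0 else nrm
            inner = mesh.nodes[k]
            inner.x = out.x - wall[k] * nrm
            inner.d1 = out.d1.copy()
            inner.d2 = out.d2.copy()
            inner.d12 = out.d12.copy()
        update_scale_factors(mesh)

        proj = project_points(cloud, mesh, cfg.exclude_elements)
        history.append(compute_rms(proj))
        if abs(history[-2] - history[-1]) < cfg.rms_tol:
            converged = True
            break
    return MeshFitResult(mesh, history, it, converged, proj)


# ---------------------------------------------------------------------------
# Refinement and binning
# ---------------------------------------------------------------------------

class BinIndex:
    """Deterministic enumeration of the 5x5 xi-aligned bins of each element.

    Bin (element, i, j) spans [i/5, (i+1)/5] x [j/5, (j+1)/5] in (xi1, xi2).
    """

    def __init__(self, n_elements: int, n: int = 5, tube_shape=None):
        self.n_elements = int(n_elements)
        self.n = int(n)
        self.tube_shape = tube_shape

    def keys(self):
        return [(e, i, j) for e in range(self.n_elements)
                for i in range(self.n) for j in range(self.n)]

    def __len__(self):
        return self.n_elements * self.n * self.n

    def center(self, e: int, i: int, j: int):
        return ((i + 0.5) / self.n, (j + 0.5) / self.n)

    def locate(self, xi1: float, xi2: float):
        i = min(int(np.asarray(xi1) * self.n), self.n - 1)
        j = min(int(np.asarray(xi2) * self.n), self.n - 1)
        return i, j

    def to_refined(self, e: int, xi1: float, xi2: float):
        """Map original-element coordinates to the 2x2-refined mesh."""
        if self.tube_shape is None:
            raise ValueError("bin index lacks tube topology information")
        n_circ, n_long = self.tube_shape
        c, jrow = e % n_circ, e // n_circ
        sub1 = 1 if xi1 >= 0.5 else 0
        sub2 = 1 if xi2 >= 0.5 else 0
        C = 2 * c + sub1
        J = 2 * jrow + sub2
        ref_eid = J * (2 * n_circ) + C
        return ref_eid, 2.0 * xi1 - sub1, 2.0 * xi2 - sub2


def refine_and_bin(mesh: HermiteMesh):
    """2x2 subdivision of every surface element plus the 5x5 bin index.

    The refined mesh interpolates the parent surface: new nodes take the
    parent's position, tangent directions and (rescaled) mixed derivative at
    the subdivision points, and the scale factors are reconverged.
    """
    if mesh.tube_shape is None:
        raise ValueError("refinement requires a tube-topology mesh")
    n_circ, n_long = mesh.tube_shape
    N_circ, N_long = 2 * n_circ, 2 * n_long
    n_per_new = N_circ * (N_long + 1)
    nodes = [None] * (2 * n_per_new)

    for layer in (0, 1):
        for J in range(N_long + 1):
            jrow = min(J // 2, n_long - 1)
            x2 = (J - 2 * jrow) / 2.0
            for C in range(N_circ):
                c = C // 2
                x1 = (C - 2 * c) / 2.0
                e = jrow * n_circ + c
                P = surface_params(mesh, e, layer)
                u = surface_weights(x1, x2) @ P
                t1 = surface_weights(x1, x2, d1=1) @ P
                t2 = surface_weights(x1, x2, d2=1) @ P
                m12 = surface_weights(x1, x2, d1=1, d2=1) @ P
                m1, m2 = np.linalg.norm(t1), np.linalg.norm(t2)
                d12 = m12 / (m1 * m2) if m1 > 0 and m2 > 0 else np.zeros(3)
                nid = layer * n_per_new + J * N_circ + C
                nodes[nid] = MeshNode(u, t1, t2, d12)

    elements = []
    for J in range(N_long):
        for C in range(N_circ):
            C1 = (C + 1) % N_circ
            corners = [J * N_circ + C, J * N_circ + C1,
                       (J + 1) * N_circ + C, (J + 1) * N_circ + C1]
            elements.append(HermiteElement(
                tuple(corners) + tuple(np.array(corners) + n_per_new)))
    refined = HermiteMesh(nodes, elements, topology_tag="refined-tube",
                          tube_shape=(N_circ, N_long))
    update_scale_factors(refined)
    return refined, BinIndex(mesh.n_elements, 5, tube_shape=mesh.tube_shape)
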