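"""Mapping cell data onto fitted meshes: alignment, bins, fields, variance.

Cell centroids are projected onto the outer surface of the fitted mesh and
aggregated in the 5x5 xi-aligned bins of each element; bin tissue volume
comes from projecting the myocardium mask voxels the same way, which defines
the inter-cellular-space volume V_ICS = V_tissue - sum(V_cell) and the cell
density rho = N_cell / V_tissue.  Continuous feature fields are fitted on
the 2x2-refined mesh with the same Sobolev-regularized least-squares
machinery as the geometry fit; local heterogeneity is measured as the
variance of a feature over each cell and its nine nearest neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .fitting import (
    BinIndex,
    FitConfig,
    FitSingularError,
    PointCloud,
    _scaled_surface_weight_matrix,
    _sobolev_matrix,
    project_points,
    refine_and_bin,
)
from .hermite import HermiteMesh, surface_weights

__all__ = [
    "RigidTransform",
    "rigid_align",
    "map_cells_to_bins",
    "FieldFit",
    "fit_feature_field",
    "neighbor_variance",
    "BIN_TABLE_COLUMNS",
]

BIN_TABLE_COLUMNS = [
    "element", "i", "j", "region", "time", "N_cell", "V_cell_mean",
    "V_tissue", "V_ICS", "rho", "anisotropy_mean",
    "evec_x", "evec_y", "evec_z", "eval1",
]


@dataclass
class RigidTransform:
    """Rotation + translation, no scaling."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation.T + self.translation

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        return np.atleast_2d(vectors) @ self.rotation.T

    @property
    def residual(self) -> float:
        return getattr(self, "_residual", np.nan)


def rigid_align(src_landmarks: np.ndarray,
                dst_landmarks: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping src landmarks onto dst.

    Kabsch algorithm (SVD of the cross-covariance with a det-sign fix), so no
    scaling or reflection enters.  Two landmark pairs are permitted: the roll
    about the segment axis is then fixed by the minimal rotation between the
    segment directions.
    """
    src = np.atleast_2d(np.asarray(src_landmarks, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_landmarks, dtype=float))
    if src.shape != dst.shape or src.shape[0] < 2:
        raise ValueError("need matching landmark arrays with k >= 2")
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    if len(src) == 2:
        a = src[1] - src[0]
        b = dst[1] - dst[0]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            raise ValueError("degenerate two-point landmark configuration")
        R = _minimal_rotation(a / na, b / nb)
    else:
        H = (src - sc).T @ (dst - dc)
        U, S, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        if S[1] < 1e-12 * max(S[0], 1.0):
            raise ValueError("degenerate (collinear) landmark configuration")
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    tr = RigidTransform(R, dc - R @ sc)
    tr._residual = float(np.sqrt(np.mean(
        np.sum((tr.apply(src) - dst) ** 2, axis=1))))
    return tr


def _minimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest-angle rotation taking unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-14:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        p = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, p)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


# ---------------------------------------------------------------------------
# Bin aggregation
# ---------------------------------------------------------------------------

def _beyond_ends(mesh: HermiteMesh, points, proj, tol=1e-6):
    """Flag projections that run off the open tube ends.

    A point whose best projection clamps xi2 at the mesh's longitudinal
    boundary and whose residual has a component along the longitudinal
    tangent did not achieve a normal projection: it lies beyond the end ring.
    """
    if mesh.tube_shape is None:
        return np.zeros(len(points), dtype=bool)
    n_circ, n_long = mesh.tube_shape
    flags = np.zeros(len(points), dtype=bool)
    for k in range(len(points)):
        e = int(proj.element_id[k])
        x1, x2 = proj.xi[k]
        jrow = e // n_circ
        at_end = (jrow == 0 and x2 <= 0.0) or (jrow == n_long - 1 and x2 >= 1.0)
        if not at_end:
            continue
        u = surface_weights(x1, x2) @ _surface_params_cached(mesh, e)
        t2 = surface_weights(x1, x2, d2=1) @ _surface_params_cached(mesh, e)
        r = np.asarray(points[k]) - u
        if abs(np.dot(r, t2 / np.linalg.norm(t2))) > tol * max(1.0, np.linalg.norm(r)):
            flags[k] = bool(np.linalg.norm(r) > tol)
    return flags


def _surface_params_cached(mesh, e):
    from .hermite import surface_params

    return surface_params(mesh, e, 1)


def map_cells_to_bins(cells: pd.DataFrame, mesh: HermiteMesh,
                      mask=None, regions: dict = None, time: int = 0,
                      exclude_elements=(), tissue_sample_step: int = 1,
                      bin_index: BinIndex = None):
    """Project cell centroids onto the mesh and aggregate per 5x5 bin.

    ``cells`` is a cell feature table (see morphometry.CELL_TABLE_COLUMNS) in
    the mesh's frame.  ``mask`` is an optional myocardium
    :class:`~loopkin.morphometry.LabeledVolume` (binary) whose voxels are
    projected the same way to attribute tissue volume to bins
    (``tissue_sample_step`` subsamples the voxel lattice; counts are scaled
    back by step^3).  ``regions`` maps (element, i, j) or element -> region
    label.  Returns (bin_table, unassigned_labels).
    """
    bin_index = bin_index or BinIndex(mesh.n_elements, 5, mesh.tube_shape)
    cent = cells[["cx", "cy", "cz"]].to_numpy(float)
    proj = project_points(PointCloud(cent), mesh, exclude_elements)
    unassigned = _beyond_ends(mesh, cent, proj)

    n = bin_index.n
    agg = {}
    for k in range(len(cells)):
        if unassigned[k]:
            continue
        e = int(proj.element_id[k])
        i, j = bin_index.locate(proj.xi[k, 0], proj.xi[k, 1])
        agg.setdefault((e, i, j), []).append(k)

    tissue = {}
    if mask is not None:
        vox = np.asarray(mask.voxels).astype(bool)
        step = int(tissue_sample_step)
        zz, yy, xx = np.nonzero(vox[::step, ::step, ::step])
        vs = mask.voxel_size
        world = np.column_stack([
            mask.origin[0] + vs * step * xx,
            mask.origin[1] + vs * step * yy,
            mask.origin[2] + vs * step * zz,
        ])
        if len(world):
            vproj = project_points(PointCloud(world), mesh, exclude_elements)
            vun = _beyond_ends(mesh, world, vproj)
            voxvol = (vs * step) ** 3
            for k in range(len(world)):
                if vun[k]:
                    continue
                e = int(vproj.element_id[k])
                i, j = bin_index.locate(vproj.xi[k, 0], vproj.xi[k, 1])
                tissue[(e, i, j)] = tissue.get((e, i, j), 0.0) + voxvol

    def region_of(key):
        if regions is None:
            return ""
        return regions.get(key, regions.get(key[0], ""))

    rows = []
    for key in bin_index.keys():
        if key[0] in set(exclude_elements):
            continue
        idx = agg.get(key, [])
        sub = cells.iloc[idx] if idx else None
        n_cell = len(idx)
        v_mean = float(sub["volume_um3"].mean()) if n_cell else np.nan
        v_sum = float(sub["volume_um3"].sum()) if n_cell else 0.0
        a_mean = float(sub["anisotropy"].mean()) if n_cell else np.nan
        ev1 = float(sub["ev1"].mean()) if n_cell else np.nan
        if n_cell:
            vecs = sub[["vec1x", "vec1y", "vec1z"]].to_numpy(float)
            # axial mean: align signs to the first vector before averaging
            ref = vecs[0]
            signs = np.where(vecs @ ref < 0, -1.0, 1.0)
            mv = (vecs * signs[:, None]).mean(axis=0)
            nm = np.linalg.norm(mv)
            mv = mv / nm if nm > 0 else mv
        else:
            mv = np.full(3, np.nan)
        v_t = tissue.get(key, np.nan)
        v_ics = v_t - v_sum if np.isfinite(v_t) else np.nan
        rho = n_cell / v_t if np.isfinite(v_t) and v_t > 0 else np.nan
        rows.append([key[0], key[1], key[2], region_of(key), time, n_cell,
                     v_mean, v_t, v_ics, rho, a_mean, *mv, ev1])
    table = pd.DataFrame(rows, columns=BIN_TABLE_COLUMNS)
    return table, cells["label"].to_numpy()[unassigned]


def bin_deltas(bins_ref: pd.DataFrame, bins_def: pd.DataFrame,
               deform: pd.DataFrame = None) -> pd.DataFrame:
    """Per-bin changes between two time points, for the growth model.

    Joins the two bin tables on (element, i, j) and differences the cellular
    aggregates; the tissue volume change comes from the kinematics records
    (deltaV) when given, else from the bin tissue volumes.  Region and the
    reference time tag are carried through (``Time`` labels the period).
    """
    key = ["element", "i", "j"]
    a = bins_ref.set_index(key)
    b = bins_def.set_index(key)
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    out = pd.DataFrame(index=common)
    out["dN_cell"] = b["N_cell"] - a["N_cell"]
    out["dV_cell"] = b["V_cell_mean"] - a["V_cell_mean"]
    out["dA_cell"] = b["anisotropy_mean"] - a["anisotropy_mean"]
    out["dV_ICS"] = b["V_ICS"] - a["V_ICS"]
    out["drho_cell"] = b["rho"] - a["rho"]
    out["Region"] = a["region"]
    out["Time"] = a["time"]
    if deform is not None:
        d = deform.set_index(key)
        out["dV_tissue"] = d.loc[common, "deltaV"]
    else:
        out["dV_tissue"] = b["V_tissue"] - a["V_tissue"]
    return out.reset_index()


# ---------------------------------------------------------------------------
# Field fitting
# ---------------------------------------------------------------------------

class FieldFit:
    """A scalar or vector feature fitted as a continuous nodal field.

    The field lives on the outer surface of the 2x2-refined mesh; nodal
    parameters per component are (value, d/ds1, d/ds2, d2/ds1 ds2), exactly
    mirroring the geometric parameterization, so evaluation reuses the same
    basis weights.
    """

    def __init__(self, refined_mesh: HermiteMesh, bin_index: BinIndex,
                 params: np.ndarray, n_components: int):
        self.mesh = refined_mesh
        self.bin_index = bin_index
        self.params = params  # (n_dof, n_components)
        self.n_components = n_components

    def evaluate(self, element: int, xi1, xi2) -> np.ndarray:
        """Evaluate on original-element coordinates (mapped to the refinement)."""
        ref_e, r1, r2 = self.bin_index.to_refined(int(element), float(xi1),
                                                  float(xi2))
        w = _scaled_surface_weight_matrix(self.mesh, ref_e, r1, r2)
        elem = self.mesh.elements[ref_e]
        n_per = self.mesh.n_per_layer
        idx = []
        for nid in elem.layer_nodes(1):
            slot = nid - n_per
            idx.extend(range(4 * slot, 4 * slot + 4))
        out = w @ self.params[idx]
        return out if self.n_components > 1 else float(out[0])


def fit_feature_field(data: pd.DataFrame, mesh: HermiteMesh,
                      cfg: FitConfig = None, value_columns=("value",),
                      refined=None) -> FieldFit:
    """Fit a smooth feature field over the refined mesh surface.

    ``data`` needs columns element, xi1, xi2 (original-mesh coordinates, e.g.
    bin centers or projected cells) plus the value column(s).  The same
    normal-equation assembly as the geometry fit is used, with the nodal
    field parameters as unknowns; vector features are fitted componentwise
    (shared system matrix).
    """
    cfg = cfg or FitConfig()
    if len(data) == 0:
        raise ValueError("no field data")
    if refined is None:
        refined = refine_and_bin(mesh)
    rmesh, bidx = refined
    n_per = rmesh.n_per_layer
    n_dof = 4 * n_per
    ncomp = len(value_columns)

    dof_of_elem = {}
    for e, elem in enumerate(rmesh.elements):
        idx = []
        for nid in elem.layer_nodes(1):
            slot = nid - n_per
            idx.extend(range(4 * slot, 4 * slot + 4))
        dof_of_elem[e] = np.array(idx)

    A = np.zeros((n_dof, n_dof))
    b = np.zeros((n_dof, ncomp))
    vals = data[list(value_columns)].to_numpy(float)
    for k in range(len(data)):
        e0 = int(data["element"].iloc[k])
        ref_e, r1, r2 = bidx.to_refined(e0, float(data["xi1"].iloc[k]),
                                        float(data["xi2"].iloc[k]))
        w = _scaled_surface_weight_matrix(rmesh, ref_e, r1, r2)
        idx = dof_of_elem[ref_e]
        A[np.ix_(idx, idx)] += np.outer(w, w)
        b[idx] += np.outer(w, vals[k])
    A += _sobolev_matrix(rmesh, range(rmesh.n_elements), dof_of_elem, n_dof,
                         cfg.alpha, cfg.beta)
    diag = np.diag(A)
    A[np.diag_indices_from(A)] += 1e-10 * np.maximum(diag, 1e-2) + 1e-12
    try:
        d = np.sqrt(np.maximum(np.diag(A), 1e-30))
        params = np.linalg.solve(A / np.outer(d, d), b / d[:, None]) / d[:, None]
    except np.linalg.LinAlgError as exc:
        raise FitSingularError(
            "field system singular; increase alpha/beta or supply more data"
        ) from exc
    return FieldFit(rmesh, bidx, params, ncomp)


# ---------------------------------------------------------------------------
# Neighbor variance
# ---------------------------------------------------------------------------

def neighbor_variance(cells: pd.DataFrame, feature: str, k: int = 9) -> np.ndarray:
    """Per-cell local variance of a feature over the cell + its k nearest cells.

    Population variance (divide by k+1) of the feature values over each cell
    and its k nearest neighbors by centroid Euclidean distance.  Units are
    the squared feature units.
    """
    if len(cells) < k + 1:
        raise ValueError(f"need at least {k + 1} cells")
    cent = cells[["cx", "cy", "cz"]].to_numpy(float)
    vals = cells[feature].to_numpy(float)
    tree = cKDTree(cent)
    _, idx = tree.query(cent, k=k + 1)  # includes the cell itself
    return np.var(vals[idx], axis=1)
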