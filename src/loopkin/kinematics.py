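"""Tissue deformation between time-point meshes.

Two meshes with identical topology provide the reference (undeformed) and
current (deformed) configurations; material correspondence is by shared
(element, xi).  At the center of every 5x5 subregion (mid-wall, xi3 = 0.5)
the deformation gradient is F = (dx/dxi)(dX/dxi)^-1, the local volume ratio
is J = det F, and the volume change of the subregion is dV (J - 1) with dV
the reference subregion volume.  A sign-corrected SVD F = U S V^T separates
the principal stretches (diagonal of S) from the tissue rotation R = U V^T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import BinIndex
from .hermite import HermiteMesh, xi_jacobian

__all__ = [
    "DeformationRecord",
    "deformation_gradient_field",
    "decompose_deformation",
    "records_to_frame",
    "mesh_volume",
]


def mesh_volume(mesh: HermiteMesh, n_gauss: int = 4) -> float:
    """Total wall volume by Gauss quadrature of |det du/dxi| over all elements."""
    from .hermite import _gauss01

    xg, wg = _gauss01(n_gauss)
    total = 0.0
    for e in range(mesh.n_elements):
        for a, wa in zip(xg, wg):
            for b, wb in zip(xg, wg):
                for c, wc in zip(xg, wg):
                    J = xi_jacobian(mesh, e, (a, b, c))
                    total += wa * wb * wc * abs(np.linalg.det(J))
    return float(total)


@dataclass
class DeformationRecord:
    """Per-bin deformation state."""

    element: int
    i: int
    j: int
    F: np.ndarray
    J: float
    dV: float
    deltaV: float
    stretches: np.ndarray = None
    rotation: np.ndarray = None
    U: np.ndarray = None
    V: np.ndarray = None
    degenerate: bool = False


def decompose_deformation(F: np.ndarray):
    """(U, S, V, R, stretches) from the sign-corrected SVD of F.

    U and V are made proper rotations (det = +1); for det F > 0 this leaves
    the singular values positive.  R = U V^T is the polar rotation.  det F
    <= 0 raises (callers flag such bins degenerate instead).
    """
    F = np.asarray(F, dtype=float).reshape(3, 3)
    detF = np.linalg.det(F)
    if detF <= 0:
        raise ValueError("deformation gradient must have positive determinant")
    U, s, Vt = np.linalg.svd(F)
    V = Vt.T
    if np.linalg.det(U) < 0:
        # det(U) det(V) = sign(det F) = +1, so both flip together
        U = U.copy()
        V = V.copy()
        U[:, -1] *= -1
        V[:, -1] *= -1
    R = U @ V.T
    return U, np.diag(s), V, R, s.copy()


def deformation_gradient_field(ref_mesh: HermiteMesh, def_mesh: HermiteMesh,
                               bin_index: BinIndex = None,
                               xi3: float = 0.5):
    """Deformation records at every 5x5 subregion center.

    Both meshes must share topology and element numbering.  The reference
    subregion volume dV is |det dX/dxi| times the xi-measure of the bin
    (1/25 of the unit cube).  Bins whose reference Jacobian is singular or
    whose J is non-positive are flagged degenerate (no decomposition).
    """
    if ref_mesh.n_elements != def_mesh.n_elements or \
            ref_mesh.n_nodes != def_mesh.n_nodes:
        raise ValueError("meshes must share topology and numbering")
    bin_index = bin_index or BinIndex(ref_mesh.n_elements, 5,
                                      ref_mesh.tube_shape)
    n = bin_index.n
    xi_measure = 1.0 / (n * n)
    records = []
    for (e, i, j) in bin_index.keys():
        x1, x2 = bin_index.center(e, i, j)
        GX = xi_jacobian(ref_mesh, e, (x1, x2, xi3))
        gx = xi_jacobian(def_mesh, e, (x1, x2, xi3))
        detX = np.linalg.det(GX)
        if abs(detX) < 1e-12:
            records.append(DeformationRecord(e, i, j, np.full((3, 3), np.nan),
                                             np.nan, 0.0, np.nan,
                                             degenerate=True))
            continue
        F = gx @ np.linalg.inv(GX)
        Jdet = float(np.linalg.det(F))
        dV = abs(detX) * xi_measure
        rec = DeformationRecord(e, i, j, F, Jdet, dV, dV * (Jdet - 1.0))
        if Jdet > 0:
            U, S, V, R, lam = decompose_deformation(F)
            rec.U, rec.V, rec.rotation, rec.stretches = U, V, R, lam
        else:
            rec.degenerate = True
        records.append(rec)
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Flatten deformation records into the CSV-oriented table."""
    rows = []
    for r in records:
        F = r.F.ravel()
        lam = r.stretches if r.stretches is not None else np.full(3, np.nan)
        R = (r.rotation if r.rotation is not None
             else np.full((3, 3), np.nan)).ravel()
        rows.append([r.element, r.i, r.j, *F, r.J, r.dV, r.deltaV, *lam, *R,
                     r.degenerate])
    cols = (["element", "i", "j"]
            + [f"F{a}{b}" for a in (1, 2, 3) for b in (1, 2, 3)]
            + ["J", "dV", "deltaV", "l1", "l2", "l3"]
            + [f"R{a}{b}" for a in (1, 2, 3) for b in (1, 2, 3)]
            + ["degenerate"])
    return pd.DataFrame(rows, columns=cols)
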