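"""Rotation of cell principal axes between time points and cell-tissue alignment.

Principal eigenvectors of cell ellipsoids are axial (sign-free), so before
constructing the rotation between the time-t and time-t+1 directions the
later vector is sign-flipped to the hemisphere of the earlier one; the
rotation axis is their normalized cross product, the angle comes from the
atan2 of the cross/dot magnitudes, and the rotation matrix is the Rodrigues
form.  Cell-tissue coupling is measured by the absolute cosines between the
columns of the tissue and cell rotation matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RotationRecord",
    "rotation_between_vectors",
    "alignment_cosines",
]


@dataclass
class RotationRecord:
    axis: np.ndarray
    angle: float
    rotation: np.ndarray


def _cross_matrix(a: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -a[2], a[1]],
                     [a[2], 0.0, -a[0]],
                     [-a[1], a[0], 0.0]])


def rotation_between_vectors(v_t: np.ndarray, v_t1: np.ndarray) -> RotationRecord:
    """Rotation carrying the direction of v_t onto that of v_t1.

    Both vectors are treated as axial: if they point into opposite
    hemispheres, v_t1 is flipped first, so the angle never exceeds pi/2.
    Parallel vectors give the identity.
    """
    v0 = np.asarray(v_t, dtype=float).reshape(3)
    v1 = np.asarray(v_t1, dtype=float).reshape(3)
    n0, n1 = np.linalg.norm(v0), np.linalg.norm(v1)
    if n0 == 0 or n1 == 0:
        raise ValueError("vectors must be non-zero")
    if np.dot(v0, v1) < 0:
        v1 = -v1
    cross = np.cross(v0, v1)
    sin_t = np.linalg.norm(cross) / (n0 * n1)
    cos_t = np.dot(v0, v1) / (n0 * n1)
    theta = float(np.arctan2(sin_t, cos_t))
    if sin_t < 1e-14:
        return RotationRecord(np.array([0.0, 0.0, 1.0]), 0.0, np.eye(3))
    axis = cross / np.linalg.norm(cross)
    K = _cross_matrix(axis)
    R = (np.cos(theta) * np.eye(3) + np.sin(theta) * K
         + (1.0 - np.cos(theta)) * np.outer(axis, axis))
    return RotationRecord(axis, theta, R)


def alignment_cosines(R_tissue: np.ndarray, R_cell: np.ndarray) -> np.ndarray:
    """Absolute cosines between corresponding columns of two rotations.

    Values lie in [0, 1]: 1 when the orientation changes are aligned, 0 when
    perpendicular.  Inputs must be orthonormal.
    """
    Rt = np.asarray(R_tissue, dtype=float).reshape(3, 3)
    Rc = np.asarray(R_cell, dtype=float).reshape(3, 3)
    for M in (Rt, Rc):
        if np.linalg.norm(M.T @ M - np.eye(3)) > 1e-6:
            raise ValueError("rotation matrices must be orthonormal")
    return np.abs(np.einsum("ik,ik->k", Rt, Rc))
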