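"""Tensor-product cubic Hermite surface/volume meshes with arc-length scaling.

The heart tube is represented by a bicubic-linear finite-element mesh: two
node layers (endocardial and epicardial surfaces of the myocardium) carrying
bicubic Hermite patches in the circumferential (xi1) and longitudinal (xi2)
directions, blended linearly through the wall (xi3).  Nodal derivatives are
stored with respect to arc length, so that a per-node scale factor S
(the local ds/dxi) converts them to the xi-derivatives the tensor-product
interpolation needs.  Keeping the scale factors nodal (shared by every
element at a node) makes the interpolated geometry C1 across element
boundaries.

Each node stores four parameter vectors: position, du/ds1, du/ds2 and the
mixed derivative d2u/ds1ds2.  Cross-derivatives involving xi3 are identically
zero for the bicubic-linear basis and are not stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss

__all__ = [
    "MeshNode",
    "HermiteElement",
    "HermiteMesh",
    "ScaleFactorError",
    "basis_functions",
    "basis_derivatives",
    "interpolate_1d",
    "arc_length_1d",
    "surface_weights",
    "surface_point",
    "interpolate",
    "xi_jacobian",
    "surface_normal",
    "update_scale_factors",
]


class ScaleFactorError(RuntimeError):
    """Arc-length scale-factor iteration failed to converge."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"scale-factor iteration did not converge within {max_iter} "
            f"iterations (residual {residual:.3e})"
        )


# ---------------------------------------------------------------------------
# 1D cubic Hermite basis
# ---------------------------------------------------------------------------

def basis_functions(xi):
    """The four 1D cubic Hermite basis functions (psi1_0, psi2_0, psi1_1, psi2_1).

    psi1_0 interpolates the value at the first node, psi2_0 at the second;
    psi1_1 and psi2_1 interpolate the derivatives.  ``xi`` may be a scalar or
    array in [0, 1].
    """
    xi = np.asarray(xi, dtype=float)
    if np.any(xi < 0.0) or np.any(xi > 1.0):
        raise ValueError("xi must lie in [0, 1]")
    p10 = 1.0 - 3.0 * xi**2 + 2.0 * xi**3
    p20 = xi**2 * (3.0 - 2.0 * xi)
    p11 = xi * (xi - 1.0) ** 2
    p21 = xi**2 * (xi - 1.0)
    return p10, p20, p11, p21


def basis_derivatives(xi, order: int = 1):
    """Derivatives of the four Hermite basis functions with respect to xi."""
    xi = np.asarray(xi, dtype=float)
    if order == 0:
        return basis_functions(xi)
    if order == 1:
        return (
            6.0 * xi**2 - 6.0 * xi,
            6.0 * xi - 6.0 * xi**2,
            3.0 * xi**2 - 4.0 * xi + 1.0,
            3.0 * xi**2 - 2.0 * xi,
        )
    if order == 2:
        return (
            12.0 * xi - 6.0,
            6.0 - 12.0 * xi,
            6.0 * xi - 4.0,
            6.0 * xi - 2.0,
        )
    raise ValueError("order must be 0, 1 or 2")


def interpolate_1d(u1, u2, d1, d2, S, xi, order: int = 0):
    """Cubic Hermite interpolation along one edge with arc-length scaling.

    ``u1, u2`` are nodal values, ``d1, d2`` the arc-length derivatives du/ds
    at the nodes and ``S`` the scale factor ds/dxi (a scalar, or a pair for
    node-specific factors).  ``order`` selects the xi-derivative order of the
    result.
    """
    S = np.atleast_1d(np.asarray(S, dtype=float))
    Sa, Sb = (S[0], S[0]) if S.size == 1 else (S[0], S[1])
    p10, p20, p11, p21 = basis_derivatives(np.asarray(xi, dtype=float), order)
    u1, u2 = np.asarray(u1, dtype=float), np.asarray(u2, dtype=float)
    d1, d2 = np.asarray(d1, dtype=float), np.asarray(d2, dtype=float)
    return (
        np.multiply.outer(p10, u1)
        + np.multiply.outer(p20, u2)
        + np.multiply.outer(p11, d1 * Sa)
        + np.multiply.outer(p21, d2 * Sb)
    )


_GAUSS_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gauss01(n: int):
    if n not in _GAUSS_CACHE:
        x, w = leggauss(n)
        _GAUSS_CACHE[n] = (0.5 * (x + 1.0), 0.5 * w)
    return _GAUSS_CACHE[n]


def arc_length_1d(u1, u2, d1, d2, S, n_gauss: int = 16) -> float:
    """Arc length of a cubic Hermite edge, s = int_0^1 ||du/dxi|| dxi.

    Gauss-Legendre quadrature; 16 points resolve the quartic integrand of a
    cubic curve far below the scale-factor iteration tolerance.
    """
    xg, wg = _gauss01(n_gauss)
    tang = interpolate_1d(u1, u2, d1, d2, S, xg, order=1)
    tang = np.atleast_2d(tang)
    return float(np.sum(wg * np.linalg.norm(tang, axis=-1)))


# ---------------------------------------------------------------------------
# Mesh data structures
# ---------------------------------------------------------------------------

@dataclass
class MeshNode:
    """One mesh node: position plus arc-length-based derivative vectors (um)."""

    x: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    d12: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float).reshape(3)
        self.d1 = np.asarray(self.d1, dtype=float).reshape(3)
        self.d2 = np.asarray(self.d2, dtype=float).reshape(3)
        self.d12 = np.asarray(self.d12, dtype=float).reshape(3)

    def copy(self) -> "MeshNode":
        return MeshNode(self.x.copy(), self.d1.copy(), self.d2.copy(), self.d12.copy())


@dataclass
class HermiteElement:
    """Bicubic-linear volume element.

    ``node_ids`` lists 8 global node ids: the four xi3=0 (inner) corners in
    (xi1, xi2) lexicographic order, then the four xi3=1 (outer) corners in the
    same order.
    """

    node_ids: tuple
    basis: tuple = ("cubic", "cubic", "linear")

    def __post_init__(self):
        self.node_ids = tuple(int(i) for i in self.node_ids)
        self.basis = tuple(self.basis)

    def layer_nodes(self, layer: int) -> tuple:
        return self.node_ids[4 * layer: 4 * layer + 4]


@dataclass
class HermiteMesh:
    """A bicubic-linear tube mesh: nodes, elements and nodal scale factors."""

    nodes: list
    elements: list
    scale_factors: np.ndarray = None  # (n_nodes, 2): S1, S2 per node
    topology_tag: str = "tube"
    tube_shape: tuple = None  # (n_circ, n_long) for tube topologies

    def __post_init__(self):
        if self.scale_factors is None:
            self.scale_factors = np.ones((len(self.nodes), 2))
        self.scale_factors = np.asarray(self.scale_factors, dtype=float).reshape(
            len(self.nodes), 2
        )
        if self.tube_shape is not None:
            self.tube_shape = tuple(int(v) for v in self.tube_shape)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_per_layer(self) -> int:
        """Nodes per transmural layer (inner ids come first by convention)."""
        return len(self.nodes) // 2

    def node_positions(self) -> np.ndarray:
        return np.array([n.x for n in self.nodes])

    def copy(self) -> "HermiteMesh":
        return HermiteMesh(
            [n.copy() for n in self.nodes],
            [HermiteElement(e.node_ids, e.basis) for e in self.elements],
            self.scale_factors.copy(),
            self.topology_tag,
            self.tube_shape,
        )


# ---------------------------------------------------------------------------
# Surface (bicubic) evaluation
# ---------------------------------------------------------------------------

def surface_weights(xi1, xi2, d1: int = 0, d2: int = 0) -> np.ndarray:
    """Weights of the 16 bicubic-Hermite surface parameters at (xi1, xi2).

    Parameter order per corner node a (a = 1..4 in (xi1, xi2) lexicographic
    order): value, du/dxi1, du/dxi2, d2u/dxi1 dxi2 — i.e. weight index
    ``4*(a-1) + p``.  ``d1, d2`` select the derivative order with respect to
    xi1 and xi2.  Broadcasts over array-valued xi.
    """
    a10, a20, a11, a21 = basis_derivatives(np.asarray(xi1, dtype=float), d1)
    b10, b20, b11, b21 = basis_derivatives(np.asarray(xi2, dtype=float), d2)
    w = np.empty(np.broadcast(a10, b10).shape + (16,))
    # corners: a=1 (0,0), a=2 (1,0), a=3 (0,1), a=4 (1,1)
    w[..., 0], w[..., 1], w[..., 2], w[..., 3] = a10 * b10, a11 * b10, a10 * b11, a11 * b11
    w[..., 4], w[..., 5], w[..., 6], w[..., 7] = a20 * b10, a21 * b10, a20 * b11, a21 * b11
    w[..., 8], w[..., 9], w[..., 10], w[..., 11] = a10 * b20, a11 * b20, a10 * b21, a11 * b21
    w[..., 12], w[..., 13], w[..., 14], w[..., 15] = a20 * b20, a21 * b20, a20 * b21, a21 * b21
    return w


def surface_params(mesh: HermiteMesh, eid: int, layer: int) -> np.ndarray:
    """(16, 3) scaled parameter matrix of one element face (one xi3 layer).

    Derivative parameters carry the nodal scale factors, converting stored
    arc-length derivatives to the xi-derivatives of the interpolation formula.
    """
    elem = mesh.elements[eid]
    P = np.empty((16, 3))
    for a, nid in enumerate(elem.layer_nodes(layer)):
        node = mesh.nodes[nid]
        S1, S2 = mesh.scale_factors[nid]
        P[4 * a + 0] = node.x
        P[4 * a + 1] = node.d1 * S1
        P[4 * a + 2] = node.d2 * S2
        P[4 * a + 3] = node.d12 * (S1 * S2)
    return P


def surface_point(mesh, eid, xi1, xi2, layer: int = 1, d1: int = 0, d2: int = 0):
    """Evaluate a face of element ``eid`` (default outer layer, xi3 = 1)."""
    w = surface_weights(xi1, xi2, d1, d2)
    return w @ surface_params(mesh, eid, layer)


def interpolate(mesh: HermiteMesh, eid: int, xi) -> np.ndarray:
    """Position inside element ``eid`` at local coordinates xi.

    ``xi`` may be (xi1, xi2) — evaluated on the outer surface — or
    (xi1, xi2, xi3) for the full bicubic-linear volume interpolation.
    """
    xi = np.asarray(xi, dtype=float)
    if xi.shape[-1] == 2:
        return surface_point(mesh, eid, xi[..., 0], xi[..., 1], layer=1)
    if xi.shape[-1] != 3:
        raise ValueError("xi must have 2 or 3 components")
    if np.any(xi < 0) or np.any(xi > 1):
        raise ValueError("xi must lie in [0, 1]")
    inner = surface_point(mesh, eid, xi[..., 0], xi[..., 1], layer=0)
    outer = surface_point(mesh, eid, xi[..., 0], xi[..., 1], layer=1)
    t = xi[..., 2:3]
    return (1.0 - t) * inner + t * outer


def xi_jacobian(mesh: HermiteMesh, eid: int, xi) -> np.ndarray:
    """3x3 Jacobian du/dxi at a volume point; columns are d/dxi1, d/dxi2, d/dxi3."""
    xi = np.asarray(xi, dtype=float).reshape(3)
    x1, x2, t = xi
    g = np.empty((3, 3))
    inner1 = surface_point(mesh, eid, x1, x2, 0, d1=1)
    outer1 = surface_point(mesh, eid, x1, x2, 1, d1=1)
    inner2 = surface_point(mesh, eid, x1, x2, 0, d2=1)
    outer2 = surface_point(mesh, eid, x1, x2, 1, d2=1)
    inner0 = surface_point(mesh, eid, x1, x2, 0)
    outer0 = surface_point(mesh, eid, x1, x2, 1)
    g[:, 0] = (1 - t) * inner1 + t * outer1
    g[:, 1] = (1 - t) * inner2 + t * outer2
    g[:, 2] = outer0 - inner0
    return g


def surface_normal(mesh, eid, xi1, xi2, layer: int = 1) -> np.ndarray:
    """Outward unit normal of a face (cross of the xi1 and xi2 tangents).

    The template construction orders nodes so that t1 x t2 points outward on
    the outer layer.
    """
    t1 = surface_point(mesh, eid, xi1, xi2, layer, d1=1)
    t2 = surface_point(mesh, eid, xi1, xi2, layer, d2=1)
    n = np.cross(t1, t2)
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    return n / np.where(norm == 0, 1.0, norm)


# ---------------------------------------------------------------------------
# Edges, arc lengths, scale factors
# ---------------------------------------------------------------------------

def element_edges(mesh: HermiteMesh):
    """Unique element face edges as (node_a, node_b, direction) triples.

    direction 0 = along xi1, direction 1 = along xi2.  Both layers contribute
    their own edges (scale factors are nodal, and the two layers generally
    have different physical arc lengths).
    """
    seen = set()
    edges = []
    for elem in mesh.elements:
        for layer in (0, 1):
            n1, n2, n3, n4 = elem.layer_nodes(layer)
            for a, b, d in ((n1, n2, 0), (n3, n4, 0), (n1, n3, 1), (n2, n4, 1)):
                key = (min(a, b), max(a, b), d)
                if key not in seen:
                    seen.add(key)
                    edges.append((a, b, d))
    return edges


def edge_arc_length(mesh: HermiteMesh, a: int, b: int, direction: int,
                    n_gauss: int = 16) -> float:
    na, nb = mesh.nodes[a], mesh.nodes[b]
    da = na.d1 if direction == 0 else na.d2
    db = nb.d1 if direction == 0 else nb.d2
    Sa = mesh.scale_factors[a, direction]
    Sb = mesh.scale_factors[b, direction]
    return arc_length_1d(na.x, nb.x, da, db, (Sa, Sb), n_gauss=n_gauss)


def arc_length(mesh: HermiteMesh, eid: int, direction: int, layer: int = 1,
               side: int = 0) -> float:
    """Arc length of one edge of an element face.

    ``direction`` 0/1 picks the xi direction; ``side`` 0/1 picks which of the
    two parallel edges of the face.
    """
    elem = mesh.elements[eid]
    n1, n2, n3, n4 = elem.layer_nodes(layer)
    if direction == 0:
        a, b = (n1, n2) if side == 0 else (n3, n4)
    else:
        a, b = (n1, n3) if side == 0 else (n2, n4)
    return edge_arc_length(mesh, a, b, direction)


def update_scale_factors(mesh: HermiteMesh, tol: float = 1e-9,
                         max_iter: int = 50) -> HermiteMesh:
    """Fixed-point iteration of the arc-length / scale-factor coupling.

    First-derivative vectors are normalized to unit magnitude (their length
    is what the scale factor expresses), then nodal scale factors are set to
    the mean arc length of the adjacent element edges in each xi direction
    and re-iterated until the largest relative change falls below ``tol``.
    Raises :class:`ScaleFactorError` on non-convergence.
    """
    for node in mesh.nodes:
        for name in ("d1", "d2"):
            v = getattr(node, name)
            m = np.linalg.norm(v)
            if m > 1e-14:
                setattr(node, name, v / m)
    edges = element_edges(mesh)
    # adjacency: node -> list of edge indices per direction
    adj = {0: {}, 1: {}}
    for idx, (a, b, d) in enumerate(edges):
        adj[d].setdefault(a, []).append(idx)
        adj[d].setdefault(b, []).append(idx)

    residual = np.inf
    for _ in range(max_iter):
        lengths = np.array(
            [edge_arc_length(mesh, a, b, d) for a, b, d in edges]
        )
        newS = mesh.scale_factors.copy()
        for d in (0, 1):
            for nid, eidx in adj[d].items():
                newS[nid, d] = max(float(np.mean(lengths[eidx])), 1e-12)
        residual = float(
            np.max(np.abs(newS - mesh.scale_factors) / np.maximum(newS, 1e-12))
        )
        mesh.scale_factors = newS
        if residual < tol:
            return mesh
    raise ScaleFactorError(residual, max_iter)
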