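"""Readers and writers for the package's file formats.

Meshes use a small JSON dialect with canonical key order and 9-significant-
digit float quantization, so write -> read -> write is byte-identical.
Volumes are multi-page TIFF stacks, tables are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .hermite import HermiteElement, HermiteMesh, MeshNode

__all__ = [
    "MeshParseError",
    "mesh_to_dict",
    "mesh_from_dict",
    "save_mesh",
    "load_mesh",
    "save_volume",
    "load_volume",
]


class MeshParseError(ValueError):
    """Mesh JSON schema violation; the message names the offending field."""


def _q(x: float) -> float:
    """Quantize to 9 significant digits (idempotent under re-parse)."""
    return float(f"{float(x):.9g}")


def _qv(v) -> list:
    return [_q(x) for x in np.asarray(v, dtype=float).ravel()]


def mesh_to_dict(mesh: HermiteMesh) -> dict:
    return {
        "nodes": [
            {"x": _qv(n.x), "dxi1": _qv(n.d1), "dxi2": _qv(n.d2),
             "dxi1xi2": _qv(n.d12)}
            for n in mesh.nodes
        ],
        "elements": [
            {"nodes": list(e.node_ids), "basis": list(e.basis)}
            for e in mesh.elements
        ],
        "scale_factors": [_qv(s) for s in mesh.scale_factors],
        "topology_tag": mesh.topology_tag,
        "tube_shape": list(mesh.tube_shape) if mesh.tube_shape else None,
    }


def _require(obj, key, where):
    if isinstance(obj, dict):
        if key not in obj:
            raise MeshParseError(f"missing field '{where}/{key}'")
        return obj[key]
    raise MeshParseError(f"expected object at '{where}'")


def mesh_from_dict(data: dict) -> HermiteMesh:
    nodes_raw = _require(data, "nodes", "")
    elements_raw = _require(data, "elements", "")
    sf_raw = _require(data, "scale_factors", "")
    nodes = []
    for i, nd in enumerate(nodes_raw):
        vals = []
        for key in ("x", "dxi1", "dxi2", "dxi1xi2"):
            v = _require(nd, key, f"/nodes/{i}")
            if len(v) != 3:
                raise MeshParseError(
                    f"field '/nodes/{i}/{key}' must have 3 components")
            vals.append(np.asarray(v, dtype=float))
        nodes.append(MeshNode(*vals))
    elements = []
    for i, el in enumerate(elements_raw):
        nid = _require(el, "nodes", f"/elements/{i}")
        basis = _require(el, "basis", f"/elements/{i}")
        elements.append(HermiteElement(tuple(nid), tuple(basis)))
    sf = np.asarray(sf_raw, dtype=float)
    shape = data.get("tube_shape")
    return HermiteMesh(nodes, elements, sf,
                       topology_tag=data.get("topology_tag", "tube"),
                       tube_shape=tuple(shape) if shape else None)


def save_mesh(mesh: HermiteMesh, path) -> None:
    Path(path).write_text(
        json.dumps(mesh_to_dict(mesh), indent=1) + "\n")


def load_mesh(path) -> HermiteMesh:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise MeshParseError(f"invalid mesh JSON: {exc}") from exc
    return mesh_from_dict(data)


def save_volume(array: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(str(path), np.asarray(array))


def load_volume(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(str(path))
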