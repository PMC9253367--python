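"""Memory-bounded tiling of large 3D stacks, merging, masking and Dice metrics.

Large confocal volumes cannot be processed whole; they are cut into
fixed-size overlapping windows laid out on a stride lattice (overlap =
window - stride per axis), processed tile by tile, and merged back.  The
volume is first cropped (origin-anchored) so that (dim - window) is a
multiple of the stride on every axis, making the lattice exact and every
tile traceable by its origin index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TileSet",
    "slice_volume",
    "merge_tiles",
    "dice_metrics",
    "apply_mask",
]


@dataclass
class TileSet:
    """Sliced sub-volumes with their lattice bookkeeping.

    ``tiles`` is a list of (origin, array) pairs where origin is the (z, y, x)
    voxel index of the tile's corner in the cropped volume; tiles are in
    lattice order (axis 0 slowest).
    """

    tiles: list
    window: tuple
    stride: tuple
    cropped_shape: tuple

    @property
    def overlap(self) -> tuple:
        return tuple(w - s for w, s in zip(self.window, self.stride))

    @property
    def grid_shape(self) -> tuple:
        return tuple((c - w) // s + 1 for c, w, s in
                     zip(self.cropped_shape, self.window, self.stride))


def _as_triple(v) -> tuple:
    if np.ndim(v) == 0:
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError("expected a scalar or a 3-tuple")
    return t


def slice_volume(volume: np.ndarray, window=(128, 128, 128),
                 stride=(78, 78, 78)) -> TileSet:
    """Cut a volume into a stride lattice of fixed-size overlapping tiles.

    The volume is cropped at the trailing end of each axis to the largest
    length with (length - window) an exact multiple of stride.  Axes shorter
    than the window are an error.
    """
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError("volume must be 3D")
    window = _as_triple(window)
    stride = _as_triple(stride)
    if any(s <= 0 for s in stride) or any(w <= 0 for w in window):
        raise ValueError("window and stride must be positive")
    if any(d < w for d, w in zip(vol.shape, window)):
        raise ValueError(
            f"volume shape {vol.shape} smaller than window {window}")
    counts = [(d - w) // s + 1 for d, w, s in zip(vol.shape, window, stride)]
    cropped = tuple(w + (n - 1) * s for w, s, n in zip(window, stride, counts))
    vol = vol[: cropped[0], : cropped[1], : cropped[2]]
    tiles = []
    for i0 in range(counts[0]):
        for i1 in range(counts[1]):
            for i2 in range(counts[2]):
                o = (i0 * stride[0], i1 * stride[1], i2 * stride[2])
                tiles.append((o, vol[o[0]:o[0] + window[0],
                                     o[1]:o[1] + window[1],
                                     o[2]:o[2] + window[2]].copy()))
    return TileSet(tiles, window, stride, cropped)


def merge_tiles(ts: TileSet, mode: str = "last") -> np.ndarray:
    """Reassemble the cropped volume from a complete tile lattice.

    ``mode='last'`` resolves overlaps by last-writer-wins in lattice order;
    ``mode='or'`` takes the logical union (for binary prediction maps).
    A missing lattice tile is an error naming its origin.
    """
    window, stride = ts.window, ts.stride
    counts = ts.grid_shape
    have = {tuple(o): arr for o, arr in ts.tiles}
    out = None
    for i0 in range(counts[0]):
        for i1 in range(counts[1]):
            for i2 in range(counts[2]):
                o = (i0 * stride[0], i1 * stride[1], i2 * stride[2])
                if o not in have:
                    raise ValueError(f"missing tile at origin {o}")
                arr = have[o]
                if tuple(arr.shape) != window:
                    raise ValueError(
                        f"tile at {o} has shape {arr.shape}, expected {window}")
                if out is None:
                    out = np.zeros(ts.cropped_shape, dtype=arr.dtype)
                sl = tuple(slice(a, a + w) for a, w in zip(o, window))
                if mode == "or":
                    out[sl] |= arr.astype(out.dtype)
                elif mode == "last":
                    out[sl] = arr
                else:
                    raise ValueError("mode must be 'last' or 'or'")
    return out


def dice_metrics(pred, truth, n_classes: int = 2):
    """(Dice coefficient, soft multi-class Dice loss).

    The coefficient is 2|A.B| / (|A| + |B|) on binarized masks (both-empty
    counts as perfect agreement, coefficient 1).  The loss averages the soft
    per-class Dice over ``n_classes`` using the prediction scores directly
    and negates it, so a perfect two-class prediction scores -1.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth)
    if pred.shape != truth.shape and pred.shape[:-1] != truth.shape:
        raise ValueError("prediction and truth shapes must match")

    pb = pred > 0.5 if pred.shape == truth.shape else np.argmax(pred, -1) > 0
    tb = np.asarray(truth) > 0
    inter = np.logical_and(pb, tb).sum()
    denom = pb.sum() + tb.sum()
    coefficient = 1.0 if denom == 0 else 2.0 * inter / denom

    loss = 0.0
    for c in range(n_classes):
        if pred.shape == truth.shape:
            s = pred if c == 1 else 1.0 - pred
        else:
            s = pred[..., c]
        l = (np.asarray(truth) == c).astype(float)
        sl = float((s * l).sum())
        tot = float(s.sum() + l.sum())
        loss += 0.0 if tot == 0 else sl / tot
    dice_loss = -2.0 * loss / n_classes
    return float(coefficient), float(dice_loss)


def apply_mask(prediction: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero every voxel outside the (myocardium) mask."""
    pred = np.asarray(prediction)
    m = np.asarray(mask)
    if pred.shape != m.shape:
        raise ValueError(
            f"shape mismatch: prediction {pred.shape} vs mask {m.shape}")
    return np.where(m.astype(bool), pred, np.zeros((), dtype=pred.dtype))
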