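"""Evaluation metrics: IoU, Hausdorff distance and Euclidean distance.

The segmentation and detection stages are scored by intersection-over-union
(overlap of predicted and reference pixel sets) and the symmetric Hausdorff
distance (worst-case boundary disagreement); reconstructed tumor volumes are
additionally scored by a mean surface distance built from the pointwise 3-D
Euclidean distance.

Conventions (documented and tested, since degenerate inputs do occur):

* ``iou`` of two empty masks is 1.0 (perfect agreement); empty vs non-empty
  is 0.0;
* Hausdorff distances require non-empty point sets and raise otherwise;
* volume distances are computed in physical units via ``VoxelVolume.spacing``.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import MaskImage, VoxelVolume

__all__ = [
    "iou", "directed_hausdorff", "hausdorff", "euclidean3", "surface_metrics",
]


def _as_mask_array(mask) -> np.ndarray:
    if isinstance(mask, MaskImage):
        return mask.labels
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("mask must be 2-D")
    return (arr != 0).astype(np.uint8)


def _as_points(points) -> np.ndarray:
    """Coerce a point set (array of coordinates or set of tuples) to (n, d)."""
    if isinstance(points, (set, frozenset, list)):
        points = np.array(sorted(points), dtype=float) if len(points) else \
            np.empty((0, 2))
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2:
        raise ValueError("point set must be an (n, d) array")
    return arr


def iou(a, b) -> float:
    """Intersection over union of two same-shape binary masks.

    |A ∩ B| / |A ∪ B| over the sets of non-zero pixels.  Two empty masks
    agree perfectly and score 1.0; one-sided empty scores 0.0.
    """
    a_arr, b_arr = _as_mask_array(a), _as_mask_array(b)
    if a_arr.shape != b_arr.shape:
        raise ValueError(f"mask shapes differ: {a_arr.shape} vs {b_arr.shape}")
    inter = int(np.logical_and(a_arr, b_arr).sum())
    union = int(np.logical_or(a_arr, b_arr).sum())
    if union == 0:
        return 1.0
    return inter / union


def directed_hausdorff(a, b) -> float:
    """max over a in A of the distance from a to its nearest point of B."""
    a_pts, b_pts = _as_points(a), _as_points(b)
    if len(a_pts) == 0 or len(b_pts) == 0:
        raise ValueError("directed Hausdorff distance needs non-empty sets")
    d, _ = cKDTree(b_pts).query(a_pts)
    return float(np.max(d))


def hausdorff(a, b) -> float:
    """Symmetric Hausdorff distance max(h(A,B), h(B,A))."""
    return max(directed_hausdorff(a, b), directed_hausdorff(b, a))


def euclidean3(p, q) -> float:
    """Straight-line distance between two points in 3-D space."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != (3,) or q.shape != (3,):
        raise ValueError("points must be 3-vectors")
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise ValueError("points must be finite")
    return float(np.sqrt(((p - q) ** 2).sum()))


def _boundary_voxels(binary: np.ndarray) -> np.ndarray:
    """Voxels with at least one 6-connected background neighbour."""
    padded = np.pad(binary, 1)
    interior = np.ones_like(binary, dtype=bool)
    for axis in range(3):
        for shift in (-1, 1):
            interior &= np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1] > 0
    boundary = (binary > 0) & ~interior
    if not boundary.any():  # a fully interior blob cannot occur with padding,
        boundary = binary > 0  # but guard the degenerate single-voxel case
    return boundary


def surface_metrics(pred: VoxelVolume, truth: VoxelVolume,
                    threshold: float = 0.5) -> dict[str, float]:
    """Hausdorff and mean surface distance between two tumor volumes.

    ``hd`` is the symmetric Hausdorff distance over the binarised voxel point
    sets; ``ed`` is the symmetric mean nearest-neighbour distance between the
    binarised surfaces, which reduces to the pointwise 3-D Euclidean distance
    when each volume holds a single voxel.  Coordinates are scaled by the
    per-axis voxel spacing.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    if pred.shape != truth.shape:
        raise ValueError(f"volume shapes differ: {pred.shape} vs {truth.shape}")
    pred_bin = pred.binarize(threshold)
    truth_bin = truth.binarize(threshold)
    if pred_bin.sum() == 0:
        raise ValueError("predicted volume is empty after binarization")
    if truth_bin.sum() == 0:
        raise ValueError("truth volume is empty after binarization")
    spacing = np.asarray(pred.spacing, dtype=float)

    pred_pts = np.argwhere(pred_bin) * spacing
    truth_pts = np.argwhere(truth_bin) * spacing
    hd = hausdorff(pred_pts, truth_pts)

    pred_surface = np.argwhere(_boundary_voxels(pred_bin)) * spacing
    truth_surface = np.argwhere(_boundary_voxels(truth_bin)) * spacing
    d_pt, _ = cKDTree(truth_surface).query(pred_surface)
    d_tp, _ = cKDTree(pred_surface).query(truth_surface)
    ed = 0.5 * (float(np.mean(d_pt)) + float(np.mean(d_tp)))
    return {"hd": hd, "ed": ed}
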