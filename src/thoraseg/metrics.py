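"""Segmentation evaluation: Dice coefficient, Hausdorff distance, ASSD.

The Dice similarity coefficient (DSC) is the overlap ratio
``2|X ∩ Y| / (|X| + |Y|)``; 1 is a perfect match.  The Hausdorff distance
(HD) is ``max(h(A,B), h(B,A))`` where ``h(A,B)`` is the largest distance from
a border point of A to its nearest border point of B.  The average symmetric
surface distance (ASSD) sums every border point's nearest-neighbour distance
in both directions and divides by the total number of border points.

Border points are foreground voxels with at least one background
face-neighbour (4-connectivity in 2D, 6-connectivity in 3D).  Distances are
Euclidean over physical coordinates ``index × spacing``; with unit spacing on
a 128×128 grid the largest attainable distance is the image diagonal,
127·√2 ≈ 181.0193 mm.  Both distance metrics are undefined when either mask
is empty; such cases are flagged and excluded from dataset means rather than
silently reported as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import GridError, PairingError, UndefinedMetricError

__all__ = [
    "dsc",
    "surface_points",
    "hausdorff",
    "assd",
    "distance_range",
    "evaluate_dataset",
    "MetricReport",
]


def distance_range(shape: tuple[int, ...], spacing=None) -> tuple[float, float]:
    """Attainable range of HD/ASSD on a grid: (0, image diagonal) in mm.

    The upper bound treats each pixel as a unit cell, so for a 128×128 image
    with 1 mm pixels the diagonal is √(128² + 128²) ≈ 181.0193 mm — the
    conventional reporting range for surface distances on that grid.
    """
    dims = np.asarray(shape, dtype=float)
    sp = np.ones_like(dims) if spacing is None else np.asarray(spacing, dtype=float)
    return 0.0, float(np.sqrt(((dims * sp) ** 2).sum()))


def _binary(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def _check_shapes(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise GridError(f"mask shapes differ: {x.shape} vs {y.shape}")


def dsc(x: np.ndarray, y: np.ndarray) -> float:
    """Dice similarity coefficient in [0, 1]; DSC(∅, ∅) is defined as 1.0."""
    x = _binary(x)
    y = _binary(y)
    _check_shapes(x, y)
    nx = int(x.sum())
    ny = int(y.sum())
    if nx + ny == 0:
        return 1.0
    return 2.0 * int((x & y).sum()) / (nx + ny)


def surface_points(mask: np.ndarray) -> np.ndarray:
    """Indices (n_points, ndim) of border voxels of a binary mask.

    A voxel is a border point iff it is foreground and at least one of its
    face neighbours (or the outside of the array) is background.
    """
    mask = _binary(mask)
    if not mask.any():
        return np.empty((0, mask.ndim), dtype=np.intp)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    # border_value=0: voxels on the array edge count as having background outside
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return np.argwhere(mask & ~eroded)


def _surface_sets(a: np.ndarray, b: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    a = _binary(a)
    b = _binary(b)
    _check_shapes(a, b)
    if not a.any() or not b.any():
        raise UndefinedMetricError("surface-distance metrics are undefined for empty masks")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (a.ndim,):
        raise GridError(f"spacing must have {a.ndim} components for a {a.ndim}D mask")
    sa = surface_points(a) * spacing
    sb = surface_points(b) * spacing
    return sa, sb


def hausdorff(a: np.ndarray, b: np.ndarray, spacing=(1.0, 1.0)) -> float:
    """Symmetric Hausdorff distance between mask borders, in mm."""
    sa, sb = _surface_sets(a, b, spacing)
    d_ab = cKDTree(sb).query(sa)[0]
    d_ba = cKDTree(sa).query(sb)[0]
    return float(max(d_ab.max(), d_ba.max()))


def assd(a: np.ndarray, b: np.ndarray, spacing=(1.0, 1.0)) -> float:
    """Average symmetric surface distance between mask borders, in mm."""
    sa, sb = _surface_sets(a, b, spacing)
    d_ab = cKDTree(sb).query(sa)[0]
    d_ba = cKDTree(sa).query(sb)[0]
    return float((d_ab.sum() + d_ba.sum()) / (len(sa) + len(sb)))


@dataclass
class MetricReport:
    """Per-case metrics plus dataset mean ± (sample) std."""

    per_case: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)
    n_undefined_distances: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.per_case)


def _mean_std(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    mean = float(arr.mean())
    std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, std


def _case_metrics(pred, truth, spacing, mode):
    """One case: 2D per-slice metrics averaged over slices, or direct 3D."""
    pred = _binary(pred)
    truth = _binary(truth)
    _check_shapes(pred, truth)
    if mode == "volume3d" or pred.ndim == 2:
        sp = spacing if pred.ndim == 3 else spacing[-2:]
        d = dsc(pred, truth)
        try:
            hd = hausdorff(pred, truth, sp)
            as_ = assd(pred, truth, sp)
        except UndefinedMetricError:
            hd = as_ = None
        return d, hd, as_
    # slice2d: average metrics over slices; skip slice distances where undefined
    dscs, hds, assds = [], [], []
    sp2 = spacing[-2:]
    for k in range(pred.shape[0]):
        dscs.append(dsc(pred[k], truth[k]))
        try:
            hds.append(hausdorff(pred[k], truth[k], sp2))
            assds.append(assd(pred[k], truth[k], sp2))
        except UndefinedMetricError:
            pass
    hd = float(np.mean(hds)) if hds else None
    as_ = float(np.mean(assds)) if assds else None
    return float(np.mean(dscs)), hd, as_


def evaluate_dataset(
    pred_masks: list[np.ndarray],
    truth_masks: list[np.ndarray],
    spacings: list[tuple[float, ...]] | tuple[float, ...] = (1.0, 1.0, 1.0),
    case_ids: list[str] | None = None,
    mode: str = "slice2d",
) -> MetricReport:
    """Evaluate paired predictions against ground truth.

    ``mode='slice2d'`` (default) computes 2D metrics per slice and averages
    them within a case before aggregating across cases; ``mode='volume3d'``
    computes a single 3D metric per case.  Cases with undefined distances
    (empty masks) keep their DSC but are excluded from HD/ASSD means, with a
    count recorded on the report.
    """
    if len(pred_masks) != len(truth_masks):
        raise PairingError(
            f"{len(pred_masks)} predictions cannot be paired with {len(truth_masks)} truths"
        )
    if len(pred_masks) == 0:
        raise PairingError("empty dataset")
    if mode not in ("slice2d", "volume3d"):
        raise ValueError(f"unknown mode {mode!r}")
    if case_ids is None:
        case_ids = [f"case-{i:03d}" for i in range(len(pred_masks))]
    if not isinstance(spacings, list):
        spacings = [tuple(spacings)] * len(pred_masks)

    report = MetricReport()
    dscs, hds, assds = [], [], []
    for cid, pred, truth, sp in zip(case_ids, pred_masks, truth_masks, spacings):
        d, hd, as_ = _case_metrics(pred, truth, sp, mode)
        report.per_case.append({"case_id": cid, "dsc": d, "hd_mm": hd, "assd_mm": as_})
        dscs.append(d)
        if hd is None:
            report.n_undefined_distances += 1
        else:
            hds.append(hd)
            assds.append(as_)
    for name, vals in (("dsc", dscs), ("hd_mm", hds), ("assd_mm", assds)):
        mean, std = _mean_std(vals)
        report.summary[f"{name}_mean"] = mean
        report.summary[f"{name}_std"] = std
    report.summary["n_cases"] = len(pred_masks)
    report.summary["n_undefined_distances"] = report.n_undefined_distances
    return report
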