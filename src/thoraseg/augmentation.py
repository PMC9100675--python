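"""Domain-knowledge data augmentation: synthetic nodule insertion.

Nodule regions of interest (HU patch + binary mask) are extracted from donor
cases and pasted into recipient slices at sites sampled inside the recipient
lung, so the training set gains pathological findings exactly where they
occur anatomically.  The recipient's ground-truth masks are updated
coherently: the pasted mask becomes a new nodule instance and is unioned into
the lung mask (a coherent protocol counts nodules as lung).  Training with
defective labels can deliberately skip that union — see the experiments
module — which reproduces the incoherent label condition where an image
contains a nodule the lung label excludes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .ct_io import CTVolume, MaskSet
from .errors import ConfigurationError, ExtractionError, GridError, PlacementError

__all__ = [
    "NoduleROI",
    "AugmentationRecord",
    "extract_nodule",
    "build_roi_bank",
    "sample_insertion_site",
    "insert_nodule",
    "augment_training_set",
]

DEFAULT_ROI_BANK_SIZE = 40


@dataclass
class NoduleROI:
    """A cropped nodule: HU patch, aligned binary mask, provenance."""

    patch: np.ndarray
    mask: np.ndarray
    source_id: str = ""
    diameter_mm: float = 0.0

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch)
        self.mask = (np.asarray(self.mask) != 0).astype(np.uint8)
        if self.patch.shape != self.mask.shape:
            raise GridError("ROI patch and mask shapes differ")
        _, n = ndimage.label(self.mask)
        if n != 1:
            raise ExtractionError(f"ROI mask must be a single connected component, found {n}")


@dataclass
class AugmentationRecord:
    """Provenance of one insertion (manifest entry)."""

    recipient_id: str
    roi_source_id: str
    center_index: tuple[int, ...]
    seed: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["center_index"] = [int(v) for v in self.center_index]
        return d


def equivalent_diameter_mm(n_voxels: int, spacing: tuple[float, ...]) -> float:
    """Diameter of the sphere with the same volume as ``n_voxels`` voxels."""
    vol = n_voxels * float(np.prod(spacing))
    return (6.0 * vol / math.pi) ** (1.0 / 3.0)


def extract_nodule(volume: CTVolume, nodule_mask: np.ndarray, margin_mm: float = 2.0) -> NoduleROI:
    """Crop the bounding box of a nodule mask (dilated by ``margin_mm``)."""
    mask = (np.asarray(nodule_mask) != 0)
    if mask.shape != volume.voxels.shape:
        raise GridError("nodule mask shape differs from volume shape")
    if not mask.any():
        raise ExtractionError("empty nodule mask")
    _, n = ndimage.label(mask)
    if n != 1:
        raise ExtractionError(f"nodule mask has {n} connected components, expected 1")
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    margin = [int(math.ceil(margin_mm / s)) for s in volume.spacing]
    lo = np.maximum(lo - margin, 0)
    hi = np.minimum(hi + margin, np.asarray(mask.shape) - 1)
    sl = tuple(slice(a, b + 1) for a, b in zip(lo, hi))
    return NoduleROI(
        patch=volume.voxels[sl].copy(),
        mask=mask[sl],
        source_id=volume.id,
        diameter_mm=equivalent_diameter_mm(int(mask.sum()), volume.spacing),
    )


def build_roi_bank(cases, margin_mm: float = 2.0, max_size: int = DEFAULT_ROI_BANK_SIZE) -> list[NoduleROI]:
    """Extract nodule ROIs from donor cases until the bank is full."""
    bank: list[NoduleROI] = []
    for case in cases:
        for nod in case.truth.nodules:
            if len(bank) >= max_size:
                return bank
            bank.append(extract_nodule(case.volume, nod, margin_mm=margin_mm))
    return bank


def _footprint_slices(center, shape_roi, shape_grid):
    """Grid slices for pasting an ROI centred at ``center``; None if outside."""
    sl = []
    for c, r, g in zip(center, shape_roi, shape_grid):
        start = int(c) - r // 2
        stop = start + r
        if start < 0 or stop > g:
            return None
        sl.append(slice(start, stop))
    return tuple(sl)


def sample_insertion_site(
    lung: np.ndarray,
    roi: NoduleROI,
    peripheral: bool = False,
    rng_seed: int | np.random.Generator = 0,
    max_tries: int = 500,
) -> tuple[int, ...]:
    """Sample a paste centre for an ROI inside a lung mask.

    Interior mode requires the pasted mask to lie entirely inside the lung;
    peripheral mode requires it to intersect the lung border band.
    Deterministic for a fixed seed.
    """
    lung = np.asarray(lung).astype(bool)
    if not lung.any():
        raise PlacementError("empty lung mask")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    structure = ndimage.generate_binary_structure(lung.ndim, 1)
    border = lung & ~ndimage.binary_erosion(lung, structure=structure, border_value=0)
    pool = np.argwhere(border if peripheral else lung)
    mask = roi.mask.astype(bool)
    for _ in range(max_tries):
        center = tuple(int(v) for v in pool[rng.integers(len(pool))])
        sl = _footprint_slices(center, mask.shape, lung.shape)
        if sl is None:
            continue
        footprint = np.zeros(lung.shape, dtype=bool)
        footprint[sl] = mask
        if peripheral:
            if (footprint & border).any() and (footprint & lung).any():
                return center
        else:
            if not (footprint & ~lung).any():
                return center
    raise PlacementError(f"no feasible insertion site after {max_tries} tries")


def insert_nodule(
    volume: CTVolume,
    masks: MaskSet,
    roi: NoduleROI,
    center: tuple[int, ...],
    blend: str = "replace",
    seed: int = 0,
    update_lung: bool = True,
) -> tuple[CTVolume, MaskSet, AugmentationRecord]:
    """Paste an ROI into a recipient volume at ``center``.

    Voxels outside the pasted mask footprint are bit-identical to the input.
    ``blend='replace'`` copies donor HU inside the mask; ``blend='max'``
    takes the voxelwise maximum.  The pasted mask is appended as a new nodule
    instance; with ``update_lung`` it is also unioned into the lung mask
    (coherent ground truth).
    """
    if blend not in ("replace", "max"):
        raise ConfigurationError(f"unknown blend mode {blend!r}")
    if masks.lung.shape != volume.voxels.shape:
        raise GridError("mask grid does not match volume grid")
    sl = _footprint_slices(center, roi.mask.shape, volume.voxels.shape)
    if sl is None:
        raise PlacementError(f"ROI footprint at centre {center} falls outside the grid")
    voxels = volume.voxels.copy()
    m = roi.mask.astype(bool)
    patch = roi.patch.astype(voxels.dtype)
    region = voxels[sl]
    if blend == "replace":
        region[m] = patch[m]
    else:
        region[m] = np.maximum(region[m], patch[m])
    voxels[sl] = region

    pasted = np.zeros(volume.voxels.shape, dtype=np.uint8)
    pasted[sl] = roi.mask
    new_masks = masks.copy()
    new_masks.nodules.append(pasted)
    if update_lung:
        new_masks.lung = (new_masks.lung.astype(bool) | pasted.astype(bool)).astype(np.uint8)

    out_vol = CTVolume(voxels=voxels, spacing=volume.spacing, origin=volume.origin, id=volume.id)
    record = AugmentationRecord(
        recipient_id=volume.id,
        roi_source_id=roi.source_id,
        center_index=tuple(int(c) for c in center),
        seed=int(seed),
    )
    return out_vol, new_masks, record


def augment_training_set(
    cases: list,
    roi_bank: list[NoduleROI],
    rate: float = 0.5,
    seed: int = 0,
    blend: str = "replace",
    update_defective_lung: bool = False,
) -> tuple[list, list[AugmentationRecord]]:
    """Insert one random ROI into a seeded-random subset of cases.

    ``ceil(rate × n)`` cases are selected; the others are returned untouched.
    Each selected case's volume gains one pasted nodule and its coherent
    truth masks are always updated.  The defective original lung label is
    handled in one of two ways: with ``update_defective_lung`` it is unioned
    with the pasted mask (coherent labels everywhere); without it the label
    is updated the way the case's own annotation protocol would have
    annotated the new image — a protocol that excludes tumour masses carves
    the inserted nodule out of its lung label — which reproduces augmentation
    on top of incoherent annotations: the image shows a nodule the training
    label excludes.  Returns the augmented case list (inputs are not mutated)
    and the manifest of insertion records.
    """
    if not roi_bank:
        raise ConfigurationError("ROI bank is empty")
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError("rate must be in [0, 1]")
    n = len(cases)
    n_aug = int(math.ceil(rate * n))
    rng = np.random.default_rng(seed)
    selected = set(rng.choice(n, size=n_aug, replace=False).tolist()) if n_aug else set()
    out_cases = []
    manifest: list[AugmentationRecord] = []
    from copy import deepcopy

    for i, case in enumerate(cases):
        if i not in selected:
            out_cases.append(case)
            continue
        roi = roi_bank[int(rng.integers(len(roi_bank)))]
        case_seed = int(rng.integers(2**31))
        center = sample_insertion_site(
            case.truth.lung, roi, peripheral=False,
            rng_seed=np.random.default_rng(case_seed),
        )
        new_vol, new_truth, record = insert_nodule(
            case.volume, case.truth, roi, center, blend=blend, seed=case_seed
        )
        new_case = deepcopy(case)
        new_case.volume = new_vol
        new_case.truth = new_truth
        pasted = new_truth.nodules[-1].astype(bool)
        if update_defective_lung:
            _, om, _ = insert_nodule(case.volume, case.original_masks, roi, center, blend=blend, seed=case_seed)
            new_case.original_masks = om
        else:
            om = case.original_masks.copy()
            spec = getattr(case, "spec", None)
            protocol = getattr(spec, "protocol", None)
            if protocol in ("nodules_excluded", "auto_noisy"):
                om.lung = (om.lung.astype(bool) & ~pasted).astype(np.uint8)
            elif protocol == "coherent":
                om.lung = (om.lung.astype(bool) | pasted).astype(np.uint8)
            # other/unknown protocols: label left as annotated
            om.nodules.append(new_truth.nodules[-1].copy())
            new_case.original_masks = om
        out_cases.append(new_case)
        manifest.append(record)
    return out_cases, manifest
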