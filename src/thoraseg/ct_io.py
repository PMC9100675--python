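"""Reading, writing and in-memory representation of CT volumes and masks.

All arrays in this package use the ``(z, y, x)`` axis order: index 0 walks
through slices, indices 1 and 2 are the in-plane rows and columns.  Physical
position of voxel ``(k, i, j)`` is ``origin + (k, i, j) * spacing`` with
0-based indices and spacing in millimetres.

NIfTI (``.nii``/``.nii.gz``) is the canonical interchange format; NRRD is
supported for both reading and writing, DICOM series directories are
read-only (single-frame CT slices sorted by slice position).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .errors import FormatError, GridError, MetadataError

__all__ = ["CTVolume", "MaskSet", "read_volume", "write_volume", "read_mask", "write_mask"]

#: HU bounds used only for sanity checks; 12-bit CT plus offset.
_HU_MIN, _HU_MAX = -1024.0, 3071.0


@dataclass
class CTVolume:
    """A 3D scalar field of Hounsfield units on a regular grid.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, h, w)
        HU values; must be finite.
    spacing : tuple of float
        Voxel spacing in mm, ordered (z, y, x); strictly positive.
    origin : tuple of float
        Physical position of voxel (0, 0, 0) in mm, ordered (z, y, x).
    id : str
        Free-form case identifier.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise GridError(f"CTVolume expects a 3D array, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise MetadataError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if not np.isfinite(self.voxels).all():
            raise MetadataError("HU values must be finite (no NaN/inf)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def _as_binary(mask: np.ndarray) -> np.ndarray:
    """Map any nonzero value to 1 (uint8); tolerant of annotation dialects."""
    return (np.asarray(mask) != 0).astype(np.uint8)


@dataclass
class MaskSet:
    """Binary masks (lung, airway, nodule instances) sharing one voxel grid."""

    lung: np.ndarray
    airway: np.ndarray | None = None
    nodules: list[np.ndarray] = field(default_factory=list)
    grid_id: str = ""

    def __post_init__(self) -> None:
        self.lung = _as_binary(self.lung)
        if self.airway is not None:
            self.airway = _as_binary(self.airway)
            if self.airway.shape != self.lung.shape:
                raise GridError("airway mask shape differs from lung mask shape")
        clean = []
        for nod in self.nodules:
            nod = _as_binary(nod)
            if nod.shape != self.lung.shape:
                raise GridError("nodule mask shape differs from lung mask shape")
            clean.append(nod)
        self.nodules = clean

    @property
    def shape(self) -> tuple[int, ...]:
        return self.lung.shape

    def copy(self) -> "MaskSet":
        return MaskSet(
            lung=self.lung.copy(),
            airway=None if self.airway is None else self.airway.copy(),
            nodules=[n.copy() for n in self.nodules],
            grid_id=self.grid_id,
        )


def _sitk_to_volume(img: sitk.Image, case_id: str) -> CTVolume:
    arr = sitk.GetArrayFromImage(img)  # already (z, y, x)
    if arr.ndim == 2:
        arr = arr[None]
    spacing = tuple(reversed(img.GetSpacing()))  # sitk is (x, y, z)
    origin = tuple(reversed(img.GetOrigin()))
    if len(spacing) != 3:
        raise MetadataError(f"expected 3 spacing components, file header has {len(spacing)}")
    if any(s <= 0 for s in spacing):
        raise MetadataError(f"non-positive spacing in file header: {spacing}")
    return CTVolume(voxels=arr, spacing=spacing, origin=origin, id=case_id)


def read_volume(path: str | os.PathLike, format: str | None = None) -> CTVolume:
    """Read a CT volume from disk.

    Parameters
    ----------
    path : path
        File (NIfTI/NRRD) or directory (DICOM series).
    format : {"nifti", "nrrd", "dicom_series", None}
        Explicit format; inferred from the path when None (a directory is
        treated as a DICOM series).
    """
    path = os.fspath(path)
    if format is None:
        if os.path.isdir(path):
            format = "dicom_series"
        elif path.endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif path.endswith((".nrrd", ".nhdr", ".mhd", ".mha")):
            format = "nrrd"
        else:
            raise FormatError(f"cannot infer image format from path {path!r}")
    if format == "dicom_series":
        reader = sitk.ImageSeriesReader()
        series = reader.GetGDCMSeriesFileNames(path)
        if not series:
            raise FormatError(f"no DICOM series found under {path!r}")
        reader.SetFileNames(series)  # sorted by slice position by GDCM
        try:
            img = reader.Execute()
        except RuntimeError as exc:  # pragma: no cover - sitk error text varies
            raise FormatError(f"failed to read DICOM series at {path!r}: {exc}") from exc
    elif format in ("nifti", "nrrd"):
        if not os.path.exists(path):
            raise FormatError(f"no such file: {path!r}")
        try:
            img = sitk.ReadImage(path)
        except RuntimeError as exc:
            raise FormatError(f"failed to parse {path!r} as {format}: {exc}") from exc
    else:
        raise FormatError(f"unknown format {format!r}")
    case_id = os.path.basename(path.rstrip("/"))
    for suffix in (".nii.gz", ".nii", ".nrrd", ".nhdr", ".mhd", ".mha"):
        if case_id.endswith(suffix):
            case_id = case_id[: -len(suffix)]
            break
    return _sitk_to_volume(img, case_id)


def write_volume(vol: CTVolume, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a CT volume to NIfTI or NRRD.

    Integer HU round-trips bit-exactly; spacing round-trips to <=1e-6 mm.
    """
    path = os.fspath(path)
    if format is None:
        if path.endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif path.endswith((".nrrd", ".nhdr")):
            format = "nrrd"
        else:
            raise FormatError(f"cannot infer image format from path {path!r}")
    if format == "dicom_series":
        raise FormatError("DICOM support is read-only")
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent!r}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels))
    img.SetSpacing(tuple(reversed(vol.spacing)))
    img.SetOrigin(tuple(reversed(vol.origin)))
    sitk.WriteImage(img, path)


def read_mask(path: str | os.PathLike, format: str | None = None) -> np.ndarray:
    """Read a mask volume; any nonzero voxel maps to 1 (uint8)."""
    return _as_binary(read_volume(path, format=format).voxels)


def write_mask(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    path: str | os.PathLike,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    format: str | None = None,
) -> None:
    """Write a binary mask as an unsigned 8-bit volume."""
    vol = CTVolume(voxels=_as_binary(mask), spacing=spacing, origin=origin)
    write_volume(vol, path, format=format)
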