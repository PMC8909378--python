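"""Imaging data model and NIfTI I/O with strict grid-consistency checking.

Volumes, lung masks and five-class label maps live on a shared voxel grid.
Arrays are ordered ``(z, y, x)`` internally, so an axial slice is a fixed-z
plane — the orientation the slice-wise segmentation pipeline works in.
Label maps use the vocabulary {1..5} inside the lung and the ``OUTSIDE``
sentinel (0) elsewhere, so files on disk carry {0..5} with a conventional
zero background.

Loaders reject, and never silently repair, any geometry mismatch.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: Sentinel label for voxels outside the lung mask.
OUTSIDE = 0

#: Valid tissue classes (1 = normal lung ... 5 = consolidation).
CLASSES = (1, 2, 3, 4, 5)

_SPACING_TOL_MM = 1e-3


class AlignmentError(ValueError):
    """Two grids that must share geometry do not."""


class VocabularyError(ValueError):
    """A label map contains values outside {OUTSIDE, 1..5}."""


@dataclass
class CTVolume:
    """HU-valued scalar grid with spacing metadata.

    voxels : (z, y, x) float array in Hounsfield units
    spacing : (z, y, x) voxel size in mm
    origin : world-space position of voxel (0,0,0) in mm
    orientation : anatomical orientation tag (diagonal RAS by default)
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.voxels.shape}")
        if any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive and finite, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite HU values")

    @property
    def shape(self):
        return self.voxels.shape


@dataclass
class LungMask:
    """Binary lung parenchyma mask on the same grid as its volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        vals = np.unique(self.voxels)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError(f"mask values must be 0/1, found {vals}")
        self.voxels = self.voxels.astype(np.uint8)

    @property
    def shape(self):
        return self.voxels.shape

    @property
    def bool(self) -> np.ndarray:
        return self.voxels.astype(np.bool_)


@dataclass
class LabelMap:
    """Voxel-wise tissue classes {1..5} inside lung, OUTSIDE (0) elsewhere."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        vals = np.unique(self.voxels)
        bad = vals[~np.isin(vals, [OUTSIDE, *CLASSES])]
        if bad.size:
            raise VocabularyError(
                f"label map contains values outside {{0..5}}: {bad.tolist()}"
            )
        self.voxels = self.voxels.astype(np.int16)

    @property
    def shape(self):
        return self.voxels.shape


def check_aligned(a, b, name_a: str = "first", name_b: str = "second") -> None:
    """Raise :class:`AlignmentError` unless the two grids share geometry."""
    if a.shape != b.shape:
        raise AlignmentError(
            f"shape mismatch: {name_a} {a.shape} vs {name_b} {b.shape}"
        )
    da = np.abs(np.asarray(a.spacing) - np.asarray(b.spacing))
    if np.any(da > _SPACING_TOL_MM):
        raise AlignmentError(
            f"spacing mismatch beyond {_SPACING_TOL_MM} mm: "
            f"{name_a} {a.spacing} vs {name_b} {b.spacing}"
        )


def validate_labels(labels: LabelMap, mask: LungMask) -> None:
    """Check the label vocabulary against the lung mask.

    Inside lung every voxel must carry a class in {1..5}; outside the lung
    every voxel must carry the OUTSIDE sentinel.
    """
    check_aligned(labels, mask, "labels", "mask")
    inside = mask.bool
    if np.any(labels.voxels[inside] == OUTSIDE):
        raise VocabularyError("lung voxels carry the OUTSIDE sentinel")
    if np.any(labels.voxels[~inside] != OUTSIDE):
        raise VocabularyError("non-lung voxels carry tissue classes")


# --------------------------------------------------------------------- NIfTI


def _affine(spacing, origin) -> np.ndarray:
    # internal (z,y,x) order; NIfTI stores (x,y,z)
    sz, sy, sx = spacing
    aff = np.diag([sx, sy, sz, 1.0])
    aff[:3, 3] = origin[::-1]
    return aff


def _to_nifti(voxels: np.ndarray, spacing, origin) -> nib.Nifti1Image:
    return nib.Nifti1Image(
        np.transpose(voxels, (2, 1, 0)), _affine(spacing, origin)
    )


def _from_nifti(path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(os.fspath(path))
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
    sx, sy, sz = img.header.get_zooms()[:3]
    ox, oy, oz = img.affine[:3, 3]
    return data, (float(sz), float(sy), float(sx)), (float(oz), float(oy), float(ox))


def save_volume(volume: CTVolume, path) -> None:
    nib.save(
        _to_nifti(volume.voxels.astype(np.float32), volume.spacing, volume.origin),
        os.fspath(path),
    )


def save_mask(mask: LungMask, reference: CTVolume, path) -> None:
    check_aligned(mask, reference, "mask", "reference")
    nib.save(_to_nifti(mask.voxels, mask.spacing, mask.origin), os.fspath(path))


def save_labels(labels: LabelMap, reference: CTVolume, path) -> None:
    """Write a label map as int16 NIfTI on the reference geometry."""
    check_aligned(labels, reference, "labels", "reference")
    nib.save(_to_nifti(labels.voxels, labels.spacing, labels.origin), os.fspath(path))


def load_volume(path) -> CTVolume:
    data, spacing, origin = _from_nifti(path)
    return CTVolume(data.astype(np.float32), spacing, origin)


def load_case(volume_path, mask_path, labels_path) -> tuple[CTVolume, LungMask, LabelMap]:
    """Load an aligned (volume, lung mask, label map) triplet.

    Raises :class:`AlignmentError` naming the offending file on any shape or
    spacing mismatch, and :class:`VocabularyError` on out-of-vocabulary
    label values.
    """
    volume = load_volume(volume_path)
    mdata, mspacing, morigin = _from_nifti(mask_path)
    ldata, lspacing, lorigin = _from_nifti(labels_path)
    mask = LungMask(np.rint(mdata).astype(np.uint8), mspacing, morigin)
    labels = LabelMap(np.rint(ldata).astype(np.int16), lspacing, lorigin)
    try:
        check_aligned(mask, volume, "mask", "volume")
    except AlignmentError as e:
        raise AlignmentError(f"{mask_path}: {e}") from None
    try:
        check_aligned(labels, volume, "labels", "volume")
    except AlignmentError as e:
        raise AlignmentError(f"{labels_path}: {e}") from None
    validate_labels(labels, mask)
    return volume, mask, labels
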