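"""NIfTI I/O, intensity normalization, masking, and conversion between 3D
volumes and the flat voxel vectors consumed by the factorization.

Voxel ordering convention
-------------------------
The flat vector runs over mask voxels with the *first* grid axis varying
fastest (Fortran/column-major order). The order is materialized in
:class:`MaskedGrid.voxel_index` so that every downstream artifact (component
maps, coefficient maps) is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

from voxnmf.errors import (
    ArgumentError,
    DataError,
    DimensionError,
    DomainError,
    NormalizationError,
)

#: Negative intensities above this threshold are treated as interpolation
#: artifacts and clamped to zero; anything below is rejected.
NEGATIVE_CLAMP_THRESHOLD = -1e-6

_AFFINE_ATOL = 1e-4


@dataclass(frozen=True)
class MaskedGrid:
    """A 3D grid plus a boolean mask and the deterministic voxel ordering.

    Attributes
    ----------
    shape : tuple of int
        3D grid dimensions.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform.
    mask : ndarray of bool
        Inclusion mask over the grid.
    voxel_index : ndarray, shape (n_voxels, 3)
        Row ``k`` holds the (i, j, k) grid coordinate of flat position ``k``,
        ordered with the first axis fastest.
    """

    shape: tuple
    affine: np.ndarray
    mask: np.ndarray
    voxel_index: np.ndarray = field(repr=False)

    @classmethod
    def from_mask(cls, mask: np.ndarray, affine: np.ndarray | None = None) -> "MaskedGrid":
        mask = np.asarray(mask).astype(bool)
        if mask.ndim != 3:
            raise DimensionError(f"mask must be 3D, got {mask.ndim}D")
        if affine is None:
            affine = np.eye(4)
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise DimensionError(f"affine must be 4x4, got {affine.shape}")
        flat = np.flatnonzero(mask.ravel(order="F"))
        i, j, k = np.unravel_index(flat, mask.shape, order="F")
        voxel_index = np.column_stack([i, j, k])
        return cls(shape=tuple(mask.shape), affine=affine, mask=mask, voxel_index=voxel_index)

    @classmethod
    def from_nifti(cls, path: str | Path) -> "MaskedGrid":
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
        values = np.unique(data)
        if not np.all(np.isin(values, [0.0, 1.0])):
            raise DataError(f"mask {path} contains values other than 0/1: {values[:5]}")
        return cls.from_mask(data > 0.5, img.affine)

    @property
    def n_voxels(self) -> int:
        return self.voxel_index.shape[0]

    def _flat_positions(self) -> np.ndarray:
        i, j, k = self.voxel_index.T
        return np.ravel_multi_index((i, j, k), self.shape, order="F")


@dataclass
class VoxelMatrix:
    """Nonnegative subject-by-voxel matrix with the metadata needed to map
    columns back to 3D space."""

    values: np.ndarray
    subject_ids: list
    modality: str
    grid: MaskedGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = list(self.subject_ids)
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise DataError("subject_ids must be unique")
        if self.values.ndim != 2:
            raise DimensionError("values must be 2D (subjects x voxels)")
        if self.values.shape[0] != len(self.subject_ids):
            raise DimensionError(
                f"{self.values.shape[0]} rows but {len(self.subject_ids)} subject ids"
            )
        if self.values.shape[1] != self.grid.n_voxels:
            raise DimensionError(
                f"{self.values.shape[1]} columns but grid has {self.grid.n_voxels} mask voxels"
            )
        if self.values.size and self.values.min() < 0:
            raise DomainError("VoxelMatrix values must be nonnegative")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def save(self, prefix: str | Path) -> None:
        """Write values as .npy plus a JSON sidecar next to it."""
        prefix = Path(prefix)
        np.save(str(prefix) + ".npy", self.values)
        sidecar = {
            "subject_ids": self.subject_ids,
            "modality": self.modality,
            "shape": list(self.grid.shape),
            "voxel_order": "first-axis-fastest",
        }
        with open(str(prefix) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


def vectorize(volume: np.ndarray, grid: MaskedGrid) -> np.ndarray:
    """Extract the masked voxels of ``volume`` in the grid's flat order."""
    volume = np.asarray(volume)
    if tuple(volume.shape) != tuple(grid.shape):
        raise DimensionError(f"volume shape {volume.shape} != grid shape {grid.shape}")
    return volume.ravel(order="F")[grid._flat_positions()].copy()


def devectorize(vector: np.ndarray, grid: MaskedGrid, fill: float = 0.0) -> np.ndarray:
    """Scatter a flat vector back into a 3D volume; off-mask voxels = ``fill``."""
    vector = np.asarray(vector)
    if vector.ndim != 1 or vector.shape[0] != grid.n_voxels:
        raise DimensionError(
            f"vector length {vector.shape} != number of mask voxels {grid.n_voxels}"
        )
    out = np.full(int(np.prod(grid.shape)), fill, dtype=float)
    out[grid._flat_positions()] = vector
    return out.reshape(grid.shape, order="F")


def suvr_normalize(pet: np.ndarray, reference_mask: np.ndarray) -> np.ndarray:
    """Divide every voxel by the median intensity over ``reference_mask``.

    The reference is intended to be a precomputed eroded white-matter mask;
    no erosion is performed here.
    """
    pet = np.asarray(pet, dtype=float)
    reference_mask = np.asarray(reference_mask).astype(bool)
    if pet.shape != reference_mask.shape:
        raise DimensionError(
            f"image shape {pet.shape} != reference mask shape {reference_mask.shape}"
        )
    if not reference_mask.any():
        raise ArgumentError("reference mask selects no voxels")
    ref_median = float(np.median(pet[reference_mask]))
    if ref_median <= 0:
        raise NormalizationError(f"non-positive reference median: {ref_median}")
    return pet / ref_median


def load_image_set(
    paths: Sequence[str | Path],
    grid: MaskedGrid,
    modality: str,
    subject_ids: Iterable[str] | None = None,
) -> VoxelMatrix:
    """Load NIfTI volumes into a subject-by-voxel matrix.

    Row ``i`` holds the masked voxels of ``paths[i]`` in the grid's flat
    order. All images must share the grid's shape and affine (affine entries
    within 1e-4). Values in ``[-1e-6, 0)`` are clamped to zero; anything more
    negative is rejected.
    """
    paths = [Path(p) for p in paths]
    if subject_ids is None:
        subject_ids = [p.name.removesuffix(".gz").removesuffix(".nii") for p in paths]
    subject_ids = list(subject_ids)
    if len(subject_ids) != len(paths):
        raise ArgumentError("subject_ids length must match paths length")

    rows = np.empty((len(paths), grid.n_voxels))
    for i, path in enumerate(paths):
        img = nib.load(str(path))
        if tuple(img.shape[:3]) != tuple(grid.shape):
            raise DimensionError(
                f"{path}: image shape {tuple(img.shape[:3])} != grid shape {grid.shape}"
            )
        if not np.allclose(img.affine, grid.affine, atol=_AFFINE_ATOL):
            raise DimensionError(f"{path}: affine differs from grid affine beyond 1e-4")
        vec = vectorize(np.asarray(img.get_fdata()), grid)
        if not np.all(np.isfinite(vec)):
            raise DataError(f"{path}: NaN or Inf inside the mask")
        if vec.min() < NEGATIVE_CLAMP_THRESHOLD:
            raise DomainError(
                f"{path}: masked value {vec.min():g} below clamp threshold "
                f"{NEGATIVE_CLAMP_THRESHOLD:g}"
            )
        rows[i] = np.clip(vec, 0.0, None)
    return VoxelMatrix(values=rows, subject_ids=subject_ids, modality=modality, grid=grid)


def save_volume(volume: np.ndarray, grid: MaskedGrid, path: str | Path) -> None:
    """Write a 3D volume as NIfTI using the grid's affine."""
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), grid.affine)
    nib.save(img, str(path))


def save_component_maps(dictionary: np.ndarray, grid: MaskedGrid, path: str | Path) -> None:
    """Write dictionary rows as a 4D NIfTI (one 3D map per component)."""
    dictionary = np.asarray(dictionary)
    vols = np.stack([devectorize(row, grid, fill=0.0) for row in dictionary], axis=-1)
    img = nib.Nifti1Image(vols.astype(np.float64), grid.affine)
    nib.save(img, str(path))
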