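"""On-disk formats: NIfTI label/probability volumes, seed-coordinate lists,
and whitespace-delimited matrix files.

All voxel coordinates handled by this package are 0-based integer indices
into the image array (not world mm).  The matrix text format is a one-line
header ``rows cols`` followed by whitespace-delimited rows, readable with
standard tools in any language.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "FormatError",
    "EmptyMaskError",
    "LabelVolume",
    "SeedSet",
    "read_label_volume",
    "write_label_volume",
    "write_probability_volume",
    "extract_seed_coordinates",
    "read_coordinates",
    "write_coordinates",
    "read_matrix",
    "write_matrix",
]


class FormatError(ValueError):
    """A file exists but does not conform to the documented layout."""


class EmptyMaskError(ValueError):
    """A seed mask contains no nonzero voxels."""


@dataclass
class LabelVolume:
    """A 3D integer label image; 0 is background.

    Parameters
    ----------
    data : ndarray of int, shape (X, Y, Z)
        Label per voxel, 0 = background.
    affine : ndarray, shape (4, 4)
        Voxel-to-world (mm) transform.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"label volume must be 3D, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise FormatError("label volume data must be integer-typed")
        if self.data.min() < 0:
            raise FormatError("labels must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Voxel edge lengths (mm) from the affine column norms."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class SeedSet:
    """Ordered nonzero-voxel coordinates of a seed mask.

    The order is fixed (lexicographic in x, then y, then z) and reused
    everywhere downstream: row i of every per-seed matrix corresponds to
    ``coordinates[i]``.
    """

    coordinates: np.ndarray  # (n, 3) int
    shape: tuple[int, int, int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.int64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise FormatError("coordinates must have shape (n, 3)")
        if len(np.unique(self.coordinates, axis=0)) != len(self.coordinates):
            raise FormatError("seed coordinates must be unique")
        if self.coordinates.size and (
            self.coordinates.min() < 0
            or (self.coordinates >= np.asarray(self.shape)).any()
        ):
            raise FormatError("seed coordinates outside volume shape")
        self.affine = np.asarray(self.affine, dtype=float)

    def __len__(self) -> int:
        return len(self.coordinates)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def flat_indices(self) -> np.ndarray:
        """C-order flat index of each seed voxel in the volume grid."""
        return np.ravel_multi_index(self.coordinates.T, self.shape)


def read_label_volume(path: str | os.PathLike) -> LabelVolume:
    """Read an integer-valued NIfTI-1 image.

    Values are rounded to the nearest integer only if every voxel is within
    1e-6 of one; larger deviations raise :class:`FormatError`.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    rounded = np.round(data)
    if np.abs(data - rounded).max(initial=0.0) > 1e-6:
        raise FormatError(f"{path}: non-integer label data")
    return LabelVolume(rounded.astype(np.int32), np.asarray(img.affine))


def write_label_volume(vol: LabelVolume, path: str | os.PathLike) -> None:
    """Write a label volume as int32 NIfTI-1 (round-trips exactly)."""
    img = nib.Nifti1Image(vol.data.astype(np.int32), vol.affine)
    img.header.set_data_dtype(np.int32)
    nib.save(img, str(path))


def write_probability_volume(
    data: np.ndarray, affine: np.ndarray, path: str | os.PathLike
) -> None:
    """Write a real-valued map (e.g. a probabilistic map) as float32 NIfTI."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_data_dtype(np.float32)
    nib.save(img, str(path))


def extract_seed_coordinates(vol: LabelVolume) -> SeedSet:
    """All nonzero voxels of a mask, in lexicographic (x, y, z) order."""
    coords = np.argwhere(vol.data != 0)  # argwhere is C-order == lexicographic
    if coords.size == 0:
        raise EmptyMaskError("seed mask has no nonzero voxels")
    return SeedSet(coords, vol.shape, vol.affine)


def write_coordinates(seeds: SeedSet, path: str | os.PathLike) -> None:
    """Plain-text export: one 0-based ``x y z`` triple per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for x, y, z in seeds.coordinates:
            fh.write(f"{x} {y} {z}\n")


def read_coordinates(
    path: str | os.PathLike,
    shape: tuple[int, int, int],
    affine: np.ndarray | None = None,
) -> SeedSet:
    coords = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{path}: expected 'x y z' per line, got {line!r}")
            coords.append([int(p) for p in parts])
    if not coords:
        raise EmptyMaskError(f"{path}: no coordinates")
    return SeedSet(
        np.asarray(coords), shape, np.eye(4) if affine is None else affine
    )


def write_matrix(matrix: np.ndarray, path: str | os.PathLike) -> None:
    """Write a real matrix with a ``rows cols`` header line.

    Values use repr-round-trip precision so write/read is identity far
    below 1e-12.
    """
    m = np.atleast_2d(np.asarray(matrix, dtype=np.float64))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{m.shape[0]} {m.shape[1]}\n")
        for row in m:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_matrix(path: str | os.PathLike) -> np.ndarray:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path}: missing 'rows cols' header")
        rows, cols = (int(h) for h in header)
        body = np.loadtxt(fh, dtype=np.float64, ndmin=2)
    if body.size == 0:
        body = body.reshape(0, cols)
    if body.shape != (rows, cols):
        raise FormatError(
            f"{path}: header says {rows}x{cols} but data is "
            f"{body.shape[0]}x{body.shape[1]}"
        )
    return body
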