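"""PET volume and label-mask I/O with an axis-aligned world-coordinate contract.

All downstream geometry (lesion centroids, inter-lesion distances) is computed
on voxel-center coordinates in world millimetres.  The contract is strict:
``world(i, j, k) = origin + (i, j, k) * spacing`` with positive spacing, i.e.
the image axes coincide with the world axes.  Rotated or sheared affines are
rejected rather than resampled, because the Manhattan and Chebyshev distances
are axis-dependent and silent resampling would change their values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "LabelMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "world_coords",
]

#: relative tolerance on off-diagonal affine terms before an image is
#: declared non-axis-aligned
AFFINE_TOL = 1e-3


def _check_geometry(spacing: np.ndarray, origin: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if spacing.shape != (3,) or origin.shape != (3,):
        raise ValueError("spacing and origin must be 3-vectors")
    if not np.all(spacing > 0):
        raise ValueError(f"spacing components must be > 0, got {spacing}")
    if not (np.all(np.isfinite(spacing)) and np.all(np.isfinite(origin))):
        raise ValueError("spacing/origin must be finite")
    return spacing, origin


@dataclass
class VoxelGrid:
    """A 3D SUV image on an axis-aligned grid.

    Parameters
    ----------
    values
        3D array of standardized uptake values (dimensionless, >= 0).
    spacing
        Voxel size in mm along each axis, all components > 0.
    origin
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {self.values.ndim}D")
        if np.isnan(self.values).any():
            raise ValueError("volume contains NaN voxels")
        self.spacing, self.origin = _check_geometry(self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 diagonal affine mapping voxel indices to world mm."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world(self, indices: np.ndarray) -> np.ndarray:
        """World-mm coordinates of voxel centres for an (..., 3) index array."""
        idx = np.asarray(indices, dtype=float)
        return self.origin + idx * self.spacing

    def same_geometry(self, other: "VoxelGrid | LabelMask", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class LabelMask:
    """Integer label volume sharing the geometry of a companion :class:`VoxelGrid`.

    Label 0 is background; positive labels identify regions (seed regions or
    final lesions).  ``relabel()`` maps the labels present onto the contiguous
    set {1..L} ordered by first (lexicographically minimal) voxel index.
    """

    labels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"expected a 3D label volume, got {labels.ndim}D")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.round(labels)):
                raise ValueError("label volume must be integer-valued")
            labels = np.round(labels).astype(np.int32)
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = labels.astype(np.int32, copy=False)
        self.spacing, self.origin = _check_geometry(self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def present_labels(self) -> np.ndarray:
        """Sorted positive labels present in the mask."""
        labs = np.unique(self.labels)
        return labs[labs > 0]

    def relabel(self) -> "LabelMask":
        """Return a mask whose labels form {1..L}, ordered by minimal voxel index."""
        flat = self.labels.ravel()
        labs, first = np.unique(flat, return_index=True)
        keep = labs > 0
        labs, first = labs[keep], first[keep]
        order = np.argsort(first)
        lut = np.zeros(int(labs.max()) + 1 if labs.size else 1, dtype=np.int32)
        for new, old in enumerate(labs[order], start=1):
            lut[old] = new
        return LabelMask(lut[self.labels], self.spacing.copy(), self.origin.copy())

    def world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return self.origin + idx * self.spacing


def _geometry_from_affine(affine: np.ndarray, shape: tuple[int, ...]):
    """Extract (spacing, origin, flips) from an affine, enforcing axis alignment.

    Negative diagonal scales (common in NIfTI RAS affines) are folded into an
    axis flip so the returned spacing is positive; any rotation or shear beyond
    AFFINE_TOL is an error.
    """
    lin = np.asarray(affine, dtype=float)[:3, :3]
    scales = np.diag(lin)
    off = lin - np.diag(scales)
    col_norms = np.linalg.norm(lin, axis=0)
    if np.any(col_norms <= 0):
        raise ValueError("degenerate affine: zero scale on an image axis")
    if np.max(np.abs(off)) > AFFINE_TOL * np.max(col_norms):
        raise ValueError(
            "non-axis-aligned affine: image axes must coincide with world axes "
            "(rotation/shear beyond tolerance)"
        )
    origin = np.asarray(affine, dtype=float)[:3, 3].copy()
    flips = scales < 0
    spacing = np.abs(scales)
    for ax in np.nonzero(flips)[0]:
        # flipping index i -> n-1-i moves the origin to the other end of the axis
        origin[ax] = origin[ax] + (shape[ax] - 1) * scales[ax]
    return spacing, origin, flips


def read_volume(path: str | Path) -> VoxelGrid:
    """Read a 3D single-channel NIfTI volume as a :class:`VoxelGrid`.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        For 4D input, non-axis-aligned affines, or NaN voxel values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    spacing, origin, flips = _geometry_from_affine(img.affine, data.shape)
    for ax in np.nonzero(flips)[0]:
        data = np.flip(data, axis=ax)
    return VoxelGrid(np.ascontiguousarray(data, dtype=np.float64), spacing, origin)


def write_volume(grid: VoxelGrid, path: str | Path) -> None:
    """Write a :class:`VoxelGrid` as NIfTI-1 with its diagonal affine."""
    img = nib.Nifti1Image(grid.values.astype(np.float64), grid.affine)
    nib.save(img, str(path))


def read_mask(path: str | Path, like: VoxelGrid | None = None) -> LabelMask:
    """Read a NIfTI label volume; optionally verify geometry against ``like``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise ValueError(f"expected a 3D label volume, got shape {data.shape}")
    if np.isnan(np.asarray(data, dtype=float)).any():
        raise ValueError("label volume contains NaN")
    spacing, origin, flips = _geometry_from_affine(img.affine, data.shape)
    for ax in np.nonzero(flips)[0]:
        data = np.flip(data, axis=ax)
    mask = LabelMask(np.ascontiguousarray(data), spacing, origin)
    if like is not None and not like.same_geometry(mask):
        raise ValueError("label mask geometry (shape/spacing/origin) does not match volume")
    return mask


def write_mask(mask: LabelMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.int32), mask.affine)
    nib.save(img, str(path))


def world_coords(mask: LabelMask, label: int) -> np.ndarray:
    """World-mm coordinates of voxel centres carrying ``label``.

    The order is deterministic: lexicographic by voxel index.
    """
    idx = np.argwhere(mask.labels == label)
    if idx.size == 0:
        raise ValueError(f"label {label} absent from mask")
    return mask.world(idx)
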