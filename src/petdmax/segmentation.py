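"""Lesion segmentation by the 41% SUVmax rule and metabolic tumor volume.

Each seed region (one label of a :class:`~petdmax.volumes.LabelMask`) is
thresholded at ``fraction * SUVmax`` where SUVmax is taken over that seed
region, and the connected component containing the SUVmax voxel is kept.
Per-lesion SUVmax thresholding is the standard EANM-style rule; a global
threshold would merge or lose lesions with dissimilar uptake.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import LabelMask, VoxelGrid

__all__ = [
    "Lesion",
    "LesionSet",
    "connected_components",
    "threshold_lesion",
    "build_lesion_set",
    "DEFAULT_THRESHOLD_FRACTION",
]

DEFAULT_THRESHOLD_FRACTION = 0.41

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class Lesion:
    """One segmented lesion: voxel coordinates in world mm plus summary stats."""

    label: int
    indices: np.ndarray        # (n, 3) voxel indices, lexicographic order
    coords: np.ndarray         # (n, 3) world mm voxel centres
    suvs: np.ndarray           # (n,) SUV per voxel
    suv_max: float
    volume_ml: float
    centroid: np.ndarray       # geometric centroid, world mm

    @property
    def n_voxels(self) -> int:
        return len(self.coords)


@dataclass
class LesionSet:
    """All lesions of one patient plus the total metabolic tumor volume (cm3)."""

    lesions: list[Lesion] = field(default_factory=list)

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)

    @property
    def total_mtv_ml(self) -> float:
        return float(sum(l.volume_ml for l in self.lesions))

    @property
    def has_min_lesions(self) -> bool:
        """True when at least two lesions are present (distances are defined)."""
        return self.n_lesions >= 2

    def all_coords(self) -> np.ndarray:
        """Union of all lesion voxel coordinates, (N, 3) world mm."""
        if not self.lesions:
            return np.empty((0, 3))
        return np.vstack([l.coords for l in self.lesions])

    def centroids(self, weighting: str = "geometric") -> np.ndarray:
        from .metrics import centroid  # local import to avoid a cycle

        return np.array([centroid(l, weighting) for l in self.lesions])


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def connected_components(mask: LabelMask, connectivity: int = 26) -> LabelMask:
    """Label connected components of a binary mask.

    Components are numbered 1..L by their lexicographically minimal voxel
    index, which makes the labeling deterministic. An empty mask yields L=0.
    """
    binary = mask.labels > 0
    labeled, _ = ndimage.label(binary, structure=_structure(connectivity))
    out = LabelMask(labeled, mask.spacing.copy(), mask.origin.copy())
    return out.relabel()


def _seed_to_bool(grid: VoxelGrid, seed) -> np.ndarray:
    """Accept a boolean array or an (n, 3) index array as the seed region."""
    seed = np.asarray(seed)
    if seed.dtype == bool:
        if seed.shape != grid.shape:
            raise ValueError("boolean seed shape does not match grid")
        return seed
    if seed.ndim != 2 or seed.shape[1] != 3:
        raise ValueError("seed must be a boolean volume or an (n, 3) index array")
    if seed.size == 0:
        raise ValueError("seed region is empty")
    if (seed < 0).any() or (seed >= np.array(grid.shape)).any():
        raise ValueError("seed indices fall outside the grid")
    out = np.zeros(grid.shape, dtype=bool)
    out[tuple(seed.T)] = True
    return out


def threshold_lesion(
    grid: VoxelGrid,
    seed,
    fraction: float = DEFAULT_THRESHOLD_FRACTION,
    connectivity: int = 26,
    label: int = 1,
) -> Lesion | None:
    """Segment one lesion from a seed region at ``fraction`` of its SUVmax.

    SUVmax is the maximum SUV over the seed region. Voxels of the seed with
    SUV >= fraction * SUVmax are kept, and of those only the connected
    component containing the SUVmax voxel (thresholding may shatter the seed).
    Returns None when nothing survives (all-zero seed region).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    seed_bool = _seed_to_bool(grid, seed)
    if not seed_bool.any():
        raise ValueError("seed region is empty")

    suv_in_seed = np.where(seed_bool, grid.values, -np.inf)
    suv_max = float(suv_in_seed.max())
    if suv_max <= 0:
        return None
    above = seed_bool & (grid.values >= fraction * suv_max)
    # SUVmax voxel: lexicographically first among the maxima
    peak_idx = np.unravel_index(int(np.argmax(suv_in_seed)), grid.shape)
    labeled, n = ndimage.label(above, structure=_structure(connectivity))
    comp = labeled[peak_idx]
    if comp == 0:  # cannot happen: the peak always passes its own threshold
        return None
    keep = labeled == comp
    indices = np.argwhere(keep)
    coords = grid.world(indices)
    suvs = grid.values[tuple(indices.T)]
    volume_ml = len(indices) * grid.voxel_volume_mm3 / 1000.0
    return Lesion(
        label=label,
        indices=indices,
        coords=coords,
        suvs=suvs,
        suv_max=suv_max,
        volume_ml=volume_ml,
        centroid=coords.mean(axis=0),
    )


def build_lesion_set(
    grid: VoxelGrid,
    seeds: LabelMask,
    fraction: float = DEFAULT_THRESHOLD_FRACTION,
    connectivity: int = 26,
) -> LesionSet:
    """Apply :func:`threshold_lesion` to every seed label and collect the result.

    Empty results (seed regions with no uptake) are dropped. A warning is
    emitted when fewer than two lesions remain, since inter-lesion distances
    need at least two lesions; the returned set still carries the survivors.
    """
    if not grid.same_geometry(seeds):
        raise ValueError("seed mask geometry does not match grid")
    lesions: list[Lesion] = []
    for lab in seeds.present_labels():
        lesion = threshold_lesion(
            grid, seeds.labels == lab, fraction=fraction,
            connectivity=connectivity, label=int(lab),
        )
        if lesion is not None:
            lesions.append(lesion)
    lesion_set = LesionSet(lesions)
    if lesion_set.n_lesions < 2:
        warnings.warn(
            f"only {lesion_set.n_lesions} lesion(s) segmented; "
            "dissemination distances are undefined below 2 lesions",
            stacklevel=2,
        )
    return lesion_set
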