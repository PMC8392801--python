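"""Dissemination features: standardized maximal inter-lesion distances and the
Travelling-Salesman loop distance.

Seven features per patient, each a distance in mm divided by 1000 and by the
body surface area (Mosteller), hence in m^-1:

* ``sdmax_euc`` / ``sdmax_man`` / ``sdmax_tch`` — the largest Euclidean /
  Manhattan / Chebyshev distance between lesion *centroids* (Dmax, then
  standardized to SDmax);
* ``sdmax_euc_vox`` / ``sdmax_man_vox`` / ``sdmax_tch_vox`` — the same maxima
  taken over the two most distant *voxels* of the total metabolic tumor
  volume, regardless of which lesion each voxel belongs to;
* ``sd_tsp`` — the length of the shortest closed loop through all lesion
  centroids (Travelling Salesman tour).

The Manhattan and Chebyshev metrics are evaluated along the image world axes
(the patient-aligned scanner axes); they are axis-dependent by construction.

Farthest-pair computations use exact fast paths (axis ranges for Chebyshev,
the four sign-pattern linear functionals for Manhattan, convex-hull vertex
restriction for Euclidean), each provably equal to the all-pairs maximum.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .segmentation import Lesion, LesionSet

__all__ = [
    "METRICS",
    "PatientBody",
    "DisseminationFeatures",
    "metric_distance",
    "centroid",
    "centroid_max_distance",
    "voxel_max_distance",
    "max_pair_distance",
    "tsp_tour",
    "tsp_loop_length",
    "standardize",
    "compute_features",
]

METRICS = ("euclidean", "manhattan", "tchebychev")

# Manhattan fast path: |dx|+|dy|+|dz| = max over sign vectors s of s.(a-b),
# and by symmetry only the four patterns with s_x=+1 are needed.
_MANHATTAN_SIGNS = np.array(
    [[1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1]], dtype=float
)


@dataclass(frozen=True)
class PatientBody:
    """Height (cm), weight (kg) and the derived Mosteller body surface area.

    bsa = sqrt(height_cm * weight_kg / 3600), in m^2.
    """

    height_cm: float
    weight_kg: float

    def __post_init__(self) -> None:
        if not 50 < self.height_cm < 260:
            raise ValueError(f"implausible height {self.height_cm} cm")
        if not 20 < self.weight_kg < 300:
            raise ValueError(f"implausible weight {self.weight_kg} kg")

    @property
    def bsa_m2(self) -> float:
        return math.sqrt(self.height_cm * self.weight_kg / 3600.0)


def metric_distance(a, b, metric: str = "euclidean") -> float:
    """Distance between two world-mm points under the named metric."""
    d = np.abs(np.asarray(b, dtype=float) - np.asarray(a, dtype=float))
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite coordinates")
    if metric == "euclidean":
        return float(np.sqrt((d * d).sum()))
    if metric == "manhattan":
        return float(d.sum())
    if metric == "tchebychev":
        return float(d.max())
    raise ValueError(f"unknown metric {metric!r}")


def centroid(lesion: Lesion, weighting: str = "geometric") -> np.ndarray:
    """Lesion centroid in world mm: unweighted or SUV-weighted voxel mean."""
    if weighting == "geometric":
        return lesion.coords.mean(axis=0)
    if weighting == "suv":
        w = lesion.suvs
        return (lesion.coords * w[:, None]).sum(axis=0) / w.sum()
    raise ValueError(f"unknown centroid weighting {weighting!r}")


def _pairwise_argmax(points: np.ndarray, metric: str) -> tuple[float, tuple[int, int]]:
    """All-pairs maximum with lexicographic tie-break on the index pair."""
    n = len(points)
    best = -1.0
    best_pair = (0, 1)
    for i in range(n - 1):
        d = points[i + 1:] - points[i]
        if metric == "euclidean":
            row = np.sqrt((d * d).sum(axis=1))
        elif metric == "manhattan":
            row = np.abs(d).sum(axis=1)
        else:
            row = np.abs(d).max(axis=1)
        j = int(np.argmax(row))
        if row[j] > best:
            best = float(row[j])
            best_pair = (i, i + 1 + j)
    return best, best_pair


def centroid_max_distance(
    centroids: np.ndarray, metric: str = "euclidean"
) -> tuple[float, tuple[int, int]]:
    """Largest pairwise distance between lesion centroids (raw Dmax, mm).

    Ties resolve to the smallest lexicographic index pair. Requires at least
    two centroids; the dissemination features are undefined otherwise.
    """
    pts = np.atleast_2d(np.asarray(centroids, dtype=float))
    if len(pts) < 2:
        raise ValueError("at least 2 centroids are required for Dmax")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    return _pairwise_argmax(pts, metric)


def max_pair_distance(points: np.ndarray, metric: str = "euclidean") -> float:
    """Exact farthest-pair distance over a point cloud, via metric-specific
    fast paths.

    * Chebyshev: max over the three axes of the coordinate range.
    * Manhattan: max over the four sign patterns s (s_x fixed +) of the range
      of the linear functional s.p — the L1 diameter equals the Linf diameter
      in the transformed coordinates.
    * Euclidean: brute force restricted to convex-hull vertices (the diameter
      of a finite set is attained at hull vertices); degenerate clouds fall
      back to the all-pairs scan.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 2:
        raise ValueError("at least 2 points are required")
    if metric == "tchebychev":
        return float((pts.max(axis=0) - pts.min(axis=0)).max())
    if metric == "manhattan":
        proj = pts @ _MANHATTAN_SIGNS.T
        return float((proj.max(axis=0) - proj.min(axis=0)).max())
    if metric == "euclidean":
        hull_pts = pts
        if len(pts) > 16:
            try:
                hull_pts = pts[ConvexHull(pts).vertices]
            except QhullError:  # coplanar/collinear clouds
                hull_pts = pts
        d, _ = _pairwise_argmax(hull_pts, "euclidean")
        return d
    raise ValueError(f"unknown metric {metric!r}")


def voxel_max_distance(lesion_set: LesionSet, metric: str = "euclidean") -> float:
    """Distance between the two most distant voxels of the total MTV (mm)."""
    pts = lesion_set.all_coords()
    if len(pts) < 2:
        raise ValueError("at least 2 voxels are required")
    return max_pair_distance(pts, metric)


def _tour_length(dist: np.ndarray, tour: np.ndarray) -> float:
    return float(dist[tour, np.roll(tour, -1)].sum())


def _distance_matrix(points: np.ndarray, metric: str) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    if metric == "euclidean":
        return np.sqrt((diff * diff).sum(axis=2))
    if metric == "manhattan":
        return np.abs(diff).sum(axis=2)
    if metric == "tchebychev":
        return np.abs(diff).max(axis=2)
    raise ValueError(f"unknown metric {metric!r}")


def _tsp_exact(dist: np.ndarray) -> tuple[np.ndarray, float]:
    n = len(dist)
    if n > 10:
        raise ValueError("exact TSP is limited to n <= 10 centroids")
    best_len = np.inf
    best_tour = np.arange(n)
    # fix city 0; count each direction once by requiring perm[0] < perm[-1]
    for perm in itertools.permutations(range(1, n)):
        if perm[0] > perm[-1]:
            continue
        tour = np.array((0,) + perm)
        length = _tour_length(dist, tour)
        if length < best_len:
            best_len = length
            best_tour = tour
    return best_tour, best_len


def _two_opt(dist: np.ndarray, tour: np.ndarray) -> np.ndarray:
    """2-opt local search until no improving edge swap remains."""
    n = len(tour)
    tour = tour.copy()
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            a, b = tour[i], tour[(i + 1) % n]
            for j in range(i + 2, n):
                if i == 0 and j == n - 1:
                    continue  # same edge pair
                c, d = tour[j], tour[(j + 1) % n]
                delta = dist[a, c] + dist[b, d] - dist[a, b] - dist[c, d]
                if delta < -1e-12:
                    tour[i + 1:j + 1] = tour[i + 1:j + 1][::-1]
                    improved = True
                    b = tour[(i + 1) % n]
    return tour


def _tsp_heuristic(dist: np.ndarray) -> tuple[np.ndarray, float]:
    """Multi-start nearest-neighbour construction followed by full 2-opt."""
    n = len(dist)
    best_len = np.inf
    best_tour = np.arange(n)
    for start in range(n):
        unvisited = list(range(n))
        unvisited.remove(start)
        tour = [start]
        while unvisited:
            last = tour[-1]
            nxt = min(unvisited, key=lambda k: (dist[last, k], k))
            tour.append(nxt)
            unvisited.remove(nxt)
        tour = _two_opt(dist, np.array(tour))
        length = _tour_length(dist, tour)
        if length < best_len - 1e-12:
            best_len = length
            best_tour = tour
    return best_tour, best_len


def tsp_tour(
    centroids: np.ndarray, metric: str = "euclidean", mode: str = "heuristic"
) -> tuple[np.ndarray, float]:
    """Shortest closed loop through all centroids; returns (tour, length mm).

    ``mode='exact'`` enumerates all (n-1)!/2 tours (n <= 10); ``'heuristic'``
    is nearest-neighbour from every start followed by 2-opt, deterministic
    given the input order. For n = 2 the loop is out-and-back, length 2 d(A,B).
    """
    pts = np.atleast_2d(np.asarray(centroids, dtype=float))
    n = len(pts)
    if n < 2:
        raise ValueError("at least 2 centroids are required for the TSP loop")
    dist = _distance_matrix(pts, metric)
    if n == 2:
        return np.array([0, 1]), float(2.0 * dist[0, 1])
    if n == 3:  # single tour up to direction
        return np.array([0, 1, 2]), _tour_length(dist, np.array([0, 1, 2]))
    if mode == "exact":
        return _tsp_exact(dist)
    if mode == "heuristic":
        return _tsp_heuristic(dist)
    raise ValueError(f"unknown TSP mode {mode!r}")


def tsp_loop_length(
    centroids: np.ndarray, metric: str = "euclidean", mode: str = "heuristic"
) -> float:
    return tsp_tour(centroids, metric=metric, mode=mode)[1]


def standardize(distance_mm: float, body: PatientBody) -> float:
    """BSA-standardize a distance: (mm / 1000) / bsa, yielding m^-1."""
    if distance_mm < 0:
        raise ValueError("distance must be >= 0")
    return (distance_mm / 1000.0) / body.bsa_m2


@dataclass
class DisseminationFeatures:
    """The seven standardized dissemination features plus raw mm counterparts."""

    n_lesions: int
    mtv_ml: float
    bsa_m2: float
    # raw distances, mm
    dmax_euc_mm: float
    dmax_man_mm: float
    dmax_tch_mm: float
    d_tsp_mm: float
    dmax_euc_vox_mm: float
    dmax_man_vox_mm: float
    dmax_tch_vox_mm: float
    # standardized, m^-1
    sdmax_euc: float
    sdmax_man: float
    sdmax_tch: float
    sd_tsp: float
    sdmax_euc_vox: float
    sdmax_man_vox: float
    sdmax_tch_vox: float

    FEATURE_NAMES = (
        "sdmax_euc", "sdmax_man", "sdmax_tch", "sd_tsp",
        "sdmax_euc_vox", "sdmax_man_vox", "sdmax_tch_vox",
    )

    def to_dict(self) -> dict[str, float]:
        return {
            "n_lesions": self.n_lesions,
            "mtv_ml": self.mtv_ml,
            "bsa_m2": self.bsa_m2,
            "dmax_euc_mm": self.dmax_euc_mm,
            "dmax_man_mm": self.dmax_man_mm,
            "dmax_tch_mm": self.dmax_tch_mm,
            "d_tsp_mm": self.d_tsp_mm,
            "dmax_euc_vox_mm": self.dmax_euc_vox_mm,
            "dmax_man_vox_mm": self.dmax_man_vox_mm,
            "dmax_tch_vox_mm": self.dmax_tch_vox_mm,
            "sdmax_euc": self.sdmax_euc,
            "sdmax_man": self.sdmax_man,
            "sdmax_tch": self.sdmax_tch,
            "sd_tsp": self.sd_tsp,
            "sdmax_euc_vox": self.sdmax_euc_vox,
            "sdmax_man_vox": self.sdmax_man_vox,
            "sdmax_tch_vox": self.sdmax_tch_vox,
        }


def compute_features(
    lesion_set: LesionSet,
    body: PatientBody,
    centroid_weighting: str = "geometric",
    tsp_mode: str = "heuristic",
    tsp_metric: str = "euclidean",
) -> DisseminationFeatures:
    """Assemble all seven dissemination features for one patient.

    With fewer than two lesions every distance feature is NaN (the features
    are undefined; callers decide whether to exclude the patient).
    """
    n = lesion_set.n_lesions
    mtv = lesion_set.total_mtv_ml
    if n < 2:
        nan = float("nan")
        return DisseminationFeatures(
            n_lesions=n, mtv_ml=mtv, bsa_m2=body.bsa_m2,
            dmax_euc_mm=nan, dmax_man_mm=nan, dmax_tch_mm=nan, d_tsp_mm=nan,
            dmax_euc_vox_mm=nan, dmax_man_vox_mm=nan, dmax_tch_vox_mm=nan,
            sdmax_euc=nan, sdmax_man=nan, sdmax_tch=nan, sd_tsp=nan,
            sdmax_euc_vox=nan, sdmax_man_vox=nan, sdmax_tch_vox=nan,
        )
    cents = lesion_set.centroids(centroid_weighting)
    raw_cent = {m: centroid_max_distance(cents, m)[0] for m in METRICS}
    raw_vox = {m: voxel_max_distance(lesion_set, m) for m in METRICS}
    d_tsp = tsp_loop_length(cents, metric=tsp_metric, mode=tsp_mode)
    return DisseminationFeatures(
        n_lesions=n, mtv_ml=mtv, bsa_m2=body.bsa_m2,
        dmax_euc_mm=raw_cent["euclidean"],
        dmax_man_mm=raw_cent["manhattan"],
        dmax_tch_mm=raw_cent["tchebychev"],
        d_tsp_mm=d_tsp,
        dmax_euc_vox_mm=raw_vox["euclidean"],
        dmax_man_vox_mm=raw_vox["manhattan"],
        dmax_tch_vox_mm=raw_vox["tchebychev"],
        sdmax_euc=standardize(raw_cent["euclidean"], body),
        sdmax_man=standardize(raw_cent["manhattan"], body),
        sdmax_tch=standardize(raw_cent["tchebychev"], body),
        sd_tsp=standardize(d_tsp, body),
        sdmax_euc_vox=standardize(raw_vox["euclidean"], body),
        sdmax_man_vox=standardize(raw_vox["manhattan"], body),
        sdmax_tch_vox=standardize(raw_vox["tchebychev"], body),
    )
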