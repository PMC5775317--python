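"""Seed-based correlation baseline for tumor delineation.

The comparator the ICA/DICI route is evaluated against: a small spherical
seed is placed near the lesion centre, its mean BOLD time course is
correlated (Pearson) with every brain voxel's time course, and the map is
thresholded at fixed r cutoffs.  No cluster filtering is applied to the
thresholded maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, SpecError
from .imaging import BinaryMask, Series4D, VoxelGrid

__all__ = ["SeedSpec", "CorrelationMap", "seed_sphere", "seed_correlation",
           "threshold_correlation"]


@dataclass(frozen=True)
class SeedSpec:
    """A spherical seed: centre (voxel indices or mm), radius, r thresholds."""

    center: tuple[float, float, float]
    radius_mm: float = 6.0
    space: str = "vox"
    r_thresholds: tuple[float, ...] = (0.5, 0.8)

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise SpecError("radius_mm must be positive")
        if self.space not in ("vox", "mm"):
            raise SpecError("space must be 'vox' or 'mm'")
        thr = tuple(float(t) for t in self.r_thresholds)
        if any(not 0 < t < 1 for t in thr) or any(b <= a for a, b in zip(thr, thr[1:])):
            raise SpecError("r_thresholds must be strictly increasing values in (0,1)")
        object.__setattr__(self, "r_thresholds", thr)

    def center_mm(self, grid: VoxelGrid) -> np.ndarray:
        c = np.asarray(self.center, float)
        return c if self.space == "mm" else np.atleast_1d(grid.vox_to_mm(c))


@dataclass(frozen=True)
class CorrelationMap:
    grid: VoxelGrid
    r: np.ndarray = field(repr=False)      # full 3D array, NaN outside brain
    brain: BinaryMask = None               # type: ignore[assignment]
    seed: SeedSpec = None                  # type: ignore[assignment]


def seed_sphere(grid: VoxelGrid, seed: SeedSpec) -> BinaryMask:
    """Voxels whose centres lie within radius_mm of the seed centre."""
    center = seed.center_mm(grid)
    idx = np.indices(grid.shape, dtype=float).reshape(3, -1).T
    mm = np.atleast_2d(grid.vox_to_mm(idx))
    inside = ((mm - center) ** 2).sum(axis=1) <= seed.radius_mm ** 2
    return BinaryMask(grid, inside.reshape(grid.shape))


def seed_correlation(series: Series4D, mask: BinaryMask, seed: SeedSpec) -> CorrelationMap:
    """Pearson correlation of every in-mask voxel with the mean in-sphere course.

    The seed course is the unweighted mean over sphere voxels that are
    also inside the brain mask (in-seed voxels stay in the output map).
    """
    sphere = seed_sphere(series.grid, seed)
    in_seed = sphere.data & mask.data
    if not in_seed.any():
        raise SpecError("seed sphere does not intersect the brain mask")
    course = series.data[in_seed].mean(axis=0)
    course = course - course.mean()
    denom_seed = np.sqrt((course ** 2).sum())
    if denom_seed < 1e-12:
        raise DataError("seed time course has zero variance")

    X = series.data[mask.data]
    X = X - X.mean(axis=1, keepdims=True)
    denom_vox = np.sqrt((X ** 2).sum(axis=1))
    denom_vox[denom_vox == 0] = np.inf    # zero-variance voxels get r = 0
    r_vals = (X @ course) / (denom_vox * denom_seed)
    r = np.full(series.grid.shape, np.nan)
    r[mask.data] = np.clip(r_vals, -1.0, 1.0)
    return CorrelationMap(grid=series.grid, r=r, brain=mask, seed=seed)


def threshold_correlation(cmap: CorrelationMap, r_thr: float) -> BinaryMask:
    """Binary mask of voxels with r strictly above the threshold."""
    if not 0 < r_thr < 1:
        raise SpecError("r_thr must be in (0, 1)")
    with np.errstate(invalid="ignore"):
        member = np.nan_to_num(cmap.r, nan=-np.inf) > r_thr
    return BinaryMask(cmap.grid, member)
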