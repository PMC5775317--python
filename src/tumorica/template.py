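"""Rough tumor-template generation by intensity-based 3D region growth.

Mimics the interactive "create 3D VOI from a seed" workflow used to draw
rough lesion templates on an anatomical image.  Growth starts at a seed
voxel and admits a voxel iff it is 26-connected to an already admitted
voxel, its intensity is within ``diff_from_origin`` of the seed intensity,
within ``diff_from_edge`` of the intensity of the neighbor it was reached
from, and its centre lies within ``radius_mm`` of the seed centre (mm
distance via the affine).  A single morphological closing with a ball of
``closing_radius_vox`` voxels optionally polishes the edge afterwards.

The admitted set is order-independent: the parent-difference rule is
applied as "reachable through *some* admissible chain", implemented as a
breadth-first search that may re-visit voxels (a voxel rejected through
one parent can be admitted through another), so the result is the full
fixed point of rules (a)-(d).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .errors import DataError, SpecError
from .imaging import BinaryMask, Volume3D

__all__ = ["GrowthParams", "TumorTemplate", "grow_voi", "template_stats"]

_NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the seeded region growth.

    ``seed_point`` is a voxel-index triple unless ``seed_space`` is "mm",
    in which case it is converted through the image affine (nearest voxel).
    """

    seed_point: tuple[float, float, float]
    radius_mm: float
    diff_from_origin: float
    diff_from_edge: float
    closing_radius_vox: int = 1
    seed_space: str = "vox"

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise SpecError("radius_mm must be positive")
        if self.diff_from_origin < 0 or self.diff_from_edge < 0:
            raise SpecError("intensity tolerances must be nonnegative")
        if self.closing_radius_vox < 0:
            raise SpecError("closing_radius_vox must be nonnegative")
        if self.seed_space not in ("vox", "mm"):
            raise SpecError("seed_space must be 'vox' or 'mm'")

    def seed_voxel(self, grid) -> tuple[int, int, int]:
        p = np.asarray(self.seed_point, float)
        if self.seed_space == "mm":
            p = grid.mm_to_vox(p)
        ijk = tuple(int(round(x)) for x in p)
        if any(not 0 <= ijk[a] < grid.shape[a] for a in range(3)):
            raise SpecError(f"seed voxel {ijk} is outside the image bounds {grid.shape}")
        return ijk


@dataclass(frozen=True)
class TumorTemplate:
    mask: BinaryMask
    params: GrowthParams = None  # type: ignore[assignment]
    source_image_id: str = ""


def grow_voi(anat: Volume3D, params: GrowthParams) -> TumorTemplate:
    """Grow a binary VOI from the seed under the intensity/radius rules."""
    grid = anat.grid
    seed = params.seed_voxel(grid)
    intens = anat.data
    if not np.isfinite(intens[seed]):
        raise DataError("seed voxel intensity is not finite")
    seed_val = intens[seed]

    # precompute the mm-radius ball around the seed
    idx = np.indices(grid.shape, dtype=float)
    delta_vox = idx - np.asarray(seed, float).reshape(3, 1, 1, 1)
    mm = np.einsum("ij,j...->i...", grid.affine[:3, :3], delta_vox)
    within_radius = (mm ** 2).sum(axis=0) <= params.radius_mm ** 2
    origin_ok = np.abs(intens - seed_val) <= params.diff_from_origin
    admissible = within_radius & origin_ok

    member = np.zeros(grid.shape, dtype=bool)
    member[seed] = True
    queue = deque([seed])
    shape = grid.shape
    while queue:
        v = queue.popleft()
        vval = intens[v]
        for d in _NEIGHBORS_26:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if not (0 <= w[0] < shape[0] and 0 <= w[1] < shape[1] and 0 <= w[2] < shape[2]):
                continue
            if member[w] or not admissible[w]:
                continue
            if abs(intens[w] - vval) <= params.diff_from_edge:
                member[w] = True
                queue.append(w)

    if params.closing_radius_vox > 0:
        member = ndimage.binary_closing(member, structure=ball(params.closing_radius_vox))
        member &= within_radius  # closing must not leak past the radius
        member[seed] = True
    return TumorTemplate(mask=BinaryMask(grid, member), params=params,
                         source_image_id=getattr(anat, "image_id", ""))


def template_stats(t: TumorTemplate) -> dict:
    """Voxel count, physical volume and mm centroid of a template."""
    mask = t.mask
    n = mask.n_voxels
    ijk = np.argwhere(mask.data)
    centroid_mm = mask.grid.vox_to_mm(ijk.mean(axis=0)) if n else np.full(3, np.nan)
    return {
        "n_voxels": n,
        "volume_mm3": n * mask.grid.voxel_volume_mm3,
        "centroid_mm": tuple(float(x) for x in np.atleast_1d(centroid_mm)),
    }
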