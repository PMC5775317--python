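"""Voxel-grid data model, NIfTI-1 I/O, brain masking and Gaussian smoothing.

All volumes in the package live on a :class:`VoxelGrid` that carries the
array shape together with the NIfTI affine, so millimetre quantities
(seed radii, smoothing FWHM) can always be converted to voxel units.
Voxel indices are 0-based throughout; mm coordinates are defined by the
affine in the usual NIfTI convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DataError, DegenerateMaskError, FormatError

__all__ = [
    "VoxelGrid",
    "Volume3D",
    "Series4D",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "compute_brain_mask",
    "smooth_gaussian",
]

#: conversion factor between a Gaussian FWHM and its standard deviation
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D voxel lattice with physical (mm) geometry.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each axis, all >= 1.
    affine : ndarray, shape (4, 4)
        Voxel-index -> mm homogeneous transform (NIfTI convention).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(affine)) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be finite and invertible")
        object.__setattr__(self, "affine", affine)
        vox = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
        if np.any(vox <= 0):
            raise ValueError("voxel sizes must be positive")
        object.__setattr__(self, "_voxel_size", tuple(float(v) for v in vox))

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return self._voxel_size  # type: ignore[attr-defined]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @classmethod
    def isotropic(cls, shape, voxel_size_mm: float = 1.0) -> "VoxelGrid":
        """Grid with isotropic voxels and a diagonal affine centred at the origin corner."""
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
        return cls(tuple(shape), affine)

    def vox_to_mm(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        hom = np.c_[ijk, np.ones(len(ijk))]
        return np.squeeze((self.affine @ hom.T).T[:, :3])

    def mm_to_vox(self, xyz) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        hom = np.c_[xyz, np.ones(len(xyz))]
        return np.squeeze((np.linalg.inv(self.affine) @ hom.T).T[:, :3])

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)


def _check_grid_data(grid: VoxelGrid, data: np.ndarray, ndim: int) -> np.ndarray:
    data = np.asarray(data)
    if data.ndim != ndim:
        raise ValueError(f"expected {ndim}D data, got {data.ndim}D")
    if tuple(data.shape[:3]) != grid.shape:
        raise ValueError(f"data shape {data.shape[:3]} does not match grid {grid.shape}")
    return data


@dataclass(frozen=True)
class Volume3D:
    """A scalar 3D image on a voxel grid."""

    grid: VoxelGrid
    data: np.ndarray = field(repr=False)

    def __post_init__(self):
        data = _check_grid_data(self.grid, self.data, 3).astype(float, copy=False)
        if not np.all(np.isfinite(data)):
            raise ValueError("Volume3D values must be finite")
        object.__setattr__(self, "data", data)


@dataclass(frozen=True)
class Series4D:
    """A 4D BOLD series: grid x time, with a repetition time in seconds."""

    grid: VoxelGrid
    data: np.ndarray = field(repr=False)
    tr_seconds: float = 2.0

    def __post_init__(self):
        data = _check_grid_data(self.grid, self.data, 4).astype(float, copy=False)
        if data.shape[3] < 2:
            raise ValueError("a Series4D needs at least 2 frames")
        if not np.all(np.isfinite(data)):
            raise ValueError("Series4D values must be finite")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "data", data)

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[3])

    def mean_volume(self) -> Volume3D:
        return Volume3D(self.grid, self.data.mean(axis=3))


@dataclass(frozen=True)
class BinaryMask:
    """A boolean 3D volume (brain mask, tumor template, thresholded component)."""

    grid: VoxelGrid
    data: np.ndarray = field(repr=False)

    def __post_init__(self):
        data = _check_grid_data(self.grid, self.data, 3).astype(bool, copy=False)
        object.__setattr__(self, "data", data)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.grid, self.data & other.data)

    def dilate(self, iterations: int = 1) -> "BinaryMask":
        """Binary dilation with the full 26-connected structuring element."""
        struct = np.ones((3, 3, 3), bool)
        return BinaryMask(self.grid, ndimage.binary_dilation(self.data, struct, iterations=iterations))


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 0.0 when both masks are empty."""
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        return 0.0
    return 2.0 * float(np.logical_and(a.data, b.data).sum()) / (na + nb)


def read_volume(path):
    """Read a NIfTI-1 file as a :class:`Volume3D` or :class:`Series4D`.

    The header dimensionality decides the return type; trailing singleton
    dimensions beyond the third are squeezed before the decision.
    """
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of error types
        raise FormatError(f"could not read NIfTI volume from {path!r}: {exc}") from exc
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim == 3:
        grid = VoxelGrid(data.shape, img.affine)
        return Volume3D(grid, data)
    if data.ndim == 4:
        grid = VoxelGrid(data.shape[:3], img.affine)
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        return Series4D(grid, data, tr_seconds=tr if tr > 0 else 2.0)
    raise FormatError(f"{path!r} is {data.ndim}D; only 3D/4D volumes are supported")


def write_volume(vol, path):
    """Write a volume/series/mask to NIfTI-1. Masks are stored as uint8 0/1."""
    if isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data
    img = nib.Nifti1Image(data, vol.grid.affine)
    if isinstance(vol, Series4D):
        zooms = list(vol.grid.voxel_size_mm) + [vol.tr_seconds]
        img.header.set_zooms(zooms)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise OSError(f"could not write volume to {path!r}: {exc}") from exc
    return path


def compute_brain_mask(mean_img: Volume3D, frac: float = 0.2) -> BinaryMask:
    """Threshold-based head/brain mask from a mean EPI image.

    Voxels brighter than ``frac`` times the 98th percentile of the nonzero
    intensities are kept, and only the largest 26-connected foreground
    component is retained (drops isolated bright speckles).
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    data = mean_img.data
    nonzero = data[data > 0]
    if nonzero.size == 0:
        raise DegenerateMaskError("mean image has no positive voxels; cannot build a brain mask")
    thr = frac * np.percentile(nonzero, 98)
    fg = data > thr
    if not fg.any():
        raise DegenerateMaskError("no voxel exceeds the masking threshold")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3, 3), bool))
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    return BinaryMask(mean_img.grid, fg)


def smooth_gaussian(series: Series4D, fwhm_mm: float, mask: BinaryMask | None = None) -> Series4D:
    """Spatially smooth each frame with an isotropic Gaussian of the given FWHM.

    The kernel is isotropic in mm: sigma along each axis is
    ``fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm[axis]`` voxels.  Smoothing is
    applied over the full field of view; ``mask`` (if given) only restricts
    which voxels are *kept* in the output, it does not renormalise the kernel
    at mask edges.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm < np.finfo(float).eps:
        warnings.warn("fwhm_mm ~ 0: smoothing is the identity", stacklevel=2)
        return series
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in series.grid.voxel_size_mm]
    out = ndimage.gaussian_filter(series.data, sigma=sigma_vox + [0.0], mode="constant")
    if mask is not None:
        out = np.where(mask.data[..., None], out, series.data)
    return Series4D(series.grid, out, tr_seconds=series.tr_seconds)
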