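"""Volumetric data model and numerics.

A :class:`VolumeGrid` is a 3-D scalar field plus a 4x4 RAS+ affine mapping
0-based voxel indices to millimetres (MNI convention).  On top of it the
module provides the small set of image operations the ROI analysis needs:
coordinate transforms, spherical masks, Gaussian smoothing, voxelwise
one-sample t-maps, and NIfTI-1 I/O.

All user-facing coordinates are in mm; voxel indices appear only at the
boundary of the mask/peak machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
from nibabel.affines import apply_affine
from scipy import ndimage

from .errors import ArgumentError, FormatError, GeometryError

__all__ = [
    "VolumeGrid",
    "StatMap",
    "fwhm_to_sigma",
    "sphere_mask",
    "gaussian_smooth",
    "one_sample_tmap",
    "read_volume",
    "write_volume",
]

#: FWHM = 2*sqrt(2 ln 2) * sigma for a Gaussian kernel.
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a full width at half maximum to a Gaussian sigma (same units)."""
    return float(fwhm) / FWHM_FACTOR


@dataclass
class VolumeGrid:
    """A 3-D scalar volume with an affine voxel->mm mapping (RAS+).

    Parameters
    ----------
    data
        3-D float array of voxel values.  NaN flags a missing value.
    affine
        4x4 invertible matrix taking 0-based voxel indices to mm.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise GeometryError(f"volume data must be 3-D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size along each axis in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    def voxel_to_mm(self, index) -> np.ndarray:
        """mm coordinates of the centre of the voxel at ``index``."""
        idx = np.asarray(index)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            raise GeometryError(f"voxel index {tuple(idx)} outside shape {self.shape}")
        return apply_affine(self.affine, idx)

    def mm_to_voxel(self, point) -> tuple[int, int, int]:
        """Nearest voxel index to an mm point; raises if outside the grid."""
        inv = np.linalg.inv(self.affine)
        vox = np.round(apply_affine(inv, np.asarray(point, dtype=float))).astype(int)
        if np.any(vox < 0) or np.any(vox >= np.array(self.shape)):
            raise GeometryError(f"mm point {tuple(point)} falls outside the grid")
        return tuple(int(v) for v in vox)

    def contains_mm(self, point) -> bool:
        inv = np.linalg.inv(self.affine)
        vox = np.round(apply_affine(inv, np.asarray(point, dtype=float)))
        return bool(np.all(vox >= 0) and np.all(vox < np.array(self.shape)))

    def copy_with(self, data: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(data=np.asarray(data, dtype=np.float64), affine=self.affine.copy())


@dataclass
class StatMap:
    """A voxelwise statistic map (currently one-sample t)."""

    grid: VolumeGrid
    statistic: str
    df: int
    n_subjects: int

    def __post_init__(self) -> None:
        if self.statistic != "t":
            raise ArgumentError(f"unsupported statistic {self.statistic!r}")


def mni_grid(shape=(61, 73, 61), voxel_size: float = 3.0) -> VolumeGrid:
    """An empty grid covering the MNI bounding box at the given resolution.

    The default 61x73x61 lattice at 3 mm spans x in [-90, 90],
    y in [-126, 90], z in [-72, 108] with the origin voxel at
    (-90, -126, -72) mm.
    """
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    affine[:3, 3] = (-90.0, -126.0, -72.0)
    return VolumeGrid(data=np.zeros(shape), affine=affine)


def voxel_center_coords(grid: VolumeGrid, indices: np.ndarray) -> np.ndarray:
    """mm coordinates of many voxel centres at once (n x 3 in, n x 3 out)."""
    return apply_affine(grid.affine, np.asarray(indices))


def sphere_mask(grid: VolumeGrid, center, radius: float) -> np.ndarray:
    """Boolean mask of voxels whose centres lie within ``radius`` mm of ``center``.

    Inclusion is by Euclidean distance from the voxel centre to the sphere
    centre, inclusive of the boundary.  A centre outside the grid yields an
    empty mask with a warning rather than an error.
    """
    if radius <= 0:
        raise ArgumentError("sphere radius must be > 0")
    center = np.asarray(center, dtype=float)
    mask = np.zeros(grid.shape, dtype=bool)
    inv = np.linalg.inv(grid.affine)
    cvox = apply_affine(inv, center)
    if np.any(np.round(cvox) < 0) or np.any(np.round(cvox) >= np.array(grid.shape)):
        warnings.warn(
            f"sphere centre {tuple(center)} mm lies outside the grid; empty mask",
            stacklevel=2,
        )
        return mask
    # restrict the search to a voxel-space bounding box around the centre
    halfwidth = radius / grid.spacing + 1.0
    lo = np.maximum(np.floor(cvox - halfwidth).astype(int), 0)
    hi = np.minimum(np.ceil(cvox + halfwidth).astype(int) + 1, np.array(grid.shape))
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    dist = np.linalg.norm(voxel_center_coords(grid, idx) - center, axis=1)
    inside = idx[dist <= radius]
    mask[inside[:, 0], inside[:, 1], inside[:, 2]] = True
    return mask


def gaussian_smooth(grid: VolumeGrid, fwhm: float) -> VolumeGrid:
    """Separable Gaussian smoothing with the kernel width given as FWHM in mm.

    sigma per axis is ``fwhm / (2 sqrt(2 ln 2))`` divided by that axis's
    voxel spacing.  The discrete kernel is truncated at 4 sigma and
    normalized to unit sum, so constant volumes are preserved exactly
    (reflective boundary).  ``fwhm=0`` returns the input unchanged.
    """
    if fwhm < 0:
        raise ArgumentError("fwhm must be >= 0")
    if fwhm == 0:
        return grid
    sigma_vox = fwhm_to_sigma(fwhm) / grid.spacing
    smoothed = ndimage.gaussian_filter(grid.data, sigma=sigma_vox, truncate=4.0, mode="reflect")
    return grid.copy_with(smoothed)


def one_sample_tmap(volumes: list[VolumeGrid]) -> StatMap:
    """Voxelwise one-sample t statistic across subjects.

    t = mean / (sd / sqrt(n)) with the n-1 denominator in sd.  Voxels with
    zero variance across subjects are flagged NaN (missing) so that peak
    searches never land on degenerate voxels.  df = n - 1.
    """
    if len(volumes) < 2:
        raise ArgumentError("one_sample_tmap needs at least 2 volumes")
    ref = volumes[0]
    for v in volumes[1:]:
        if not ref.same_geometry(v):
            raise GeometryError("volumes differ in shape or affine")
    stack = np.stack([v.data for v in volumes], axis=0)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[sd == 0.0] = np.nan
    return StatMap(grid=ref.copy_with(t), statistic="t", df=n - 1, n_subjects=n)


def read_volume(path) -> VolumeGrid:
    """Read a NIfTI-1 volume from disk."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"could not read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return VolumeGrid(data=data.astype(np.float64), affine=np.asarray(img.affine))


def write_volume(grid: VolumeGrid, path) -> None:
    """Write a volume as NIfTI-1 (float32 on disk)."""
    img = nib.Nifti1Image(grid.data.astype(np.float32), grid.affine)
    nib.save(img, str(path))
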