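"""Volume geometry, masks and basic image operations.

Everything downstream (seed maps, overlap counts, TFCE, ALE fields) lives on a
single :class:`VolumeGrid` — a lattice with a voxel-index -> world-mm affine in
the RAS+ convention, typically the 2 mm isotropic MNI152 grid. Grids must match
exactly between interacting volumes; resampling is never silent and must go
through :func:`resample_mask` / :func:`resample_scalar` deliberately, because
implicit interpolation would corrupt voxel-overlap counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "ScalarVolume",
    "BinaryMask",
    "GridMismatchError",
    "make_grid",
    "make_sphere_seed",
    "union_masks",
    "connected_components",
    "gaussian_smooth",
    "dice",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "resample_mask",
    "resample_scalar",
]

#: FWHM of a Gaussian in units of its standard deviation.
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (unlike numpy's banker's
    rounding) so snapping of reported coordinates is deterministic and
    direction-symmetric."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D lattice with a voxel-index -> world-mm affine (RAS+).

    Parameters
    ----------
    dims:
        Number of voxels along each axis; each must be >= 1.
    affine:
        4x4 homogeneous transform mapping 0-based voxel indices to world mm.
    """

    dims: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims!r}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine linear part is singular")
        affine = affine.copy()
        affine.setflags(write=False)
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "affine", affine)

    # -- geometry ---------------------------------------------------------
    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge length (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, index) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        world = idx @ self.affine[:3, :3].T + self.affine[:3, 3]
        return world[0] if np.ndim(index) == 1 else world

    def world_to_voxel_float(self, coord_mm) -> np.ndarray:
        coord = np.atleast_2d(np.asarray(coord_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        vox = coord @ inv[:3, :3].T + inv[:3, 3]
        return vox[0] if np.ndim(coord_mm) == 1 else vox

    def world_to_voxel(self, coord_mm) -> tuple[int, int, int]:
        """Map a world coordinate to the nearest 0-based voxel index
        (ties rounded away from zero). Raises for out-of-grid coordinates."""
        idx = _round_half_away(self.world_to_voxel_float(coord_mm))
        if idx.ndim != 1:
            raise ValueError("world_to_voxel takes a single coordinate triple")
        if not self.contains_index(idx):
            raise ValueError(
                f"world coordinate {tuple(np.asarray(coord_mm, float))} maps to voxel "
                f"{tuple(idx)} outside grid dims {self.dims}"
            )
        return tuple(int(i) for i in idx)

    def contains_index(self, index) -> bool:
        idx = np.asarray(index)
        return bool(np.all(idx >= 0) and np.all(idx < np.asarray(self.dims)))

    def matches(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return self.dims == other.dims and np.allclose(
            self.affine, other.affine, atol=tol
        )

    def require_matches(self, other: "VolumeGrid", what: str = "volumes") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"{what} are defined on different grids "
                f"({self.dims} vs {other.dims}); resample explicitly first"
            )


def make_grid(dims, voxel_mm: float = 2.0, centred: bool = True) -> VolumeGrid:
    """Convenience constructor for an axis-aligned isotropic grid.

    With ``centred=True`` the world origin sits at the grid centre, mimicking
    MNI-style coordinates with positive and negative mm on every axis.
    """
    dims = tuple(int(d) for d in dims)
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = float(voxel_mm)
    if centred:
        affine[:3, 3] = -(np.asarray(dims, dtype=float) - 1.0) / 2.0 * voxel_mm
    return VolumeGrid(dims, affine)


@dataclass
class ScalarVolume:
    """One real value per voxel on a :class:`VolumeGrid` (t-map, TFCE map,
    ALE field, p-map, overlap count...)."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.shape != self.grid.dims:
            if values.size == self.grid.n_voxels:
                values = values.reshape(self.grid.dims)
            else:
                raise ValueError(
                    f"values shape {values.shape} does not match grid {self.grid.dims}"
                )
        self.values = values

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.grid, self.values.copy())


@dataclass
class BinaryMask:
    """Boolean membership per voxel (lesion tracing, seed, brain mask...)."""

    grid: VolumeGrid
    membership: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.membership)
        if m.shape != self.grid.dims:
            if m.size == self.grid.n_voxels:
                m = m.reshape(self.grid.dims)
            else:
                raise ValueError(
                    f"membership shape {m.shape} does not match grid {self.grid.dims}"
                )
        self.membership = m.astype(bool)

    @property
    def size(self) -> int:
        """Number of member voxels."""
        return int(self.membership.sum())

    @property
    def flat_indices(self) -> np.ndarray:
        return np.flatnonzero(self.membership.ravel())

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.grid, self.membership.copy(), self.label)


# ---------------------------------------------------------------------------
# mask construction and algebra
# ---------------------------------------------------------------------------

def make_sphere_seed(center_mm, radius_mm: float, grid: VolumeGrid,
                     label: str = "") -> BinaryMask:
    """Spherical seed: every voxel whose centre lies within ``radius_mm``
    (inclusive) of ``center_mm`` in world space.

    The inclusive boundary is deliberate so membership is a deterministic,
    documented tie rule.
    """
    if radius_mm <= 0:
        raise ValueError(f"radius must be positive, got {radius_mm}")
    center = np.asarray(center_mm, dtype=float)
    # bounding box in voxel space, padded by one voxel for safety
    c_vox = grid.world_to_voxel_float(center)
    if not grid.contains_index(_round_half_away(c_vox)):
        raise ValueError(f"sphere centre {tuple(center)} is outside the grid")
    pad = radius_mm / grid.voxel_size_mm + 1.0
    lo = np.maximum(np.floor(c_vox - pad).astype(int), 0)
    hi = np.minimum(np.ceil(c_vox + pad).astype(int) + 1, grid.dims)
    membership = np.zeros(grid.dims, dtype=bool)
    ii, jj, kk = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    world = grid.voxel_to_world(idx)
    inside = np.linalg.norm(world - center, axis=1) <= radius_mm
    membership[ii.ravel()[inside], jj.ravel()[inside], kk.ravel()[inside]] = True
    return BinaryMask(grid, membership, label=label)


def union_masks(masks: list[BinaryMask], label: str = "") -> BinaryMask:
    """Voxelwise OR of masks on one shared grid (no silent resampling)."""
    if not masks:
        raise ValueError("union_masks requires a nonempty list")
    grid = masks[0].grid
    out = np.zeros(grid.dims, dtype=bool)
    for m in masks:
        grid.require_matches(m.grid, "masks")
        out |= m.membership
    return BinaryMask(grid, out, label=label)


def intersect_masks(a: BinaryMask, b: BinaryMask, label: str = "") -> BinaryMask:
    a.grid.require_matches(b.grid, "masks")
    return BinaryMask(a.grid, a.membership & b.membership, label=label)


def connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def connected_components(mask: BinaryMask | np.ndarray,
                         connectivity: int = 26) -> tuple[np.ndarray, np.ndarray]:
    """Label maximal connected components under the 6/18/26 neighbourhood.

    Returns ``(labels, sizes)`` where ``labels`` is 0 for background and
    ``sizes[i]`` is the voxel count of component ``i + 1``; sizes always sum to
    the mask's voxel count.
    """
    arr = mask.membership if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    structure = connectivity_structure(connectivity)
    labels, n = ndimage.label(arr, structure=structure)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:].astype(int)
    return labels, sizes


def gaussian_smooth(vol: ScalarVolume, fwhm_mm: float) -> ScalarVolume:
    """Isotropic-in-mm Gaussian smoothing (sigma per axis scales with the voxel
    size); reflective boundary, so constant fields are unchanged and total
    mass is conserved."""
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be nonnegative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return vol.copy()
    sigma_vox = fwhm_mm / FWHM_PER_SIGMA / vol.grid.voxel_size_mm
    smoothed = ndimage.gaussian_filter(
        np.asarray(vol.values, dtype=float), sigma=sigma_vox, mode="reflect"
    )
    return ScalarVolume(vol.grid, smoothed)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap coefficient 2|A∩B| / (|A|+|B|); 0 when both are empty."""
    a.grid.require_matches(b.grid, "masks")
    denom = a.size + b.size
    if denom == 0:
        return 0.0
    return 2.0 * int((a.membership & b.membership).sum()) / denom


# ---------------------------------------------------------------------------
# NIfTI I/O — affines are taken from / written to the header verbatim
# ---------------------------------------------------------------------------

def load_volume(path) -> ScalarVolume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return ScalarVolume(VolumeGrid(data.shape, img.affine), data)


def save_volume(vol: ScalarVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32),
                          np.asarray(vol.grid.affine))
    nib.save(img, str(path))


def load_mask(path, label: str | None = None) -> BinaryMask:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return BinaryMask(VolumeGrid(data.shape, img.affine), data > 0.5,
                      label=label if label is not None else str(path))


def save_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.membership.astype(np.uint8),
                          np.asarray(mask.grid.affine))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# explicit resampling (never called implicitly)
# ---------------------------------------------------------------------------

def _source_coords(src: VolumeGrid, dst: VolumeGrid) -> np.ndarray:
    """Voxel coordinates in `src` of every voxel centre of `dst`."""
    idx = np.indices(dst.dims).reshape(3, -1).T.astype(float)
    world = dst.voxel_to_world(idx)
    return src.world_to_voxel_float(world).T  # (3, n)


def resample_mask(mask: BinaryMask, grid: VolumeGrid) -> BinaryMask:
    """Nearest-neighbour resampling of a mask onto another grid."""
    coords = _source_coords(mask.grid, grid)
    out = ndimage.map_coordinates(mask.membership.astype(np.uint8), coords,
                                  order=0, mode="constant", cval=0)
    return BinaryMask(grid, out.reshape(grid.dims) > 0, label=mask.label)


def resample_scalar(vol: ScalarVolume, grid: VolumeGrid) -> ScalarVolume:
    """Trilinear resampling of a scalar map onto another grid."""
    coords = _source_coords(vol.grid, grid)
    out = ndimage.map_coordinates(np.asarray(vol.values, float), coords,
                                  order=1, mode="constant", cval=0.0)
    return ScalarVolume(grid, out.reshape(grid.dims))
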