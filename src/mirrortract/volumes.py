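"""Volumes, binary ROIs and their geometry.

Everything downstream works on three kinds of objects sharing one sampling
grid: a :class:`GridSpec` (shape + voxel-to-world affine), boolean
:class:`MaskVolume` (lesion, white matter, brain, targets, exclusion shells)
and real-valued :class:`ScalarVolume` (anisotropy, connection probability).

The left-right axis is by convention the first grid axis; contralateral
mirroring flips voxel index ``i -> Nx-1-i``, which presumes the volume has
been aligned so the inter-hemispheric plane coincides with the grid
mid-plane.  All metric operations (dilation by a physical distance, sphere
ROIs, physical volumes) are computed in world millimetres so anisotropic
voxels (e.g. 1.0 x 1.0 x 1.5 mm) are handled correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


class GridMismatchError(ValueError):
    """Two volumes do not live on the same grid."""


@dataclass(frozen=True)
class GridSpec:
    """Sampling grid: voxel array shape plus voxel-to-world affine (mm).

    Voxel indices are 0-based; a voxel's world position is the affine image
    of its integer index (voxel-centre convention).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4, mm
    lr_axis: int = 0  # which grid axis runs left-right

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        affine = np.asarray(self.affine, dtype=float)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be 3 positive ints, got {shape}")
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)
        affine.setflags(write=False)

    @classmethod
    def create(cls, shape, voxel_size=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
               lr_axis: int = 0) -> "GridSpec":
        vs = np.asarray(voxel_size, dtype=float)
        if np.any(vs <= 0):
            raise ValueError("voxel_size components must be > 0")
        aff = np.eye(4)
        aff[:3, :3] = np.diag(vs)
        aff[:3, 3] = origin
        return cls(tuple(shape), aff, lr_axis)

    @property
    def voxel_size(self) -> np.ndarray:
        """Physical voxel edge lengths (mm) along each grid axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    def voxel_to_world(self, ijk) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        out = np.atleast_2d(ijk) @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if ijk.ndim == 1 else out

    def world_to_voxel(self, xyz) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = self.inverse_affine
        out = np.atleast_2d(xyz) @ inv[:3, :3].T + inv[:3, 3]
        return out[0] if xyz.ndim == 1 else out

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centres, shape (*shape, 3)."""
        idx = np.indices(self.shape, dtype=float)
        ijk = np.stack(idx, axis=-1).reshape(-1, 3)
        return self.voxel_to_world(ijk).reshape(*self.shape, 3)

    def matches(self, other: "GridSpec", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol)


def _check_same_grid(a, b):
    if not a.grid.matches(b.grid):
        raise GridMismatchError(
            f"incompatible grids: {a.grid.shape} vs {b.grid.shape} "
            "(or differing affines)")


@dataclass
class MaskVolume:
    """Binary 3D region of interest on a grid."""

    grid: GridSpec
    data: np.ndarray = field(repr=False)

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {data.shape} != grid shape {self.grid.shape}")
        self.data = data.astype(bool)

    @classmethod
    def empty(cls, grid: GridSpec) -> "MaskVolume":
        return cls(grid, np.zeros(grid.shape, dtype=bool))

    def count(self) -> int:
        return int(self.data.sum())

    def center_of_mass_world(self) -> np.ndarray:
        if not self.data.any():
            raise ValueError("empty mask has no centre of mass")
        com_ijk = np.array(ndimage.center_of_mass(self.data.astype(float)))
        return self.grid.voxel_to_world(com_ijk)


@dataclass
class ScalarVolume:
    """Real-valued 3D volume (anisotropy, probability) on a grid."""

    grid: GridSpec
    data: np.ndarray = field(repr=False)

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {data.shape} != grid shape {self.grid.shape}")
        self.data = data


# ---------------------------------------------------------------------------
# ROI geometry
# ---------------------------------------------------------------------------

def mirror_sagittal(mask: MaskVolume) -> MaskVolume:
    """Mirror a mask across the sagittal mid-plane (grid left-right axis).

    Voxel (i, j, k) maps to (Nx-1-i, j, k) along the grid's declared
    left-right axis; the grid itself is unchanged.  Total and involutive.
    """
    return MaskVolume(mask.grid, np.flip(mask.data, axis=mask.grid.lr_axis))


def intersect(a: MaskVolume, b: MaskVolume) -> MaskVolume:
    """Voxelwise logical AND of two masks on the same grid."""
    _check_same_grid(a, b)
    return MaskVolume(a.grid, a.data & b.data)


def resample_mask(mask: MaskVolume, target: GridSpec,
                  threshold: float = 0.9) -> MaskVolume:
    """Resample a mask onto another grid, binarising conservatively.

    The mask is trilinearly interpolated as a 0/1 field at the target
    voxel centres, then kept where the interpolated value is >= threshold.
    The default 0.9 keeps only voxels almost fully inside the source mask,
    so resampled masks shrink rather than bleed.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    # voxel(target) -> world -> voxel(source)
    xform = mask.grid.inverse_affine @ target.affine
    idx = np.indices(target.shape, dtype=float).reshape(3, -1)
    src = xform[:3, :3] @ idx + xform[:3, 3:4]
    vals = ndimage.map_coordinates(mask.data.astype(float), src, order=1,
                                   mode="constant", cval=0.0)
    out = (vals >= threshold - 1e-9).reshape(target.shape)
    return MaskVolume(target, out)


def dilate_mm(mask: MaskVolume, distance: float) -> MaskVolume:
    """Dilate a mask by a physical distance (mm, world metric).

    A voxel is included when its centre lies within ``distance`` of some
    input voxel centre; anisotropic voxels are respected via the Euclidean
    distance transform with per-axis sampling.
    """
    if distance < 0:
        raise ValueError("dilation distance must be >= 0")
    if not mask.data.any() or distance == 0:
        return MaskVolume(mask.grid, mask.data.copy())
    edt = ndimage.distance_transform_edt(~mask.data,
                                         sampling=mask.grid.voxel_size)
    return MaskVolume(mask.grid, edt <= distance + 1e-9)


def dilate_to_factor(mask: MaskVolume, factor: float = 1.2) -> MaskVolume:
    """Grow a mask by 1-voxel morphological steps until its voxel count
    reaches ``factor`` times the original; returns the first such iterate.

    Uses a 6-connected structuring element per iteration.
    """
    if not mask.data.any():
        raise ValueError("cannot dilate an empty mask to a volume factor")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    target_count = factor * mask.count()
    data = mask.data.copy()
    struct = ndimage.generate_binary_structure(3, 1)
    while data.sum() < target_count:
        data = ndimage.binary_dilation(data, structure=struct)
    return MaskVolume(mask.grid, data)


def sphere_mask(grid: GridSpec, center, diameter: float = 10.0) -> MaskVolume:
    """Spherical ROI: voxels whose centres lie within diameter/2 (world mm)
    of ``center``.  The 10 mm default is the target-ROI size."""
    center = np.asarray(center, dtype=float)
    vox = grid.world_to_voxel(center)
    if np.any(vox < -0.5) or np.any(vox > np.array(grid.shape) - 0.5):
        raise ValueError(f"sphere centre {center} outside grid bounds")
    radius = diameter / 2.0
    # restrict to a bounding box for speed
    vs = grid.voxel_size
    lo = np.maximum(np.floor(vox - radius / vs - 1).astype(int), 0)
    hi = np.minimum(np.ceil(vox + radius / vs + 2).astype(int),
                    np.array(grid.shape))
    data = np.zeros(grid.shape, dtype=bool)
    if np.any(lo >= hi):
        return MaskVolume(grid, data)
    sub = np.stack(np.meshgrid(*[np.arange(lo[d], hi[d]) for d in range(3)],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    pts = grid.voxel_to_world(sub.astype(float))
    inside = np.linalg.norm(pts - center, axis=1) <= radius + 1e-9
    data[sub[inside, 0], sub[inside, 1], sub[inside, 2]] = True
    return MaskVolume(grid, data)


def mask_volume_cm3(mask: MaskVolume) -> float:
    """Physical mask volume in cm^3 (voxel count x voxel volume)."""
    return mask.count() * mask.grid.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def save_mask(mask: MaskVolume, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def load_mask(path, lr_axis: int = 0) -> MaskVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    grid = GridSpec(tuple(data.shape), img.affine, lr_axis)
    return MaskVolume(grid, data != 0)


def save_scalar(vol: ScalarVolume, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.grid.affine)
    nib.save(img, str(path))


def load_scalar(path, lr_axis: int = 0) -> ScalarVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    grid = GridSpec(tuple(data.shape), img.affine, lr_axis)
    return ScalarVolume(grid, data)
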