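"""Fiber-orientation fields and ODF peak extraction.

An :class:`OrientationField` stores up to three unit fiber directions plus
an anisotropy scalar per voxel — the substrate multi-fiber tracking runs
on.  Directions are axial (sign-ambiguous), as for any diffusion ODF.

:func:`find_odf_peaks` is a simplified extraction of principal directions
from a spherical function sampled on a tessellation: local maxima over the
tessellation's neighbour graph, pruned by a relative-amplitude floor and a
minimum angular separation.  It stands in for full spherical-deconvolution
machinery; the pipeline only ever consumes peaks, from whatever source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .volumes import GridSpec, ScalarVolume

MAX_PEAKS = 3


@dataclass
class OrientationField:
    """Per-voxel fiber directions (<=3 unit vectors) and anisotropy.

    ``peaks`` has shape (*grid.shape, 3, 3): axis -2 indexes the peak slot,
    axis -1 the vector component; unused slots are zero.  ``n_peaks`` is the
    per-voxel peak count and ``anisotropy`` an FA-like scalar in [0, 1].
    """

    grid: GridSpec
    peaks: np.ndarray = field(repr=False)
    n_peaks: np.ndarray = field(repr=False)
    anisotropy: ScalarVolume = field(repr=False)

    def __post_init__(self):
        expected = (*self.grid.shape, MAX_PEAKS, 3)
        if self.peaks.shape != expected:
            raise ValueError(f"peaks shape {self.peaks.shape} != {expected}")
        if self.n_peaks.shape != self.grid.shape:
            raise ValueError("n_peaks shape mismatch")
        self.peaks = np.asarray(self.peaks, dtype=np.float32)
        self.n_peaks = np.asarray(self.n_peaks, dtype=np.uint8)
        self.anisotropy.data = np.clip(self.anisotropy.data, 0.0, 1.0)

    @classmethod
    def empty(cls, grid: GridSpec) -> "OrientationField":
        return cls(grid,
                   np.zeros((*grid.shape, MAX_PEAKS, 3), dtype=np.float32),
                   np.zeros(grid.shape, dtype=np.uint8),
                   ScalarVolume(grid, np.zeros(grid.shape)))

    def add_peak(self, ijk, direction, fa: float) -> None:
        """Append one unit direction at a voxel (up to the 3-peak cap)."""
        i, j, k = ijk
        n = int(self.n_peaks[i, j, k])
        if n >= MAX_PEAKS:
            return
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        self.peaks[i, j, k, n] = d
        self.n_peaks[i, j, k] = n + 1
        self.anisotropy.data[i, j, k] = max(self.anisotropy.data[i, j, k], fa)

    def mirror_sagittal(self) -> "OrientationField":
        """Mirror the whole field across the grid mid-plane: voxel data are
        flipped along the left-right axis and the corresponding vector
        component is negated (axial directions, so the sign is cosmetic)."""
        ax = self.grid.lr_axis
        peaks = np.flip(self.peaks, axis=ax).copy()
        peaks[..., ax] *= -1
        return OrientationField(
            self.grid, peaks, np.flip(self.n_peaks, axis=ax).copy(),
            ScalarVolume(self.grid,
                         np.flip(self.anisotropy.data, axis=ax).copy()))


# ---------------------------------------------------------------------------
# Sampled spherical functions and peak finding
# ---------------------------------------------------------------------------

@dataclass
class SphericalFunction:
    """A non-negative function sampled on a sphere tessellation.

    Values are symmetrised on construction so that f(u) = f(-u), matching
    the antipodal symmetry of diffusion ODFs.
    """

    directions: np.ndarray  # (N, 3) unit vectors
    values: np.ndarray      # (N,)
    neighbors: list = None  # adjacency lists over the tessellation edges

    def __post_init__(self):
        d = np.asarray(self.directions, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3 or len(v) != len(d):
            raise ValueError("directions must be (N,3) with matching values")
        if len(v) == 0 or np.any(v < 0):
            raise ValueError("values must be non-empty and non-negative")
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        # symmetrise: average each value with that of the nearest antipode
        anti = np.argmax(-d @ d.T, axis=1)
        v = 0.5 * (v + v[anti])
        self.directions, self.values = d, v
        if self.neighbors is None:
            self.neighbors = _nearest_neighbor_graph(d)


def icosphere_tessellation(subdivisions: int = 3):
    """Unit-sphere tessellation from a recursively subdivided icosahedron.

    Returns (directions, adjacency lists from the mesh edges).
    """
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(mesh.vertices, dtype=float)
    nbrs = [[] for _ in range(len(verts))]
    for a, b in mesh.edges_unique:
        nbrs[a].append(int(b))
        nbrs[b].append(int(a))
    return verts, nbrs


def _nearest_neighbor_graph(directions: np.ndarray, k: int = 6):
    """Fallback adjacency when no mesh edges are available: k nearest
    vertices by angle."""
    cos = directions @ directions.T
    np.fill_diagonal(cos, -np.inf)
    order = np.argsort(-cos, axis=1)[:, :k]
    return [list(map(int, row)) for row in order]


def canonical_sign(v: np.ndarray) -> np.ndarray:
    """Represent an axial direction with non-negative first nonzero
    component."""
    v = np.asarray(v, dtype=float)
    for c in v:
        if abs(c) > 1e-12:
            return v if c > 0 else -v
    return v


def find_odf_peaks(f: SphericalFunction, min_separation_deg: float = 25.0,
                   relative_threshold: float = 0.25,
                   max_peaks: int = MAX_PEAKS) -> list[np.ndarray]:
    """Extract up to ``max_peaks`` principal directions from a sampled
    spherical function.

    Strict local maxima over the tessellation's neighbour graph are sorted
    by value and greedily retained when at least ``min_separation_deg``
    (axial angle) from every already-retained peak and at least
    ``relative_threshold`` times the global maximum.  Each retained peak is
    refined sub-vertex by a value-weighted mean over its graph
    neighbourhood (sign-aligned), and reported in the +hemisphere sign
    convention.
    """
    vmax = f.values.max()
    if vmax <= 0:
        return []
    is_max = np.array([
        all(f.values[i] > f.values[j] for j in f.neighbors[i])
        for i in range(len(f.values))
    ])
    cand = np.nonzero(is_max)[0]
    cand = cand[np.argsort(-f.values[cand])]
    cos_sep = np.cos(np.deg2rad(min_separation_deg))
    retained: list[np.ndarray] = []
    for i in cand:
        if f.values[i] < relative_threshold * vmax:
            continue
        d = _refine_peak(f, i)
        if any(abs(float(d @ p)) > cos_sep for p in retained):
            continue
        retained.append(canonical_sign(d))
        if len(retained) >= max_peaks:
            break
    return retained


def _refine_peak(f: SphericalFunction, i: int) -> np.ndarray:
    """Sub-vertex refinement: fit a quadratic to the function over the
    gnomonic projection of the vertex's neighbourhood and move to its
    stationary point (falls back to the raw vertex when the fit is not a
    well-conditioned maximum)."""
    v = f.directions[i]
    idx = [i] + list(f.neighbors[i])
    dirs = f.directions[idx].copy()
    flip = dirs @ v < 0
    dirs[flip] *= -1
    e1 = np.cross(v, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(v, [1.0, 0.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v, e1)
    t = dirs @ v
    if np.any(t <= 0.1):
        return v
    proj = dirs / t[:, None]
    x, y = proj @ e1, proj @ e2
    a = np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
    try:
        coef, *_ = np.linalg.lstsq(a, f.values[idx], rcond=None)
    except np.linalg.LinAlgError:
        return v
    _, b, c, d, e, g = coef
    hess = np.array([[2 * d, e], [e, 2 * g]])
    if np.linalg.det(hess) <= 0 or hess[0, 0] >= 0:
        return v
    step = np.linalg.solve(hess, -np.array([b, c]))
    if np.linalg.norm(step) > 0.2:  # beyond the neighbourhood: distrust
        return v
    out = v + step[0] * e1 + step[1] * e2
    return out / np.linalg.norm(out)


# ---------------------------------------------------------------------------
# Serialization: 5D NIfTI (x, y, z, peak, component) + anisotropy NIfTI
# ---------------------------------------------------------------------------

def save_orientation_field(field_: OrientationField, peaks_path,
                           fa_path) -> None:
    img = nib.Nifti1Image(field_.peaks.astype(np.float32),
                          field_.grid.affine)
    nib.save(img, str(peaks_path))
    fa_img = nib.Nifti1Image(field_.anisotropy.data.astype(np.float32),
                             field_.grid.affine)
    nib.save(fa_img, str(fa_path))


def load_orientation_field(peaks_path, fa_path,
                           lr_axis: int = 0) -> OrientationField:
    img = nib.load(str(peaks_path))
    peaks = np.asanyarray(img.dataobj).astype(np.float32)
    if peaks.ndim != 5 or peaks.shape[3:] != (MAX_PEAKS, 3):
        raise ValueError("expected a 5D (x,y,z,peak,component) peaks volume")
    grid = GridSpec(tuple(peaks.shape[:3]), img.affine, lr_axis)
    norms = np.linalg.norm(peaks, axis=-1)
    n_peaks = (norms > 0.5).sum(axis=-1).astype(np.uint8)
    fa_img = nib.load(str(fa_path))
    fa = ScalarVolume(grid, np.asanyarray(fa_img.dataobj).astype(float))
    return OrientationField(grid, peaks, n_peaks, fa)
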