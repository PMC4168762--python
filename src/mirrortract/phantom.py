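"""Synthetic two-hemisphere phantoms with controlled lesion effects.

The generator emulates the study design the pipeline is built for: a
mirror-symmetric brain containing parametric white-matter bundles, with a
lesion on one side that either *displaces* the bundle (meningioma-like
mass effect: geometry pushed, fibers intact) or *infiltrates* it
(glioma-like: a stated fraction of fibers deleted in place, geometry of
the survivors unchanged).

A bundle is a tube of "fiber chains" around a parametric centerline.
Each voxel of the tube carries one unit peak tangent to the (possibly
tapered) tube flow and belongs to exactly one chain, identified by its
offset in a parallel-transported cross-section frame.  Chains are the
granularity at which infiltration deletes: removing a whole chain thins
the bundle without truncating the survivors, which is what produces the
graded tract-count reductions the pipeline measures.  Bundle ends taper
into narrow funnels so that streamline terminal points converge onto a
compact cortical-like projection site that a 10 mm target sphere can
capture.

All randomness flows through one seeded generator; identical seeds give
identical cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield, replace

import numpy as np
from scipy.spatial import cKDTree

from .peaks import OrientationField
from .volumes import GridSpec, MaskVolume, ScalarVolume, sphere_mask

_CENTERLINE_DS = 0.25  # mm, centerline sampling step
_CHAIN_PITCH = 1.0     # mm, fiber-chain lattice pitch in the reference frame


@dataclass(frozen=True)
class BundleSpec:
    """Parametric bundle: centerline control points (world mm), tube
    radius, interior anisotropy and optional funnel tapers at the ends."""

    centerline: np.ndarray          # (M, 3) control points, mm
    radius: float                   # mm, full tube radius
    fa_inside: float = 0.8
    fibers_fraction: float = 1.0    # fraction of tube voxels carrying a peak
    taper_start_mm: float = 0.0     # funnel length at the first end
    taper_end_mm: float = 0.0       # funnel length at the last end
    tip_radius: float = 1.0         # funnel tip radius, mm

    def __post_init__(self):
        object.__setattr__(self, "centerline",
                           np.atleast_2d(np.asarray(self.centerline, float)))
        if self.radius <= 0:
            raise ValueError("bundle radius must be > 0")
        if not (0 < self.fibers_fraction <= 1):
            raise ValueError("fibers_fraction must be in (0, 1]")
        if not (0.2 < self.fa_inside <= 1.0):
            raise ValueError("fa_inside must exceed the 0.2 tracking floor")


@dataclass(frozen=True)
class LesionSpec:
    """Lesion model: a sphere that displaces or infiltrates bundles.

    magnitude is millimetres of radial push (displace) or the fiber
    removal fraction in [0, 1] (infiltrate).
    """

    center: tuple
    radius: float
    mode: str  # {"displace", "infiltrate"}
    magnitude: float

    def __post_init__(self):
        if self.mode not in ("displace", "infiltrate"):
            raise ValueError(f"unknown lesion mode {self.mode!r}")
        if self.radius <= 0:
            raise ValueError("lesion radius must be > 0")
        if self.mode == "infiltrate" and not (0 <= self.magnitude <= 1):
            raise ValueError("infiltration removal fraction must be in [0,1]")
        if self.mode == "displace" and self.magnitude < 0:
            raise ValueError("displacement magnitude must be >= 0")


@dataclass
class BundleField:
    """Generative record of one synthesised bundle on a grid.

    voxels/peaks/chain arrays are aligned; ``resolvable`` marks voxels in
    the full-radius section where a chain is at least one voxel wide (the
    section where chain deletion is representable on the grid).
    """

    grid: GridSpec
    spec: BundleSpec
    voxels: np.ndarray      # (K, 3) int indices
    peak_dirs: np.ndarray   # (K, 3) unit tangents
    chain_ids: np.ndarray   # (K,) int
    resolvable: np.ndarray  # (K,) bool
    samples: np.ndarray     # (S, 3) densified centerline

    def chains(self) -> np.ndarray:
        return np.unique(self.chain_ids)

    def chains_crossing(self, mask: MaskVolume) -> np.ndarray:
        i, j, k = self.voxels.T
        inside = mask.data[i, j, k]
        return np.unique(self.chain_ids[inside])


@dataclass
class PhantomCase:
    """One synthetic case: orientation field, masks and ground truth."""

    field: OrientationField
    brain_mask: MaskVolume
    wm_mask: MaskVolume
    lesion_mask: MaskVolume
    truth: dict
    rng_seed: int

    def __post_init__(self):
        if np.any(self.lesion_mask.data & ~self.brain_mask.data):
            raise ValueError("lesion mask must lie inside the brain mask")
        if np.any(self.wm_mask.data & ~self.brain_mask.data):
            raise ValueError("WM mask must lie inside the brain mask")


# ---------------------------------------------------------------------------
# Bundle synthesis
# ---------------------------------------------------------------------------

def _densify(control: np.ndarray, ds: float = _CENTERLINE_DS):
    """Resample a polyline at uniform arc length; returns (samples, arclen)."""
    seg = np.diff(control, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    total = seglen.sum()
    if total <= 0:
        raise ValueError("degenerate centerline")
    t = np.concatenate([[0.0], np.cumsum(seglen)])
    s = np.arange(0.0, total + ds / 2, ds)
    pts = np.column_stack([np.interp(s, t, control[:, d]) for d in range(3)])
    return pts, s


def _transport_frames(samples: np.ndarray):
    """Unit tangents plus a parallel-transported orthonormal cross-section
    frame (n1, n2) along the sampled centerline."""
    tang = np.gradient(samples, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    n1 = np.zeros_like(tang)
    seedv = np.array([0.0, 0.0, 1.0])
    if abs(tang[0] @ seedv) > 0.9:
        seedv = np.array([1.0, 0.0, 0.0])
    v = seedv - (seedv @ tang[0]) * tang[0]
    n1[0] = v / np.linalg.norm(v)
    for i in range(1, len(tang)):
        v = n1[i - 1] - (n1[i - 1] @ tang[i]) * tang[i]
        n1[i] = v / np.linalg.norm(v)
    n2 = np.cross(tang, n1)
    return tang, n1, n2


def _radius_profile(spec: BundleSpec, s: np.ndarray) -> np.ndarray:
    """Tube radius along arc length with linear funnel tapers."""
    r = np.full_like(s, spec.radius)
    total = s[-1]
    if spec.taper_start_mm > 0:
        m = s < spec.taper_start_mm
        r[m] = spec.tip_radius + (spec.radius - spec.tip_radius) * (
            s[m] / spec.taper_start_mm)
    if spec.taper_end_mm > 0:
        m = s > total - spec.taper_end_mm
        r[m] = np.minimum(r[m], spec.tip_radius
                          + (spec.radius - spec.tip_radius)
                          * ((total - s[m]) / spec.taper_end_mm))
    return r


def synth_bundle(grid: GridSpec, spec: BundleSpec,
                 rng: np.random.Generator | None = None) -> BundleField:
    """Rasterise one bundle onto the grid.

    Every voxel whose centre lies within the local tube radius of the
    centerline receives a unit peak tangent to the warped tube flow (so
    funnel sections point inward toward the tip) and is assigned to the
    fiber chain of its normalised cross-section offset.
    """
    samples, s = _densify(spec.centerline)
    tang, n1, n2 = _transport_frames(samples)
    rprof = _radius_profile(spec, s)
    tree = cKDTree(samples)

    lo = np.floor(grid.world_to_voxel(samples.min(0) - spec.radius - 1))
    hi = np.ceil(grid.world_to_voxel(samples.max(0) + spec.radius + 1)) + 1
    lo = np.maximum(lo.astype(int), 0)
    hi = np.minimum(hi.astype(int), np.array(grid.shape))
    if np.any(lo >= hi):
        raise ValueError("bundle centerline exits the grid")
    sub = np.stack(np.meshgrid(*[np.arange(lo[d], hi[d]) for d in range(3)],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    centers = grid.voxel_to_world(sub.astype(float))
    _, idx = tree.query(centers, workers=-1)
    off = centers - samples[idx]
    along = np.einsum("ij,ij->i", off, tang[idx])
    u = np.einsum("ij,ij->i", off, n1[idx])
    w = np.einsum("ij,ij->i", off, n2[idx])
    rad = np.sqrt(u * u + w * w)
    # perpendicular distance within the local radius, and no overhang past
    # the flat end caps (interior voxels project within half a sample step)
    inside = (rad <= rprof[idx] + 1e-9) & (np.abs(along)
                                           <= 0.75 * _CENTERLINE_DS)
    sub, idx, u, w = sub[inside], idx[inside], u[inside], w[inside]

    # normalised offsets in the reference (full-radius) cross-section
    scale = spec.radius / rprof[idx]
    un, wn = u * scale, w * scale

    # tangent of the warped-offset curve P(t) = C(t) + (un n1 + wn n2) r(t)/R
    nsamp = len(samples)
    d = max(int(round(1.0 / _CENTERLINE_DS)), 1)  # ~1 mm finite difference
    ia = np.maximum(idx - d, 0)
    ib = np.minimum(idx + d, nsamp - 1)
    ratio = 1.0 / spec.radius
    pa = samples[ia] + (un[:, None] * n1[ia] + wn[:, None] * n2[ia]) \
        * (rprof[ia] * ratio)[:, None]
    pb = samples[ib] + (un[:, None] * n1[ib] + wn[:, None] * n2[ib]) \
        * (rprof[ib] * ratio)[:, None]
    dirs = pb - pa
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    iu = np.round(un / _CHAIN_PITCH).astype(np.int64)
    iw = np.round(wn / _CHAIN_PITCH).astype(np.int64)
    span = int(np.ceil(spec.radius / _CHAIN_PITCH)) + 2
    chain_ids = (iu + span) * (2 * span + 1) + (iw + span)
    resolvable = rprof[idx] >= spec.radius - 1e-9

    if spec.fibers_fraction < 1.0:
        if rng is None:
            raise ValueError("fibers_fraction < 1 requires an rng")
        keep = rng.random(len(sub)) < spec.fibers_fraction
        sub, dirs = sub[keep], dirs[keep]
        chain_ids, resolvable = chain_ids[keep], resolvable[keep]

    return BundleField(grid, spec, sub, dirs, chain_ids, resolvable, samples)


def paint_bundles(grid: GridSpec, bundles: list[BundleField],
                  skip_chains: dict | None = None,
                  low_fa_voxels: list | None = None,
                  rng: np.random.Generator | None = None) -> OrientationField:
    """Compose bundle contributions into one OrientationField.

    skip_chains maps bundle index -> set of chain ids to omit (deleted
    fibers); their voxels are collected into low_fa_voxels if given.
    """
    field = OrientationField.empty(grid)
    for bi, b in enumerate(bundles):
        drop = skip_chains.get(bi, frozenset()) if skip_chains else frozenset()
        for v, d, cid, res in zip(b.voxels, b.peak_dirs, b.chain_ids,
                                  b.resolvable):
            # chain deletion acts where the chain is grid-resolvable
            # (full-radius section); funnel voxels are shared by many
            # chains and are never deleted
            if cid in drop and res:
                if low_fa_voxels is not None:
                    low_fa_voxels.append(tuple(v))
                continue
            field.add_peak(tuple(v), d, b.spec.fa_inside)
    return field


# ---------------------------------------------------------------------------
# Lesion operators
# ---------------------------------------------------------------------------

_PUSH_DECAY_RADII = 3.0  # displacement reaches zero at this multiple of
#                          the lesion radius; the wide support keeps the
#                          bent tube's curvature radius well above the
#                          bundle radius so displaced fibers stay trackable


def _push(points: np.ndarray, lesion: LesionSpec) -> np.ndarray:
    """Smooth radial push: magnitude m at the lesion centre decaying with a
    C1 quartic profile to zero at ``_PUSH_DECAY_RADII`` lesion radii.

    The map d -> d + m w(d) must be strictly increasing for the push to be
    invertible; max |w'| = 1.54 / D bounds the admissible magnitude.
    """
    c = np.asarray(lesion.center, dtype=float)
    big = _PUSH_DECAY_RADII * lesion.radius
    if lesion.magnitude >= big / 1.54:
        raise ValueError(
            f"push magnitude {lesion.magnitude} mm too large relative to "
            f"the lesion radius (non-invertible beyond {big / 1.54:.1f} mm)")
    delta = points - c
    d = np.linalg.norm(delta, axis=1)
    w = np.zeros_like(d)
    m = d < big
    w[m] = (1.0 - (d[m] / big) ** 2) ** 2
    safe = np.where(d > 1e-9, d, 1.0)
    return points + lesion.magnitude * w[:, None] * delta / safe[:, None]


def lesion_displace(bundles: list[BundleField],
                    lesion: LesionSpec) -> list[BundleField]:
    """Displace bundle geometry around the lesion: each bundle's densified
    centerline is pushed radially and the tube re-synthesised around it,
    which re-orients the tangent peaks exactly."""
    if lesion.mode != "displace":
        raise ValueError("lesion mode must be 'displace'")
    out = []
    for b in bundles:
        pushed = _push(b.samples, lesion)
        spec = replace(b.spec, centerline=pushed)
        out.append(synth_bundle(b.grid, spec))
    return out


def lesion_infiltrate(bundles: list[BundleField], lesion_mask: MaskVolume,
                      fraction: float,
                      rng: np.random.Generator) -> dict[int, set]:
    """Choose fiber chains to delete: each chain crossing the lesion is
    independently removed with probability ``fraction``.  Returns the
    per-bundle sets of deleted chain ids (geometry of survivors is left
    untouched)."""
    if not (0 <= fraction <= 1):
        raise ValueError("removal fraction must be in [0, 1]")
    deleted: dict[int, set] = {}
    for bi, b in enumerate(bundles):
        crossing = b.chains_crossing(lesion_mask)
        kill = crossing[rng.random(len(crossing)) < fraction]
        deleted[bi] = set(int(c) for c in kill)
    return deleted


# ---------------------------------------------------------------------------
# Whole-case assembly
# ---------------------------------------------------------------------------

def _merge_mirror(affected: OrientationField) -> OrientationField:
    """Union of an affected-hemisphere field with its sagittal mirror; the
    two supports must be disjoint (bundles confined to one hemisphere)."""
    mirrored = affected.mirror_sagittal()
    both = (affected.n_peaks > 0) & (mirrored.n_peaks > 0)
    if both.any():
        raise ValueError("bundles must be confined to one hemisphere")
    out = OrientationField.empty(affected.grid)
    for src in (affected, mirrored):
        sel = src.n_peaks > 0
        out.peaks[sel] = src.peaks[sel]
        out.n_peaks[sel] = src.n_peaks[sel]
        out.anisotropy.data[sel] = src.anisotropy.data[sel]
    return out


def make_symmetric_case(grid: GridSpec, bundles: list[BundleSpec],
                        lesion: LesionSpec, rng_seed: int) -> PhantomCase:
    """Build a mirror-symmetric two-hemisphere case and apply the lesion on
    the affected side only.

    Bundles are specified (and built) in the affected hemisphere — the one
    containing the lesion centre — then mirrored exactly into the other
    hemisphere, so the pre-lesion left/right fields are mirror images.
    """
    rng = np.random.default_rng(rng_seed)
    ax = grid.lr_axis
    mid_index = (grid.shape[ax] - 1) / 2.0
    lesion_center_vox = grid.world_to_voxel(np.asarray(lesion.center, float))
    side = lesion_center_vox[ax] - mid_index
    if abs(side) < 0.5:
        raise ValueError("lesion centred on the sagittal mid-plane")

    lesion_mask = sphere_mask(grid, lesion.center, 2.0 * lesion.radius)
    built = [synth_bundle(grid, spec, rng) for spec in bundles]
    for b in built:
        vside = b.voxels[:, ax] - mid_index
        if np.any(np.sign(vside) != np.sign(side)):
            raise ValueError("all bundles must lie in the lesion hemisphere")

    low_fa: list[tuple] = []
    if lesion.mode == "infiltrate":
        deleted = lesion_infiltrate(built, lesion_mask, lesion.magnitude, rng)
        affected = paint_bundles(grid, built, skip_chains=deleted,
                                 low_fa_voxels=low_fa)
        lesioned_chains = {bi: len(b.chains()) - len(deleted[bi])
                           for bi, b in enumerate(built)}
    else:
        displaced = lesion_displace(built, lesion)
        deleted = {}
        affected = paint_bundles(grid, displaced)
        lesioned_chains = {bi: len(b.chains())
                           for bi, b in enumerate(displaced)}

    # the mirrored (healthy) copy is taken before any lesion edits touch
    # the affected side, so symmetry of the pre-lesion field is exact
    healthy_only = paint_bundles(grid, built)
    field = _merge_mirror(healthy_only)

    # overwrite the affected hemisphere with the lesioned version
    idx = np.arange(grid.shape[ax])
    affected_sel = (idx - mid_index) * np.sign(side) > 0
    slicer = [slice(None)] * 3
    slicer[ax] = affected_sel
    slicer = tuple(slicer)
    field.peaks[slicer] = affected.peaks[slicer]
    field.n_peaks[slicer] = affected.n_peaks[slicer]
    field.anisotropy.data[slicer] = affected.anisotropy.data[slicer]

    # tumor mass / destroyed tissue: sub-threshold anisotropy
    if lesion.mode == "infiltrate":
        for v in low_fa:
            field.anisotropy.data[v] = float(rng.uniform(0.05, 0.18))
    else:
        core = lesion_mask.data
        field.anisotropy.data[core] = 0.0
        field.n_peaks[core] = 0
        field.peaks[core] = 0.0

    brain = np.zeros(grid.shape, dtype=bool)
    brain[2:-2, 2:-2, 2:-2] = True
    brain_mask = MaskVolume(grid, brain)
    wm_mask = MaskVolume(grid, field.n_peaks > 0)

    truth = {
        "lesion": {"center": list(map(float, lesion.center)),
                   "radius": lesion.radius, "mode": lesion.mode,
                   "magnitude": lesion.magnitude},
        "healthy_chains": {bi: int(len(b.chains()))
                           for bi, b in enumerate(built)},
        "lesioned_chains": {bi: int(n) for bi, n in lesioned_chains.items()},
        "deleted_chains": {bi: sorted(c) for bi, c in deleted.items()},
        "rng_seed": int(rng_seed),
    }
    return PhantomCase(field, brain_mask, wm_mask, lesion_mask, truth,
                       int(rng_seed))


# ---------------------------------------------------------------------------
# Default study-condition cases (desk scale, 64^3 at 1 mm isotropic)
# ---------------------------------------------------------------------------

def default_grid() -> GridSpec:
    return GridSpec.create((64, 64, 64), (1.0, 1.0, 1.0))


def default_infiltration_case(fraction: float, rng_seed: int) -> PhantomCase:
    """Glioma-like case: a thick straight bundle ending inside the lesion
    (seed-station geometry) and funnelling to a distal projection site; a
    stated fraction of its fiber chains is deleted in place."""
    grid = default_grid()
    spec = BundleSpec(centerline=[(16.0, 12.0, 32.0), (16.0, 58.0, 32.0)],
                      radius=9.0, fa_inside=0.8,
                      taper_end_mm=18.0, tip_radius=1.0)
    lesion = LesionSpec(center=(16.0, 14.0, 32.0), radius=11.0,
                        mode="infiltrate", magnitude=fraction)
    return make_symmetric_case(grid, [spec], lesion, rng_seed)


def default_displacement_case(magnitude: float = 8.0,
                              rng_seed: int = 0) -> PhantomCase:
    """Meningioma-like case: a slender mid-tract bundle pushed around a
    zero-anisotropy tumor core; fibers intact, geometry deviated."""
    grid = default_grid()
    spec = BundleSpec(centerline=[(16.0, 6.0, 32.0), (16.0, 58.0, 32.0)],
                      radius=3.0, fa_inside=0.8,
                      taper_start_mm=10.0, taper_end_mm=10.0, tip_radius=1.0)
    lesion = LesionSpec(center=(13.0, 32.0, 32.0), radius=5.0,
                        mode="displace", magnitude=magnitude)
    return make_symmetric_case(grid, [spec], lesion, rng_seed)
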