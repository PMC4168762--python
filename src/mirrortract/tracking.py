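"""Deterministic and probabilistic multi-fiber streamline tracking.

The propagator is FACT-style: at each step the peak in the *current voxel*
with the largest absolute dot product against the incoming direction is
followed (sign chosen to keep forward motion), so fiber crossings are
traversed rather than averaged away.  Stopping rules: anisotropy below
0.2, a turn of more than 60 degrees across a voxel, exit from the brain
mask, or a maximum length.  Seeding launches one streamline per
(voxel, peak) pair, propagated in both directions from the seed and
concatenated.

The probabilistic variant replaces the selected peak by a draw from an
axial von Mises-Fisher-like distribution with concentration ``kappa``
around it; everything else is identical.  Connection-probability images
count, per voxel, the fraction of streamlines that enter the voxel.

The inner loops are numba-compiled; deterministic tracking is
bit-reproducible and probabilistic tracking is seed-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from numba import njit

from .peaks import OrientationField
from .volumes import GridSpec, MaskVolume, ScalarVolume, _check_same_grid

REASONS = {0: "none", 1: "low_anisotropy", 2: "sharp_turn",
           3: "out_of_brain", 4: "max_length"}


@dataclass
class TrackingParams:
    """Streamline propagation parameters.

    step_mm defaults to half the smallest voxel dimension.  min_length_mm
    discards stubs; the method targets long- and medium-range connectivity.
    """

    step_mm: float | None = None
    max_turn_deg: float = 60.0
    fa_min: float = 0.2
    min_length_mm: float = 10.0
    max_length_mm: float = 200.0
    kappa: float = 80.0  # probabilistic only
    iterations: int = 1000  # probabilistic only

    def resolve_step(self, grid: GridSpec) -> float:
        return self.step_mm if self.step_mm is not None \
            else 0.5 * float(grid.voxel_size.min())

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("step_mm", "max_turn_deg", "fa_min", "min_length_mm",
                 "max_length_mm", "kappa", "iterations")}


@dataclass
class Streamline:
    points: np.ndarray  # (n, 3) world mm, ordered
    seed_index: tuple
    termination_reasons: tuple  # (reason at points[0], reason at points[-1])

    def length_mm(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0),
                                    axis=1).sum())


@dataclass
class Tractogram:
    streamlines: list
    params: dict
    provenance: dict = dfield(default_factory=dict)

    def __len__(self):
        return len(self.streamlines)


def voxel_of(grid: GridSpec, points: np.ndarray) -> np.ndarray:
    """Nearest-voxel index of world points (round-half-up, matching the
    tracker kernel so audits and pruning agree with propagation)."""
    v = grid.world_to_voxel(np.atleast_2d(points))
    return np.floor(v + 0.5).astype(np.int64)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=False)
def _sample_axial(mux, muy, muz, kappa):
    """Draw a unit vector from a vMF-like axial distribution about mu."""
    u = np.random.random()
    if u < 1e-12:
        u = 1e-12
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    # random tangent direction orthogonal to mu
    while True:
        gx = np.random.normal()
        gy = np.random.normal()
        gz = np.random.normal()
        d = gx * mux + gy * muy + gz * muz
        tx = gx - d * mux
        ty = gy - d * muy
        tz = gz - d * muz
        tn = np.sqrt(tx * tx + ty * ty + tz * tz)
        if tn > 1e-8:
            break
    s = np.sqrt(max(0.0, 1.0 - w * w)) / tn
    return w * mux + s * tx, w * muy + s * ty, w * muz + s * tz


@njit(cache=True)
def _track_half(peaks, npeaks, fa, brain, inv, seeds, dirs, step,
                cos_turn, fa_min, max_steps, kappa, pts_out, npts_out,
                reason_out):
    """Propagate every seed along its initial direction; one direction only.

    pts_out: (N, max_steps+1, 3) float32; npts_out, reason_out: (N,).
    """
    nx, ny, nz = npeaks.shape
    n = seeds.shape[0]
    for s in range(n):
        px, py, pz = seeds[s, 0], seeds[s, 1], seeds[s, 2]
        dx, dy, dz = dirs[s, 0], dirs[s, 1], dirs[s, 2]
        pts_out[s, 0, 0] = px
        pts_out[s, 0, 1] = py
        pts_out[s, 0, 2] = pz
        cnt = 1
        reason = 4
        for _ in range(max_steps):
            fi = inv[0, 0] * px + inv[0, 1] * py + inv[0, 2] * pz + inv[0, 3]
            fj = inv[1, 0] * px + inv[1, 1] * py + inv[1, 2] * pz + inv[1, 3]
            fk = inv[2, 0] * px + inv[2, 1] * py + inv[2, 2] * pz + inv[2, 3]
            i = int(np.floor(fi + 0.5))
            j = int(np.floor(fj + 0.5))
            k = int(np.floor(fk + 0.5))
            if i < 0 or j < 0 or k < 0 or i >= nx or j >= ny or k >= nz \
                    or brain[i, j, k] == 0:
                reason = 3
                break
            if fa[i, j, k] < fa_min:
                reason = 1
                break
            npk = int(npeaks[i, j, k])
            if npk == 0:
                reason = 1
                break
            best = 0
            bestdot = -2.0
            sign = 1.0
            for q in range(npk):
                dot = (dx * peaks[i, j, k, q, 0]
                       + dy * peaks[i, j, k, q, 1]
                       + dz * peaks[i, j, k, q, 2])
                ad = abs(dot)
                if ad > bestdot:
                    bestdot = ad
                    best = q
                    sign = 1.0 if dot >= 0.0 else -1.0
            ndx = sign * peaks[i, j, k, best, 0]
            ndy = sign * peaks[i, j, k, best, 1]
            ndz = sign * peaks[i, j, k, best, 2]
            if kappa > 0.0:
                ndx, ndy, ndz = _sample_axial(ndx, ndy, ndz, kappa)
                if ndx * dx + ndy * dy + ndz * dz < 0.0:
                    ndx, ndy, ndz = -ndx, -ndy, -ndz
            if ndx * dx + ndy * dy + ndz * dz < cos_turn:
                reason = 2
                break
            px += step * ndx
            py += step * ndy
            pz += step * ndz
            dx, dy, dz = ndx, ndy, ndz
            pts_out[s, cnt, 0] = px
            pts_out[s, cnt, 1] = py
            pts_out[s, cnt, 2] = pz
            cnt += 1
        npts_out[s] = cnt
        reason_out[s] = reason


@njit(cache=True)
def _track_visits(peaks, npeaks, fa, brain, inv, seeds, dirs, step,
                  cos_turn, fa_min, max_steps, kappa,
                  roi_a1, roi_b1, roi_a2, roi_b2,
                  counts1, counts2, stamp1, stamp2, retained):
    """Bidirectional propagation that accumulates connection counts.

    For each launch, both half-tracks are run and the visited voxels (flat
    indices) buffered.  If the two terminal voxels land one in roi_a and
    one in roi_b (order-agnostic) the streamline is retained for that ROI
    pair and each *distinct* visited voxel's count is incremented.  Two ROI
    pairs are evaluated in the same pass (one per hemisphere).
    """
    nx, ny, nz = npeaks.shape
    n = seeds.shape[0]
    buf = np.empty(2 * max_steps + 2, dtype=np.int64)
    for s in range(n):
        nbuf = 0
        end_vox = np.empty(2, dtype=np.int64)
        for half in range(2):
            sgn = 1.0 if half == 0 else -1.0
            px, py, pz = seeds[s, 0], seeds[s, 1], seeds[s, 2]
            dx = sgn * dirs[s, 0]
            dy = sgn * dirs[s, 1]
            dz = sgn * dirs[s, 2]
            last_flat = -1
            for _ in range(max_steps):
                fi = (inv[0, 0] * px + inv[0, 1] * py + inv[0, 2] * pz
                      + inv[0, 3])
                fj = (inv[1, 0] * px + inv[1, 1] * py + inv[1, 2] * pz
                      + inv[1, 3])
                fk = (inv[2, 0] * px + inv[2, 1] * py + inv[2, 2] * pz
                      + inv[2, 3])
                i = int(np.floor(fi + 0.5))
                j = int(np.floor(fj + 0.5))
                k = int(np.floor(fk + 0.5))
                if i < 0 or j < 0 or k < 0 or i >= nx or j >= ny or k >= nz \
                        or brain[i, j, k] == 0:
                    break
                flat = (i * ny + j) * nz + k
                if flat != last_flat:
                    buf[nbuf] = flat
                    nbuf += 1
                    last_flat = flat
                if fa[i, j, k] < fa_min or npeaks[i, j, k] == 0:
                    break
                npk = int(npeaks[i, j, k])
                best = 0
                bestdot = -2.0
                sign = 1.0
                for q in range(npk):
                    dot = (dx * peaks[i, j, k, q, 0]
                           + dy * peaks[i, j, k, q, 1]
                           + dz * peaks[i, j, k, q, 2])
                    ad = abs(dot)
                    if ad > bestdot:
                        bestdot = ad
                        best = q
                        sign = 1.0 if dot >= 0.0 else -1.0
                ndx = sign * peaks[i, j, k, best, 0]
                ndy = sign * peaks[i, j, k, best, 1]
                ndz = sign * peaks[i, j, k, best, 2]
                if kappa > 0.0:
                    ndx, ndy, ndz = _sample_axial(ndx, ndy, ndz, kappa)
                    if ndx * dx + ndy * dy + ndz * dz < 0.0:
                        ndx, ndy, ndz = -ndx, -ndy, -ndz
                if ndx * dx + ndy * dy + ndz * dz < cos_turn:
                    break
                px += step * ndx
                py += step * ndy
                pz += step * ndz
                dx, dy, dz = ndx, ndy, ndz
            # terminal voxel of this half (clamped flat index of last pos)
            fi = inv[0, 0] * px + inv[0, 1] * py + inv[0, 2] * pz + inv[0, 3]
            fj = inv[1, 0] * px + inv[1, 1] * py + inv[1, 2] * pz + inv[1, 3]
            fk = inv[2, 0] * px + inv[2, 1] * py + inv[2, 2] * pz + inv[2, 3]
            i = min(max(int(np.floor(fi + 0.5)), 0), nx - 1)
            j = min(max(int(np.floor(fj + 0.5)), 0), ny - 1)
            k = min(max(int(np.floor(fk + 0.5)), 0), nz - 1)
            end_vox[half] = (i * ny + j) * nz + k
        ea, eb = end_vox[0], end_vox[1]
        for pair in range(2):
            if pair == 0:
                ok = ((roi_a1[ea] and roi_b1[eb])
                      or (roi_a1[eb] and roi_b1[ea]))
            else:
                ok = ((roi_a2[ea] and roi_b2[eb])
                      or (roi_a2[eb] and roi_b2[ea]))
            if not ok:
                continue
            retained[pair] += 1
            for b in range(nbuf):
                v = buf[b]
                if pair == 0:
                    if stamp1[v] != s:
                        stamp1[v] = s
                        counts1[v] += 1
                else:
                    if stamp2[v] != s:
                        stamp2[v] = s
                        counts2[v] += 1


def _field_arrays(field: OrientationField, brain: MaskVolume):
    return (np.ascontiguousarray(field.peaks, dtype=np.float32),
            np.ascontiguousarray(field.n_peaks, dtype=np.int64),
            np.ascontiguousarray(field.anisotropy.data, dtype=np.float32),
            np.ascontiguousarray(brain.data, dtype=np.uint8),
            np.ascontiguousarray(field.grid.inverse_affine[:3],
                                 dtype=np.float64))


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def _launch(field, brain, seeds, dirs, seed_indices, params,
            kappa=0.0, rng_seed=None):
    """Run bidirectional tracking for many (seed, direction) launches and
    return stitched Streamlines (no length filtering)."""
    step = params.resolve_step(field.grid)
    max_steps = int(np.ceil(params.max_length_mm / step / 2.0))
    cos_turn = float(np.cos(np.deg2rad(params.max_turn_deg)))
    pk, npk, fa, br, inv = _field_arrays(field, brain)
    n = len(seeds)
    seeds = np.ascontiguousarray(seeds, dtype=np.float64)
    dirs = np.ascontiguousarray(dirs, dtype=np.float64)
    halves = []
    for h, dsign in enumerate((1.0, -1.0)):
        pts = np.zeros((n, max_steps + 1, 3), dtype=np.float32)
        npts = np.zeros(n, dtype=np.int64)
        reas = np.zeros(n, dtype=np.int64)
        if kappa > 0.0 and rng_seed is not None:
            _seed_numba_rng(int(rng_seed) + h)
        _track_half(pk, npk, fa, br, inv, seeds, dsign * dirs, step,
                    cos_turn, params.fa_min, max_steps, float(kappa),
                    pts, npts, reas)
        halves.append((pts, npts, reas))
    out = []
    (fp, fn, fr), (bp, bn, br_) = halves
    for s in range(n):
        fwd = fp[s, :fn[s]].astype(np.float64)
        bwd = bp[s, :bn[s]].astype(np.float64)
        points = np.vstack([bwd[:0:-1], fwd])  # backward reversed + forward
        out.append(Streamline(points, tuple(seed_indices[s]),
                              (REASONS[int(br_[s])], REASONS[int(fr[s])])))
    return out


@njit(cache=True)
def _seed_numba_rng(seed):
    np.random.seed(seed)


def propagate(field: OrientationField, brain: MaskVolume, seed_point,
              initial_dir, params: TrackingParams | None = None) -> Streamline:
    """Propagate a single streamline bidirectionally from a world point."""
    params = params or TrackingParams()
    seed_point = np.asarray(seed_point, dtype=float)
    d = np.asarray(initial_dir, dtype=float)
    d = d / np.linalg.norm(d)
    ijk = tuple(voxel_of(field.grid, seed_point)[0])
    sls = _launch(field, brain, seed_point[None], d[None], [ijk], params)
    return sls[0]


def _seed_launches(field: OrientationField, mask: MaskVolume):
    """(voxel, peak) launch list: voxel-centre seeds, one per peak."""
    idx = np.argwhere(mask.data & (field.n_peaks > 0))
    seeds, dirs, seed_indices = [], [], []
    for ijk in idx:
        i, j, k = map(int, ijk)
        c = field.grid.voxel_to_world(np.array([i, j, k], dtype=float))
        for q in range(int(field.n_peaks[i, j, k])):
            seeds.append(c)
            dirs.append(field.peaks[i, j, k, q].astype(float))
            seed_indices.append((i, j, k))
    if not seeds:
        return (np.zeros((0, 3)), np.zeros((0, 3)), [])
    return np.array(seeds), np.array(dirs), seed_indices


def track_from_mask(field: OrientationField, brain: MaskVolume,
                    seed_mask: MaskVolume,
                    params: TrackingParams | None = None) -> Tractogram:
    """Deterministic tracking seeded from every (voxel, peak) pair of a
    mask; streamlines shorter than min_length are discarded (count logged
    in provenance)."""
    params = params or TrackingParams()
    _check_same_grid(field, seed_mask)
    seeds, dirs, seed_indices = _seed_launches(field, seed_mask)
    prov = {"seed_mask_count": seed_mask.count(), "mode": "deterministic",
            "launched": len(seeds)}
    if len(seeds) == 0:
        return Tractogram([], params.to_dict(), prov | {"discarded_short": 0})
    sls = _launch(field, brain, seeds, dirs, seed_indices, params)
    kept = [s for s in sls if s.length_mm() >= params.min_length_mm]
    prov["discarded_short"] = len(sls) - len(kept)
    return Tractogram(kept, params.to_dict(), prov)


def track_whole_brain(field: OrientationField, brain: MaskVolume,
                      params: TrackingParams | None = None) -> Tractogram:
    """Deterministic tracking seeded from every brain voxel with >=1 peak."""
    t = track_from_mask(field, brain, brain, params)
    t.provenance["mode"] = "deterministic-whole-brain"
    return t


def prune_by_endpoints(t: Tractogram, roi_a: MaskVolume,
                       roi_b: MaskVolume) -> Tractogram:
    """Keep streamlines with one terminal point's voxel in roi_a and the
    other's in roi_b (order-agnostic).  Idempotent."""
    _check_same_grid(roi_a, roi_b)
    grid = roi_a.grid
    kept = []
    for s in t.streamlines:
        if len(s.points) < 2:
            continue
        va, vb = voxel_of(grid, s.points[[0, -1]])
        a_in = _in_mask(roi_a, va)
        b_in = _in_mask(roi_b, vb)
        if (a_in and b_in) or (_in_mask(roi_a, vb) and _in_mask(roi_b, va)):
            kept.append(s)
    return Tractogram(kept, dict(t.params),
                      dict(t.provenance) | {"pruned_from": len(t)})


def _in_mask(mask: MaskVolume, ijk) -> bool:
    i, j, k = ijk
    if not (0 <= i < mask.grid.shape[0] and 0 <= j < mask.grid.shape[1]
            and 0 <= k < mask.grid.shape[2]):
        return False
    return bool(mask.data[i, j, k])


def probabilistic_tracts(field: OrientationField, brain: MaskVolume,
                         params: TrackingParams | None = None,
                         iterations: int | None = None,
                         rng_seed: int = 0) -> Tractogram:
    """Probabilistic variant: per step the direction is drawn from an axial
    distribution (concentration kappa) about the selected peak; seeding as
    in whole-brain tracking with ``iterations`` repetitions per launch."""
    params = params or TrackingParams()
    if params.kappa <= 0:
        raise ValueError("kappa must be > 0 for probabilistic tracking")
    iterations = iterations if iterations is not None else params.iterations
    seeds, dirs, seed_indices = _seed_launches(field, brain)
    prov = {"mode": "probabilistic", "iterations": iterations,
            "launched": len(seeds) * iterations, "rng_seed": rng_seed}
    if len(seeds) == 0:
        return Tractogram([], params.to_dict(), prov | {"discarded_short": 0})
    seeds = np.tile(seeds, (iterations, 1))
    dirs = np.tile(dirs, (iterations, 1))
    seed_indices = seed_indices * iterations
    sls = _launch(field, brain, seeds, dirs, seed_indices, params,
                  kappa=params.kappa, rng_seed=rng_seed)
    kept = [s for s in sls if s.length_mm() >= params.min_length_mm]
    prov["discarded_short"] = len(sls) - len(kept)
    return Tractogram(kept, params.to_dict(), prov)


def probabilistic_connection_maps(field: OrientationField, brain: MaskVolume,
                                  roi_pairs, params: TrackingParams,
                                  iterations: int, rng_seed: int):
    """Memory-lean probabilistic run: connection-probability maps for up to
    two endpoint-ROI pairs in a single pass, without materialising the
    tractogram.  Returns (maps, retained_counts)."""
    if len(roi_pairs) not in (1, 2):
        raise ValueError("one or two ROI pairs supported")
    seeds, dirs, _ = _seed_launches(field, brain)
    grid = field.grid
    nvox = int(np.prod(grid.shape))
    flat = lambda m: np.ascontiguousarray(m.data.reshape(-1),
                                          dtype=np.bool_)
    pairs = list(roi_pairs) + [roi_pairs[-1]] * (2 - len(roi_pairs))
    (a1, b1), (a2, b2) = pairs
    counts1 = np.zeros(nvox, dtype=np.int64)
    counts2 = np.zeros(nvox, dtype=np.int64)
    stamp1 = np.full(nvox, -1, dtype=np.int64)
    stamp2 = np.full(nvox, -1, dtype=np.int64)
    retained = np.zeros(2, dtype=np.int64)
    step = params.resolve_step(grid)
    max_steps = int(np.ceil(params.max_length_mm / step / 2.0))
    cos_turn = float(np.cos(np.deg2rad(params.max_turn_deg)))
    pk, npk, fa, br, inv = _field_arrays(field, brain)
    if len(seeds):
        allseeds = np.ascontiguousarray(np.tile(seeds, (iterations, 1)))
        alldirs = np.ascontiguousarray(np.tile(dirs, (iterations, 1)))
        _seed_numba_rng(int(rng_seed))
        _track_visits(pk, npk, fa, br, inv, allseeds, alldirs, step,
                      cos_turn, params.fa_min, max_steps,
                      float(params.kappa), flat(a1), flat(b1), flat(a2),
                      flat(b2), counts1, counts2, stamp1, stamp2, retained)
    maps = []
    for c, r in ((counts1, retained[0]), (counts2, retained[1])):
        denom = max(int(r), 1)
        maps.append(ScalarVolume(grid, (c / denom).reshape(grid.shape)))
    return maps[:len(roi_pairs)], retained[:len(roi_pairs)].copy()


def connection_probability_map(t: Tractogram, grid: GridSpec) -> ScalarVolume:
    """Per voxel: (number of distinct streamlines entering the voxel) /
    (total number of streamlines)."""
    if len(t) == 0:
        raise ValueError("connection probability of an empty tractogram")
    shape = grid.shape
    counts = np.zeros(shape, dtype=np.int64)
    for s in t.streamlines:
        v = voxel_of(grid, s.points)
        ok = np.all((v >= 0) & (v < np.array(shape)), axis=1)
        v = v[ok]
        flat = np.unique(np.ravel_multi_index(v.T, shape))
        counts.reshape(-1)[flat] += 1
    return ScalarVolume(grid, counts / len(t))


def tract_voxels(t: Tractogram, grid: GridSpec) -> np.ndarray:
    """Distinct voxel indices visited by any streamline, (M, 3)."""
    if len(t) == 0:
        return np.zeros((0, 3), dtype=np.int64)
    allv = np.vstack([voxel_of(grid, s.points) for s in t.streamlines])
    ok = np.all((allv >= 0) & (allv < np.array(grid.shape)), axis=1)
    return np.unique(allv[ok], axis=0)


# ---------------------------------------------------------------------------
# TrackVis export / import
# ---------------------------------------------------------------------------

def save_trk(t: Tractogram, grid: GridSpec, path) -> None:
    import nibabel as nib
    from nibabel.streamlines import Tractogram as NibTractogram

    nt = NibTractogram([s.points for s in t.streamlines],
                       affine_to_rasmm=np.eye(4))
    hdr = {"voxel_to_rasmm": grid.affine.astype(np.float32),
           "voxel_sizes": grid.voxel_size.astype(np.float32),
           "dimensions": np.asarray(grid.shape, dtype=np.int16)}
    nib.streamlines.save(nib.streamlines.TrkFile(nt, hdr), str(path))


def load_trk(path) -> list:
    import nibabel as nib

    trk = nib.streamlines.load(str(path))
    return [Streamline(np.asarray(p, dtype=float), (-1, -1, -1),
                       ("none", "none"))
            for p in trk.tractogram.streamlines]
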