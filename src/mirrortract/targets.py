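"""Data-driven target ROIs from streamline endpoints.

The terminal voxels of the seed-tracked streamlines (last ten distinct
voxels of each end, with a 2 cm peri-lesional shell excluded) are
clustered with k-means; the cluster structure decides whether the
mirrored-lesion region behaves as an interconnecting node between two
diametrically opposed areas (two targets) or as a seed station projecting
to one area (one target).  Each selected centroid is promoted to a
10 mm-diameter sphere ROI, together with its sagittal mirror for the
affected hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .tracking import Tractogram, voxel_of
from .volumes import GridSpec, MaskVolume, mirror_sagittal, sphere_mask


@dataclass
class EndpointSet:
    """Collected terminal voxels with provenance."""

    voxels: np.ndarray          # (N, 3) int voxel indices
    streamline_ids: np.ndarray  # (N,)
    excluded_count: int
    grid: GridSpec

    def world_points(self) -> np.ndarray:
        return self.grid.voxel_to_world(self.voxels.astype(float))


@dataclass
class TargetSet:
    centroids: list          # 1 or 2 world points (mm)
    decision: str            # {"opposed_pair", "single_majority"}
    spheres: list            # MaskVolume, 10 mm diameter
    mirrored_spheres: list   # sagittal mirrors

    def __post_init__(self):
        if len(self.centroids) not in (1, 2) \
                or len(self.centroids) != len(self.spheres):
            raise ValueError("TargetSet must hold 1 or 2 centroid/spheres")
        want = "opposed_pair" if len(self.centroids) == 2 \
            else "single_majority"
        if self.decision != want:
            raise ValueError(
                f"decision {self.decision!r} inconsistent with "
                f"{len(self.centroids)} centroids")


def collect_endpoints(t: Tractogram, exclusion: MaskVolume,
                      n_last: int = 10) -> EndpointSet:
    """Last ``n_last`` distinct voxels of each streamline end, dropping
    (and counting) any that fall inside the exclusion mask.

    Distinctness is in path order — the step size is smaller than a voxel,
    so consecutive points often share a voxel; a short path contributes
    all of its voxels (clamp).
    """
    grid = exclusion.grid
    vox_list, ids = [], []
    excluded = 0
    for sid, s in enumerate(t.streamlines):
        if len(s.points) == 0:
            continue
        path = voxel_of(grid, s.points)
        # distinct voxels in path order (consecutive dedup then full dedup
        # preserving first occurrence)
        _, first = np.unique(path, axis=0, return_index=True)
        ordered = path[np.sort(first)]
        for end in (ordered[::-1], ordered):  # from each end inward
            take = end[:n_last]
            for v in take:
                if np.any(v < 0) or np.any(v >= np.array(grid.shape)):
                    continue
                if exclusion.data[v[0], v[1], v[2]]:
                    excluded += 1
                else:
                    vox_list.append(v)
                    ids.append(sid)
    if vox_list:
        voxels = np.array(vox_list, dtype=np.int64)
        sids = np.array(ids, dtype=np.int64)
    else:
        voxels = np.zeros((0, 3), dtype=np.int64)
        sids = np.zeros(0, dtype=np.int64)
    return EndpointSet(voxels, sids, excluded, grid)


def cluster_endpoints(e: EndpointSet, k_max: int = 4,
                      rng_seed: int = 0,
                      silhouette_floor: float = 0.5) -> list[tuple]:
    """k-means over the endpoint cloud with silhouette model selection.

    k runs from 2 to ``k_max`` (10 seeded restarts each); the best k by
    silhouette score is kept unless that score is below
    ``silhouette_floor``, in which case the cloud is treated as a single
    cluster.  Fewer than ``k_max`` points also force k = 1.  Returns
    (centroid mm, member count) sorted by count, descending.
    """
    pts = e.world_points()
    if len(pts) == 0:
        raise ValueError("cannot cluster an empty endpoint set")
    if len(pts) < k_max or np.allclose(pts.var(axis=0).sum(), 0):
        return [(pts.mean(axis=0), len(pts))]
    best_k, best_score, best_labels, best_centers = 1, -np.inf, None, None
    sample = min(len(pts), 2000)
    for k in range(2, k_max + 1):
        if k >= len(pts):
            break
        km = KMeans(n_clusters=k, n_init=10, random_state=rng_seed)
        labels = km.fit_predict(pts)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(pts, labels, sample_size=sample,
                                 random_state=rng_seed)
        if score > best_score:
            best_k, best_score = k, score
            best_labels, best_centers = labels, km.cluster_centers_
    if best_labels is None or best_score < silhouette_floor:
        return [(pts.mean(axis=0), len(pts))]
    out = [(best_centers[c], int((best_labels == c).sum()))
           for c in range(best_k)]
    out.sort(key=lambda t: -t[1])
    return out


def select_targets(clusters: list[tuple], seed_mask: MaskVolume,
                   grid: GridSpec, sphere_diam_mm: float = 10.0,
                   opposed_angle_deg: float = 120.0) -> TargetSet:
    """Apply the one-vs-two-target rule and emit sphere ROIs + mirrors.

    With s the seed mask's centre of mass, the two most-populated
    centroids c1, c2 are "diametrically opposed" when the angle between
    c1-s and c2-s is at least ``opposed_angle_deg``; then both become
    targets.  Otherwise only the majority centroid does.
    """
    if not clusters:
        raise ValueError("no centroids to select targets from")
    s = seed_mask.center_of_mass_world()
    chosen = [clusters[0][0]]
    decision = "single_majority"
    if len(clusters) >= 2:
        c1, c2 = clusters[0][0], clusters[1][0]
        v1, v2 = c1 - s, c2 - s
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 > 1e-9 and n2 > 1e-9:
            ang = np.degrees(np.arccos(np.clip(v1 @ v2 / (n1 * n2), -1, 1)))
            if ang >= opposed_angle_deg:
                chosen = [c1, c2]
                decision = "opposed_pair"
    spheres = [sphere_mask(grid, c, sphere_diam_mm) for c in chosen]
    mirrored = [mirror_sagittal(m) for m in spheres]
    return TargetSet([np.asarray(c, dtype=float) for c in chosen],
                     decision, spheres, mirrored)
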