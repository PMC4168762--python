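"""End-to-end single-case analysis in both hemispheres.

Stages: mirror the lesion into the healthy hemisphere, intersect with
white matter to form the seed, track tumor-out, harvest distal endpoints
beyond a 2 cm exclusion shell, cluster them into one or two targets,
whole-brain track, and prune homologous tract pairs in both hemispheres
with the same ROI logic.  The output is the per-hemisphere tract count
and the percentage decrease on the lesioned side, weighted downstream by
the physical tumor volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield

import numpy as np

from . import targets as tg
from . import tracking as tk
from . import volumes as vol
from .config import RunConfig
from .peaks import OrientationField

log = logging.getLogger(__name__)


class UninformativeCaseError(RuntimeError):
    """No reference tracts in the healthy hemisphere: the case carries no
    usable asymmetry signal and must be reported as such."""


@dataclass
class CaseResult:
    case_id: str
    decision: str
    n_healthy: int
    n_lesioned: int
    pct_decrease: float
    tumor_volume_cm3: float
    target_centroids: list
    provenance: dict = dfield(default_factory=dict)

    @property
    def weighted_pct(self) -> float:
        return self.pct_decrease / self.tumor_volume_cm3


def roi_pairs(cfg: RunConfig, lesion: vol.MaskVolume,
              homolog: vol.MaskVolume, targetset: tg.TargetSet):
    """Endpoint-ROI pairs for (healthy, affected) hemispheres."""
    if targetset.decision == "opposed_pair":
        healthy = (targetset.spheres[0], targetset.spheres[1])
        affected = (targetset.mirrored_spheres[0],
                    targetset.mirrored_spheres[1])
    else:
        dil_homolog = vol.dilate_to_factor(homolog, cfg.dilate_factor)
        if cfg.affected_roi == "lesion":
            dil_affected = vol.dilate_to_factor(lesion, cfg.dilate_factor)
        else:  # mirror the dilated homolog back (default)
            dil_affected = vol.mirror_sagittal(dil_homolog)
        healthy = (dil_homolog, targetset.spheres[0])
        affected = (dil_affected, targetset.mirrored_spheres[0])
    return healthy, affected


def prepare_rois(field: OrientationField, brain: vol.MaskVolume,
                 wm: vol.MaskVolume, lesion_mask: vol.MaskVolume,
                 cfg: RunConfig):
    """Shared front half of both pipelines: seed, exclusion, targets."""
    if not lesion_mask.grid.matches(field.grid):
        lesion_mask = vol.resample_mask(lesion_mask, field.grid,
                                        cfg.resample_threshold)
    homolog = vol.mirror_sagittal(lesion_mask)
    seed = vol.intersect(homolog, wm)
    log.info("seed voxels (mirrored lesion ∩ WM): %d", seed.count())

    t_seed = tk.track_from_mask(field, brain, seed, cfg.tracking)
    log.info("tumor-out tracking: %d launched, %d kept, %d short",
             t_seed.provenance["launched"], len(t_seed),
             t_seed.provenance["discarded_short"])

    exclusion = vol.dilate_mm(homolog, cfg.exclusion_mm)
    eps = tg.collect_endpoints(t_seed, exclusion, cfg.n_last)
    log.info("endpoints: %d collected, %d excluded by %0.0f mm shell",
             len(eps.voxels), eps.excluded_count, cfg.exclusion_mm)
    if len(eps.voxels) == 0:
        raise UninformativeCaseError(
            "no endpoints beyond the exclusion shell")

    clusters = tg.cluster_endpoints(eps, cfg.k_max, cfg.rng_seed)
    targetset = tg.select_targets(clusters, seed, field.grid,
                                  cfg.sphere_diam_mm, cfg.opposed_angle_deg)
    log.info("targets: %s with %d centroid(s)", targetset.decision,
             len(targetset.centroids))
    return lesion_mask, homolog, targetset


def run_case(field: OrientationField, brain: vol.MaskVolume,
             wm: vol.MaskVolume, lesion_mask: vol.MaskVolume,
             cfg: RunConfig | None = None,
             case_id: str = "case") -> CaseResult:
    """Deterministic bilateral tract-count comparison for one case."""
    cfg = cfg or RunConfig()
    lesion_mask, homolog, targetset = prepare_rois(field, brain, wm,
                                                   lesion_mask, cfg)
    healthy_pair, affected_pair = roi_pairs(cfg, lesion_mask, homolog,
                                            targetset)
    t_all = tk.track_whole_brain(field, brain, cfg.tracking)
    t_healthy = tk.prune_by_endpoints(t_all, *healthy_pair)
    t_affected = tk.prune_by_endpoints(t_all, *affected_pair)
    n_h, n_l = len(t_healthy), len(t_affected)
    log.info("tract counts: healthy %d, lesioned %d", n_h, n_l)
    if n_h == 0:
        raise UninformativeCaseError(
            "no reference tracts reconstructed in the healthy hemisphere")
    pct = 100.0 * (n_h - n_l) / n_h
    return CaseResult(
        case_id=case_id, decision=targetset.decision,
        n_healthy=n_h, n_lesioned=n_l, pct_decrease=pct,
        tumor_volume_cm3=vol.mask_volume_cm3(lesion_mask),
        target_centroids=[c.tolist() for c in targetset.centroids],
        provenance={
            "config": cfg.to_dict(),
            "whole_brain_count": len(t_all),
            "healthy_tracts": n_h, "affected_tracts": n_l,
        })


def run_case_probabilistic(field: OrientationField, brain: vol.MaskVolume,
                           wm: vol.MaskVolume, lesion_mask: vol.MaskVolume,
                           cfg: RunConfig | None = None):
    """Probabilistic counterpart: same ROI logic, per-step directions drawn
    around the selected peak, `iterations` repetitions per launch; returns
    (healthy map, affected map, retained counts) where each map is a
    connection-probability image."""
    cfg = cfg or RunConfig()
    lesion_mask, homolog, targetset = prepare_rois(field, brain, wm,
                                                   lesion_mask, cfg)
    healthy_pair, affected_pair = roi_pairs(cfg, lesion_mask, homolog,
                                            targetset)
    maps, retained = tk.probabilistic_connection_maps(
        field, brain, [healthy_pair, affected_pair], cfg.tracking,
        cfg.tracking.iterations, cfg.rng_seed)
    log.info("probabilistic retained: healthy %d, affected %d",
             retained[0], retained[1])
    return maps[0], maps[1], retained


# ---------------------------------------------------------------------------
# Phantom-truth diagnostics used by the validation suite
# ---------------------------------------------------------------------------

def mean_closest_approach(tractogram: tk.Tractogram, point) -> float:
    """Mean over streamlines of the closest distance (mm) to a point."""
    p = np.asarray(point, dtype=float)
    d = [np.linalg.norm(s.points - p, axis=1).min()
         for s in tractogram.streamlines if len(s.points)]
    if not d:
        raise ValueError("empty tractogram")
    return float(np.mean(d))
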