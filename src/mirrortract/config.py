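"""Run configuration: every tunable constant of the pipeline in one
serialisable object, so each artifact directory records exactly what
produced it."""

from __future__ import annotations

from dataclasses import dataclass, field

from .tracking import TrackingParams


@dataclass
class RunConfig:
    """Pipeline constants.

    Tracking: 0.2 anisotropy floor, 60 degree per-voxel turn limit.
    Targets: last 10 voxels per streamline end, 2 cm peri-lesional
    exclusion, 10 mm-diameter target spheres, 120 degree bearing threshold
    for the "diametrically opposed" decision, k-means model selection up
    to k_max.  ROI handling: masks resampled with a conservative 0.9
    threshold, tumor-based endpoint ROIs grown to 1.2x their voxel count.
    """

    tracking: TrackingParams = field(default_factory=TrackingParams)
    n_last: int = 10
    exclusion_mm: float = 20.0
    sphere_diam_mm: float = 10.0
    opposed_angle_deg: float = 120.0
    k_max: int = 4
    dilate_factor: float = 1.2
    resample_threshold: float = 0.9
    affected_roi: str = "mirrored_homolog"  # or "lesion"
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 < self.resample_threshold <= 1):
            raise ValueError("resample_threshold must be in (0, 1]")
        if self.dilate_factor < 1:
            raise ValueError("dilate_factor must be >= 1")
        if self.affected_roi not in ("mirrored_homolog", "lesion"):
            raise ValueError("affected_roi must be 'mirrored_homolog' or "
                             "'lesion'")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("n_last", "exclusion_mm", "sphere_diam_mm",
              "opposed_angle_deg", "k_max", "dilate_factor",
              "resample_threshold", "affected_roi", "rng_seed")}
        d["tracking"] = self.tracking.to_dict()
        return d

    @classmethod
    def from_flat(cls, items: dict) -> "RunConfig":
        """Build from a flat key=value mapping (config file / CLI flags);
        tracking keys are recognised by name."""
        tp_fields = TrackingParams().__dict__.keys()
        tp_kwargs, cfg_kwargs = {}, {}
        for k, v in items.items():
            if v is None:
                continue
            if k in tp_fields:
                tp_kwargs[k] = v
            else:
                cfg_kwargs[k] = v
        return cls(tracking=TrackingParams(**tp_kwargs), **cfg_kwargs)
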