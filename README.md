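# mirrortract

Lesion-mirrored multi-fiber diffusion tractography: quantify how a brain
tumor has altered the white matter running through it, **without any
prior knowledge of which tracts those are**.

## The problem

Brain lesions affect white-matter (WM) fiber pathways by displacement
(typical of meningiomas), infiltration, or outright destruction (typical
of high-grade gliomas), and the distinction matters for surgical
planning.  Atlas- or landmark-based tractography breaks down precisely
where it is needed: the tumor has already deviated the anatomy, and for
many lesion locations no canonical tract definition exists.

`mirrortract` implements an atlas-free alternative for people working
with diffusion-MRI fiber-orientation data (multi-peak per voxel).  The
lesion mask is mirrored across the sagittal mid-plane into the healthy
hemisphere; deterministic multi-fiber streamline tracking seeded from
that homologous region discovers *which* pathways would have crossed the
tumor; their endpoint clusters define data-driven target ROIs; and
homologous tracts are then reconstructed in both hemispheres by two-ROI
endpoint filtering of a whole-brain tractogram.  The read-out per case is
the tract-count decrease on the lesioned side,

```
pct_decrease = 100 · (n_healthy − n_lesioned) / n_healthy ,
```

optionally weighted by the tumor volume (cm³) and related to histological
aggressiveness via the MIB-1 (Ki-67) proliferation index.  Tracking uses
FACT-style propagation over per-voxel peak sets with standard stopping
rules (anisotropy < 0.2, turn > 60° across a voxel, brain-mask exit), a
deterministic core plus a probabilistic variant (per-step axial
directional sampling, 1000 iterations) that produces connection-
probability images for cross-checking.

Because no public per-case imaging accompanies the method, the package
ships a first-class synthetic phantom module: mirror-symmetric
two-hemisphere orientation fields with parametric bundles and lesions
that either *displace* geometry (fibers intact, deviated) or
*infiltrate* (a stated fraction of fiber chains deleted in place), so
every stage is testable at desk scale against known truth.

## Worked example

Simulate a glioma-like case in which half of the fiber chains crossing
the lesion are destroyed, then run the bilateral analysis:

```bash
$ mirrortract --quiet simulate-case --mode infiltrate --fraction 0.5 \
      --seed 7 --out case/
wrote phantom case to case

$ mirrortract --quiet run-case --peaks case/peaks.nii.gz --fa case/fa.nii.gz \
      --brain case/brain.nii.gz --wm case/wm.nii.gz \
      --lesion case/lesion.nii.gz --out case/run
pct_decrease = 45.02% (2008 -> 1104 tracts)
```

2008 streamlines connect the mirrored-lesion ROI to its data-driven
target in the healthy hemisphere; only 1104 survive on the lesioned side,
a 45% decrease for a 50% ground-truth fiber removal (the package's
validation requires agreement within ±10 percentage points).  The same
entry point on a displacement phantom reports a small decrease (~10%)
while the reconstructed tracts are deviated by more than half the applied
push — the "intact but displaced" meningioma signature.

Cohort-level statistics on a table of per-case outcomes:

```bash
$ mirrortract --quiet cohort-stats src/mirrortract/data/cohort16.csv
n = 16 cases
MIB-1 vs volume-weighted tract decrease: r = 0.83 (p = 5.73e-05), slope = 0.1570 %/cm^3 per MIB-1%
meningioma  (n=5): 17.75 +/- 9.17 %
LGG         (n=7): 61.90 +/- 28.05 %
HGG         (n=4): 93.53 +/- 2.79 %
meningioma vs gliomas: t = -4.42, p = 0.0006
```

The packaged 16-case table (5 meningiomas, 7 low-grade and 4 high-grade
gliomas) shows the intended use: the more proliferative the tumor
(higher MIB-1), the larger the volume-weighted tract destruction
(r = 0.83), and tumor types separate cleanly on the raw percentage
decrease (pooled t-test, p = 0.0006).

The same functionality is available as a library; see
`mirrortract.run_case`, `mirrortract.default_infiltration_case`, and
`docs/methods.md` for the model, parameter defaults, and the phantom's
scope and limitations.

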