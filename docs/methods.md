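# Methods

`mirrortract` quantifies tumor-induced white-matter alteration by
comparing tract counts between a lesioned hemisphere and its healthy
mirror, without anatomical priors.  This note documents the model behind
each stage, the defaults and why they were chosen, what the synthetic
phantom does and does not emulate, and the numerical decisions a reader
would otherwise have to reverse-engineer from the code.

## Pipeline model

The measurement chain for one case is:

1. **Contralateral seed.** The binary lesion mask is mirrored across the
   sagittal mid-plane (voxel index flip `i -> Nx-1-i` along the declared
   left-right axis) and intersected with the white-matter mask.  Mirroring
   in index space presumes the inputs have been aligned so the
   inter-hemispheric plane coincides with the grid mid-plane; this is an
   input contract, not something the package estimates.  When masks arrive
   on a different grid they are trilinearly resampled and binarised at a
   conservative 0.9, so transformed ROIs shrink rather than bleed into
   neighbouring tissue.
2. **Tumor-out tracking.** Deterministic multi-fiber streamlines are
   launched from every (seed voxel, peak) pair — the seed count per voxel
   equals its number of fiber-orientation peaks — and propagated
   bidirectionally.
3. **Data-driven targets.** The last ten distinct voxels of each
   streamline end are harvested; a shell formed by dilating the mirrored
   lesion by 2 cm (world metric) removes peri-seed endpoints so that only
   medium/long-range projections drive target placement.  k-means over the
   surviving endpoint cloud, with silhouette-based selection of k (see
   below), yields one or two centroids; each becomes a 10 mm-diameter
   sphere ROI, mirrored back into the lesioned hemisphere.
4. **Two-ROI pruning in both hemispheres.** Whole-brain streamlines are
   retained when their two terminal points fall one in each ROI of a pair.
   If the endpoint clusters sit in diametrically opposed areas relative to
   the seed (bearing angle >= 120 deg), the pair is (target A, target B),
   mirrored for the lesioned side.  Otherwise the pair is (mirrored-lesion
   ROI grown to 1.2x its voxel count, majority target), with the grown ROI
   mirrored back for the lesioned side (a config switch substitutes the
   original lesion ROI instead).
5. **Asymmetry statistic.** The per-case outcome is
   `pct_decrease = 100 (n_healthy - n_lesioned) / n_healthy`, with the
   physical tumor volume (voxel count x voxel volume) used downstream to
   weight it.

A case with `n_healthy = 0` carries no reference signal and raises
`UninformativeCaseError` rather than reporting a silent zero.

## Tracking

Propagation is FACT-style: the orientation field is looked up at the
nearest voxel of the current point (no interpolation between voxels), the
peak with maximal |dot| against the incoming direction is selected, and
its sign is chosen to keep forward motion.  Stopping rules: anisotropy
below 0.2, a turn of more than 60 degrees across a voxel, exit from the
brain mask, or a 200 mm length cap.  With nearest-voxel lookup the
direction is constant within a voxel, so the per-step turn check is
exactly a per-voxel-transition check.  Parameters:

| parameter | default | rationale |
|---|---|---|
| step | 0.5 x min voxel dim (mm) | sub-voxel stepping without oversampling a piecewise-constant field |
| anisotropy floor | 0.2 | standard white/gray matter tracking floor |
| max turn | 60 deg / voxel | excludes biologically implausible bends |
| min length | 10 mm | drops stubs; the method targets medium/long-range connectivity |
| max length | 200 mm | safety cap; phantom paths are bounded by the brain mask first |

Seeding is bidirectional; unidirectional launches would halve bundle
recovery for seeds in mid-tract.  Ties between peaks with equal |dot| go
to the lowest peak index, making deterministic tracking bit-reproducible.
The inner loops are numba-compiled; a pure-Python fine-step integrator
(10x finer) in the test suite serves as an independent oracle, with
endpoint agreement within one voxel required on curved fields.

The probabilistic variant draws each step direction from an axial
von Mises-Fisher-like distribution centred on the selected peak,
concentration kappa = 80 (~6 deg angular sd) — a generic uncertainty
model, deliberately simple since only the support of the resulting
connection-probability image is compared against deterministic tracts.
Each deterministic launch is repeated `iterations` (default 1000) times;
the connection-probability image holds, per voxel, the number of distinct
retained streamlines entering the voxel divided by the total retained.
All randomness flows through an explicit integer seed.

## Peak extraction

`find_odf_peaks` extracts up to three principal directions from any
spherical function sampled on a tessellation (default: icosahedron
subdivided 3 times, 642 vertices; values antipodally symmetrised on
load).  Candidates are strict local maxima over the tessellation edge
graph, pruned at 25% of the global maximum and 25 deg minimum axial
separation, then refined sub-vertex by a quadratic fit over the gnomonic
projection of the one-ring neighbourhood (worst-case direction error
~0.5 deg at subdivision 3, versus ~2.5 deg for the raw argmax).  Full
spherical-function reconstruction from diffusion signal is out of scope:
the pipeline consumes peaks, from whatever source.

## The phantom

The synthetic generator emulates the *study design*, not diffusion
physics: a mirror-symmetric two-hemisphere "brain" (64x64x64 voxels at
1 mm isotropic by default) containing parametric fiber bundles, with a
spherical lesion applied to one side only.  Bundles are tubes around a
centerline; every tube voxel carries a unit peak tangent to the local
tube flow and anisotropy 0.8, and belongs to exactly one **fiber chain**
(the lattice cell of its cross-section offset in a parallel-transported
frame, 1 mm pitch).  Chains are the phantom's unit of fiber identity.

Two design choices matter for interpreting results:

- **Funnelled ends.** Bundle ends taper into narrow funnels (tangents
  tilt toward the tip), so streamline terminal points converge onto a
  compact projection site.  Without this, endpoints of a 9 mm-radius
  tube spread over its whole cross-section and no 10 mm target sphere
  placed at the endpoint-cloud centroid could capture them — both
  hemispheres would count zero tracts.  Real bundles funnel into
  cortical terminations; the phantom makes that explicit.
- **Chain-level infiltration.** A glioma-like lesion deletes each fiber
  chain crossing it independently with the stated removal fraction, and
  removes the *whole* chain (its grid-resolvable section plus the lesion
  interior), assigning sub-0.2 anisotropy to the vacated voxels.
  Deleting only the intra-lesional segment would leave remnants whose
  lesion-side endpoints still fall inside the dilated-lesion endpoint
  ROI, so they would still be counted and the tract-count decrease would
  under-report the damage.  Whole-chain deletion makes the expected
  pipeline read-out equal the removal fraction.  Funnel voxels are
  shared by many chains (sub-voxel chain width) and are never deleted.

A meningioma-like lesion instead displaces geometry: the densified
centerline is pushed radially away from the lesion centre with a C1
quartic profile decaying to zero at **three** lesion radii, and the tube
is re-synthesised around the pushed curve, which re-orients the tangents
exactly.  The 3R support (rather than a tighter one) keeps the bent
tube's curvature radius well above the bundle radius; with a tighter
support the bend concentrates, inner fibers face near-zero curvature
radius, and tracking terminates on the turn rule — contradicting the
displacement phantom's defining property of intact, merely deviated
fibers.  The push map `d -> d + m w(d)` is required to be invertible
(`m < 0.65 D`), and lesion-core voxels are set to zero anisotropy
(tumor mass).

Default study conditions: the infiltration case uses a straight
9 mm-radius bundle whose end lies inside an 11 mm-radius lesion
(seed-station geometry, yielding the one-target decision), ~285 chains;
the displacement case uses a slender 3 mm-radius mid-tract bundle passing
3 mm from a 5 mm-radius lesion pushed 8 mm (yielding the opposed-pair
decision).  Both bundle tips carry funnels.

What the phantom does **not** emulate: diffusion signal formation, noise,
partial volume at tissue interfaces, crossing-fiber ambiguity inside the
lesion, edema, and anatomical variability.  Passing phantom tests
therefore demonstrates that the pipeline's geometry, bookkeeping and
statistics behave as designed under known truth — not that the method's
clinical sensitivity on patient data is reproduced.

## Target generation decisions

The cluster count k is selected by silhouette score over k = 2..4
(k-means with 10 seeded restarts; silhouette evaluated on a subsample of
at most 2000 points for cost); if the best silhouette is below 0.5, or
fewer points than k_max exist, the endpoint cloud is treated as a single
cluster.  "Diametrically opposed" is operationalised as a >= 120 deg
angle between the two most-populated centroids' bearings from the seed
centre of mass; both thresholds are exposed in `RunConfig`.  Visual
inspection steps of a human operator are replaced by stage-level logging
(seeds launched, endpoints excluded, decision taken, counts) — there is
no human gate in the pipeline.

## Cohort statistics

`percent_decrease` may be negative (lesioned count exceeding healthy).
Tumor-volume weighting divides the percentage by the lesion volume in
cm^3.  The MIB-1 association is a simple linear regression of the
weighted decrease on MIB-1, with the two-sided p from the exact
t-distribution (df = n-2).  The tumor-group comparison defaults to the
pooled-variance two-sample t-test; on the packaged 16-case cohort the
pooled test reproduces the expected p ~ 6e-4 whereas Welch's variant
gives ~3e-5, so pooled is the default and Welch is available via
`equal_var=False`.  Sample SDs use the n-1 denominator (validated against
the published per-group SDs).  Group membership is parsed from the case
identifier prefix (M/LGG/HGG).

## Numerical conventions

- Voxel indices are 0-based; a voxel's world position is the affine image
  of its integer index (voxel-centre convention).  Point-to-voxel lookup
  is round-half-up everywhere (tracker kernel, pruning, endpoint
  harvesting, probability maps), so post-hoc audits agree with the
  propagator bit-for-bit.
- `dilate_mm` uses the Euclidean distance transform with per-axis
  sampling, so anisotropic voxels (e.g. 1.0 x 1.0 x 1.5 mm) dilate
  correctly in world units; `dilate_to_factor` iterates 6-connected
  morphological dilation until the voxel count reaches the factor.
- Masks serialise to NIfTI as uint8 (any nonzero reads as true);
  orientation fields as a 5D (x, y, z, peak, component) float32 NIfTI
  plus an anisotropy volume; streamlines as TrackVis `.trk`.
- Problem sizes: validation runs use the 64^3 desk-scale grid; a full
  deterministic case takes a few seconds and a 1000-iteration
  probabilistic case about a minute on one core.

## Known limitations

- Mirroring is exact voxel flipping: real brains are only approximately
  symmetric and registration residuals propagate directly into the seed.
- The tract count counts retained streamlines (launch-weighted), not
  anatomically distinct axon bundles; counts are comparable between
  hemispheres of one case, not across cases or acquisition protocols.
- The opposed-pair / single-target decision depends on two configurable
  thresholds with no ground-truth anatomical meaning; borderline
  endpoint clouds can switch regimes between runs with different seeds.
- Streamlines seeded at the tube rim terminate on a knife edge; their
  endpoints are not stable under integrator refinement.  This is
  inherent to hard-threshold stopping rules, affects both hemispheres
  symmetrically, and cancels in the asymmetry statistic.
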