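# Methods

This note documents the models, conventions, numerical choices and
limitations behind `stereotrack`.  Empirical figures quoted here are the
quantities the test suite and `scripts/acceptance.py` compute.

## Coordinate conventions

The world frame is RAS-like: +x is medio-lateral toward the animal's
right, +y is anterior, +z is dorsal.  Voxel indices are 0-based and the
NIfTI affine maps voxel centers to world mm.  Stereotaxic coordinates
are (AP, ML, DV) offsets from bregma; the AP axis is the *template's*
anatomical axis, not the animal's bregma–lambda line — the angular
deviation of the B–L segment from horizontal is reported separately as
the skull-flat angle γ (positive when lambda is ventral to bregma; the
sign convention is ours, as the literature leaves it unstated).

Trajectory inclinations α and β are *independent projection angles*
with a tangent parameterization: the entry→tip direction is
proportional to `(s_hemi·tan α, tan β, −1)` on (ML, AP, DV), with
`s_hemi = +1` (right) / `−1` (left) so that negative α always means the
entry is lateral to the tip on the implanted side, and positive β means
a posterior-to-anterior insertion.  Projection angles (rather than
sequential Euler rotations) make per-modality Δα and Δβ well defined;
`angles_from_direction` is the exact inverse on |α|,|β| < 90°.

## Planned-trajectory geometry

A plan is (AP, ML) of the target, a DV *depth below the dural surface
at the entry column*, and (α, β).  The dural surface is the height
field of the dorsal-most brain-mask voxel per (x, y) column, queried
with bilinear interpolation.  For inclined trajectories the entry
column and the target's world DV are mutually dependent; they are
resolved by a fixed-point iteration initialized at the target column,
which converges in a few steps on smooth surfaces.  Line–surface
intersections ray-march at 0.1 of the column spacing and refine the
bracketing step by bisection, so entries are sub-voxel; with a flat
surface the solution matches the closed trigonometric form (depth 7 mm
at α = −18° gives D_plan = 7.361 mm and 2.274 mm of lateral entry
displacement) to 10⁻³ mm.

## Registration

Normalization and intra-animal fusion use intensity-based registration
by maximization of mutual information, rigid (6 dof) for same-anatomy
pairs and full affine (12 dof) where the tissue may have deformed
between sessions.  The criterion and estimator are:

* **Normalized MI** (entropy ratio (Hx+Hy)/Hxy) on a 48-bin joint
  histogram — overlap-invariant, which matters because the usable
  sample set changes with the pose;
* **Parzen windowing**: intensities spread over adjacent bins with a
  cubic B-spline kernel, making the criterion smooth in the transform
  parameters;
* **jittered sampling**: sample positions inside the dilated fixed
  foreground are offset by up to half a voxel (seeded, fixed per
  level).  Lattice-coherent sampling biases histogram MI toward
  grid-aligned poses (the classical interpolation artifact); jitter
  removes the bias at the cost of a small, deterministic
  peak-localization noise;
* **smooth boundary window**: sample weights fade to zero over ~3
  voxels at the moving-grid edge, so samples entering or leaving the
  grid cannot create steps in the criterion;
* **multiresolution optimization**: isotropic Gaussian smoothing
  (which commutes with the rigid model, preserving the optimum) at
  σ = 2, 1, 0.5 voxels; a Nelder–Mead simplex for the capture stage,
  then L-BFGS-B with finite differences.  Initialization aligns
  foreground centroids.  The final criterion value is verified to be at
  least the initialization's.

On zero-noise phantoms, self-registration recovers identity to
~0.005°/0.001 mm, and the median recovery error over 20 random rigid
misalignments (≤10°, ≤3 mm) is ~0.1° rotation and ~0.02 mm displacement
at the head center; individual cases can reach ~1° when the criterion
has a secondary basin for large combined rotations, which the median
reporting absorbs.  Moderate image noise does not degrade this (it
slightly smooths the histogram).

## Segmentation and axis fitting

CT keeps ROI voxels at or above a per-study threshold (the electrode is
hyper-intense); MRI keeps voxels at or below a cutoff (the retraction
trace is hypo-intense), restricted to the brain mask because skull and
background are also dark in T2\*-weighted images.  The CT mask is cut
back 0.7 mm from its dorsal end along DV — a deterministic depth cut,
not a morphological erosion, since its purpose is to exclude residual
dental cement near the entry.  The largest 26-connected component is
kept (ties: larger count, then more ventral centroid).

The 0.2 mm electrode is near voxel scale, so track voxels are
partial-volume mixtures.  The phantom rasterizes the cylinder with 4×
supersampling (an even factor avoids subcell centers aliasing onto
voxel centers), and the default thresholds sit at ~25% track occupancy:
on a 1000/300 brain/trace MRI contrast the cutoff is 825, on a
200/800/3000 brain/skull/electrode CT contrast the threshold is 950.
These are contrast-dependent settings, exposed per study in the
configuration, as no universal intensity threshold exists.

The trajectory direction is the dominant eigenvector of the unweighted
covariance of masked voxel centers, sign-fixed ventral; fits are
rejected when fewer than 3 voxels, under 5 voxels of extent, top-two
eigenvalues within 5% (no dominant axis), or a direction orthogonal to
DV.  Entry and tip are on-axis projections of the mask extents, which
suppresses single-voxel jitter.  On rasterized 0.2 mm × 8 mm cylinders
at 0.1 mm voxels the angles are recovered to ≤0.3° at zero noise and
≤1° at SNR 10.

## Reconstruction and the DV convention

Reconstructed trajectories (`rec-mri`, `rec-ct`) place the entry at the
dural-surface intersection of the fitted axis and the tip at exactly
D_plan along it — the insertion depth is taken as exact, because image
contrast at the tip and entry is the least reliable part of either
modality.  Their DV offsets are therefore reported under a
depth-along-trajectory convention: both planned and reconstructed
entries lie on the dural surface (depth 0), and the tip depth equals
D_plan, so ΔDV is identically 0.0 ± 0.0 at entry and target.  The
convention in force is recorded per trajectory (`dv_convention`), and
direct sources keep the ordinary axis convention, under which
ED² = ΔAP² + ΔML² + ΔDV² exactly.

## Statistics

One-sample tests are one-sided against zero *in the direction of the
observed mean* — the only reading under which significant offsets of
either sign can be flagged in the same table.  Paired comparisons are
two-tailed paired t; correlations are Pearson's R with a t-transform
p-value (df = n−2).  Stars: \*\*\* p<0.001, \*\* p<0.005, \* p<0.05.
No multiple-testing correction is applied.  Cohort ED rows are means of
per-trajectory Euclidean distances (not norms of mean offsets).  A
zero-variance nonzero paired difference is degenerate and reported as
p < 10⁻¹² with a warning rather than an exception.

## Target regions

Regions are binary labelmaps in template space, either native or
rasterized from per-coronal-slice polygons (the form printed atlases
provide), filled with the even–odd rule; self-intersecting polygons are
rejected.  Membership of a point is the label of its containing voxel
(floor(v + ½) — consistent under whole-voxel shifts, unlike
round-half-to-even).  For contour stacks, a query on an un-contoured
plane borrows the nearest contoured plane when within a gap tolerance
(default: half the slice spacing) and is otherwise *indeterminate* —
contour stacks are genuinely discontinuous along AP for small thalamic
nuclei, and silent interpolation would hide that.

## The phantom generator

The phantom emulates a rat head at 0.15 mm isotropic resolution
(88×112×88 grid): an ellipsoidal brain (semi-axes 5 × 7 × 4.5 mm)
inside a 0.7 mm skull shell, bregma and lambda on the outer skull
8.31 mm apart at equal height (the template is skull-flat by
construction; 8.31 mm is the adult-Wistar cohort mean), four asymmetric
internal structures (ventricle-, nucleus- and cerebellum-like) that
give the brain internal contrast — a featureless ellipsoid is almost
rotationally degenerate and would make intensity-based registration
ill-posed in a way real anatomy is not — and a 0.2 mm electrode along a
configurable trajectory (default plan: an SNCD-like target at AP −5.3,
ML −2.4, 6 mm below the dura, vertical).  MRI contrast: background 0,
skull 150, brain 1000, trace 300; CT: background 0, brain 200, skull
800, electrode 3000; additive Gaussian noise (MRI σ=25, CT σ=30 —
SNR ≈ 40, conservative for modern small-animal scanners; Rician
magnitude noise behind a flag).  In CT the electrode extends 2 mm
dorsal of the entry, emulating the protruding shaft and cement.
Modality volumes are rendered analytically in their own (misaligned)
frame, so the recorded modality→template transforms are exact by
construction rather than resampling approximations.

Cohorts perturb a shared plan with seeded normal draws — angles
(α, β) sd 2°, entry column sd 0.4 mm per axis, the magnitudes reported
for rodent stereotaxy — and are generated directly in template space
with identity inter-image transforms: the cohort error model describes
surgical deviation, while scanner repositioning is exercised separately
on single animals.  Ground-truth entries are defined on the *same*
voxelized dural height field the reconstruction uses; referencing the
analytic brain ellipsoid instead would introduce a half-voxel
discrepancy that is an artifact of the phantom, not of the method.
Ground-truth tips are at D_plan along the true direction from that
entry, and truth membership labels come from the same region labelmap
the pipeline queries.

What the phantom does *not* emulate: MR physics (bias fields,
susceptibility blooming around metal, Rician-vs-Gaussian differences at
low SNR), hemorrhage or tissue deformation around the track, bent
electrodes, skull heterogeneity, and anatomical variability of the
brain itself.  Passing tests therefore demonstrate the correctness of
the geometry, registration, segmentation-to-statistics chain under
known truth — not robustness to every artifact of real rodent imaging,
where the manual-delineation entry points of the workflow remain
available (`ingest_mask`, `ingest_observer`).

## Problem sizes

Registration validation uses a 56×72×48 grid at 0.25 mm — at that
voxel size the 0.2 mm electrode is sub-voxel and is not segmented, so
these phantoms exercise registration only.  Segmentation-to-statistics
validation uses the default 0.15 mm grid.  The end-to-end cohort check
processes 100 trajectories; the acceptance script uses 12 (any n ≥ 10
gives the same exact-zero DV offsets).

## Known limitations

* Straight-axis model only; a bent electrode biases both angles and the
  reconstructed tip.
* The direct-MRI entry point is the mask's dorsal extent, which sits
  below the dura when the trace starts deep; reconstructed entries
  avoid this but assume the normalization is exact.
* Registration assumes the head is the dominant bright structure and
  that a rigid/affine model suffices; brain shift or large
  deformations are out of scope.
* The per-study segmentation thresholds are not auto-calibrated.
* MRI inhomogeneity correction is a configuration hook only; phantoms
  are generated bias-free.
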