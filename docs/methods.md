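# Methods

`vwiloc` estimates the intracranial vessel tree of a subject from black-blood
vessel-wall MRI (VWI) alone, without the bright-blood angiogram (MRA) that
clinical pipelines normally use for localization.  The estimate is produced
by warping the vessel trees of reference subjects ("atlases", each with a
paired VWI/MRA and an extracted tree) into the target's coordinate frame:

1. **Stage one — model-based registration.**  Every atlas VWI is rigidly
   aligned to the target VWI and ranked by post-alignment mutual information;
   the top *k* (default 3) atlases then undergo a low-degree-of-freedom
   B-spline registration.  The affine and deformable transforms compose into
   a dense displacement field *d* on the target grid, in pull-back
   convention: resampling reads the atlas at *p + d(p)* for each target
   point *p*.  All displacement components are stored in millimetres.
2. **Stage two — learned residual correction.**  A 3-D attention-gated
   residual U-Net regresses the residual between the stage-one field and a
   reference field obtained (at training time only) by deformable MRA-to-MRA
   registration; adding the predicted residual corrects the stage-one field.
3. **Hybrid atlas integration.**  Per clinical segment (BA, vertebral,
   middle cerebral, internal carotid windows), the warped atlas with the
   highest local normalized cross-correlation against the target VWI
   provides the segment estimate.  The output tree only ever contains
   branches present in some atlas, so vascular topology is inherited rather
   than synthesized.

Because clinical VWI/MRA pairs are not distributable, every stage is
validated on a synthetic phantom cohort with known vessel trees and known
inter-subject deformations.

## Synthetic phantoms

`vwiloc.phantom` generates cohorts on a 48 x 96 x 80 grid at 2.2 mm isotropic
spacing — the working resolution the refinement network consumes (a 4x
downsampling of a typical 0.55 mm acquisition).  A reduced 24 x 48 x 40
option exists for desk-scale training studies.

* **Vessel trees** are curvature-bounded random walks: one root branch
  (radius tapering 2.4 to 1.5 mm) plus bifurcating children (>= 1.15 mm),
  all radii within [0.8, 2.5] mm.  Tubes are rasterized on a 2x supersampled
  subgrid and block-averaged, giving correct partial-volume fractions for
  millimetre tubes on the coarse grid.
* **MRA** is the tube occupancy times a bright lumen intensity on an exactly
  zero background, plus Gaussian noise (default sd 4 intensity units against
  a lumen of 100).
* **VWI** is a mid-gray background (60) modulated by a two-scale smooth
  texture field (10 mm lobe-scale and 4 mm parenchymal-scale components,
  ~16%/8% relative amplitude), a multiplicative bias field
  (exp of a random second-order polynomial, max +-20%), a dark lumen (15% of
  background) and a thin brighter wall ring spanning radius x [1.0, 1.3]
  (150% of background), plus noise.  The two texture scales matter: they are
  what gives any registration metric gradient information away from the
  sparse vessels, as real parenchyma does.
* **Subjects** are one hidden template warped through independent smooth
  random fields (cubic interpolation of random knot coefficients, default
  knot spacing 24 mm, amplitude normalized so the maximum displacement is
  3 mm), with freshly seeded bias and noise per subject.  Warps use
  edge-clamped padding so no artificial zero rim enters the images.  The
  amplitude is a free parameter reported with results; the study default of
  3 mm is not claimed to be clinically calibrated.  Tree points are mapped
  by numerically inverting the field (fixed-point iteration, tolerance 0.05
  voxel, max 20 iterations), keeping images and trees exactly consistent.

What the phantoms do **not** emulate: anatomically realistic
Circle-of-Willis topology, flow artifacts, pathology beyond radius taper,
multi-coil intensity profiles, or inter-subject variation beyond smooth
diffeomorphic warps.  Passing tests therefore demonstrate the machinery is
correct and that the pipeline's claims hold under its own assumptions — not
clinical-grade accuracy.

## Stage-one registration choices

Registration is SimpleITK-backed.  Rigid/affine alignment maximizes Mattes
mutual information (128 bins) with gradient-descent line search over a
two-level pyramid; sampling is exhaustive by default (deterministic) and 50%
seeded-random in the fast preset.  A divergence guard retries once with a
4x smaller step if a hard pair is marched out of overlap.

The deformable model is a **three-layer cascade of cubic B-spline grids**
with knot spacings of 24, 12 and 6 voxels, coarse to fine; each layer is
optimized (bounded L-BFGS-B, full-sampling MI at a coarsened resolution)
against the composition of all earlier stages, so the fine grid only models
what the coarse grids could not.  Two points deserve emphasis:

* *Physical knot pitch.*  "Control points every 12 pixels" at a 0.55 mm
  acquisition is a 6.6 mm pitch.  At the 2.2 mm working grid, a 12-voxel
  grid would be 26.4 mm — a four-fold stiffer transform whose best possible
  approximation of a 24 mm-scale deformation still leaves 46% of the
  deformation unexplained.  The finest cascade layer (6 voxels = 13.2 mm)
  is the closest the low-DOF floor (>= 4 voxels) allows to the physical
  pitch.
* *Complexity control.*  Every control-point coefficient is box-bounded
  (+-8 mm) inside the optimizer, not merely clipped afterwards.  With the
  default settings, phantom-scale registrations produce zero non-positive
  Jacobian determinants.

Histogram bins were raised from the conventional 32 to 128 because the
synthetic VWI concentrates intensities in a narrow band; at 32 bins the MI
objective is too coarsely quantized to drive sub-voxel B-spline updates and
optimization stalls or wanders.  128-bin full-sampling MI matches the
recovery quality of a MeanSquares oracle on the same problems.

Measured on ten independent 3 mm-amplitude phantom pairs at the working
grid: the composed stage-one field leaves 27-30% of the identity-baseline
mean displacement error (the acceptance suite recomputes this).

## The refinement network

Both wirings share one architecture: a 4-level encoder of residual blocks
(two 3x3x3 convolutions, voxel-wise skip from the block input, 1x1x1
projection when channel counts differ), filters 16-32-64-128, max-pooling by
2; a decoder of kernel-2 up-convolutions and residual blocks; one additive
attention gate per skip (``alpha = sigmoid(psi(relu(Wx x + Wh h + Wg g)))``
with x the encoder skip features, h the decoder signal at that level, g the
auxiliary attention input average-pooled alongside the encoder); a final
1x1x1 three-channel head with no activation, **zero-initialized** so the
untrained network is exactly the identity correction.  ReLU follows every
other convolution.

* DVF2dDVF: main input = stage-one DVF (3 channels, divided by 10 mm) + ROI
  mask; attention input = z-scored target VWI + (target − warped atlas)
  difference.
* IM2dDVF: main input = target VWI + warped atlas VWI + ROI mask; attention
  input = stage-one DVF (3 channels) + difference.

The ROI mask is the target-grid footprint of the affinely mapped atlas box
(the "parallelogram" mask); the loss is the mean squared residual error
over masked voxels.  The regression target is the residual between the
MRA-derived reference field and the stage-one field; the reference comes
from correlation-driven B-spline registration of the (same-modality,
high-vessel-contrast) MRA pair and is trusted only near vessels — exactly
where the warped atlas tree lives.

The tensor engine is a compact reverse-mode autodiff written for this
package (numba-jitted direct 3-D convolutions, float32 throughout, Adam,
batch size 1, deterministic for a fixed seed).  Optimizer defaults: Adam
1e-3, 200 epochs.

Desk-scale study (frozen conditions, recomputed by the acceptance suite):
17 reduced-grid subjects; 2 atlases x 10 targets = 20 training pairs; 5
held-out targets x 2 atlases = 10 test pairs; IM2dDVF with a width-reduced
ladder (4-8-16-32) for CPU tractability; 200 epochs.  The corrected field
lowers the masked RMSE against the MRA-derived reference on 8-9 of the 10
held-out pairs.

## Vessel extraction

Bright tubes are detected with the scale-normalized Hessian: eigenvalues
sorted by magnitude, bright-tube sign test (two large negative
cross-sectional eigenvalues), ``tubeness = sqrt(|l2*l3|)``, ``roundness =
|l2|/|l3|`` with a minimum of 0.2 (rejects plates).  The radius scale is
found by the literal recursion — start at 1.5 mm, shrink by 0.75x until a
tubular cross-section passes — with a numerical floor of 0.7 voxel on the
filter scale (sub-voxel Gaussian derivatives alias).  The acceptance
threshold is 10% of the volume's robust intensity range, defined as
max-minus-median of a lightly smoothed copy because vessels occupy well
under 1% of an angiographic volume and percentile spans miss them.

Centerlines are traced both ways from a seed by stepping 0.5 voxel along
the minor eigenvector with re-centering to the cross-sectional tubeness
maximum; the scale estimate is refreshed every 15 steps (and on failure) to
follow tapering vessels.  Trees grow over a few scans: endpoints *and*
lateral offsets of points along each traced tube (2 voxels, axis and
diagonal directions) seed the next scan; seeds inside already-claimed tubes
are skipped, and traces overlapping claimed tubes are trimmed to their
novel runs, which also yields parent/child topology at junctions.  Inputs
coarser than 1 mm are linearly upsampled before filtering.

Radius estimates saturate at the first passing scale and are only accurate
to ~50%; radius-accurate quantification is out of scope.

## Evaluation metrics

* One-direction percentile Hausdorff distance: for each ground-truth point,
  the distance to the nearest predicted point; the 80/90/100th percentile
  of that distribution (linear interpolation between order statistics;
  100% is exactly the maximum).  Extra predicted points are never
  penalized.
* DVF RMSE = root mean squared per-voxel residual component sum; MAE = mean
  per-voxel residual Euclidean norm; both in mm, optionally masked.
* Clinical validity: a segment whose worst centerline deviation (100%
  one-direction HD) is within 10 mm, boundary inclusive; success rate =
  percentage of valid segments.
* Point sets are densified centerlines (<= 0.5 voxel arc-length steps);
  tube-surface voxel sets are not used.

The cross-validation harness reproduces the six-fold protocol: 30 subjects,
25/5 train/test splits, each subject tested once, k = 3 atlases per target,
with the per-case 80/90/100% HD distribution table
(mean/std/min/quartiles/max), per-segment validity and per-fold success
rates; when ground-truth deformations are available (phantoms), per-case
DVF RMSE/MAE against the exact relative field between the chosen atlas and
the target are included.  The shipped harness configuration runs at the
reduced grid with the fast registration preset and a seeded 3-candidate
atlas pool per fold — problem sizes chosen so the whole validation suite
runs on a single CPU at desk scale.

## Numerical conventions and degenerate inputs

* Grids are axis-aligned; voxel index and world position are a bijection.
* Field inversion uses fixed-point iteration with edge-clamped field
  sampling; failure at more than 1% of points raises.
* Zero-variance patches in local NCC return 0 (flagged degenerate) rather
  than NaN; constant images are rejected before MI registration.
* Ties in atlas ranking and segment selection break toward the lower atlas
  id, so results are reproducible.
* All generators and trainers take explicit seeds; identical seeds give
  bit-identical phantoms and training traces.

## Known limitations

* The MRA-derived "reference" field is only meaningful near vessels; masked
  RMSE over the whole ROI therefore mixes vessel-relevant error with
  background disagreement between two imperfect registrations.
* The refinement study uses a width-reduced network and reduced grid; the
  default 16-128 ladder at the full working grid is implemented and audited
  but not trained in the test suite.
* Radius estimates from tracing are coarse (first-passing-scale).
* Phantom realism limits are listed above; no claim of clinical performance
  is made or implied.
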