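# Methods

This note records the models, conventions, parameter choices and known
limitations of the drrmatch pipeline.

## Coordinate and intensity conventions

CT volumes are arrays indexed `(z, y, x)`: z runs superior→inferior
(slice 0 most superior), y is the axial row (anterior→posterior for a
supine acquisition), x the axial column. Spacing is `(dz, dy, dx)` in mm.
The inter-slice spacing dz is the median of consecutive slice-*position*
differences, never the slice-thickness tag — thickness and reconstruction
increment differ in overlapping reconstructions. Series whose gaps deviate
from the median by more than 1% are rejected rather than silently
resampled, because resampling would corrupt downstream geometry without
the user noticing. Filenames never influence slice order.

Loaded 2D images are min–max normalised to [0, 1]; MONOCHROME1 DICOM data
are inverted so bone is bright, matching the DRR convention.

## Segmentation

Bone extraction is a band-pass voxel test, foreground iff `t1 < HU ≤ t2`.
The half-open interval (strict lower, inclusive upper bound) is the
package's fixed reading of the band; it only matters at the two exact
boundary values and is asserted by a dedicated test. The default band
(200, 3000) HU spans trabecular to cortical bone while excluding metal;
both ends are configurable.

Region growing compares each candidate voxel against the HU value of the
*originating seed* (not a running region mean) under 6-connectivity. A
fixed reference makes the result independent of visit order, hence
deterministic; it is implemented as the seed's connected component inside
the admissible set `|HU − HU(seed)| ≤ tol`, which is equivalent to
breadth-first growth (property-tested against a BFS oracle). The
tolerance has no universally correct value — it plays the role an
operator's interactive corrections play in commercial tools — so it is an
explicit parameter (CLI default 300 HU, logged).

Mask splitting is pure 6-connected component labelling, relabelled by
descending voxel count with positional anatomical names. Meshing is
marching cubes at iso-level 0.5 on a one-voxel zero pad (so boundary
structures still produce closed surfaces), with vertices scaled to mm.

## Virtual screw

The screw/guide is a parametric cylinder — entry point, unit direction,
length, radius — or an STL mesh already posed in volume space. Typical
clinical dimensions (length 70–90 mm, radius 3.25 mm) are the config
examples; the defaults are 80 mm × 3.25 mm. Voxelization is a
voxel-centre membership test with no partial-volume antialiasing: this
keeps fused voxels exactly at `fuse_hu` (default 3000 HU, metal-like but
below the signed 16-bit ceiling), so a MIP attains `fuse_hu` precisely on
the screw's projected footprint and the screw is unambiguous in every
DRR. Mesh voxelization uses an even–odd ray cast per (z, y) grid cell
with a sub-nanometre ray-origin nudge to avoid counting shared triangle
edges twice.

## DRR generation

DRRs are parallel-ray maximum-intensity projections along the
anteroposterior axis of the volume rotated in-plane about z. Positive θ
is counterclockwise in the axial plane viewed from superior, 0° the
native AP orientation; a `flip_sign` flag covers the opposite convention,
which is not standardised across vendors. Rotation uses bilinear
interpolation about the slice centre with out-of-domain samples set to
−1000 HU (air); a nearest-neighbour mode exists for exact permutation
oracles. No ray-sum (attenuation) or divergent-beam geometry is
implemented — the MIP formulation is the method being modelled, and MIP
commutes with monotone intensity maps, a property the tests exploit.

An angle ladder `base ± half_range` in steps of `step` (default 1°, the
granularity at which adjacent pelvic views become distinguishable)
produces the series; angles are stored canonically in [0, 360) and
reported normalised to (−180, 180], so the standard 30° protocol reads
345°…15° raw and −15°…+15° normalised.

## Histogram matching

Classical histogram specification over `bins` levels (default 256): the
input is pushed through its own CDF and then through the monotone inverse
of the reference's CDF; outputs are reference bin-centre intensities, so
the output range is contained in the reference range. Constant images are
rejected (the inverse is undefined). The sup-distance between the matched
output's empirical CDF and the reference's is bounded by ~2/bins, which
is the accuracy test.

## Demons registration

Thirion's original demons with the fixed-image gradient:
`v = (m − s)∇s / (‖∇s‖² + (m − s)²)`, force zeroed where the denominator
falls below `intensity_eps` (1e-9). The field is updated additively and
Gaussian-smoothed each iteration — diffusion-like regularisation.
Defaults: 3 pyramid levels with (100, 50, 25) iterations
coarsest→finest, σ = 2.0 px, early stop when the mean update drops below
1e-3 px. A symmetric-forces variant (averaging fixed and warped-moving
gradients) exists but is off by default. Warping is backward with
bilinear interpolation and edge clamping, so warped intensities stay
inside the moving image's range. The whole procedure is deterministic;
two runs produce bit-identical fields.

The literature sometimes files demons under "affine" registration; it is
in fact non-parametric (a dense displacement field). We implement the
dense-field method the update equation describes.

**Known limitation — multimodal pairs.** Demons minimises squared
intensity difference. When two images of identical geometry differ by a
monotone nonlinear intensity map (e.g. a gamma curve), the SSD optimum is
*not* at zero deformation: the field distorts geometry to compensate
intensity, and global correlation can decrease. This is not an
implementation artefact — SimpleITK's `DemonsRegistrationFilter` shows
the same behaviour on the same pair — but the classical reason SSD
methods need intensity normalisation across modalities. The pipeline's
histogram-matching step exists precisely for this; with it, registration
reliably increases correlation on gamma-distorted pairs, and that is the
property the test suite asserts.

## Similarity metrics

SSIM uses the standard stabilised form with `C1 = (0.01 L)²`,
`C2 = (0.03 L)²` and local statistics in Gaussian windows (σ = 1.5 px,
truncated at 3.5σ ⇒ 11×11); the mean over the valid interior is
reported. A `global_window` flag evaluates the formula once on
whole-image statistics (used by the closed-form oracle tests). Raw SSIM
can be negative for anticorrelated structure; the angle-search table
clamps reported values at 0 and logs the raw value. Correlation is
evaluated literally as Σ(xᵢ−x̄)(yᵢ−ȳ) / √(Σ(xᵢ−x̄)² · Σ(yᵢ−ȳ)²), clipped
to [−1, 1].

## Angle search and consensus

Per angle: DRR → isotropic resampling → min–max normalisation (after
1st–99th percentile clipping, which stabilises the scale against isolated
bright pixels) → resize to the reference's working grid → optional
histogram matching → demons → SSIM and correlation of warped vs
reference. The reference itself is capped at 512 px on its longest side;
registering multi-megapixel radiographs at native resolution buys no
angular discrimination and costs an order of magnitude in time.
Histogram matching defaults to off in the search: it changes the metric
landscape substantially and its benefit is data-dependent, so it is an
explicit flag rather than silent preprocessing.

Each metric nominates its argmax (ties broken toward the smaller
|normalised angle|, then the smaller angle). The consensus is the common
nominee when they agree, otherwise the nominee nearer the base
projection, a residual tie going to the higher SSIM. The rationale: the
base angle encodes the prior that the patient's pose is close to the
planned AP view, so between two metric optima the less surprising one is
preferred.

## Synthetic phantom

The phantom emulates what the pipeline needs from a pelvis CT, not
anatomy: an air background (−1000 HU), a soft-tissue ellipsoid (40 HU),
and bone primitives (1200 HU) — two iliac-wing ellipsoids, a sacrum
ellipsoid, a pelvic-ring torus, two femoral cylinders — plus additive
Gaussian CT noise (30 HU, a typical abdominal reconstruction level),
clipped to the valid HU range. The left wing is deliberately enlarged:
a left-right symmetric phantom makes ±θ projections indistinguishable and
would invalidate pose-recovery tests for spurious reasons. The default
grid is 128³ at 1 mm isotropic — large enough that 1° steps produce
distinguishable projections, small enough for minute-scale test runs.

The pseudo-X-ray is the DRR at a ground-truth pose θ* (default 5°) passed
through a gamma curve (1.8), Gaussian blur (1 px) and additive noise (2%
of range), emulating the monotone response difference, detector blur and
noise of computed radiography. It does **not** model scatter, beam
hardening, divergent-beam magnification, patient tilt out of the axial
plane, or overlying soft-tissue contrast; passing tests therefore show
the chain recovers pose under a monotone intensity gap plus noise, not
that it handles every clinical confound.

## Problem sizes in tests and the acceptance script

Oracle-equivalence checks run on random volumes up to 16³ and images up
to 32² (100 trials), where exhaustive loops are exact and fast. The
end-to-end study uses 10 independent 128³ phantoms, each searched over 31
angles at the natural 128² working grid; recovery within ±2° of θ* is the
success criterion. These sizes were chosen so the full suite and the
acceptance script each complete in a few minutes on a single CPU while
keeping every stage of the method exercised at realistic anisotropy and
noise levels.
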