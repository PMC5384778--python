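# Methods

`dosewarp` aligns a moving CT volume (typically a brachytherapy acquisition
with an applicator in place) to a fixed planning CT and uses the resulting
spatial transform to map fraction dose grids into the fixed frame for
voxelwise accumulation.  This note describes the model, the numerical
choices, and what the synthetic phantom does and does not establish.

## Transform model

The total transform is additive:

    T(x) = T_global(x) + sum_k u_k(x)

`T_global` is rigid (rotation + translation) or affine (adds scaling and
shear).  Each `u_k` is a free-form deformation (FFD): a displacement field
parameterised by an `n_x x n_y x n_z` lattice of control points with uniform
world spacing `delta`, interpolated by tensor-product uniform cubic B-splines
over the 4x4x4 neighbourhood of each point.  Coefficients are world-space
displacements in millimetres.  All local fields are evaluated at fixed-frame
coordinates and summed — local fields are never composed through one
another.  Warping is pull-back: the transform maps fixed-frame points into
the moving frame, and the warped image samples the moving volume there.

Control points outside the stored mesh contribute zero (virtual zero
padding), so a lattice's field decays smoothly to exactly zero two control
spacings away from its last non-zero coefficient.  Lattices are sized to
cover the fixed-image domain plus a one-spacing margin.

An ROI-constrained lattice has two evaluation modes:

* **smooth** (default): the spline is evaluated everywhere; only control
  points whose node lies inside the ROI dilated by one spacing are free to
  move, and the field decays naturally outside.
* **strict piecewise**: the displacement is the spline sum inside the ROI and
  exactly zero outside, reproducing the literal ROI-restricted definition.
  This trades a discontinuity at the ROI boundary for exact confinement.

## Similarity metrics

The joint intensity histogram uses equal-width bins spanning each image's
[min, max] over the evaluation mask, hard assignment (no Parzen windows),
and entropies in nats.  Normalised mutual information
NMI = (H(A)+H(B))/H(A,B) is the default registration metric; mutual
information, joint entropy, mean squared difference, Pearson correlation
(CC) and the correlation ratio are also available, all normalised internally
to "larger is better".  CC between the fixed volume and the warped moving
volume is the evaluation surrogate reported after registration.

Numerical choices:

* The public similarity functions default to 64 bins.  Inside the
  registration the bin count is capped per pyramid level at roughly
  `sqrt(n_samples / 8)` (at least 8) so the joint histogram stays populated
  on coarse levels; a 16^3 level would otherwise spread ~4 k samples over
  4 k cells and produce a useless gradient.
* Histogram ranges are frozen per resolution level from the images at the
  start of the level, so the objective is stationary during optimisation.
* Metric sampling in the *linear* stage clamps out-of-footprint positions
  to the volume edge instead of padding.  Strict padding makes the
  objective discontinuous exactly on the aligned-grid manifold (a boundary
  plane of samples sits exactly on the footprint edge and flips to the pad
  value under an infinitesimal rotation), which stalls gradient ascent from
  the aligned starts that reorientation produces.  The FFD objective keeps
  strict padding: it starts from a non-degenerate linear initialisation, and
  the pad penalty constrains boundary drift of the deformation, which
  measurably improves ground-truth field accuracy.  The public resampling
  and warping operations always keep the exact-pad contract.

## Optimisation

Deterministic regular-step gradient ascent (no randomness anywhere): the
gradient is the central finite difference of the objective; each iteration
moves along the gradient normalised by its largest component, so the step
length is the largest single-parameter move in native units (mm for
translations and control-point displacements, 0.01 rad / 1 % scale units for
rotations and affine entries).  The step halves on rejection, doubles back
(capped at its initial value) after an acceptance so one noisy rejection
does not strand a level at a tiny step, and the level ends when the step
falls below `min_step` (initial/64), the gain falls below `tol` (1e-5), or
the iteration budget is exhausted.  A steepest-descent variant with
golden-section line search is available.  Defaults: finite-difference step
0.5 mm; initial step 0.4 x control spacing for FFD, 1 unit for linear
models.

For FFD parameters the NMI gradient is computed incrementally: perturbing
one control point only moves the samples inside its 4x4x4-cell support, so
only their histogram contributions are re-binned (and reverted), which
equals full recomputation to floating-point roundoff and reduces the cost
per gradient from O(P * V) to O(P * s) with `s` the support size.  Frozen
control points (`free_mask` false) are never perturbed and keep their
coefficients bit-exactly.

## Multi-resolution protocol

Three pyramid levels by default: Gaussian smoothing (sigma = 1 voxel) then
x2 decimation per coarser level.  The FFD lattice starts at 20 mm control
spacing on the coarsest level and is halved per finer level by B-spline
subdivision (stencils (1,6,1)/8 and (1,1)/2), which represents the coarse
displacement field exactly on the refined lattice.  Coarser levels receive a
larger iteration budget (x2 per level of coarsening) because their
iterations are orders of magnitude cheaper and most of the capture range is
resolved there.

## Multi-phase (LFFD + FFD) strategy

For locally large deformations (the thigh repositioning induced by the
applicator), plain intensity FFD is initialised too far from the optimum in
the affected region.  The multi-phase strategy first fits a
**landmark-driven FFD (LFFD)**: paired landmarks placed in the region of
interest drive a lattice covering the whole domain whose free control points
are restricted to the ROI.  Because the displacement is linear in the
coefficients, the mean-squared landmark distance plus a small ridge penalty
(1e-6 by default, handling under-determined systems) is minimised in closed
form; a cascade of lattices at 40 / 20 / 10 mm spacing is fitted to the
successive residuals.  The intensity FFD then runs on top with the LFFD
lattices frozen, so the landmark correction is never undone.

The LFFD lattices use the strict piecewise ROI mode by default.  At clinical
volume sizes the smooth mode's spill-over (two control spacings, 80 mm at
the 40 mm level) is a local effect, but on a desk-scale phantom it covers
most of the volume and corrupts already-aligned tissue; the strict mode is
scale-independent.  The boundary discontinuity it introduces is partially
smoothed by the subsequent free-everywhere intensity FFD.

## Dose accumulation

Each fraction dose is pulled back onto the reference grid through its
registration transform (linear interpolation, exactly 0 Gy outside the dose
footprint) and the grids are summed voxelwise with the reference dose.
Summation is pointwise physical dose in input order; radiobiological
weighting (EQD2) and energy/mass-preserving resampling are deliberately out
of scope.  Accumulation refuses geometry mismatches rather than resampling
silently.

## Synthetic phantom

The generator emulates the paired-CT setting analytically.  An intensity and
label *scene* is defined as a function of world coordinates: an elliptical
soft-tissue body, a high-intensity pelvic bone ring, bladder / rectum /
tumour blobs, and two lateral thigh cylinders whose femur-like cores taper
along the axis and carry a "femoral head" sphere and a marrow intensity
gradient — the axial structure matters, because translation-invariant
cylinders would leave intensity metrics blind to axial misregistration.
Smooth multi-scale cosine texture (amplitude 15 HU-like units, wavelengths
25-60 mm) gives the intensity metrics gradients inside otherwise uniform
tissue.

The moving volume samples the scene directly; the fixed volume samples it at
`T_truth(x)`, so pulling the moving volume back through `T_truth`
reproduces the fixed volume with no resampling error, and landmark pairs
satisfy `q = T_truth(p)` exactly.  `T_truth` is a sampled global motion
(rotations up to ~1.7 degrees, translations up to 5 mm, optionally affine)
plus a smooth background FFD on a 40 mm lattice (4 mm peak displacement by
default) plus a large deformation confined to a thigh ROI on a 24 mm lattice
(12 mm peak by default, a coherent push with node-level variation).  Local
fields are rescaled so their maximum displacement equals the requested
amplitude exactly.  Applicator-like noise adds bright impulse voxels
(3 x the tissue maximum) inside a central tube in the moving volume only.
Everything is bit-reproducible from one integer seed.

What the phantom does *not* emulate: realistic CT noise and artifact
spectra, intensity differences between acquisitions (both volumes share one
scene, so even mono-modality metrics face no intensity mismatch), sliding
organ interfaces, and applicator geometry itself (only its bright-voxel
noise).  Passing the phantom suite therefore demonstrates correct mechanics
and the qualitative strategy ordering under known ground truth, not clinical
accuracy.

## Problem sizes and study design

The strategy-comparison study registers ten phantoms (48^3 voxels, 2.5 mm
spacing, defaults above) end to end per strategy — no registration, affine,
FFD, LFFD+FFD — on median-denoised volumes, plus the same FFD run on the raw
noisy volumes for the denoising comparison; 12 ascent iterations on the
finest level (scaled up on coarser levels) are used throughout.  The
dense-field recovery check uses a 64^3 phantom with a smooth 4 mm truth
deformation and no ROI component.  These sizes keep a full study within
desktop minutes while leaving the deformations several voxels large;
`scripts/acceptance.py` reruns the same protocol at three seeds.

## Known limitations

* No diffeomorphism enforcement; the evaluation report includes the minimum
  Jacobian determinant as a folding indicator, nothing more.
* The intensity FFD optimises NMI only; the other metrics are available for
  linear registration and evaluation.
* Oblique (non-axis-aligned) volumes must be reoriented/resampled before
  registration; the engine requires axis-aligned grids.
* Hard binning makes the objective piecewise smooth; with few samples or
  weak structure along an axis the finite-difference gradient can be noisy
  relative to the signal, which slows convergence along that axis.
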