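# Methods

## Imaging model and assumptions

A multi-view light-sheet acquisition is modelled as four registered views
of the same specimen, rotated in 90° steps about a common axis (y in the
package's (x, y, z) convention). Each view `i_v` is the object `e`
convolved with that view's point spread function `f_v` plus noise. The
PSFs are assumed spatially constant within a view and related across views
by exact 90° rotations about y, so a single 3D PSF determines all four.
Views are assumed registered to a common isotropic grid; registration
itself is out of scope (the preprocessing module provides dark-offset
subtraction, cubic axial resampling to isotropic voxels, and zero-padding
to a cube, i.e. the steps that make a raw stack registrable).

Multi-view deconvolution estimates `e` by Richardson–Lucy (RL) iterations

    e ← e · ((i_v / (e ∗ f_v)) ∗ b_v)

cycled over the views. Because the detection-axis blur of every view lies
in the x–z plane (the rotation maps the axial direction of one view onto
the lateral direction of another), the 3D problem nearly factorizes: a 2D
PSF (the central x–z plane of the 3D PSF) captures the in-plane blur, and
a 1D PSF (the central y column) captures the residual cross-plane blur.
The 2D+1D method exploits this: slice-wise 2D multi-view RL in the x–z
planes, then single-view 1D RL along y. For an exactly separable PSF
(PSF3D = PSF2D ⊗ PSF1D) the factorization loses no information; measured
PSFs are approximately separable.

## The weighted update rule

How per-pixel fusion weights enter the sequential RL update is a genuine
design choice. This package uses

    e ← e · (1 − W_v + W_v · c_v),   c_v = (i_v / (e ∗ f_v)) ∗ b_v ,

where the fractional weights `w_v` (one per view, summing to 1 at every
pixel) are rescaled per pixel by the largest view weight,
`W_v = w_v / max_u w_u`. Rationale: with the raw fractions (`w ≈ 1/4` for
four views) every correction would be damped four-fold, which merely
relabels the iteration axis — the optimum would move from ~5 to ~20
iterations without changing the attainable quality. Rescaling lets the
highest-contrast view apply the full RL correction, so iteration counts
keep the meaning they have for classical sequential (ordered-subsets) RL,
and the familiar behaviour — optimum near 5 iterations for the accelerated
2D scheme, artifacts well before 15 — is preserved. The update reduces to
plain RL for a single view, is a no-op where a view has weight 0, and
leaves data consistent with the forward model fixed.

Weights are computed once per slice from the registered input views, not
recomputed per iteration: they encode acquisition properties (scattering
and absorption along each optical path), not properties of the evolving
estimate.

## Back projectors

* `matched` — `b_v` is the axis-mirrored `f_v`; classical RL, slowest but
  most faithful convergence.
* `opt1` — mirrored `f_v` convolved with all other views' PSFs.
* `opt2` — one compound kernel, the inverse transform of the product of
  all views' OTFs, shared by every view; fastest convergence.

The default is method-dependent: `opt2` for the slice-wise 2D schemes and
`matched` for the full-3D reference. The accelerated compound kernel is
what makes ~5 iterations optimal for 2D fusion, but in 3D it necessarily
includes a y-blur (for four views of a Gaussian PSF with lateral σ = 1.05
vox, the compound kernel has σ_y ≈ 2.1 vox), which smears corrections
along the rotation axis and measurably erases the quality advantage that
motivates running full 3D in the first place. Matched 3D RL converges more
slowly (~8 iterations) but to a better estimate, reproducing the expected
quality ordering 3D < 2D+1D < 2D in mean squared error. Both choices can
be overridden via `FusionConfig.backprojector`.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| iterations, 2D MVD | 5 | sweeps | optimum of the accelerated (opt2) scheme before noise amplification |
| iterations, extra 1D | 3 | sweeps | diminishing returns beyond ~3 on four-view data |
| iterations, 3D MVD | 8 | sweeps | matched 3D RL converges more slowly than opt2 2D |
| weighting | entropy | — | contrast proxy; suppresses scattered/absorbed views |
| entropy patch | 11 × 11 | px | large enough for a stable variance, small enough to stay local |
| content-mask blur | 20 | px | smooth roll-off of data/weights; suppresses FFT edge ringing |
| 1D blend blur | 5 | px | same role for the columns along y |
| PSF (synthetic) | σ = (1.05, 1.05, 5.2) | vox | ≈ 2.0 µm lateral / 9.9 µm axial FWHM at 0.806 µm voxels, typical measured single-view bead widths |

## Numerical choices

* **Convolution** is zero-padded *linear* convolution via FFT
  (`scipy.signal.fftconvolve`); circular wrap-around would defeat the
  apodization masks. For slice-wise operation the transform is restricted
  to the x–z axes with the 2D kernel broadcast along y, so a slab of
  slices is processed in one vectorized call. The FFT path is verified
  against a direct shift-and-add spatial implementation to 1e-8.
* **Division guard**: zeros of the blurred estimate `e ∗ f` are replaced
  by 1 before the division; the ratio numerator and the back-projected
  correction are floored at 0 against FFT round-off. Estimates therefore
  stay nonnegative at every iteration.
* **Entropy clamp**: `H = ½ ln(2πeσ²)` is negative for
  σ² < 1/(2πe) ≈ 0.0585, which would make fractional weights ill-defined;
  σ² is clamped below at that value so flat patches get H = 0 (and weight
  0 wherever another view has texture). Patch variance is the population
  variance over a mirror-padded square patch.
* **Degenerate weights**: where the weight denominator vanishes (no view
  has content or all patches are flat) weights fall back to uniform 1/N —
  any convex combination is acceptable where no view carries information.
* **Masks** are applied once to the input views and once to the final
  estimate, not re-applied every iteration.
* **Axial resampling** uses a not-a-knot cubic spline along z only, with
  `n_out = round((n_in − 1)·step_z/voxel_xy) + 1` samples starting at the
  first slice position (endpoint-preserving, no extrapolation; the last
  sample is clipped to the input range). Constant and polynomial (≤ cubic)
  profiles are reproduced exactly; overshoots are clipped at 0.
* **Block processing**: the slice-wise scheme works on y-slabs whose size
  is either user-set or chosen from a memory budget; blocking is purely a
  scheduling concern and the result is identical (to floating-point
  associativity) for any block size.
* **Bead detection** keeps local maxima above a relative threshold,
  greedily pruned brightest-first (lexicographic coordinate order breaks
  ties) to enforce a minimum pairwise separation. FWHM is measured on the
  1D profile through the peak after subtracting the profile minimum, with
  half-maximum crossings located by linear interpolation; profiles clipped
  at the volume edge are rejected. Per-axis FWHM distributions are
  summarized by a least-squares fit of a cumulative normal to the
  empirical cumulative fractions (Hazen plotting positions); if the fit
  fails the sample mean ± SEM is reported and flagged.
* **MSE against ground truth** is computed after a least-squares gain fit
  (deconvolution does not pin the absolute intensity scale); PCC is
  scale-free and serves as the cross-check. The plain `mse` is symmetric.

## What the simulator emulates — and what it does not

`simulate` generates a ground-truth phantom (an aster of ~1-voxel-wide
anti-aliased lines with a brighter central body, resembling the
microtubule cytoskeleton of a dividing cell, or a field of single-voxel
"beads"), then for each view: rotates into the view frame (exact 90°
permutations; oblique angles are rejected rather than resampled),
attenuates exponentially with depth along the detection axis
(Beer–Lambert, default decay length half the volume extent;
excitation-side attenuation is neglected as appropriate for two-sided
illumination), convolves with the 3D PSF, applies Poisson noise at a
photon budget (default 1000 expected photons at unit intensity) followed
by zero-mean Gaussian read noise (default variance 1.6e-5 on the [0, 1]
scale), clips at 0 and rotates back. Views are therefore delivered
registered, with independent seed-offset noise streams per view.

Not emulated: registration errors, spatially varying or aberrated PSFs,
stripe artifacts, depth-dependent PSF broadening, sample motion, camera
fixed-pattern noise. Passing tests on this simulator therefore demonstrate
the correctness and the relative behaviour of the fusion algorithms under
the stated model, not robustness to those real-world effects — in
particular, real 2D-MVD results can degrade along y through slight
misregistration, which the simulator cannot show.

For the bead-resolution study the conditions emulate a bright, clear
gel phantom: photon budget 1e5, read-noise variance 1e-8 and attenuation
length 4× the volume extent. A blurred bead peak carries only ~0.7% of the
nominal intensity scale, so the line-phantom noise defaults would drown
sub-resolution beads that are, in reality, bright and imaged in a nearly
transparent medium.

## Problem sizes

The test suite and the reproduction script use scaled-down volumes chosen
to exercise every code path at full fidelity: 128³ for the standard
four-view method comparison (15-iteration MSE/PCC curves for all three
methods), 96³ for the bead study (12 beads, ≥ 20 vox apart), 64³ for the
separable-PSF exactness check, and 16³–48³ for unit-level properties. The
separable-PSF check compares 2D+1D and 3D at the same back projector
(opt2) and each at its best iteration count, so that the only varied
factor is the dimensionality split itself.

## Known limitations

* View angles restricted to multiples of 90°; arbitrary-angle fusion would
  require resampling rotations and is out of scope.
* One PSF per view, constant across the field of view.
* RL converges slowly on structures at or below the voxel scale: thin-line
  phantoms retain substantial residual error at practical iteration
  counts, so ground-truth PCC values plateau well below 1 even without
  noise. Method *comparisons* are unaffected, but absolute quality numbers
  depend strongly on phantom structure.
* The streaming (from-disk) processing mode and GPU acceleration are not
  implemented; the CPU path is the reference.
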