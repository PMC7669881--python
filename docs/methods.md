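# Methods

This note documents the models, conventions and numerical choices behind
`octavasc`, in the order data flows through the package.

## Synthetic phantom

The generator emulates the statistical structure of an SD-OCT angiography
volume of fish brain: a bright parenchyma with multiplicative speckle,
horizontal intensity bands near the surface (skin, skull, pia mater), and
perfused vessels as dark tubes — blood flow decorrelates the speckle, so a
time-averaged scan retains little coherent signal inside the lumen.

* **Geometry.** Axis convention: `x` = fast lateral scan, `y` = slow scan,
  `z` = depth. Voxel spacing per axis is `fov / dims`; the reference fine
  scan is 0.95 × 0.70 × 1.91 mm over 768 × 256 × 1024 samples.
* **Vessels.** A vessel is a constant-radius tube around a polyline
  centerline. A voxel belongs to the lumen mask iff its center lies within
  one radius of the densified centerline (densification step: half the
  smaller of voxel pitch and radius). The mask is never anti-aliased.
  Rendered intensity inside the lumen is `lumen_level × background` with
  `lumen_level = 0.15` by default: real scans show dark but not black
  lumina, and a non-zero floor makes the half-maximum landmarks behave as
  on measured profiles. No quantitative lumen contrast is published for
  this preparation, so 0.15 is a package choice, exposed in the config.
* **Point-spread emulation.** `edge_smooth_voxels` (default 1.0) convolves
  the noise-free intensity with an isotropic Gaussian before noise is
  applied, emulating the finite system PSF. Symmetric smoothing leaves the
  half-maximum crossings of a tube profile at the true wall positions, so
  it does not bias the FWHM.
* **Speckle.** Multiplicative, per voxel, gamma-distributed with unit mean
  and shape `1/contrast²` (coefficient of variation = `speckle_contrast`).
  Gamma generalizes fully developed speckle: contrast 1 gives the
  exponential intensity statistics of a single coherence cell, smaller
  contrasts model N-look averaging. Detector noise is additive Gaussian.
  Identical seed and config give a bit-identical volume; `contrast = 0`
  disables the random draw entirely.
* **What the phantom does not model.** No branching-tree growth, no flow or
  temporal dynamics, no Doppler phase, no depth-dependent signal falloff,
  no refraction at layer boundaries. Passing recovery tests therefore
  demonstrates correctness of the measurement chain on ideal tubes, not
  segmentation performance on real anatomy.

## Preprocessing

Order is fixed: float conversion → Wiener → z-capping → 16-bit rescale →
non-local means. The display Gaussian is never part of the measurement
path. All windowed operations use reflective boundary handling; statistics
use the population convention (divisor *n*) throughout, which is also what
reproduces the reference diameter-table summary rows exactly.

* **Wiener (5×5).** Per cross-section adaptive filter: local mean/variance
  over the window, noise power = mean of local variances, gain
  `max(0, v−noise)/max(v, noise)`. "Cross-section" defaults to the x–z
  B-scan (the native acquisition frame) and is configurable.
* **z-capping.** Per (x, y) column: values strictly beyond mean ± 3·SD are
  set to the threshold. "Strictly" matters: a value exactly at the
  threshold passes through. A per-slice alternative reading exists; the
  per-column rule is the literal one and is what the config exposes.
* **Rescale.** Global min → 0, max → 65535, linear. A constant volume maps
  to zeros with a logged warning. The operation is idempotent.
* **Non-local means (3³ patch, 7³ search).** Weights
  `exp(−max(0, d² − 2σ²)/h²)` on patch distance `d` (scikit-image). No
  published filter parameters exist for this chain, so `h` defaults to
  `0.8 σ` with `σ` estimated robustly as the scaled median absolute
  deviation of the Laplacian response — insensitive to edges, exact for
  i.i.d. Gaussian noise.
* **Isotropic resampling.** Target spacing is the x pitch `fov_x/nx`;
  target dims are `round(fov_axis/spacing)` with halves away from zero;
  cubic spline interpolation by default. For the 1.58 mm wide scan this
  yields a z dimension of 928 (1910/2.0573 = 928.4); one published
  restatement of that geometry prints 929, which is not reproducible from
  the stated spacing, so the op documents its own rounding rule rather
  than matching it. Diameters are measured on the raw resampled volume,
  not the denoised one: measured profiles visibly retain speckle
  structure, and denoising before landmark detection would bias the wall
  steepness.

## Diameter estimation

* **Profile.** 7 parallel lines at unit-voxel perpendicular offsets,
  bilinear sampling at one-voxel pitch along the probe, averaged
  pointwise. The probe must cross the vessel and extend past the largest
  expected diameter on both sides; violations surface as ROI detection
  failures.
* **Spline.** Resampling to 100 points uses a not-a-knot cubic spline
  (reproduces polynomials up to degree 3 exactly; endpoints exact by
  construction).
* **ROI rule.** From the global interior minimum: maximum edge point on
  each side, then the nearest local minimum beyond it; fallback order is
  outer local minimum → outer steepest point → profile end. A profile with
  no interior dip is rejected.
* **Landmarks.** Steepest wall points are extreme first differences on the
  100-point profile, ties broken toward the vessel center. Half-maximum
  crossings are localized by linear interpolation between bracketing
  samples; when speckle produces several crossings, the one nearest the
  corresponding maximum edge point is taken, consistent with the
  outer-diameter intent. This guarantees `d ≤ D_edge`.
* **Conversion.** `D_FWHM = d·√(4/3)` is applied as a constant; it is the
  standard correction from the FWHM of a cylindrical absorption profile to
  the outer diameter as used by the ImageJ FWHM plugin lineage.

## Tortuosity

Thinning uses Zhang's algorithm (2D) / Lee's (3D) from scikit-image;
branches are maximal slab-voxel runs between endpoints (1 neighbor) and
junctions (≥ 3 neighbors) under 8/26-connectivity; path length weights
steps by their Euclidean voxel displacement (1, √2, √3 × spacing). The
longest branch (ties: larger chord, then deterministic lexicographic
order) is scored as path/chord.

Known numerical properties, measured by the test suite:

* the chain-length metric overestimates the length of oblique digital
  curves by up to ~8% (worst near 22.5° slopes); for curves whose
  direction distribution spans 0–90° (arcs, slope-1 sinusoids) the net
  error after skeleton-end erosion stays within 5%;
* thinning leaves a one-voxel diagonal tip at band ends, so very short
  straight segments score slightly above 1; at ≥ ~100 voxel lengths the
  effect is below 0.5%;
* thinning is not exactly rotation-equivariant; branch metrics on a fixed
  skeleton are (tested to 1e-9 under 90° rotation, 1% at mask level).

Moment summaries use population central moments: `sd = √m2`, skewness
`m3/m2^1.5`, excess kurtosis `m4/m2² − 3`. The excess convention is chosen
because tortuosity samples of interest here are small (n ≈ 6), where raw
kurtosis would be dominated by the +3 offset; zero-variance input makes the
higher moments undefined and is rejected.

## Resolution arithmetic

The axial pixel limit is `z_max/(N/2)` (1.91 mm, 2048 sensors → 1.865 µm).
The windowed axial resolution is defined as the FWHM of the amplitude
point-spread function of the tapered-cosine window: the window (taper
fraction = total tapered fraction, flat for `1 − α`) is zero-padded 16×,
the magnitude of its DFT is measured at half maximum with linear
interpolation between bins, and the width in depth-pixel units multiplies
the pixel limit. This machinery reproduces the standard window-table
values exactly (rectangular → 1.2067 pixels, Hann → 2.000 pixels); for
taper 0.4 it gives 1.489 pixels = 2.78 µm. In-medium values divide by the
refractive index. Lateral spot size versus scan angle is out of scope: it
depends on lens-aberration modeling that cannot be reproduced from design
parameters alone.

## Problem sizes in the test suite

Recovery tests run on ~120³-voxel phantoms at 1 µm pitch with tube
diameters 6–30 voxels, arcs of 40-voxel radius, and a 64³ region for
speckle-mean checks — large enough that digitization effects, not sample
size, dominate the error terms quoted above, and the whole suite runs in a
few seconds.
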