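# Methods

This note records the models behind `cbctpost`, the parameter choices that
matter, what the synthetic phantom does and does not emulate, and the
numerical conventions that make every readout deterministic.

## Adaptive non-local-means denoising

The filter is the classic patch-weighted average with an explicit
self-weight.  For voxel `x` with search window `S(x)` (the centre excluded)
and patch operator `V(·)`:

    f(x) = ( Σ_{y∈S(x)} w_y f_ori(y) + w_ori f_ori(x) ) / Z
    w_y  = exp( −‖V(x) − V(y)‖²₂ / h² ),   Z = Σ w_y + w_ori.

`‖·‖²₂` is the plain (unnormalised) sum of squared patch differences; the
patch-size scale is absorbed into the bandwidth via `h = k·σ̂·√P` (`P` =
patch voxel count), so `k` has the same meaning at any patch size.
Design choices:

- **Search window**: radius 11 per in-plane axis (23×23), processed 2D
  per slice by default.  A full 3D search at this radius costs three
  orders of magnitude more patch comparisons per voxel for marginal gain
  on axially sampled CBCT; a 3D mode exists for isotropic data.
- **Patches**: radius 2 (5×5).  Standard NLM practice; configurable.
- **Self-weight `w_ori = 1`**: equal to the weight an exactly matching
  patch would receive — a neutral choice that keeps the filter from either
  freezing or discarding the original value.  The centre voxel appears
  only in the `w_ori` term, never in the neighbour sum, so it is not
  double-counted.
- **Bandwidth factor `k = 1`** (default `h_factor`): chosen empirically on
  the synthetic phantom by trading flat-region noise suppression against
  insert-contrast retention.  At the default study conditions `k = 1`
  suppresses flat-region SD roughly tenfold while retaining ~50–70 % of
  low-contrast insert amplitude; smaller `k` (0.6–0.8) preserves contrast
  better but denoises 3–4× less, larger `k` (≥1.2) trades visible
  contrast loss for little extra smoothing.
- **Noise adaptation**: `σ̂` is estimated per block (default 32×32 voxels)
  as the median absolute deviation of the 3×3 Immerkær
  Laplacian-difference response divided by `6·Φ⁻¹(0.75)`, which is
  unbiased for white Gaussian noise on flat blocks and annihilates
  constant and linear trends.  The MAD makes the estimate robust to sparse
  edges inside a block; densely textured blocks (e.g. bar patterns) still
  inflate `σ̂` and are smoothed harder — acceptable for the pipeline's
  purpose, since resolution readouts are made on unprocessed or
  explicitly blurred images.  `h` uses the block of the voxel being
  denoised.  Blocks with `σ̂ = 0` bypass the filter entirely (the h→0
  limit of the weights with `w_ori > 0` is the identity).
- **Borders**: mirror padding for both patches and search windows.
- Weights are a convex combination by construction: the output at every
  voxel lies within the range of its search window, and a constant image
  is a fixed point.  Both properties are asserted in the test suite, as is
  voxelwise agreement (≤1e−10) with an independent brute-force
  implementation of the definition above.

## Adaptive scatter correction from a planning CT

Scatter shading in reconstructed CBCT is smooth and low-frequency, while a
planning CT of the same anatomy is essentially scatter-free.  With the
prior already registered to the CBCT grid (registration is a precondition,
not a stage of this package), the additive artifact field is estimated as:

1. classify prior voxels by HU thresholds (air < −800 ≤ soft < +300 ≤ bone);
2. winsorize the per-voxel residual `cbct − prior` to each class's central
   [2, 98] percentile window — classes holding under 1 % of the voxels use
   the global window;
3. Gaussian low-pass at 25 mm (per axis, in voxel units of each spacing);
4. clip to ±200 HU; subtract.

The class-percentile winsorization, rather than replacing each class by a
single scalar offset, is deliberate: a per-class constant cannot represent
a spatially varying field such as cupping, whereas the winsorized residual
keeps the field's spatial structure while suppressing gross outliers from
residual misregistration or genuine anatomical difference.  The class
thresholds still control robustness per tissue type, and two limits hold
exactly: identical volumes give a zero field, and a spatially constant
residual is recovered exactly (its percentile window is degenerate).  On
the default phantom a −60 HU cupping field (80 mm scale) is recovered with
~17 % interior RMS error; the residual error is dominated by the smoothing
bias of the 25 mm low-pass against the field's curvature — a smaller
`smoothing_sigma` recovers smooth fields more faithfully but suppresses
noise in the residual less.

## Synthetic phantom

The generator emulates the three modules of a Catphan-604-style phantom on
one stacked grid (default 256×256 in-plane, 0.8 mm pixels, 2 mm slices, 20
slices: 4 sensitometry + 8 uniformity + 4 line-pair + 4 ramp; the clinical
512×512 matrix is available by configuration):

- **Sensitometry**: air (−1000), Teflon (+990), LDPE (−100) and acrylic
  (+120) inserts of 12.2 mm diameter on a water-equivalent (0 HU) body
  disk — nominal textbook HU, configurable; membership is by voxel centre
  so insert means are exact by construction.
- **Uniformity**: a uniform 100 HU disk (the SNR readout needs a nonzero
  mean).
- **Line pairs**: square-wave bar gauges at 1–6 lp/cm (bar 600 / gap
  0 HU), area-sampled along the pattern axis so partial-volume pixels are
  honest.
- **Ramp**: a thin wire inclined at 23° to the axial plane,
  partial-volume integrated per slice; its in-plane footprint length is
  `slice_thickness / tan(angle)` by construction.  The wire's sub-slice
  z-extent dilution is absorbed into the configured wire contrast.

Corruption is additive: a scatter-like field (uniform offset, radial
cupping normalised to its amplitude at the in-plane rim, or an off-centre
Gaussian blob) plus i.i.d. Gaussian noise.  The exact field is returned as
ground truth.  When no noise sigma is given it is calibrated analytically
so the unprocessed uniformity SNR (percent scale) hits 70 — the
upper-middle of the ≈25–90 range plain-FDK reconstructions occupy, i.e.
the body-protocol regime; with the default geometry this puts sigma near
115–120 HU.

What the phantom does **not** emulate: projection-domain physics (Poisson
statistics, beam hardening, detector lag), spatially correlated
reconstruction noise, streaks, motion, or anatomical structure.  Passing
tests therefore demonstrate that the pipeline behaves as designed on its
own model of noise and shading — white noise plus smooth additive fields —
not that clinical images will realise the same gain factors.

## Metric conventions

- Percentiles by linear interpolation between closest ranks; SD is the
  population SD.  Both conventions are fixed so the modulation readout is
  deterministic; at the ROI sizes used the sample/population difference is
  negligible.
- Modulation `(S90 − S10)/(S90 + S10)`; undefined when the denominator is
  zero.  The MTF low-frequency reference is the maximum modulation across
  gauges; MTF50 is read off by linear interpolation between the bracketing
  gauges and reported as undefined when the normalised curve never crosses
  0.5.
- CNR takes the absolute mean difference, so air yields a positive value.
- SNR is reported on the ×100 percent scale; the raw mean/SD ratio is also
  exposed.
- Slice thickness: the ramp ROI's long axis is the profile axis (short
  axis averaged); baseline = median of off-peak samples; a peak must
  exceed baseline + 3·(off-peak SD); half-maximum crossings by linear
  interpolation; `z = FWHM·tan(angle)`, pass iff within ±0.5 mm of
  nominal by default.
- CTDI100 integrates over exactly ±50 mm (trapezoid, with interpolated
  endpoints) and divides by the nominal beam width; CTDIw averages the
  peripheral cavities (conventionally four) and weights periphery:centre
  as 2:1.

## I/O conventions

Volumes are `(z, y, x)` float64 HU grids with per-axis mm spacing; ROI
coordinates are physical mm in the volume frame.  NIfTI I/O (nibabel)
stores float64 losslessly with an axis-aligned affine; DICOM series I/O
(pydicom) writes one CT file per slice with int16 stored values
(slope 1 / intercept −1024), i.e. HU are quantised to integers on write,
and honours RescaleSlope/Intercept and slice positions on read.  Oblique
orientations are not supported.

## Known limitations

- The scatter-correction stage assumes the prior is already registered;
  any real deformation shows up as residual error handled only by the
  winsorization.
- The NLM noise model is Gaussian and spatially white per block; strongly
  correlated noise will be under-estimated by the block estimator.
- MTF is measured from bar-pattern percentile modulation, not from an
  edge-spread Fourier transform; the two agree in ranking but not in
  absolute value.
- The 2D-per-slice default leaves through-plane noise correlations
  untouched.
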