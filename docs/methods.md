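# Methods

`lungreg` estimates a dense correspondence `h` between a pair of 3-D lung CT
volumes acquired at different inflation levels (an inspiratory, TLC-like
*template* `I1` and an expiratory, FRC-like *target* `I2`), by minimizing

    C_total(h) = C_intensity(I1, I2, h) + chi * C_SSVMD(F1, F2, h)
               + gamma * C_REG(u)

over the coefficients of a cubic B-spline free-form deformation, where
`u(x) = h(x) - x` is the displacement field and `F1`, `F2` are Frangi
vesselness fields of the two images.  This note records the model, its
assumptions, the numerical choices, and what the synthetic phantom does and
does not establish.

## Transformation model

`h(x) = x + sum_i phi_i B((x - x_i) / delta)` on a regular control-point
lattice with spacing `delta` (mm) and 3-vector coefficients `phi_i` (mm);
`B` is the separable uniform cubic B-spline kernel.  The lattice extends two
control points beyond the image domain on every side so each domain point has
full cubic support, with no boundary special-casing.  All geometry is in
world millimetres; voxel `(i,j,k)` has its centre at
`origin + (i,j,k) * spacing`.

Local injectivity: if every coefficient component satisfies
`|phi| <= delta / K` with `K = 2.479772335`, the transform has positive
Jacobian determinant everywhere (the classical sufficient bound for cubic
FFDs).  The bound is conservative — an isolated coefficient violating it by
3x still cannot fold, because transverse tensor weights attenuate its
gradient contribution by `B(0)^2 = 4/9` — so the driver treats it as a box
constraint on each resolution level's coefficient *increment* (see below)
and additionally verifies `min J > 0` after every level.

Jacobian determinants, and all displacement derivatives in the elastic term,
are computed from analytic B-spline derivatives, never finite differences.
Grid refinement between levels uses exact dyadic knot insertion (masks
`[1,4,6,4,1]/8`) whenever the spacing halves — the only case the default
schedules produce — followed by cropping the refined lattice back to a
two-control-point margin; cropped points lie beyond any domain point's
kernel support, so the field over the domain is bit-identical.  Non-dyadic
ratios fall back to a separable least-squares fit on the voxel lattice.

## Similarity costs

All sums run over `Omega`, the union of the target lung mask and the
template lung mask warped through the current transform (nearest-neighbour
lookup), recomputed once per resolution sub-level by default.  The
squared-difference costs are scaled by the voxel volume (mm^3) so values are
comparable across pyramid levels.  Warped samples `I1(h(x))` use a C2-smooth
cubic B-spline interpolant of the template (trilinear is available as
`interp_order=1`); smoothness is what lets the analytic coefficient gradient
agree with central differences to ~1e-7, which a kinked trilinear interpolant
cannot do.  Samples falling outside the template volume return air
(-1000 HU; 0 for vesselness) with zero gradient.

- **SSD** `sum v2 [I2(x) - I1(h(x))]^2`, used after histogram-matching the
  template to the target (monotone quantile mapping).
- **MI** negative mutual information from a 50x50 joint histogram over
  `Omega`, cubic-spline Parzen window on the warped-template axis (so the
  gradient exists) and hard binning on the fixed axis; intensity ranges are
  frozen per level from the masked min/max.  A `window="hard"` estimator
  (both axes hard-binned) is provided for analysis; for it the identity
  MI(X, X) = H(X) is exact, whereas the Parzen joint spreads mass off the
  diagonal and trades that identity for differentiability.
- **NCC** the negative normalized cross correlation exactly as a ratio of
  raw inner products (no mean centering); -1 for proportional images.
- **SSTVD** compares estimated regional *tissue* volumes
  `V = v * (HU + 1000)/1055` under the air/tissue mixture model with
  `HU_air = -1000`, using `v1(h(x)) = v2(x) * J(h(x))`; intensities are
  clamped below at air.  The printed denominator 1055 is kept (a pure
  rescale; exposed as `CostWeights.tissue_denominator`).  Its gradient
  includes the dependence of `J` on the coefficients through
  `dJ = J tr(F^{-1} dF)` — omitting it fails the finite-difference oracle.
- **SSVMD** `sum v2 [F2(x) - F1(h(x))]^2` over vesselness fields in [0, 1].

The vesselness fields come from multiscale Hessian eigenanalysis: Gaussian
second-derivative filtering at scales `sigma = {2, 3}` mm (in world mm,
per axis in voxel units; kernels truncated at 8 sigma so constants map to
exactly zero curvature), eigenvalues ordered by magnitude, the Frangi
response with `alpha = beta = 0.5`, `rho = 5` on the bright-tube branch
(`lambda2 < 0` and `lambda3 < 0`), maximum over scales, global min-max
rescale to [0, 1].  Because `rho` is intensity-scale dependent, HU volumes
are linearly pre-scaled to [0, 1] over a body window of [-1000, 400] HU
before filtering.  No `sigma^2` scale normalization is applied to the
Hessian.  Fields are precomputed per pyramid level from each level's
downsampled images; `F1(h(x))` interpolates the fixed field rather than
re-filtering warped images.  At pyramid levels whose voxel spacing exceeds
`2 sigma`, the effective scale is floored at half the largest spacing so the
derivative kernels stay resolvable.

**Important caveat:** vesselness is not transported as a scalar under a
deformation — tube radii, local contrast and the per-volume rescale all
change the response — so the SSVMD term's own minimum sits a fraction of a
voxel away from the true correspondence.  Its value lies in regions where
the intensity metrics are weak (small faint vessels in uniform parenchyma),
which is exactly the regime the original motivation describes.

## Regularization

`C_REG = sum_Omega ||L u||^2 v2` with the linear-elastic operator
`L u = -alpha_el lap(u) - beta_el grad(div u) + gamma_el u`.  Defaults
`alpha_el = beta_el = 1`, `gamma_el = 0.01` (the operator coefficients are
not standardized anywhere authoritative; the small zeroth-order term keeps
`L` nonsingular without pulling displacements toward zero).  With
`gamma = 0.1` the term's share of the total cost on phantom runs (~30% at
the true alignment) matches the proportions reported for clinical runs of
this family of methods.

## Optimization

L-BFGS-B over the flattened coefficients, analytic gradient, box bounds
`carried_coefficients +/- delta/K` per component.  Centering the box on the
carried-over coefficients (zero at the first level) bounds each level's
*increment*: a zero-centered box at fine grids could not even represent the
coarse solution (dyadic refinement preserves coefficient magnitude while the
bound halves), making large deformations unreachable.  The price is that
injectivity is verified rather than implied — `min J > 0` is checked on the
target lattice after every sub-level and the driver fails hard otherwise.

The multiresolution schedule alternates image-resolution and grid-spacing
refinement.  The clinical-scale default runs image factors
1/8, 1/8, 1/4, 1/4, 1/2, 1/2, 1, 1 with grids 128, 64, 32, 16, 16, 8, 8,
4 mm and iteration caps 200, 200, 200, 200, 50, 50, 20, 20.  For ~64 mm
phantoms a scaled schedule drops the 1/8 levels (an 8-voxel image cannot
host a 128 mm lattice) and starts at 32 mm; caps follow the corresponding
clinical rows.  Convergence inside a level stops early when the relative
total-cost change between accepted iterates falls below `tolerance`
(default 1e-5, config-exposed); iterates are logged (level, iteration, each
cost term, total) and the accepted totals are non-increasing within a level.
Images and masks are pre-downsampled by factors of two (Gaussian
pre-smoothing at sigma of one source voxel, then decimation; block majority
vote for masks).

`chi = 1` and `gamma = 0.1` are the defaults, appropriate for SSTVD whose
intrinsic scale they were tuned against.  Because the four intensity metrics
differ by eight orders of magnitude in scale (SSD ~1e8, SSTVD ~1e1, MI/NCC
~1e0), a raw `chi = 1` means "negligible vesselness" for SSD and
"vesselness only" for MI/NCC.  `RegistrationConfig(balance_ssvmd=True)`
therefore rescales the SSVMD weight once per run — at the first sub-level's
initial iterate — so `chi = 1` gives the vesselness term the same initial
gradient norm as the intensity term.  It is off by default and used for
cross-metric comparisons.

## Synthetic phantom

The generator builds a target volume analytically: an ellipsoidal lung of
air/tissue-mixture parenchyma (tissue fraction 0.15 by default, about
-850 HU, FRC-like) inside a soft-tissue body (+50 HU), a recursively
bifurcating tree of +50 HU tubes whose radii decay geometrically until the
finest generation is about one voxel wide, and an oblique planar fissure
represented as a zero-thickness point sheet (it does not mark intensity).
Structures are painted with analytic partial-volume edge profiles (linear
blend over one voxel of signed distance) and the whole volume is blurred
with a 0.7 mm Gaussian emulating the scanner point-spread function, then
white noise (5 HU default) is added per volume.  Without the PSF a
one-voxel tube would be painted at full ~900 HU contrast — nothing like CT,
where sub-voxel vessels fade toward the noise floor — and hard edges would
dominate every intensity cost with aliasing residuals even at the true
alignment.

The ground-truth transform is drawn on a 16 mm lattice with coefficients
correlated across control points (one-control-point Gaussian smoothing of an
iid draw, rescaled so the largest component equals
`amplitude_fraction * delta / K`).  Respiratory deformation is spatially
smooth; an uncorrelated draw concentrates energy at the lattice Nyquist
frequency, which conflicts with the elastic prior that real lungs satisfy
and no physiological motion exhibits.  The template volume is painted by
evaluating the same analytic geometry at numerically inverted transform
positions (fixed-point iteration, converging under the injectivity bound),
so it carries no resampling blur; parenchyma intensity is scaled by `1/J` so
regional tissue content is conserved — SSTVD's model holds by construction
(a `conserve_tissue=False` switch paints a uniform template fraction
instead, for robustness experiments).  Landmarks (vessel branch points and
segment midpoints), vessel centreline samples and fissure points are exact
correspondences under the truth; pre-registration landmark error is the
truth displacement magnitude (~0.8 mm at the defaults).

What the phantom does **not** emulate: parenchymal texture, airways, lobar
anatomy, breathing hysteresis, CT reconstruction artifacts, or the ~27 mm
deformations of a real FRC/TLC pair.  Registration on it is therefore much
easier than on clinical data: passing recovery tests shows the pipeline is
correctly assembled and convergent, not that clinical accuracy would match.
Notably, because SSTVD's tissue model is *exact* on the phantom, SSTVD-only
registration reaches ~0.17 voxel landmark accuracy there — far beyond the
~1.5 voxel clinical regime — and at that accuracy the vesselness term's
transport bias outweighs its information; the vesselness benefit reproduces
on the phantom for SSD, MI and NCC but not for SSTVD.

## Problem sizes and determinism

Default test and acceptance runs use 64^3 (recovery) and 48^3 (vesselness
benefit) phantoms with 1 mm voxels, the scaled schedules above, and
registrations of 20-80 s on one CPU; these sizes were chosen so the whole
pipeline exercises every level type while staying desk-scale.  All
randomness flows from explicit integer seeds through `numpy` generators
(the phantom splits its master seed deterministically into truth, tree and
per-volume noise streams), and identical seeds and configurations reproduce
registrations bit-for-bit, including cost traces.

## Known limitations

- Vesselness transport bias (above): SSVMD is a guide, not a consistent
  estimator of alignment; its weight should stay comparable to or below the
  intensity term's.
- The MI estimator freezes intensity ranges per level and clamps
  out-of-range spline overshoot into the edge bins with zero gradient.
- `Omega` is recomputed once per sub-level by default; per-iteration
  recomputation (`recompute_omega_each_iteration`) makes the objective
  slightly discontinuous across iterations and is off by default.
- Injectivity of the composed multi-level estimate is verified numerically
  per level rather than guaranteed by the coefficient bound.
- The nearest-voxel mask lookup in `domain_union` and the mask majority-vote
  downsampling are both half-voxel accurate, which is immaterial at the
  resolutions used here but untested at strongly anisotropic spacings.
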