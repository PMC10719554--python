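# Methods

This note documents the models, numerical choices and known limitations of
`tomomdr`. Units: lengths in mm, attenuation in 1/mm, angles in degrees.
Post-log projection values are line integrals of attenuation,
`y = −ln(I/I₀)`.

## Geometry and projector

The scan geometry is a partial-isocentric sweep: the source rotates in the
y–z plane about the isocenter while the detector stays horizontal below
the breast support. The default profile is 9 views over 25° in 3.125°
steps with source–isocenter 617 mm, isocenter–support 20 mm,
support–detector 23 mm and 0.1 mm detector pitch; it ships as
`profiles/pristina_like.yaml` and every field is overridable.

The forward projector is a slice-interpolated ray tracer: for each
detector pixel, the ray from the source is intersected with every slice
plane, the in-slice value is read by bilinear interpolation, and the
contribution is weighted by the ray's path length across the slice
thickness (so a uniform slab of attenuation `a` and thickness `T`
projects to `a·T/cosθ` on rays at obliquity `θ`). Each view is assembled
once into a sparse matrix; the back projector is the exact transpose, so
the pair is a matched adjoint by construction — a property the
preconditioned solver and all adjoint-based gradients rely on, and one
that randomized inner-product tests verify to 1e−10. Voxels never crossed
by any ray are flagged out-of-field and frozen (their preconditioner
entry is zero) rather than divided by a zero column sum.

Conventions: 0-based indices, voxel-center coordinates, detector row 0 at
the chest-wall edge, volumes shaped `(nx, ny, nz)` with `nz` the depth
axis (default voxel 0.1 × 0.1 × 1 mm).

## Blur, noise and prewhitening

Detector blur is a small normalized convolution kernel on the detector
grid; the default is a Gaussian with 2-pixel FWHM, a stand-in with the
correct qualitative MTF roll-off for the pixel-aperture and scintillator
spread of a real detector (the true kernel can be supplied from a
profile). Convolution uses symmetric (reflective) boundary handling.

Measurements follow `y = B A x + B ε_q + ε_r` with
`ε_q ~ N(0, σ_q²/exposure · I)` and `ε_r ~ N(0, σ_r² · I)` — quantum noise
is blurred with the signal, readout noise is not, and both variances are
constant across pixels. The prewhitener `S = (B K_q B' + K_r)^(−1/2)` is
applied as a DCT-II-domain filter: a symmetric kernel convolved under the
half-sample-symmetric boundary rule is *exactly* diagonalized by the
orthonormal DCT-II basis, so the whitening is exact rather than a
circulant approximation. The blur eigenvalues are recovered numerically
from probe images at filter construction and the diagonalization is
verified there (a non-symmetric or too-large kernel raises). The variance
response is floored at 1e−12 before the inverse square root; a vanishing
blur response with `σ_r = 0` raises a singularity error instead of
producing an unbounded filter. Whitened-noise ensembles are tested to
have a unit-flat power spectrum per DCT bin.

`σ_q` is either known (simulation) or estimated from repeated flat-field
views by the mean/variance method (`estimate_sigma_q_flat_field`),
clearly separated code paths.

## Regularizers and solver

The edge-preserving penalty applies the hyperbola potential
`η(t) = δ²(√(1+(t/δ)²)−1)` to horizontal, vertical and (weighted by γ)
diagonal in-slice first differences, normalized by `1/(1+γ)`; differences
never cross slice boundaries. η has curvature ≤ 1, and each difference
operator contributes spectral norm ≤ 4, so the penalty Hessian is bounded
by 8 — the origin of the `8β_EP` preconditioner term, confirmed by power
iteration in the tests. Defaults `γ = 1/√2` and `δ = 2` (pixel-value
units) are this package's choices; both are exposed.

The denoising penalty is `R_RED(x) = ½ x'(x − G(x))` with the update
direction `x − z`; the denoiser is never differentiated through. For a
*symmetric linear* G the penalty is an exact quadratic form and the
solver's limit point is a stationary point of the full cost (tested); for
a general trained denoiser no objective is actually minimized, so the
recorded cost trace is diagnostic only and the fixed-point drift
`‖x_n − x_{n−1}‖` is reported alongside it.

The solver alternates `N_inner` ordered-subsets cycles of the
preconditioned inner update with the denoising step `z ← G(x)`, both
variables starting at zero, and **returns z** as the final image.
Denoisers are 2D and applied slice-wise; when a suite is supplied, the
volume's RMS noise is estimated at each outer iteration and the
closest-noise denoiser is chosen (ties to the lower center). Negative
values are clamped only at export, never during iteration. Subset
orderings: maximally-spaced (default), sequential, an explicit
permutation, or `"full"` (one subset holding all views — plain
preconditioned gradient descent).

**Step size.** The preconditioner majorizes the Hessian of the *summed*
cost, which justifies unit steps for full-gradient descent (verified by a
dense eigenvalue test). Ordered subsets additionally require the
`N_p`-scaled single-view curvature to stay below the preconditioner
bound; on clinical-sized problems the views are balanced enough for
`α = 1`, but on the small grids used throughout this package's studies
the per-view whitened operators differ enough that single-view steps
overshoot. The desk-scale operating point is therefore `α = 0.25` with
one view per subset (the default `α = 1` remains appropriate for
full-gradient mode). A divergence guard aborts if the cost grows past 10×
its initial value.

**Regularization weights.** The reference operating point
`β_EP = 50, β_RED = 500` (with `N_iter = N_inner = 3`) applies to images
scaled to the DICOM pixel-value range. The package's synthetic studies
work directly in attenuation units (values ~0.05/mm), where the data-fit
Hessian is larger by roughly the squared dynamic-range ratio; the
desk-scale studies use `β_EP = 1000, β_RED = 3000`, chosen once so that
the regularizers visibly shape the image at this scale, and kept fixed.

## Denoisers

The trainable denoiser is a small fully convolutional residual network
(default 8 conv layers, width 16; the final layer starts at zero so the
network begins as the identity) trained on aligned low-dose/high-dose
32 × 32 patch pairs with MSE loss, Adam, and seeded batching. An optional
adversarial term uses a Wasserstein critic whose gradient penalty is
estimated by a seeded directional finite difference (requiring only
first-order backpropagation); it is off by default so training stays
deterministic. Being fully convolutional, a trained denoiser applies to
any slice at or above the training patch size. Suites partition volumes
into contiguous noise groups (equal-count rule) and train one denoiser
per group, with `noise_center` = group mean RMS.

## Task-based assessment

**Analytic RMS noise.** 10 × 10-pixel ROIs are tiled from anchor (0, 0)
at 25-pixel spacing (ROIs past the patch edge are dropped); each ROI is
detrended by a least-squares 2D quadratic (6 coefficients) and the RMS of
the residuals is averaged over ROIs with no degrees-of-freedom
correction. For white noise of deviation σ the estimator's expectation is
`√((100−6)/100)·σ ≈ 0.970σ`, which the tests check at the 1% level. The
measure is exactly invariant to adding any global quadratic surface.
Volume-level noise is the mean over seeded random in-slice patches.

**Observers.** The noise estimator (regression head, MSE loss,
nonnegative output) and the cluster detector (sigmoid score, binary
cross-entropy) share one of three small convolutional backbone families
(`vgg`-like plain convs, `resnet`-like with identity skips,
`convnext`-like with 5 × 5 spatial + 1 × 1 mixing convs), ending in
global pooling so any patch size is accepted. Pooling is plain global
averaging by default; a concatenated average+max variant exists, but the
max path proved to destabilize the noise-estimation regression across
phantom textures, so it is opt-in. Observer capacity is deliberately
limited (an assertion caps parameters at 1M): an over-strong observer
saturates AUC and stops discriminating between image conditions.

The detector is transfer-initialized from the trained noise estimator —
backbone *and* head, since the two networks are identical up to the exit
nonlinearity — and fine-tuned at a learning rate two orders of magnitude below the
estimator's (1e−5 vs 1e−3), matching the full-scale protocol's ratio. Training from random initialization is kept
only as a negative control. Positive patches are augmented 8-fold by the
dihedral group during training; at deployment every patch score is the
mean over its 8 dihedral transforms, positive scores are pooled by
arithmetic mean per cluster and view, and AUC (midrank convention,
`P(pos>neg) + ½P(pos=neg)`) is reported as mean ± std over repeated
trainings (default 5; the desk studies use 3). Patch sets are split by
phantom (case), enforced programmatically.

Patch extraction tiles each ground-truth box with centers separated by
the patch size in-plane and 2 slices in depth (alternate planes offset by
half a patch; boxes smaller than a patch get one centered patch), takes
the maximum intensity projection over 3 slices, and removes the
low-frequency background by the same quadratic fit used in the RMS
estimator. Negatives are seeded-random, pairwise disjoint and disjoint
from all boxes; candidates come from a patch-spaced grid visited in
random order (rejection sampling alone cannot find adjacent disjoint
placements on small slabs). The full-scale patch size is 128 pixels; the
desk studies use 32.

## Synthetic phantoms

Slab phantoms are binary gland/fat fields obtained by thresholding a
band-limited Gaussian random field (isotropic power ~ 1/f³ by default) at
the exact count quantile for the requested glandular volume fraction, then
mapped to attenuations (fat 0.046/mm, gland 0.080/mm, representative
around 20 keV). The four standard GVF categories carry compressed
-thickness ranges that can be enforced. No anatomical claim is made: the
texture reproduces a clustered binary structure adequate for noise and
detectability experiments, not ducts, ligaments or skin.

Microcalcification clusters are `n ≥ 3` ellipsoidal specks with diameters
drawn from one of four nominal ranges (0.125–0.150 to 0.212–0.250 mm),
±20% axis jitter, and centers drawn within the cluster extent under a
minimum-separation rule that keeps rasterized specks disjoint. Specks are
rasterized with adaptive sub-voxel sampling (the sampling pitch stays
well below the speck semi-axis, which matters because speck diameters are
far below the 1 mm slice thickness) and add `contrast × volume-fraction`
attenuation. The ground truth is the half-open voxel bounding box plus
speck centers.

Acquisition simulates every exposure factor from one set of clean
projections with independent named noise substreams; the largest factor
is the high-dose denoiser-training target, and a factor of ∞ produces the
noise-free blurred reference.

## The desk-scale study (`tomomdr.study`)

The frozen design: six 64 × 64 × 16-voxel phantoms at GVF 0.34, three
5-speck clusters each (0.150–0.180 mm diameters, 2 mm extent, 6/mm
contrast — toward the dense end of calcium at mammographic energies,
chosen once so the detection task is neither impossible nor saturated at
this observer scale), σ_q = 0.08, σ_r = 0.01, 2-pixel-FWHM blur, exposure
factors 0.25/1/3, SART with 3 iterations as the base reconstruction.
Observer studies split phantoms 3/3 into train/test. The noise estimator
trains on ~320 random background patches (40 px, interior slices only —
the outermost slices of a limited-angle reconstruction carry boundary
artifacts), with early stopping and repeat selection on validation
patches drawn from the *training* phantoms; the selected model's
correlation with the analytic measure on test-phantom patches is the
reported fidelity. The exposure-noise curve measures identical patch
locations at every exposure factor (paired sampling), so the
location-to-location spread of residual texture leakage cancels in
cross-factor comparisons instead of masking the dose ordering. The
ablation harness reconstructs one phantom under all six partial models
plus the full model, with a denoiser trained from the scene's own
low/high-dose pair, and scores each condition.

These sizes are the package's chosen experimental scale; everything is
parameterized upward.

## What passing tests do and do not show

The synthetic studies demonstrate internal correctness (operators,
gradients, majorization, whitening, estimator calibration) and the
qualitative phenomena of the method (noise falls with exposure; the
prewhitened data-fit alone is exceptionally noisy; regularization trades
noise for signal; transfer initialization outperforms scratch training at
fixed budget). They do not establish clinical image quality: the texture
is not anatomical, scatter / spectral effects / source motion are not
modeled, detector blur is a Gaussian stand-in, and the observers are far
smaller than those needed for human-subject images.

## Other numerical choices

* Exact count-quantile thresholding makes the achieved gland fraction
  match the target to one voxel in N; an unreachable target raises.
* The projector caches per-(geometry, grid) sparse matrices (LRU of 8).
* All file writes are atomic (temp-then-rename); HDF5 for volumes and
  sinograms, DICOM series with rescale tags for export, YAML profiles for
  geometry/noise, JSON + npz for denoiser suites.
* One global seed fans out through named substreams (`child_seed`), so no
  stage's draws shift another's.
* Degenerate inputs: constant volumes export with slope 1 and a warning;
  empty suites, empty score lists, non-finite losses, shape mismatches
  and out-of-range views raise typed errors.
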