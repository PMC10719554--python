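# tomomdr

Model-based, denoiser-regularized image reconstruction for limited-angle
digital breast tomosynthesis (DBT), together with a task-based image
quality assessment stack built around microcalcification (MC)
detectability.

DBT reconstructs a quasi-3D breast volume from a handful of projection
views spanning ~25°. The limited angular range makes the inverse problem
badly ill-posed, and the low per-view dose makes the images noisy — both
of which hurt the visibility of clustered microcalcifications, a key early
sign of breast cancer. `tomomdr` implements:

* **the physics model** — a ray-driven projector `A_i` per view with a
  matched adjoint, a detector-blur operator `B`, and a quantum + readout
  noise model with constant per-pixel variances, giving the prewhitened
  data-fit

  ```
  L(x) = 1/2 Σ_i ‖ỹ_i − Ã_i x‖²,   ỹ_i = S_i y_i,   Ã_i = S_i B A_i,
  S_i = (B K_q,i B' + K_r)^(−1/2)
  ```

  with `S_i` applied as an exact DCT-domain filter (the blur is a
  symmetric convolution under a reflective boundary rule, which the DCT-II
  basis diagonalizes exactly);

* **the regularizers** — an edge-preserving penalty `R_EP` built from the
  hyperbola potential `η(t) = δ²(√(1+(t/δ)²) − 1)` of in-slice finite
  differences (diagonals down-weighted by γ), and a
  regularization-by-denoising penalty `R_RED(x) = ½ x'(x − G(x))` for a
  plug-in denoiser `G`;

* **the solver** — proximal-gradient alternation between a diagonally
  preconditioned ordered-subsets descent on
  `L(x) + β_EP R_EP(x) + β_RED/2 ‖x − z‖²` and the denoising step
  `z ← G(x)`, with the preconditioner
  `P = (Σ_i diag{A_i'A_i 1}/(σ²_q,i+σ²_r) + 8β_EP I + β_RED I)^(−1)`
  whose inverse provably majorizes the inner-cost Hessian;

* **denoisers** — linear reference smoothers plus a trainable fully
  convolutional residual CNN (optionally with a Wasserstein-critic
  adversarial term), organized into a suite keyed by RMS noise level with
  closest-noise selection at reconstruction time;

* **task-based assessment** — an analytic ROI-grid RMS-noise estimator, a
  learned noise-estimation network (CNN-NE), and a learned model observer
  (CNN-MC) for MC-cluster detection that is transfer-initialized from the
  CNN-NE; scores use 8-fold dihedral test-time augmentation and
  per-cluster pooling, and detectability is summarized as ROC AUC over
  repeated trainings;

* **synthetic data** — procedural slab phantoms (thresholded power-law
  texture at a target glandular volume fraction), sub-voxel ellipsoidal MC
  specks with partial-volume rasterization, and acquisition simulation
  across an exposure-factor sweep;

* **harnesses** — a cost-term ablation matrix (6 partial models + full
  model) and a β_EP × β_RED grid sweep, each emitting AUC-vs-RMS tradeoff
  points.

The neural components run on a compact numpy/scipy CPU training core
(`tomomdr.nn`) and are deliberately small; everything is deterministic
given a seed.

## Worked example

Simulate a textured slab phantom with one five-speck cluster, acquire a
9-view scan at unit exposure, and compare SART with the full model-based
reconstruction (a Gaussian smoother stands in for a trained denoiser to
keep the example fast):

```python
import numpy as np
from tomomdr import (VolumeSpec, pristina_like, NoiseModel,
                     gaussian_blur_kernel, PhantomSpec, MCClusterSpec,
                     ExposureSweep, generate_phantom, insert_mc_cluster,
                     acquire, sart_reconstruct, mdr_reconstruct,
                     ReconConfig, DenoiserSpec, apply_denoiser)
from tomomdr.geometry import required_detector_shape
from tomomdr.assessment import estimate_volume_rms

vol = VolumeSpec(shape=(64, 64, 16))                 # 6.4 x 6.4 x 16 mm
geom = pristina_like(
    detector_shape=required_detector_shape(pristina_like(), vol))
noise = NoiseModel(sigma_q=0.08, sigma_r=0.01,
                   blur=gaussian_blur_kernel(2.0))

phantom, labels = generate_phantom(PhantomSpec(gvf=0.34, texture_seed=0),
                                   vol)
cluster = MCClusterSpec(center=(32, 32, 8), n_specks=5, contrast=6.0,
                        cluster_extent=2.0, layout_seed=0)
phantom, truth = insert_mc_cluster(phantom, labels, cluster, vol)

sino = acquire(phantom, geom, noise, ExposureSweep((1.0,)), seed=42,
               vol=vol)[1.0]

sart = sart_reconstruct(sino, vol, n_iterations=3, relaxation=0.5)
smoother = DenoiserSpec(kind="gaussian", params=dict(sigma=1.0))
mdr = mdr_reconstruct(sino, vol,
                      ReconConfig(beta_ep=1000.0, beta_red=3000.0,
                                  alpha=0.25),
                      denoiser=lambda v: apply_denoiser(v, smoother))

cx, cy, cz = np.round(truth.centers[0]).astype(int)
for name, image in [("SART", sart), ("MDR", mdr.image)]:
    rms = estimate_volume_rms(image, seed=0)
    peak = image[cx, cy, cz] - np.median(image)
    print(f"{name}: volume RMS noise {rms:.5f} /mm, "
          f"speck peak contrast {peak:.5f} /mm")
```

Output:

```
SART: volume RMS noise 0.00627 /mm, speck peak contrast 0.06477 /mm
MDR: volume RMS noise 0.00216 /mm, speck peak contrast 0.02288 /mm
```

The regularized reconstruction cuts the background RMS noise by roughly a
factor of three while the speck stays far above the residual noise floor
(peak contrast ≈ 10× the RMS noise in both cases) — the noise/signal
tradeoff the solver is designed to navigate. All quantities are linear
attenuation values (per mm); exported DICOM series rescale them to the
[0, 4095] integer range with recoverable slope/intercept tags.

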