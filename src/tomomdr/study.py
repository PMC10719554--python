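"""Reproducible desk-scale synthetic study.

One fixed, seeded experimental design exercises the whole pipeline on
problem sizes a single CPU handles in minutes:

* six slab phantoms (64 x 64 x 16 voxels at 0.1 x 0.1 x 1 mm) at 34%
  glandular volume fraction, each carrying three microcalcification
  clusters of 0.150-0.180 mm specks;
* a 9-view 25-degree acquisition with detector blur and quantum + readout
  noise at exposure factors 0.25 / 1 / 3;
* SART reconstructions per exposure condition;
* observer studies with a phantom-level train/test split: the noise
  estimator's held-out correlation with the analytic RMS measure, and the
  cluster detector trained by transfer from the noise estimator versus
  from random initialization.

The functions here are the substance behind both the acceptance script and
the heavier end-to-end tests; all randomness descends from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assessment import (ObserverConfig, estimate_volume_rms,
                         extract_patches, pool_cluster_scores, roc_auc,
                         roi_rms, score_patches, train_cnn_mc,
                         train_cnn_ne)
from .config import child_seed
from .geometry import (ScanGeometry, VolumeSpec, gaussian_blur_kernel,
                       pristina_like, required_detector_shape)
from .noise import NoiseModel
from .phantom import (ExposureSweep, MCClusterSpec, PhantomSpec, acquire,
                      generate_phantom, insert_mc_cluster)
from .recon import sart_reconstruct

__all__ = ["StudyDesign", "Scene", "build_scene", "exposure_noise_curve",
           "background_patches", "ne_transfer_study", "ablation_study",
           "desk_observer_config"]


@dataclass(frozen=True)
class StudyDesign:
    """Frozen desk-scale study conditions."""

    shape: tuple[int, int, int] = (64, 64, 16)
    gvf: float = 0.34
    sigma_q: float = 0.08
    sigma_r: float = 0.01
    blur_fwhm_px: float = 2.0
    factors: tuple[float, ...] = (0.25, 1.0, 3.0)
    n_phantoms: int = 6
    clusters_per_phantom: int = 3
    n_specks: int = 5
    speck_diameter_range: tuple[float, float] = (0.150, 0.180)
    cluster_extent: float = 2.0          # mm
    speck_contrast: float = 6.0          # 1/mm attenuation excess
    sart_iterations: int = 3
    patch_size: int = 32
    negatives_per_volume: int = 6


def desk_observer_config(epochs: int = 25) -> ObserverConfig:
    return ObserverConfig(backbone="vgg", width=12, epochs=epochs,
                          batch_size=32, lr=1e-3, lr_mc=1e-5,
                          pooling="avg")


@dataclass
class Scene:
    design: StudyDesign
    vol: VolumeSpec
    geom: ScanGeometry
    noise: NoiseModel
    phantoms: list[np.ndarray]
    boxes: list[list[tuple]]               # per phantom
    stacks: list[dict]                     # per phantom: factor -> sinogram
    recons: list[dict[float, np.ndarray]]  # per phantom: factor -> volume
    meta: dict = field(default_factory=dict)


def _cluster_centers(design: StudyDesign) -> list[tuple[float, float, float]]:
    nx, ny, nz = design.shape
    zc = nz / 2.0
    offset = design.cluster_extent / 2.0 / 0.1 + 3   # voxels from the rim
    lo, hi = offset, nx - offset
    mid = nx / 2.0
    return [(lo + 2, lo + 2, zc), (hi - 2, hi - 2, zc),
            (lo + 2, hi - 2, zc)][: design.clusters_per_phantom]


def build_scene(seed: int, design: StudyDesign | None = None) -> Scene:
    """Generate phantoms, acquire the exposure sweep, and reconstruct."""
    design = design or StudyDesign()
    vol = VolumeSpec(shape=design.shape)
    det = required_detector_shape(pristina_like(), vol)
    geom = pristina_like(detector_shape=det)
    noise = NoiseModel(sigma_q=design.sigma_q, sigma_r=design.sigma_r,
                       blur=gaussian_blur_kernel(design.blur_fwhm_px))
    sweep = ExposureSweep(factors=design.factors)

    phantoms, all_boxes, all_stacks, recons = [], [], [], []
    for p in range(design.n_phantoms):
        spec = PhantomSpec(gvf=design.gvf,
                           texture_seed=child_seed(seed, f"texture-{p}"))
        volume, labels = generate_phantom(spec, vol)
        boxes = []
        for ci, center in enumerate(_cluster_centers(design)):
            mc = MCClusterSpec(
                center=center, n_specks=design.n_specks,
                speck_diameter_range=design.speck_diameter_range,
                cluster_extent=design.cluster_extent,
                contrast=design.speck_contrast,
                layout_seed=child_seed(seed, f"layout-{p}-{ci}"))
            volume, gt = insert_mc_cluster(volume, labels, mc, vol)
            boxes.append(gt.box)
        stacks = acquire(volume, geom, noise, sweep,
                         seed=child_seed(seed, f"acquire-{p}"), vol=vol)
        recon = {f: sart_reconstruct(stacks[f], vol,
                                     n_iterations=design.sart_iterations,
                                     relaxation=0.5)
                 for f in design.factors}
        phantoms.append(volume)
        all_boxes.append(boxes)
        all_stacks.append(stacks)
        recons.append(recon)
    return Scene(design=design, vol=vol, geom=geom, noise=noise,
                 phantoms=phantoms, boxes=all_boxes, stacks=all_stacks,
                 recons=recons)


def exposure_noise_curve(scene: Scene, seed: int = 0,
                         n_patches: int = 32) -> dict[float, float]:
    """Mean measured volume RMS noise per exposure factor.

    The same patch locations are measured at every factor (paired
    sampling): the location-to-location spread of residual texture leakage
    then cancels in cross-factor comparisons instead of adding noise to
    them.
    """
    out = {}
    for f in scene.design.factors:
        vals = [estimate_volume_rms(r[f],
                                    seed=child_seed(seed, f"rms-{p}"),
                                    n_patches=n_patches)
                for p, r in enumerate(scene.recons)]
        out[f] = float(np.mean(vals))
    return out


def _condition_patches(scene: Scene, phantom_ids, factor, seed):
    patches = []
    for p in phantom_ids:
        patches.extend(extract_patches(
            scene.recons[p][factor], scene.boxes[p],
            patch_size=scene.design.patch_size,
            n_negatives=scene.design.negatives_per_volume,
            seed=child_seed(seed, f"patches-{p}-{factor}"), view_id=p))
    return patches


def background_patches(scene: Scene, phantom_ids, seed: int,
                       n_per_volume: int = 12, patch_size: int = 40,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Random cluster-free background patches (central slice, detrended)
    with their analytic RMS labels; patches may overlap each other.

    Sampling stays on interior slices: the top and bottom slices of a
    limited-angle reconstruction carry boundary artifacts that are not
    representative background noise."""
    from .assessment import detrend_quadratic

    rng = np.random.default_rng(seed)
    nx, ny, nz = scene.design.shape
    ps = patch_size
    z_lo, z_hi = 2, max(nz - 2, 3)
    pixels, labels = [], []
    for p in phantom_ids:
        for f in scene.design.factors:
            vol = scene.recons[p][f]
            found = 0
            while found < n_per_volume:
                cx = int(rng.integers(ps // 2, nx - ps // 2 + 1))
                cy = int(rng.integers(ps // 2, ny - ps // 2 + 1))
                zc = int(rng.integers(z_lo, z_hi))
                cand = (cx - ps // 2, cy - ps // 2, zc,
                        cx + ps // 2, cy + ps // 2, zc + 1)
                if any(all(cand[d] < b[d + 3] and b[d] < cand[d + 3]
                           for d in range(3)) for b in scene.boxes[p]):
                    continue
                patch = detrend_quadratic(
                    vol[cand[0]:cand[3], cand[1]:cand[4], zc])
                pixels.append(patch)
                labels.append(roi_rms(patch))
                found += 1
    return np.stack(pixels), np.array(labels)


def ablation_study(scene: Scene, seed: int, factor: float = 1.0,
                   beta_ep: float = 1000.0, beta_red: float = 3000.0,
                   repeats: int = 1, epochs: int = 15,
                   phantom: int = 0) -> dict[str, dict]:
    """Cost-term ablation on one phantom of the scene.

    A small denoiser is trained from the scene's own low/high-dose
    reconstruction pair, then every partial model plus the full model is
    reconstructed and scored (volume RMS noise and observer AUC). The
    regularization weights are the desk-scale operating point for
    attenuation-unit images (the published operating point assumes images
    scaled to the DICOM pixel-value range).
    """
    from .denoiser import apply_denoiser, harvest_pairs, train_denoiser
    from .harness import run_ablation
    from .recon import ReconConfig

    design = scene.design
    ld = scene.recons[phantom][min(design.factors)]
    hd = scene.recons[phantom][max(design.factors)]
    mask = np.ones_like(ld, dtype=bool)
    pairs = harvest_pairs(ld, hd, mask, 400, 24,
                          seed=child_seed(seed, "ablation-pairs"))
    dn = train_denoiser(pairs, arch=dict(depth=4, width=8), epochs=10,
                        seed=child_seed(seed, "ablation-denoiser"))
    base = ReconConfig(beta_ep=beta_ep, beta_red=beta_red, alpha=0.25,
                       n_iter=3, n_inner=3)
    return run_ablation(
        scene.stacks[phantom][factor], scene.vol, scene.boxes[phantom],
        denoiser=lambda v: apply_denoiser(v, dn), base_config=base,
        observer_config=desk_observer_config(epochs), repeats=repeats,
        seed=child_seed(seed, "ablation"),
        patch_size=design.patch_size,
        n_negatives=design.negatives_per_volume)


def ne_transfer_study(scene: Scene, seed: int, repeats: int = 3,
                      epochs: int = 25, ne_epochs: int = 50,
                      mc_factor: float = 1.0) -> dict:
    """Observer pipeline with a phantom-level split.

    Returns the noise estimator's held-out correlation with the analytic
    RMS values, and the detector AUC (mean over repeats) under transfer
    and under random initialization. The estimator trains longer than the
    detector fine-tuning, mirroring the full-scale protocol's epoch ratio.
    """
    n = scene.design.n_phantoms
    train_ids = list(range(n // 2))
    test_ids = list(range(n // 2, n))
    cfg = desk_observer_config(epochs)
    cfg_ne = desk_observer_config(ne_epochs)

    # noise-estimation sets: random background (box-free) patches across
    # all exposures; mutual overlap allowed, central slice without MIP
    ne_train_x, ne_train_y = background_patches(
        scene, train_ids, child_seed(seed, "ne-train"), n_per_volume=36)
    # validation patches come from the *training* phantoms (fresh
    # locations): they drive model selection across repeats without
    # touching the held-out phantoms
    ne_val_x, ne_val_y = background_patches(
        scene, train_ids, child_seed(seed, "ne-val"))
    ne_test_x, ne_test_y = background_patches(
        scene, test_ids, child_seed(seed, "ne-test"))

    # detection sets at the middle exposure
    mc_train = _condition_patches(scene, train_ids, mc_factor,
                                  child_seed(seed, "mc-train"))
    mc_test = _condition_patches(scene, test_ids, mc_factor,
                                 child_seed(seed, "mc-test"))
    mc_labels = np.array([p.label for p in mc_train])

    corrs, val_corrs, aucs_t, aucs_s = [], [], [], []
    seeds = np.random.SeedSequence(child_seed(seed, "repeats")).spawn(repeats)
    ne_models = []
    for r in range(repeats):
        rs = int(seeds[r].generate_state(1)[0] % (2**31))
        ne = train_cnn_ne(ne_train_x, ne_train_y, cfg_ne, seed=rs,
                          val_patches=ne_val_x, val_labels=ne_val_y)
        ne_models.append(ne)
        val_corrs.append(float(np.corrcoef(ne.predict(ne_val_x),
                                           ne_val_y)[0, 1]))
        corrs.append(float(np.corrcoef(ne.predict(ne_test_x),
                                       ne_test_y)[0, 1]))
        for transfer, acc in ((True, aucs_t), (False, aucs_s)):
            mc = train_cnn_mc(mc_train, mc_labels, ne, cfg, seed=rs,
                              transfer=transfer)
            scores = score_patches(mc, mc_test)
            pooled = pool_cluster_scores(scores, mc_test)
            neg = [s for s, p in zip(scores, mc_test) if p.label == 0]
            acc.append(roc_auc(list(pooled.values()), neg))
    # deploy the repeat with the best validation correlation (selection
    # never sees the held-out phantoms)
    best = int(np.argmax(val_corrs))
    return dict(
        ne_corr=corrs[best],
        ne_corr_mean=float(np.mean(corrs)),
        ne_corrs=corrs,
        ne_val_corrs=val_corrs,
        auc_transfer_mean=float(np.mean(aucs_t)),
        auc_scratch_mean=float(np.mean(aucs_s)),
        aucs_transfer=aucs_t,
        aucs_scratch=aucs_s,
        ne_model=ne_models[best],
        n_mc_train=len(mc_train),
        n_mc_test=len(mc_test),
    )
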