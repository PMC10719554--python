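"""Plug-in denoisers G for the denoising regularizer, and suite training.

Four denoiser kinds share one interface:

* ``identity`` — G(x) = x (no-op reference);
* ``gaussian`` — normalized Gaussian smoothing per slice (linear,
  symmetric: usable in the solver's fixed-point and cost-monotonicity
  oracles);
* ``linear_smoother`` — convolution with an arbitrary 180-degree-symmetric
  normalized kernel (also linear and symmetric);
* ``cnn`` — a small fully convolutional residual network trained on
  low-dose/high-dose patch pairs, the learned counterpart of the above.

The trainable denoiser minimizes ``w_mse * MSE + w_adv * adversarial`` on
32x32 patch pairs. The adversarial option is a Wasserstein critic with a
finite-difference estimate of the gradient penalty; it is off by default
(``w_adv = 0``) so that training is deterministic. Being fully
convolutional, a trained denoiser applies to slices of any size at or above
the training patch size.

A deployment *suite* is a list of denoisers with increasing representative
noise centers (RMS pixel-value units); the reconstruction picks the
closest-matched entry at run time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.ndimage

from . import nn

__all__ = [
    "DenoiserSpec",
    "PatchPairSet",
    "harvest_pairs",
    "train_denoiser",
    "apply_denoiser",
    "build_suite",
    "build_denoiser_network",
]


@dataclass
class DenoiserSpec:
    """One denoiser: its kind, suite key (noise center) and parameters.

    ``params`` holds the kind-specific state: ``sigma`` for gaussian,
    ``kernel`` for linear_smoother, and ``weights``/``arch``/``scale``/
    ``offset`` for cnn. ``training_meta`` records patch size, loss weights,
    seed and the loss trace for provenance.
    """

    kind: str
    noise_center: float = 0.0
    params: dict = field(default_factory=dict)
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "gaussian", "linear_smoother",
                             "cnn"):
            raise ValueError(f"unknown denoiser kind {self.kind!r}")
        if self.noise_center < 0:
            raise ValueError("noise_center must be >= 0")
        if self.kind == "cnn" and "weights" not in self.params:
            raise ValueError("cnn denoiser needs trained weights")
        if self.kind == "gaussian" and "sigma" not in self.params:
            raise ValueError("gaussian denoiser needs params['sigma']")
        if self.kind == "linear_smoother" and "kernel" not in self.params:
            raise ValueError("linear smoother needs params['kernel']")


@dataclass
class PatchPairSet:
    """Aligned low-dose / high-dose patch pairs from co-registered volumes."""

    low_dose: np.ndarray    # (n, ps, ps)
    high_dose: np.ndarray   # (n, ps, ps)
    group_id: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.low_dose = np.asarray(self.low_dose, dtype=float)
        self.high_dose = np.asarray(self.high_dose, dtype=float)
        if self.low_dose.shape != self.high_dose.shape:
            raise ValueError("LD and HD patch arrays must be aligned")

    @property
    def n_pairs(self) -> int:
        return self.low_dose.shape[0]


def harvest_pairs(ld_volume: np.ndarray, hd_volume: np.ndarray,
                  breast_mask: np.ndarray, n: int, patch_size: int = 32,
                  seed: int = 0, group_id: int = 0) -> PatchPairSet:
    """Extract ``n`` aligned LD/HD patch pairs at seeded random in-mask
    locations (identical coordinates in both volumes)."""
    ld = np.asarray(ld_volume, dtype=float)
    hd = np.asarray(hd_volume, dtype=float)
    mask = np.asarray(breast_mask, dtype=bool)
    if ld.shape != hd.shape or ld.shape != mask.shape:
        raise ValueError("LD, HD and mask must be co-registered")
    if not mask.any():
        raise ValueError("breast mask is empty")
    ps = patch_size
    nx, ny, _ = ld.shape
    if nx < ps or ny < ps:
        raise ValueError(f"volume slices smaller than patch size {ps}")
    rng = np.random.default_rng(seed)
    lds, hds = [], []
    attempts = 0
    while len(lds) < n:
        attempts += 1
        if attempts > 1000 * max(n, 1):
            raise ValueError("breast mask too small to host the patches")
        ix = rng.integers(0, nx - ps + 1)
        iy = rng.integers(0, ny - ps + 1)
        iz = rng.integers(0, ld.shape[2])
        if not mask[ix:ix + ps, iy:iy + ps, iz].all():
            continue
        lds.append(ld[ix:ix + ps, iy:iy + ps, iz])
        hds.append(hd[ix:ix + ps, iy:iy + ps, iz])
    shape = (0, ps, ps) if n == 0 else None
    return PatchPairSet(
        low_dose=np.array(lds).reshape(shape) if shape else np.array(lds),
        high_dose=np.array(hds).reshape(shape) if shape else np.array(hds),
        group_id=group_id, seed=seed)


def build_denoiser_network(depth: int = 8, width: int = 16,
                           rng: np.random.Generator | None = None,
                           ) -> nn.Sequential:
    """Fully convolutional residual body: depth conv layers, ReLU between."""
    if depth < 2:
        raise ValueError("denoiser needs at least 2 conv layers")
    rng = rng or np.random.default_rng(0)
    layers = [nn.Conv2d(1, width, rng=rng), nn.ReLU()]
    for _ in range(depth - 2):
        layers += [nn.Conv2d(width, width, rng=rng), nn.ReLU()]
    last = nn.Conv2d(width, 1, rng=rng)
    last.w.value[...] = 0.0      # start as the identity map (residual net)
    layers.append(last)
    return nn.Sequential(layers)


def _build_critic(rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential([
        nn.Conv2d(1, 8, stride=2, rng=rng), nn.ReLU(),
        nn.Conv2d(8, 16, stride=2, rng=rng), nn.ReLU(),
        nn.GlobalAvgPool(), nn.Dense(16, 1, rng=rng),
    ])


def train_denoiser(pairs: PatchPairSet,
                   loss_weights: tuple[float, float] = (1.0, 0.0),
                   arch: dict | None = None, seed: int = 0,
                   epochs: int = 20, batch_size: int = 32, lr: float = 1e-3,
                   noise_center: float = 0.0,
                   gp_weight: float = 10.0) -> DenoiserSpec:
    """Train the residual CNN denoiser on LD -> HD patch pairs.

    ``loss_weights = (w_mse, w_adv)``; with ``w_adv > 0`` a Wasserstein
    critic trains alongside the denoiser, its gradient penalty estimated by
    a seeded directional finite difference (first-order backprop only).
    Deterministic given ``seed``.
    """
    if pairs.n_pairs < 1:
        raise ValueError("need at least one training pair")
    w_mse, w_adv = loss_weights
    arch = dict(depth=8, width=16) | (arch or {})
    rng = np.random.default_rng(seed)
    net = build_denoiser_network(arch["depth"], arch["width"], rng)
    opt = nn.Adam(net.params(), lr=lr)

    offset = float(pairs.low_dose.mean())
    scale = float(pairs.low_dose.std()) or 1.0
    ld = (pairs.low_dose[:, None] - offset) / scale    # (n, 1, ps, ps)
    hd = (pairs.high_dose[:, None] - offset) / scale

    critic = _build_critic(rng) if w_adv > 0 else None
    copt = nn.Adam(critic.params(), lr=lr) if critic else None

    n = pairs.n_pairs
    loss_trace = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = ld[idx], hd[idx]
            out = net.forward(xb)
            pred = xb + out                       # residual connection
            loss, dpred = nn.mse_loss(pred, yb)
            loss *= w_mse
            dpred = w_mse * dpred
            if critic is not None:
                loss_adv, dpred_adv = _adversarial_step(
                    critic, copt, pred, yb, rng, gp_weight)
                loss += w_adv * loss_adv
                dpred = dpred + w_adv * dpred_adv
            net.zero_grad()
            net.backward(dpred)
            opt.step()
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss {loss}; trace: "
                    f"{loss_trace[-5:]}")
            epoch_loss += loss * len(idx)
        loss_trace.append(epoch_loss / n)

    return DenoiserSpec(
        kind="cnn", noise_center=noise_center,
        params=dict(weights=net.get_weights(), arch=arch, scale=scale,
                    offset=offset),
        training_meta=dict(patch_size=pairs.low_dose.shape[-1],
                           loss_weights=loss_weights, seed=seed,
                           epochs=epochs, loss_trace=loss_trace))


def _adversarial_step(critic, copt, pred, real, rng, gp_weight):
    """One critic update, then the generator's adversarial gradient."""
    fake = pred.copy()
    # critic update: E[D(fake)] - E[D(real)] + gp
    critic.zero_grad()
    d_fake = critic.forward(fake)
    critic.backward(np.ones_like(d_fake) / d_fake.size)
    d_real = critic.forward(real)
    critic.backward(-np.ones_like(d_real) / d_real.size)
    # finite-difference gradient penalty on mixed samples
    eps = rng.uniform(size=(fake.shape[0], 1, 1, 1))
    mix = eps * real + (1 - eps) * fake
    u = rng.standard_normal(mix.shape)
    u /= np.sqrt((u**2).sum(axis=(1, 2, 3), keepdims=True))
    h = 1e-3
    d0 = critic.forward(mix)
    d1 = critic.forward(mix + h * u)
    dim = np.prod(mix.shape[1:])
    slope = np.sqrt(dim) * (d1 - d0) / h
    # d/dtheta of mean((slope - 1)^2) through both forward passes
    gpen = 2.0 * (slope - 1.0) * np.sqrt(dim) / h / slope.size
    critic.forward(mix + h * u)
    critic.backward(gp_weight * gpen)
    critic.forward(mix)
    critic.backward(-gp_weight * gpen)
    copt.step()
    # generator gradient: minimize -E[D(fake)]
    d_fake = critic.forward(fake)
    loss_adv = -float(d_fake.mean())
    dpred = critic.backward(-np.ones_like(d_fake) / d_fake.size)
    critic.zero_grad()
    return loss_adv, dpred


def _cnn_network(spec: DenoiserSpec) -> tuple[nn.Sequential, float, float]:
    arch = spec.params["arch"]
    net = build_denoiser_network(arch["depth"], arch["width"])
    net.set_weights(spec.params["weights"])
    return net, spec.params["scale"], spec.params["offset"]


def apply_denoiser(image: np.ndarray, spec: DenoiserSpec) -> np.ndarray:
    """Apply a denoiser to a 2D slice or slice-wise to a 3D volume."""
    x = np.asarray(image, dtype=float)
    if x.ndim == 3:
        out = np.empty_like(x)
        for k in range(x.shape[2]):
            out[:, :, k] = apply_denoiser(x[:, :, k], spec)
        return out
    if x.ndim != 2:
        raise ValueError("input must be a 2D slice or 3D volume")
    if spec.kind == "identity":
        return x.copy()
    if spec.kind == "gaussian":
        return scipy.ndimage.gaussian_filter(x, spec.params["sigma"],
                                             mode="reflect")
    if spec.kind == "linear_smoother":
        kernel = np.asarray(spec.params["kernel"], dtype=float)
        if not np.allclose(kernel, kernel[::-1, ::-1]):
            raise ValueError("linear smoother kernel must be symmetric")
        return scipy.ndimage.convolve(x, kernel, mode="reflect")
    net, scale, offset = _cnn_network(spec)
    ps = spec.training_meta.get("patch_size", 1)
    if x.shape[0] < ps or x.shape[1] < ps:
        raise ValueError(
            f"input {x.shape} smaller than the training patch size {ps}")
    xn = (x - offset) / scale
    out = net.forward(xn[None, None])[0, 0]
    return x + scale * out


def build_suite(ld_volumes: Sequence[np.ndarray],
                hd_volumes: Sequence[np.ndarray], k_groups: int,
                rms_values: Sequence[float] | None = None,
                mask: np.ndarray | None = None,
                n_pairs_per_volume: int = 200, patch_size: int = 32,
                seed: int = 0, train_kwargs: dict | None = None,
                ) -> list[DenoiserSpec]:
    """Partition volumes into contiguous noise groups and train one
    denoiser per group.

    ``rms_values`` may supply precomputed per-volume RMS noise; otherwise
    it is measured with the ROI-grid estimator on seeded sample patches.
    Returns specs sorted by strictly increasing ``noise_center`` (the group
    mean RMS).
    """
    from .assessment import estimate_volume_rms

    if k_groups < 1:
        raise ValueError("k_groups must be >= 1")
    if len(ld_volumes) != len(hd_volumes):
        raise ValueError("need aligned LD and HD volume lists")
    if k_groups > len(ld_volumes):
        raise ValueError("more groups than volumes")
    if rms_values is None:
        rms_values = [estimate_volume_rms(v, seed=seed) for v in ld_volumes]
    rms_values = np.asarray(rms_values, dtype=float)
    order = np.argsort(rms_values, kind="stable")
    groups = np.array_split(order, k_groups)
    train_kwargs = train_kwargs or {}
    suite = []
    for gid, idx in enumerate(groups):
        center = float(rms_values[idx].mean())
        all_ld, all_hd = [], []
        for j in idx:
            m = (mask if mask is not None
                 else np.ones_like(ld_volumes[j], dtype=bool))
            p = harvest_pairs(ld_volumes[j], hd_volumes[j], m,
                              n_pairs_per_volume, patch_size,
                              seed=seed + 1000 + int(j), group_id=gid)
            all_ld.append(p.low_dose)
            all_hd.append(p.high_dose)
        pairs = PatchPairSet(np.concatenate(all_ld), np.concatenate(all_hd),
                             group_id=gid, seed=seed)
        spec = train_denoiser(pairs, seed=seed + gid,
                              noise_center=center, **train_kwargs)
        suite.append(spec)
    return suite
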