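"""Measurement noise model, covariance, and prewhitening.

The measurement model for the post-log projection view at scan angle ``i`` is

    y_i = B A_i x + B eps_q + eps_r,
    eps_q ~ N(0, sigma_q^2 / exposure * I),   eps_r ~ N(0, sigma_r^2 * I),

where ``B`` is the detector blur. Quantum and readout noise variances are
constant across detector pixels, so the view covariance is

    K_i = B K_q B' + K_r,   K_q = (sigma_q^2/exposure) I,   K_r = sigma_r^2 I,

and the prewhitening operator is S_i = K_i^{-1/2}. Applying S_i to the data
and to the blurred system matrix gives the whitened data-fit

    L_DBCN(x) = 1/2 sum_i || y~_i - A~_i x ||^2,
    y~_i = S_i y_i,   A~_i = S_i B A_i.

Because B is a symmetric convolution applied with symmetric (reflective)
boundary handling, its operator is exactly diagonalized by the orthonormal
DCT-II basis; S_i is therefore an exact DCT-domain filter

    S~(f) = (lambda_B(f)^2 sigma_q^2/exposure + sigma_r^2)^{-1/2},

not a circulant approximation. The diagonalization is verified numerically
when the filter is built.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dctn, idctn

from .geometry import (BlurKernel, ScanGeometry, VolumeSpec, apply_blur,
                       get_projector, identity_blur_kernel)

__all__ = [
    "NoiseModel",
    "PrewhitenFilter",
    "SinogramStack",
    "simulate_measurement",
    "prewhiten",
    "whitened_system",
    "data_fit_dbcn",
    "WhitenedProjector",
    "estimate_sigma_q_flat_field",
]

_VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class NoiseModel:
    """Quantum + readout noise in post-log attenuation units.

    ``sigma_q`` is the quantum noise standard deviation at unit exposure;
    the effective quantum variance scales as ``sigma_q^2 / exposure_factor``.
    ``sigma_r`` is the exposure-independent detector readout noise.
    """

    sigma_q: float
    sigma_r: float
    blur: BlurKernel = field(default_factory=identity_blur_kernel)
    exposure_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_q < 0 or self.sigma_r < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.sigma_q == 0 and self.sigma_r == 0:
            raise ValueError("at least one of sigma_q, sigma_r must be > 0")
        if self.exposure_factor <= 0:
            raise ValueError("exposure_factor must be > 0")

    @property
    def sigma_q_effective(self) -> float:
        return self.sigma_q / np.sqrt(self.exposure_factor)

    @property
    def total_variance(self) -> float:
        """Pixel variance sigma_q^2/exposure + sigma_r^2 (identity blur)."""
        return self.sigma_q_effective**2 + self.sigma_r**2

    def with_exposure(self, exposure_factor: float) -> "NoiseModel":
        return NoiseModel(self.sigma_q, self.sigma_r, self.blur,
                          exposure_factor)


def _blur_dct_eigenvalues(kernel: BlurKernel,
                          shape: tuple[int, int]) -> np.ndarray:
    """Eigenvalues of the symmetric-boundary blur operator in DCT-II basis.

    Estimated from two fixed probe images and verified on a third; raises
    if the operator is not DCT-diagonal (e.g. kernel larger than the grid).
    """
    if kernel.is_identity:
        return np.ones(shape)
    rng = np.random.default_rng(12345)
    probes = rng.standard_normal((3,) + shape)
    c1, c2 = (dctn(p, norm="ortho") for p in probes[:2])
    b1, b2 = (dctn(apply_blur(p, kernel), norm="ortho") for p in probes[:2])
    lam = (b1 * c1 + b2 * c2) / (c1**2 + c2**2)
    check = apply_blur(probes[2], kernel)
    recon = idctn(lam * dctn(probes[2], norm="ortho"), norm="ortho")
    err = np.abs(check - recon).max() / max(np.abs(check).max(), 1e-300)
    if err > 1e-8:
        raise ValueError(
            "blur kernel is not diagonalized by the DCT under the symmetric "
            f"boundary rule (residual {err:.2e}); prewhitening requires a "
            "symmetric kernel smaller than the detector grid")
    return lam


@dataclass(frozen=True)
class PrewhitenFilter:
    """The operator S_i = (B K_q B' + K_r)^{-1/2} as a DCT-domain gain."""

    model: NoiseModel
    shape: tuple[int, int]
    response: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lam = _blur_dct_eigenvalues(self.model.blur, self.shape)
        var = (lam**2 * self.model.sigma_q_effective**2
               + self.model.sigma_r**2)
        if self.model.sigma_r == 0 and var.min() <= _VARIANCE_FLOOR:
            raise ZeroDivisionError(
                "noise covariance is singular: blur response vanishes and "
                "sigma_r = 0; the prewhitening filter is unbounded")
        resp = 1.0 / np.sqrt(np.maximum(var, _VARIANCE_FLOOR))
        resp.setflags(write=False)
        object.__setattr__(self, "response", resp)

    def apply(self, view: np.ndarray) -> np.ndarray:
        img = np.asarray(view, dtype=float)
        if img.shape != self.shape:
            raise ValueError(f"view shape {img.shape} does not match filter "
                             f"shape {self.shape}")
        gain = self.response.flat[0]
        if np.all(self.response == gain):     # scalar filter (identity blur)
            return img * gain
        return idctn(self.response * dctn(img, norm="ortho"), norm="ortho")


def prewhiten(view: np.ndarray, filt: PrewhitenFilter) -> np.ndarray:
    """Whitened view y~_i = S_i y_i. S is linear and self-adjoint."""
    return filt.apply(view)


def simulate_measurement(clean_projection: np.ndarray, model: NoiseModel,
                         seed: int | np.random.Generator) -> np.ndarray:
    """One noisy post-log view: y = B(clean) + B(eps_q) + eps_r."""
    clean = np.asarray(clean_projection, dtype=float)
    if not np.all(np.isfinite(clean)):
        raise ValueError("clean projection contains non-finite values")
    rng = np.random.default_rng(seed)
    y = apply_blur(clean, model.blur)
    if model.sigma_q > 0:
        eps_q = rng.normal(0.0, model.sigma_q_effective, size=clean.shape)
        y = y + apply_blur(eps_q, model.blur)
    if model.sigma_r > 0:
        y = y + rng.normal(0.0, model.sigma_r, size=clean.shape)
    return y


@dataclass
class SinogramStack:
    """Per-angle post-log measurements plus the noise metadata needed to
    prewhiten them."""

    views: np.ndarray                     # (n_views, nu, nv)
    geom: ScanGeometry
    noise: NoiseModel | None = None       # None = noise-free / unknown

    def __post_init__(self) -> None:
        self.views = np.asarray(self.views, dtype=float)
        if self.views.ndim != 3:
            raise ValueError("views must be a (n_views, nu, nv) array")
        if self.views.shape[0] != self.geom.n_views:
            raise ValueError(
                f"stack has {self.views.shape[0]} views but geometry "
                f"defines {self.geom.n_views}")
        if self.views.shape[1:] != self.geom.detector_shape:
            raise ValueError(
                f"view shape {self.views.shape[1:]} does not match detector "
                f"grid {self.geom.detector_shape}")

    @property
    def n_views(self) -> int:
        return self.views.shape[0]


class WhitenedProjector:
    """The whitened system A~_i = S_i B A_i with its exact adjoint.

    S is self-adjoint and B is self-adjoint under the symmetric boundary
    rule, so the adjoint is A_i' B S. Accepts any base projector exposing
    ``project``/``backproject`` (the sparse-matrix projector in production,
    dense or identity operators in tests).
    """

    def __init__(self, base, kernel: BlurKernel,
                 filters: list[PrewhitenFilter]):
        if len(filters) != base.n_views:
            raise ValueError("need one prewhitening filter per view")
        self.base = base
        self.kernel = kernel
        self.filters = filters

    @property
    def n_views(self) -> int:
        return self.base.n_views

    def project(self, volume: np.ndarray, view: int) -> np.ndarray:
        return self.filters[view].apply(
            apply_blur(self.base.project(volume, view), self.kernel))

    def backproject(self, detector_image: np.ndarray, view: int) -> np.ndarray:
        return self.base.backproject(
            apply_blur(self.filters[view].apply(detector_image), self.kernel),
            view)


def whitened_filters(geom: ScanGeometry, noise: NoiseModel | list[NoiseModel],
                     ) -> list[PrewhitenFilter]:
    models = noise if isinstance(noise, list) else [noise] * geom.n_views
    if len(models) != geom.n_views:
        raise ValueError("need one noise model per view")
    return [PrewhitenFilter(m, geom.detector_shape) for m in models]


def whitened_system(volume: np.ndarray, geom: ScanGeometry, view: int,
                    filt: PrewhitenFilter, vol: VolumeSpec | None = None,
                    kernel: BlurKernel | None = None) -> np.ndarray:
    """A~_i x = S_i B A_i x on the detector grid."""
    if vol is None:
        vol = VolumeSpec(shape=np.asarray(volume).shape)
    if kernel is None:
        kernel = filt.model.blur
    proj = get_projector(geom, vol)
    return filt.apply(apply_blur(proj.project(volume, view), kernel))


def data_fit_dbcn(volume: np.ndarray, sinogram: SinogramStack,
                  vol: VolumeSpec | None = None,
                  projector=None) -> tuple[float, np.ndarray]:
    """Detector-blur-and-correlated-noise data-fit cost and gradient.

    Returns ``1/2 sum_i ||y~_i - A~_i x||^2`` and its gradient
    ``sum_i A~_i'(A~_i x - y~_i)`` as a volume-shaped array.
    """
    if sinogram.noise is None:
        raise ValueError("sinogram carries no noise model; cannot prewhiten")
    x = np.asarray(volume, dtype=float)
    if vol is None:
        vol = VolumeSpec(shape=x.shape)
    if projector is None:
        projector = get_projector(sinogram.geom, vol)
    filters = whitened_filters(sinogram.geom, sinogram.noise)
    wproj = WhitenedProjector(projector, sinogram.noise.blur, filters)
    cost = 0.0
    grad = np.zeros(x.shape)
    for i in range(sinogram.n_views):
        y_t = filters[i].apply(sinogram.views[i])
        r = wproj.project(x, i) - y_t
        cost += 0.5 * float(np.sum(r * r))
        grad += wproj.backproject(r, i)
    return cost, grad


def estimate_sigma_q_flat_field(flat_views: np.ndarray, sigma_r: float = 0.0,
                                exposure_factor: float = 1.0) -> float:
    """Estimate sigma_q from repeated flat-field (uniform) acquisitions.

    Mean/variance method on an ensemble of nominally identical views;
    subtracts the known readout variance and undoes the exposure scaling.
    Intended for calibration data, clearly distinct from the known-truth
    mode used with simulated data.
    """
    flat = np.asarray(flat_views, dtype=float)
    if flat.ndim != 3 or flat.shape[0] < 2:
        raise ValueError("need an ensemble of >= 2 flat-field views")
    pixel_var = flat.var(axis=0, ddof=1).mean()
    q_var = max(pixel_var - sigma_r**2, 0.0) * exposure_factor
    return float(np.sqrt(q_var))
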