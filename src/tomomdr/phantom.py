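"""Procedural slab phantoms, microcalcification clusters, and acquisition.

This module is a fully procedural stand-in for an anthropomorphic-phantom /
Monte-Carlo x-ray transport pipeline. It produces:

* slab breast phantoms — a binary gland/fat label field obtained by
  thresholding band-limited (power-law spectrum) Gaussian noise at the
  quantile matching the requested glandular volume fraction (GVF), mapped
  to attenuation coefficients;
* clusters of ellipsoidal microcalcification specks with controlled
  diameter range, spatial extent and attenuation contrast, rasterized with
  sub-voxel partial-volume weighting (speck diameters of 0.125-0.250 mm are
  below the 1 mm slice spacing);
* noisy acquisitions over a sweep of exposure factors sharing one set of
  clean projections, with the highest factor serving as the high-dose
  training target.

No anatomical claim is made for the texture; it reproduces a clustered
binary structure sufficient for noise and detectability experiments. All
randomness is behind named integer seeds and the outputs are deterministic
given those seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ScanGeometry, VolumeSpec, apply_blur, get_projector
from .noise import NoiseModel, SinogramStack, simulate_measurement

__all__ = [
    "PhantomSpec",
    "MCClusterSpec",
    "ClusterGroundTruth",
    "ExposureSweep",
    "GVF_CATEGORIES",
    "generate_phantom",
    "insert_mc_cluster",
    "acquire",
]

# GVF category -> compressed-thickness range (mm): almost entirely fatty,
# scattered fibroglandular, heterogeneously dense, extremely dense.
GVF_CATEGORIES: dict[float, tuple[float, float]] = {
    0.05: (52.0, 70.0),
    0.15: (46.0, 64.0),
    0.34: (36.0, 60.0),
    0.60: (31.0, 55.0),
}

# Nominal speck diameter ranges (mm).
SPECK_DIAMETER_RANGES: tuple[tuple[float, float], ...] = (
    (0.125, 0.150), (0.150, 0.180), (0.180, 0.212), (0.212, 0.250),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Slab phantom parameters.

    Attenuation defaults (1/mm) are representative of adipose and
    fibroglandular tissue around 20 keV. ``texture_exponent`` is the
    power-law exponent of the texture noise spectrum (power ~ 1/f^beta).
    ``enforce_category_range`` turns on the per-category thickness check for
    the four standard GVF categories.
    """

    gvf: float
    thickness: float = 45.0
    texture_seed: int = 0
    attenuation_fat: float = 0.046
    attenuation_gland: float = 0.080
    texture_exponent: float = 3.0
    enforce_category_range: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.gvf <= 1.0:
            raise ValueError("gvf must be in [0, 1]")
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")
        if not 0 < self.attenuation_fat < self.attenuation_gland:
            raise ValueError(
                "need attenuation_gland > attenuation_fat > 0")
        if self.enforce_category_range:
            rng = GVF_CATEGORIES.get(round(self.gvf, 2))
            if rng is None:
                raise ValueError(
                    f"gvf {self.gvf} is not one of the standard categories "
                    f"{sorted(GVF_CATEGORIES)}")
            lo, hi = rng
            if not lo <= self.thickness <= hi:
                raise ValueError(
                    f"thickness {self.thickness} mm outside the "
                    f"[{lo}, {hi}] mm range for GVF {self.gvf}")


def _power_law_field(shape: tuple[int, int, int],
                     voxel_size: tuple[float, float, float],
                     beta: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian random field with isotropic power spectrum ~ 1/f^beta."""
    white = rng.standard_normal(shape)
    spec = np.fft.fftn(white)
    freqs = [np.fft.fftfreq(n, d=d) for n, d in zip(shape, voxel_size)]
    fx, fy, fz = np.meshgrid(*freqs, indexing="ij")
    f = np.sqrt(fx**2 + fy**2 + fz**2)
    f[0, 0, 0] = f[f > 0].min()        # keep DC finite; value is irrelevant
    spec *= f ** (-beta / 2.0)
    field = np.real(np.fft.ifftn(spec))
    return (field - field.mean()) / field.std()


def generate_phantom(spec: PhantomSpec, vol: VolumeSpec,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Attenuation volume (1/mm) and binary gland label map.

    The gland/fat labels come from thresholding the band-limited texture
    field at the exact count quantile, so the achieved gland fraction
    matches ``spec.gvf`` to within one voxel in N. Deterministic given
    ``spec.texture_seed``.
    """
    n = vol.n_voxels
    target = int(round(spec.gvf * n))
    if abs(target / n - spec.gvf) > 0.01:
        raise ValueError(
            f"gvf {spec.gvf} is not reachable to within 0.01 on a grid of "
            f"{n} voxels")
    if spec.gvf == 0.0:
        labels = np.zeros(vol.shape, dtype=bool)
    elif spec.gvf == 1.0:
        labels = np.ones(vol.shape, dtype=bool)
    else:
        rng = np.random.default_rng(spec.texture_seed)
        field_ = _power_law_field(vol.shape, vol.voxel_size,
                                  spec.texture_exponent, rng)
        flat = field_.ravel()
        # threshold at the target-count order statistic (ties broken by
        # strictness: exactly `target` voxels become gland)
        order = np.argsort(flat, kind="stable")
        labels = np.zeros(n, dtype=bool)
        labels[order[n - target:]] = True
        labels = labels.reshape(vol.shape)
    atten = spec.attenuation_fat + labels * (
        spec.attenuation_gland - spec.attenuation_fat)
    return atten.astype(float), labels


@dataclass(frozen=True)
class MCClusterSpec:
    """A cluster of microcalcification specks.

    ``speck_diameter_range`` (mm) is normally one of the four nominal
    ranges in :data:`SPECK_DIAMETER_RANGES`. ``contrast`` is the attenuation
    excess over background (1/mm); calcium greatly exceeds soft tissue, but
    the sub-voxel partial-volume weighting dilutes it in the rasterized
    volume. ``center`` is in (possibly fractional) voxel coordinates.
    """

    center: tuple[float, float, float]
    n_specks: int = 6
    speck_diameter_range: tuple[float, float] = (0.150, 0.180)
    cluster_extent: float = 5.0           # mm
    contrast: float = 1.5                 # 1/mm attenuation excess
    layout_seed: int = 0
    axis_jitter: float = 0.2              # +-20% ellipsoid axis jitter

    def __post_init__(self) -> None:
        if self.n_specks < 3:
            raise ValueError("a cluster needs at least 3 specks")
        lo, hi = self.speck_diameter_range
        if not 0 < lo <= hi:
            raise ValueError("invalid speck diameter range")
        if self.cluster_extent <= 0:
            raise ValueError("cluster_extent must be > 0")
        if self.contrast < 0:
            raise ValueError("contrast must be >= 0")


@dataclass(frozen=True)
class ClusterGroundTruth:
    """Ground truth for one inserted cluster: the half-open 0-based voxel
    bounding box (x0, y0, z0, x1, y1, z1), the speck centers in voxel
    coordinates, and the attenuation that was added."""

    box: tuple[int, int, int, int, int, int]
    centers: np.ndarray
    delta: np.ndarray


def _rasterize_ellipsoid(delta: np.ndarray, center_vox: np.ndarray,
                         semi_axes_mm: np.ndarray,
                         voxel_size: tuple[float, float, float],
                         contrast: float) -> None:
    """Add `contrast * inside-fraction` to voxels overlapping the ellipsoid.

    Sub-voxel sampling is adaptive per axis: specks much smaller than a
    voxel (sub-slice-thickness diameters are the norm) need the sampling
    planes spaced well below the speck semi-axis to resolve the partial
    volume."""
    vs = np.asarray(voxel_size)
    half_vox = semi_axes_mm / vs
    lo = np.floor(center_vox - half_vox - 0.5).astype(int)
    hi = np.ceil(center_vox + half_vox + 0.5).astype(int) + 1
    if np.any(lo < 0) or np.any(hi > np.asarray(delta.shape)):
        raise ValueError("speck extends beyond the volume boundary")
    counts = np.clip(np.ceil(4.0 / np.maximum(half_vox, 1e-9)), 4,
                     64).astype(int)
    subs = [(np.arange(c) + 0.5) / c - 0.5 for c in counts]
    for ix in range(lo[0], hi[0]):
        for iy in range(lo[1], hi[1]):
            for iz in range(lo[2], hi[2]):
                gx = (ix + subs[0][:, None, None] - center_vox[0]) * vs[0]
                gy = (iy + subs[1][None, :, None] - center_vox[1]) * vs[1]
                gz = (iz + subs[2][None, None, :] - center_vox[2]) * vs[2]
                inside = ((gx / semi_axes_mm[0]) ** 2
                          + (gy / semi_axes_mm[1]) ** 2
                          + (gz / semi_axes_mm[2]) ** 2) <= 1.0
                frac = inside.mean()
                if frac > 0:
                    delta[ix, iy, iz] += contrast * frac


def insert_mc_cluster(volume: np.ndarray, labels: np.ndarray,
                      spec: MCClusterSpec, vol: VolumeSpec,
                      ) -> tuple[np.ndarray, ClusterGroundTruth]:
    """Insert a cluster of ellipsoidal specks; returns the new volume and
    the ground-truth bounding box.

    Speck centers are drawn uniformly within ``cluster_extent`` around the
    cluster center with a minimum pairwise separation (so specks stay
    disjoint after rasterization). Deterministic given ``layout_seed``.
    """
    x = np.asarray(volume, dtype=float)
    if x.shape != tuple(vol.shape):
        raise ValueError("volume does not match the grid spec")
    rng = np.random.default_rng(spec.layout_seed)
    vs = np.asarray(vol.voxel_size)
    center = np.asarray(spec.center, dtype=float)
    half_extent_vox = spec.cluster_extent / 2.0 / vs
    # minimum center separation in voxel units, per axis (keeps rasterized
    # specks in disjoint voxel neighborhoods)
    min_sep = np.array([4.0, 4.0, 2.0])

    centers: list[np.ndarray] = []
    for _ in range(10000):
        if len(centers) == spec.n_specks:
            break
        cand = center + rng.uniform(-1, 1, size=3) * half_extent_vox
        if all(np.max(np.abs(cand - c) / min_sep) >= 1.0 for c in centers):
            centers.append(cand)
    if len(centers) < spec.n_specks:
        raise ValueError(
            f"could not place {spec.n_specks} disjoint specks within a "
            f"{spec.cluster_extent} mm cluster extent")
    centers_arr = np.array(centers)

    delta = np.zeros_like(x)
    lo_d, hi_d = spec.speck_diameter_range
    boxes_lo = np.full(3, np.iinfo(np.int64).max)
    boxes_hi = np.full(3, np.iinfo(np.int64).min)
    for c in centers_arr:
        d = rng.uniform(lo_d, hi_d)
        jitter = 1.0 + rng.uniform(-spec.axis_jitter, spec.axis_jitter, 3)
        semi = (d / 2.0) * jitter
        _rasterize_ellipsoid(delta, c, semi, vol.voxel_size, spec.contrast)
        lo = np.floor(c - semi / vs).astype(int)
        hi = np.ceil(c + semi / vs).astype(int) + 1
        boxes_lo = np.minimum(boxes_lo, lo)
        boxes_hi = np.maximum(boxes_hi, hi)
    box = (int(boxes_lo[0]), int(boxes_lo[1]), int(boxes_lo[2]),
           int(boxes_hi[0]), int(boxes_hi[1]), int(boxes_hi[2]))
    gt = ClusterGroundTruth(box=box, centers=centers_arr, delta=delta)
    return x + delta, gt


@dataclass(frozen=True)
class ExposureSweep:
    """Exposure multipliers for the acquisition sweep. The default list was
    designed so reconstructed noise levels are roughly evenly spaced; the
    largest factor is the high-dose (denoiser training target) condition."""

    factors: tuple[float, ...] = (0.25, 0.3, 0.35, 0.4, 0.5, 0.6,
                                  0.75, 1.0, 1.4, 2.0, 3.0)

    def __post_init__(self) -> None:
        if len(self.factors) == 0:
            raise ValueError("sweep needs at least one exposure factor")
        if any(f <= 0 for f in self.factors):
            raise ValueError("exposure factors must be > 0")
        object.__setattr__(self, "factors",
                           tuple(float(f) for f in self.factors))

    @property
    def high_dose_factor(self) -> float:
        return max(f for f in self.factors if np.isfinite(f))


def acquire(volume: np.ndarray, geom: ScanGeometry, noise: NoiseModel,
            sweep: ExposureSweep, seed: int,
            vol: VolumeSpec | None = None) -> dict[float, SinogramStack]:
    """Simulate one noisy sinogram stack per exposure factor.

    All factors share the same clean (blur-free) projections; the noise
    realizations are independent across factors and views, drawn from named
    substreams of ``seed``. A factor of ``inf`` yields the noise-free
    blurred projections (reference condition).
    """
    x = np.asarray(volume, dtype=float)
    if vol is None:
        vol = VolumeSpec(shape=x.shape)
    proj = get_projector(geom, vol)
    clean = np.stack([proj.project(x, i) for i in range(geom.n_views)])
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(sweep.factors) * geom.n_views)
    out: dict[float, SinogramStack] = {}
    for fi, factor in enumerate(sweep.factors):
        views = np.empty_like(clean)
        if np.isinf(factor):
            for i in range(geom.n_views):
                views[i] = apply_blur(clean[i], noise.blur)
            out[factor] = SinogramStack(views=views, geom=geom, noise=None)
            continue
        model = noise.with_exposure(noise.exposure_factor * factor)
        for i in range(geom.n_views):
            rng = np.random.default_rng(streams[fi * geom.n_views + i])
            views[i] = simulate_measurement(clean[i], model, rng)
        out[factor] = SinogramStack(views=views, geom=geom, noise=model)
    return out
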