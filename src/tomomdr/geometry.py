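"""Scan geometry, ray-driven projector with matched adjoint, and detector blur.

Coordinate conventions (used everywhere in the package):

* The isocenter is the origin of the mm coordinate system.
* The x-ray source rotates in the y-z plane: at view angle ``theta`` (degrees)
  the source sits at ``(0, d_si * sin(theta), d_si * cos(theta))`` where
  ``d_si`` is the source-to-isocenter distance.
* The detector is stationary and horizontal, at
  ``z = -(isocenter_to_support + support_to_detector)``, with pixel (0, 0)
  at the corner closest to the chest wall and pixel centers on a regular
  grid of pitch ``detector_pitch`` centered laterally on the isocenter.
* Volumes are indexed ``(ix, iy, iz)`` with 0-based indices referring to
  voxel centers; ``iz`` is the depth (slice) index, slices are parallel to
  the detector.

The forward projector is a Joseph-style slice-interpolated ray tracer: for
each detector pixel the ray from the source is intersected with every slice
plane, the in-slice value is obtained by bilinear interpolation, and the
contribution is weighted by the ray path length across the slice thickness.
Each view's operator is assembled once as a sparse matrix, so the adjoint
(back projector) is the exact matrix transpose — a matched adjoint by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.ndimage
import scipy.sparse

__all__ = [
    "ScanGeometry",
    "VolumeSpec",
    "BlurKernel",
    "pristina_like",
    "gaussian_blur_kernel",
    "identity_blur_kernel",
    "SystemProjector",
    "forward_project",
    "back_project",
    "apply_blur",
    "required_detector_shape",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Limited-angle tomosynthesis scan geometry.

    The default profile (see :func:`pristina_like`) is a 9-view 25-degree
    scan in 3.125-degree increments with source-isocenter 617 mm,
    isocenter-support 20 mm, support-detector 23 mm and 0.1 mm detector
    pitch.
    """

    angles: tuple[float, ...]
    source_to_isocenter: float = 617.0
    isocenter_to_support: float = 20.0
    support_to_detector: float = 23.0
    detector_shape: tuple[int, int] = (64, 64)
    detector_pitch: float = 0.1

    def __post_init__(self) -> None:
        angles = tuple(float(a) for a in self.angles)
        object.__setattr__(self, "angles", angles)
        if len(angles) == 0:
            raise ValueError("geometry needs at least one view angle")
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ValueError("view angles must be strictly increasing")
        for name in ("source_to_isocenter", "isocenter_to_support",
                     "support_to_detector", "detector_pitch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        nu, nv = self.detector_shape
        if nu < 1 or nv < 1:
            raise ValueError("detector_shape must be at least 1x1")
        object.__setattr__(self, "detector_shape", (int(nu), int(nv)))

    @property
    def n_views(self) -> int:
        return len(self.angles)

    @property
    def n_detector_pixels(self) -> int:
        nu, nv = self.detector_shape
        return nu * nv

    @property
    def detector_z(self) -> float:
        return -(self.isocenter_to_support + self.support_to_detector)

    def source_position(self, view: int) -> np.ndarray:
        """Source (x, y, z) in mm for one view."""
        if not 0 <= view < self.n_views:
            raise IndexError(f"view {view} out of range [0, {self.n_views})")
        theta = np.deg2rad(self.angles[view])
        d = self.source_to_isocenter
        return np.array([0.0, d * np.sin(theta), d * np.cos(theta)])

    def detector_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center x and y coordinates (mm), centered on the isocenter."""
        nu, nv = self.detector_shape
        p = self.detector_pitch
        xs = (np.arange(nu) - (nu - 1) / 2.0) * p
        ys = (np.arange(nv) - (nv - 1) / 2.0) * p
        return xs, ys


def pristina_like(detector_shape: tuple[int, int] = (64, 64),
                  detector_pitch: float = 0.1) -> ScanGeometry:
    """The default 9-view, 25-degree scan profile (3.125-degree steps)."""
    angles = tuple(np.round(-12.5 + 3.125 * np.arange(9), 6))
    return ScanGeometry(angles=angles, detector_shape=detector_shape,
                        detector_pitch=detector_pitch)


@dataclass(frozen=True)
class VolumeSpec:
    """Reconstruction grid: shape ``(nx, ny, nz)``, voxel size in mm, and the
    mm offset of voxel (0, 0, 0)'s center relative to the isocenter.

    The default voxel size is 0.1 x 0.1 mm in-slice with 1 mm slice
    spacing. If ``origin`` is omitted the volume is centered laterally on
    the isocenter with its bottom slice resting on the breast support.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 1.0)
    origin: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if any(s < 1 for s in shape):
            raise ValueError("volume dimensions must be >= 1")
        vs = tuple(float(v) for v in self.voxel_size)
        object.__setattr__(self, "voxel_size", vs)
        if any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be > 0")
        if self.origin is not None:
            object.__setattr__(self, "origin",
                               tuple(float(o) for o in self.origin))

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def origin_for(self, geom: ScanGeometry) -> tuple[float, float, float]:
        if self.origin is not None:
            return self.origin
        nx, ny, nz = self.shape
        dx, dy, dz = self.voxel_size
        return (-(nx - 1) / 2.0 * dx,
                -(ny - 1) / 2.0 * dy,
                -geom.isocenter_to_support + dz / 2.0)

    @property
    def thickness(self) -> float:
        return self.shape[2] * self.voxel_size[2]


@dataclass(frozen=True)
class BlurKernel:
    """Detector blur as a small 2D convolution kernel on the detector grid.

    The taps must sum to one (blur conserves total signal) and be symmetric
    under 180-degree rotation so that the operator is self-adjoint under
    the package's symmetric (reflective) boundary rule.
    """

    taps: np.ndarray

    def __post_init__(self) -> None:
        taps = np.asarray(self.taps, dtype=float)
        object.__setattr__(self, "taps", taps)
        if taps.ndim != 2:
            raise ValueError("blur taps must be a 2D array")
        if abs(taps.sum() - 1.0) > 1e-12:
            raise ValueError("blur taps must sum to 1 (signal-conserving)")
        if not np.allclose(taps, taps[::-1, ::-1], atol=1e-12):
            raise ValueError("blur taps must be symmetric under 180-degree "
                             "rotation")

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.taps.shape, self.taps.tobytes()))

    def __eq__(self, other) -> bool:
        return (isinstance(other, BlurKernel)
                and self.taps.shape == other.taps.shape
                and np.array_equal(self.taps, other.taps))

    @property
    def is_identity(self) -> bool:
        return self.taps.size == 1 and self.taps.flat[0] == 1.0


def identity_blur_kernel() -> BlurKernel:
    return BlurKernel(taps=np.array([[1.0]]))


def gaussian_blur_kernel(fwhm_px: float = 2.0) -> BlurKernel:
    """Normalized Gaussian tap kernel with the given FWHM in detector pixels.

    A stand-in for the detector point-spread function (finite pixel
    aperture, scintillator light spread) with the correct qualitative MTF
    roll-off; the width is configurable and the kernel can be replaced by
    measured taps.
    """
    if fwhm_px <= 0:
        raise ValueError("fwhm_px must be > 0")
    sigma = fwhm_px / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    radius = max(1, int(np.ceil(3.0 * sigma)))
    t = np.arange(-radius, radius + 1)
    g = np.exp(-0.5 * (t / sigma) ** 2)
    taps = np.outer(g, g)
    taps /= taps.sum()
    return BlurKernel(taps=taps)


def apply_blur(detector_image: np.ndarray, kernel: BlurKernel) -> np.ndarray:
    """Convolve a detector image with the blur kernel.

    Uses symmetric (reflective) boundary handling; the prewhitening filter
    relies on exactly this rule, so it must not be changed independently.
    """
    img = np.asarray(detector_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detector image must be 2D")
    if kernel.is_identity:
        return img.copy()
    return scipy.ndimage.convolve(img, kernel.taps, mode="reflect")


class SystemProjector:
    """Per-view sparse system matrices A_i for a geometry/grid pair.

    ``project`` and ``backproject`` are exact adjoints because both use the
    same sparse matrix. Also exposes the per-view column sums A_i' A_i 1
    needed by the reconstruction preconditioner, and the in-field voxel
    mask (voxels intersected by at least one ray).
    """

    def __init__(self, geom: ScanGeometry, vol: VolumeSpec):
        self.geom = geom
        self.vol = vol
        self._matrices = [self._build_view_matrix(i)
                          for i in range(geom.n_views)]

    # -- construction -----------------------------------------------------

    def _build_view_matrix(self, view: int) -> scipy.sparse.csr_matrix:
        geom, vol = self.geom, self.vol
        nx, ny, nz = vol.shape
        dx, dy, dz = vol.voxel_size
        ox, oy, oz = vol.origin_for(geom)
        nu, nv = geom.detector_shape
        sx, sy, sz = geom.source_position(view)
        xs, ys = geom.detector_coords()
        xd, yd = np.meshgrid(xs, ys, indexing="ij")   # (nu, nv)
        zd = geom.detector_z

        # per-pixel path-length scale: segment length across one slice
        ray_len = np.sqrt((xd - sx) ** 2 + (yd - sy) ** 2 + (zd - sz) ** 2)
        seg = dz * ray_len / abs(zd - sz)              # (nu, nv)

        rows_all, cols_all, vals_all = [], [], []
        pix_index = np.arange(nu * nv)
        for k in range(nz):
            zk = oz + k * dz
            t = (zk - sz) / (zd - sz)
            px = sx + t * (xd - sx)
            py = sy + t * (yd - sy)
            fx = (px - ox) / dx
            fy = (py - oy) / dy
            ix0 = np.floor(fx).astype(np.int64)
            iy0 = np.floor(fy).astype(np.int64)
            wx1 = fx - ix0
            wy1 = fy - iy0
            for ddx, wx in ((0, 1.0 - wx1), (1, wx1)):
                for ddy, wy in ((0, 1.0 - wy1), (1, wy1)):
                    ix = ix0 + ddx
                    iy = iy0 + ddy
                    w = wx * wy * seg
                    ok = ((ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
                          & (w != 0)).ravel()
                    if not ok.any():
                        continue
                    rows_all.append(pix_index[ok])
                    cols_all.append(((ix.ravel()[ok] * ny
                                      + iy.ravel()[ok]) * nz + k))
                    vals_all.append(w.ravel()[ok])
        if rows_all:
            rows = np.concatenate(rows_all)
            cols = np.concatenate(cols_all)
            vals = np.concatenate(vals_all)
        else:
            rows = cols = vals = np.empty(0)
        mat = scipy.sparse.coo_matrix(
            (vals, (rows, cols)), shape=(nu * nv, vol.n_voxels))
        return mat.tocsr()

    # -- operator interface ----------------------------------------------

    @property
    def n_views(self) -> int:
        return self.geom.n_views

    def matrix(self, view: int) -> scipy.sparse.csr_matrix:
        if not 0 <= view < self.n_views:
            raise IndexError(f"view {view} out of range [0, {self.n_views})")
        return self._matrices[view]

    def project(self, volume: np.ndarray, view: int) -> np.ndarray:
        vol3 = np.asarray(volume, dtype=float)
        if vol3.shape != self.vol.shape:
            raise ValueError(f"volume shape {vol3.shape} does not match "
                             f"grid {self.vol.shape}")
        if not np.all(np.isfinite(vol3)):
            raise ValueError("volume contains non-finite voxels")
        out = self.matrix(view) @ vol3.ravel()
        return out.reshape(self.geom.detector_shape)

    def backproject(self, detector_image: np.ndarray, view: int) -> np.ndarray:
        img = np.asarray(detector_image, dtype=float)
        if img.shape != self.geom.detector_shape:
            raise ValueError(f"detector image shape {img.shape} does not "
                             f"match detector grid {self.geom.detector_shape}")
        out = self.matrix(view).T @ img.ravel()
        return out.reshape(self.vol.shape)

    def column_sums(self, view: int) -> np.ndarray:
        """diag{A_i' A_i 1_N} as a volume-shaped array."""
        m = self.matrix(view)
        colsum = np.asarray((m.T @ (m @ np.ones(self.vol.n_voxels)))).ravel()
        return colsum.reshape(self.vol.shape)

    def row_sums(self, view: int) -> np.ndarray:
        m = self.matrix(view)
        return np.asarray(m.sum(axis=1)).ravel().reshape(
            self.geom.detector_shape)

    def in_field_mask(self) -> np.ndarray:
        """Voxels intersected by at least one ray in at least one view."""
        total = np.zeros(self.vol.n_voxels)
        for m in self._matrices:
            total += np.asarray(abs(m).sum(axis=0)).ravel()
        return (total > 0).reshape(self.vol.shape)


@lru_cache(maxsize=8)
def _cached_projector(geom: ScanGeometry, vol: VolumeSpec) -> SystemProjector:
    return SystemProjector(geom, vol)


def get_projector(geom: ScanGeometry, vol: VolumeSpec) -> SystemProjector:
    """Shared, cached projector instance for a geometry/grid pair."""
    return _cached_projector(geom, vol)


def forward_project(volume: np.ndarray, geom: ScanGeometry, view: int,
                    vol: VolumeSpec | None = None) -> np.ndarray:
    """Line integrals of the attenuation volume on the detector grid.

    ``vol`` defaults to a grid with the volume's shape and the default
    voxel size/origin.
    """
    if vol is None:
        vol = VolumeSpec(shape=np.asarray(volume).shape)
    return get_projector(geom, vol).project(volume, view)


def back_project(detector_image: np.ndarray, geom: ScanGeometry, view: int,
                 vol: VolumeSpec) -> np.ndarray:
    """Exact adjoint of :func:`forward_project`."""
    return get_projector(geom, vol).backproject(detector_image, view)


def required_detector_shape(geom: ScanGeometry, vol: VolumeSpec,
                            margin_px: int = 2) -> tuple[int, int]:
    """Smallest centered detector grid catching every ray through the volume.

    Projects the volume's corner voxels for every view and returns the
    (nu, nv) extent, padded by ``margin_px``, as an even-sized grid usable
    in a replacement :class:`ScanGeometry`.
    """
    nx, ny, nz = vol.shape
    dx, dy, dz = vol.voxel_size
    ox, oy, oz = vol.origin_for(geom)
    corners = np.array([(ox + ix * dx, oy + iy * dy, oz + iz * dz)
                        for ix in (-0.5, nx - 0.5)
                        for iy in (-0.5, ny - 0.5)
                        for iz in (-0.5, nz - 0.5)])
    zd = geom.detector_z
    max_x = max_y = 0.0
    for i in range(geom.n_views):
        s = geom.source_position(i)
        t = (zd - s[2]) / (corners[:, 2] - s[2])
        hit = s[None, :2] + t[:, None] * (corners[:, :2] - s[None, :2])
        max_x = max(max_x, np.abs(hit[:, 0]).max())
        max_y = max(max_y, np.abs(hit[:, 1]).max())
    nu = 2 * (int(np.ceil(max_x / geom.detector_pitch)) + margin_px)
    nv = 2 * (int(np.ceil(max_y / geom.detector_pitch)) + margin_px)
    return nu, nv
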