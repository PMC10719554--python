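"""Standard-format I/O: HDF5 containers, DICOM series, config profiles.

All writes are atomic (write to a temporary sibling, then rename).
"""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from pathlib import Path

import h5py
import numpy as np
import pydicom
import yaml
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .denoiser import DenoiserSpec
from .geometry import BlurKernel, ScanGeometry, VolumeSpec
from .noise import NoiseModel, SinogramStack

__all__ = [
    "save_sinogram", "load_sinogram",
    "save_volume", "load_volume",
    "export_raster", "import_raster",
    "export_dicom", "import_dicom",
    "save_patches", "load_patches",
    "load_geometry_profile", "save_geometry_profile",
    "save_suite", "load_suite",
    "atomic_write",
]


class atomic_write:
    """Context manager yielding a temporary path renamed onto ``path`` on
    success."""

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def __enter__(self) -> Path:
        fd, tmp = tempfile.mkstemp(dir=self.path.parent,
                                   prefix=f".{self.path.name}.")
        os.close(fd)
        self.tmp = Path(tmp)
        return self.tmp

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc_type is None:
            os.replace(self.tmp, self.path)
        elif self.tmp.exists():
            self.tmp.unlink()


# -- sinograms --------------------------------------------------------------

def save_sinogram(path: str | Path, stack: SinogramStack) -> None:
    """HDF5 container: datasets /views/<i> plus geometry and noise attrs."""
    with atomic_write(path) as tmp:
        with h5py.File(tmp, "w") as f:
            g = f.create_group("views")
            for i in range(stack.n_views):
                g.create_dataset(str(i), data=stack.views[i].astype(
                    np.float32))
            geom = stack.geom
            f.attrs["angles"] = np.asarray(geom.angles)
            f.attrs["source_to_isocenter"] = geom.source_to_isocenter
            f.attrs["isocenter_to_support"] = geom.isocenter_to_support
            f.attrs["support_to_detector"] = geom.support_to_detector
            f.attrs["detector_pitch"] = geom.detector_pitch
            if stack.noise is not None:
                f.attrs["sigma_q"] = stack.noise.sigma_q
                f.attrs["sigma_r"] = stack.noise.sigma_r
                f.attrs["exposure_factor"] = stack.noise.exposure_factor
                f.create_dataset("blur_taps", data=stack.noise.blur.taps)


def load_sinogram(path: str | Path) -> SinogramStack:
    with h5py.File(path, "r") as f:
        keys = sorted(f["views"], key=int)
        views = np.stack([f["views"][k][()] for k in keys]).astype(float)
        geom = ScanGeometry(
            angles=tuple(f.attrs["angles"]),
            source_to_isocenter=float(f.attrs["source_to_isocenter"]),
            isocenter_to_support=float(f.attrs["isocenter_to_support"]),
            support_to_detector=float(f.attrs["support_to_detector"]),
            detector_shape=views.shape[1:],
            detector_pitch=float(f.attrs["detector_pitch"]))
        noise = None
        if "sigma_q" in f.attrs:
            blur = (BlurKernel(taps=f["blur_taps"][()])
                    if "blur_taps" in f else None)
            kwargs = {} if blur is None else {"blur": blur}
            noise = NoiseModel(sigma_q=float(f.attrs["sigma_q"]),
                               sigma_r=float(f.attrs["sigma_r"]),
                               exposure_factor=float(
                                   f.attrs["exposure_factor"]), **kwargs)
    return SinogramStack(views=views, geom=geom, noise=noise)


# -- volumes ----------------------------------------------------------------

def save_volume(path: str | Path, volume: np.ndarray,
                vol: VolumeSpec | None = None) -> None:
    with atomic_write(path) as tmp:
        with h5py.File(tmp, "w") as f:
            f.create_dataset("volume", data=np.asarray(volume,
                                                       dtype=np.float32))
            if vol is not None:
                f.attrs["voxel_size"] = np.asarray(vol.voxel_size)
                if vol.origin is not None:
                    f.attrs["origin"] = np.asarray(vol.origin)


def load_volume(path: str | Path) -> tuple[np.ndarray, VolumeSpec]:
    with h5py.File(path, "r") as f:
        volume = f["volume"][()].astype(float)
        kwargs = {}
        if "voxel_size" in f.attrs:
            kwargs["voxel_size"] = tuple(f.attrs["voxel_size"])
        if "origin" in f.attrs:
            kwargs["origin"] = tuple(f.attrs["origin"])
    return volume, VolumeSpec(shape=volume.shape, **kwargs)


def export_raster(path: str | Path, image: np.ndarray) -> None:
    """Flat 32-bit little-endian raster with a JSON shape sidecar."""
    img = np.asarray(image, dtype="<f4")
    with atomic_write(path) as tmp:
        img.tofile(tmp)
    with atomic_write(str(path) + ".json") as tmp:
        tmp.write_text(json.dumps({"shape": list(img.shape),
                                   "dtype": "<f4"}))


def import_raster(path: str | Path) -> np.ndarray:
    meta = json.loads(Path(str(path) + ".json").read_text())
    return np.fromfile(path, dtype=meta["dtype"]).reshape(
        meta["shape"]).astype(float)


# -- DICOM ------------------------------------------------------------------

_DICOM_MAX = 4095


def export_dicom(volume: np.ndarray, out_dir: str | Path,
                 vol: VolumeSpec | None = None) -> list[Path]:
    """Write a volume as a DICOM series, one file per slice.

    Pixel values are scaled linearly to the integer range [0, 4095]; the
    rescale slope and intercept tags are set so the float values are
    recoverable to within half a quantization step. Negative values are
    clamped to zero before scaling (export-time policy only).
    """
    x = np.maximum(np.asarray(volume, dtype=float), 0.0)
    if not np.all(np.isfinite(x)):
        raise ValueError("volume contains non-finite voxels")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        warnings.warn("constant volume: degenerate scale, slope set to 1")
        slope, intercept = 1.0, lo
        stored = np.zeros_like(x)
    else:
        slope = (hi - lo) / _DICOM_MAX
        intercept = lo
        stored = np.round((x - lo) / slope)
    stored = stored.astype(np.uint16)
    vs = vol.voxel_size if vol is not None else (0.1, 0.1, 1.0)

    series_uid = generate_uid()
    paths = []
    for k in range(x.shape[2]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "OT"
        ds.SeriesDescription = "tomomdr reconstruction"
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = x.shape[0], x.shape[1]
        ds.PixelSpacing = [str(vs[0]), str(vs[1])]
        ds.SliceThickness = str(vs[2])
        ds.ImagePositionPatient = ["0", "0", str(k * vs[2])]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = str(slope)
        ds.RescaleIntercept = str(intercept)
        ds.PixelData = stored[:, :, k].tobytes()
        path = out_dir / f"slice_{k:04d}.dcm"
        with atomic_write(path) as tmp:
            ds.save_as(tmp, enforce_file_format=True)
        paths.append(path)
    return paths


def import_dicom(series_dir: str | Path) -> np.ndarray:
    files = sorted(Path(series_dir).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {series_dir}")
    slices = []
    for f in files:
        ds = pydicom.dcmread(f)
        arr = ds.pixel_array.astype(float)
        slices.append(arr * float(ds.RescaleSlope)
                      + float(ds.RescaleIntercept))
    return np.stack(slices, axis=2)


# -- assessment patch sets --------------------------------------------------

def save_patches(path: str | Path, patches) -> None:
    """Patch-set HDF5: /patches, /labels, /cluster_ids, /view_ids, /is_mip.

    Missing cluster ids (negatives) are stored as -1.
    """
    from .assessment import AssessmentPatch  # noqa: F401 (type contract)

    with atomic_write(path) as tmp:
        with h5py.File(tmp, "w") as f:
            f.create_dataset("patches", data=np.stack(
                [p.pixels for p in patches]).astype(np.float32))
            f.create_dataset("labels", data=np.array(
                [p.label for p in patches], dtype=np.int8))
            f.create_dataset("cluster_ids", data=np.array(
                [-1 if p.cluster_id is None else p.cluster_id
                 for p in patches], dtype=np.int32))
            f.create_dataset("view_ids", data=np.array(
                [p.view_id for p in patches], dtype=np.int32))
            f.create_dataset("is_mip", data=np.array(
                [p.is_mip for p in patches], dtype=bool))


def load_patches(path: str | Path):
    from .assessment import AssessmentPatch

    with h5py.File(path, "r") as f:
        pixels = f["patches"][()]
        labels = f["labels"][()]
        cluster_ids = f["cluster_ids"][()]
        view_ids = f["view_ids"][()]
        is_mip = f["is_mip"][()]
    return [AssessmentPatch(
        pixels=pixels[i].astype(float), label=int(labels[i]),
        cluster_id=None if cluster_ids[i] < 0 else int(cluster_ids[i]),
        view_id=int(view_ids[i]), is_mip=bool(is_mip[i]))
        for i in range(len(labels))]


# -- geometry / noise profiles ---------------------------------------------

def save_geometry_profile(path: str | Path, geom: ScanGeometry,
                          noise: NoiseModel | None = None) -> None:
    doc = {"geometry": {
        "angles": list(geom.angles),
        "source_to_isocenter": geom.source_to_isocenter,
        "isocenter_to_support": geom.isocenter_to_support,
        "support_to_detector": geom.support_to_detector,
        "detector_shape": list(geom.detector_shape),
        "detector_pitch": geom.detector_pitch,
    }}
    if noise is not None:
        doc["noise"] = {"sigma_q": noise.sigma_q, "sigma_r": noise.sigma_r,
                        "exposure_factor": noise.exposure_factor,
                        "blur_taps": noise.blur.taps.tolist()}
    with atomic_write(path) as tmp:
        tmp.write_text(yaml.safe_dump(doc))


def load_geometry_profile(path: str | Path,
                          ) -> tuple[ScanGeometry, NoiseModel | None]:
    doc = yaml.safe_load(Path(path).read_text())
    g = doc["geometry"]
    geom = ScanGeometry(
        angles=tuple(g["angles"]),
        source_to_isocenter=g["source_to_isocenter"],
        isocenter_to_support=g["isocenter_to_support"],
        support_to_detector=g["support_to_detector"],
        detector_shape=tuple(g["detector_shape"]),
        detector_pitch=g["detector_pitch"])
    noise = None
    if "noise" in doc:
        n = doc["noise"]
        taps = np.asarray(n["blur_taps"], dtype=float)
        if abs(taps.sum() - 1.0) > 1e-3:
            raise ValueError(f"profile blur taps sum to {taps.sum():.4f}; "
                             "expected a normalized kernel")
        taps = taps / taps.sum()    # absorb rounding of the stored decimals
        noise = NoiseModel(sigma_q=n["sigma_q"], sigma_r=n["sigma_r"],
                           blur=BlurKernel(taps=taps),
                           exposure_factor=n.get("exposure_factor", 1.0))
    return geom, noise


# -- denoiser suites --------------------------------------------------------

def save_suite(directory: str | Path, suite: list[DenoiserSpec]) -> Path:
    """Suite manifest (JSON) plus one weights file per trained denoiser."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for gid, spec in enumerate(suite):
        entry = {"group_id": gid, "kind": spec.kind,
                 "noise_center": spec.noise_center,
                 "training_meta": {k: v for k, v in
                                   spec.training_meta.items()
                                   if k != "loss_trace"}}
        if spec.kind == "cnn":
            wfile = directory / f"denoiser_{gid:02d}.npz"
            weights = {f"w{i}": w for i, w in
                       enumerate(spec.params["weights"])}
            with atomic_write(wfile) as tmp:
                with open(tmp, "wb") as fh:
                    np.savez(fh, **weights)
            entry["weights_file"] = wfile.name
            entry["arch"] = spec.params["arch"]
            entry["scale"] = spec.params["scale"]
            entry["offset"] = spec.params["offset"]
        elif spec.kind == "gaussian":
            entry["sigma"] = spec.params["sigma"]
        elif spec.kind == "linear_smoother":
            entry["kernel"] = np.asarray(spec.params["kernel"]).tolist()
        entries.append(entry)
    manifest = directory / "suite.json"
    with atomic_write(manifest) as tmp:
        tmp.write_text(json.dumps({"denoisers": entries}, indent=2))
    return manifest


def load_suite(directory: str | Path) -> list[DenoiserSpec]:
    directory = Path(directory)
    doc = json.loads((directory / "suite.json").read_text())
    suite = []
    for entry in doc["denoisers"]:
        kind = entry["kind"]
        params: dict = {}
        if kind == "cnn":
            with np.load(directory / entry["weights_file"]) as data:
                weights = [data[f"w{i}"] for i in range(len(data.files))]
            params = dict(weights=weights, arch=entry["arch"],
                          scale=entry["scale"], offset=entry["offset"])
        elif kind == "gaussian":
            params = dict(sigma=entry["sigma"])
        elif kind == "linear_smoother":
            params = dict(kernel=np.asarray(entry["kernel"]))
        suite.append(DenoiserSpec(kind=kind,
                                  noise_center=entry["noise_center"],
                                  params=params,
                                  training_meta=entry.get("training_meta",
                                                          {})))
    return suite
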