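"""Run configuration, seed fan-out, and the staged pipeline.

A run is driven by one :class:`RunConfig` (serializable to YAML without
loss) and one global seed. Every stochastic operation draws from a named
child seed derived from the global seed, so changing one stage's seed
usage never shifts another stage's draws.

Stages: ``simulate`` (phantom + cluster + exposure-sweep acquisition),
``reconstruct`` (one volume per acquired stack), ``denoise-train`` (noise
-grouped denoiser suite from low/high-dose reconstructions), ``assess``
(patch extraction + observer training + AUC/RMS point). Each stage writes
its outputs under the run directory and is skipped when they already exist
(unless forced); the run manifest records inputs, outputs, seeds and wall
time for exact re-runs.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from .assessment import (ConditionData, ObserverConfig, evaluate_condition,
                         extract_patches, roi_rms)
from .denoiser import build_suite
from .geometry import (VolumeSpec, gaussian_blur_kernel, pristina_like,
                       required_detector_shape)
from .noise import NoiseModel
from .phantom import (ExposureSweep, MCClusterSpec, PhantomSpec, acquire,
                      generate_phantom, insert_mc_cluster)
from .recon import ReconConfig, mdr_reconstruct, sart_reconstruct

__all__ = ["RunConfig", "child_seed", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger("tomomdr")

ALL_STAGES = ("simulate", "reconstruct", "denoise-train", "assess")


def child_seed(global_seed: int, name: str) -> int:
    """Stable named substream seed (< 2**31)."""
    return int(np.random.SeedSequence(
        [int(global_seed), zlib.crc32(name.encode())]
    ).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Nested run configuration; every field round-trips through YAML."""

    seed: int = 0
    out_dir: str = "runs/default"
    log_level: str = "INFO"
    phantom: dict = field(default_factory=lambda: dict(
        gvf=0.34, shape=[64, 64, 16], texture_seed=0,
        cluster=dict(center=[32, 32, 8], n_specks=6,
                     speck_diameter_range=[0.150, 0.180], contrast=1.5)))
    noise: dict = field(default_factory=lambda: dict(
        sigma_q=0.05, sigma_r=0.01, blur_fwhm_px=2.0))
    sweep: dict = field(default_factory=lambda: dict(
        factors=[0.25, 1.0, 3.0]))
    recon: dict = field(default_factory=lambda: dict(
        method="sart", n_iterations=2, relaxation=0.5))
    denoiser: dict = field(default_factory=lambda: dict(
        k_groups=2, n_pairs_per_volume=200, patch_size=32,
        epochs=10, depth=4, width=8))
    assessment: dict = field(default_factory=lambda: dict(
        patch_size=40, n_negatives=12, repeats=2, epochs=20,
        backbone="vgg", width=8))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        with tio.atomic_write(path) as tmp:
            tmp.write_text(yaml.safe_dump(asdict(self)))


def _stage_outputs(cfg: RunConfig) -> dict[str, list[Path]]:
    out = Path(cfg.out_dir)
    factors = cfg.sweep["factors"]
    return {
        "simulate": [out / "phantom.h5", out / "boxes.csv"]
        + [out / f"sino_{f:g}.h5" for f in factors],
        "reconstruct": [out / f"recon_{f:g}.h5" for f in factors],
        "denoise-train": [out / "suite" / "suite.json"],
        "assess": [out / "assessment.json"],
    }


def _build_scene(cfg: RunConfig):
    shape = tuple(cfg.phantom["shape"])
    vol = VolumeSpec(shape=shape)
    geom0 = pristina_like()
    det = required_detector_shape(geom0, vol)
    geom = pristina_like(detector_shape=det)
    kernel = gaussian_blur_kernel(cfg.noise.get("blur_fwhm_px", 2.0))
    noise = NoiseModel(sigma_q=cfg.noise["sigma_q"],
                       sigma_r=cfg.noise["sigma_r"], blur=kernel)
    return vol, geom, noise


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] | list[str] = (),
                 force: bool = False) -> dict:
    """Execute the requested stages and write/update the run manifest."""
    stages = tuple(stages)
    for s in stages:
        if s not in ALL_STAGES:
            raise ValueError(f"unknown stage {s!r}; choose from {ALL_STAGES}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    manifest_path = out / "manifest.json"
    manifest = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else {"stages": {}})
    manifest["config"] = asdict(cfg)
    outputs = _stage_outputs(cfg)

    def record(stage: str, t0: float, inputs: list, outs: list) -> None:
        manifest["stages"][stage] = {
            "seed": child_seed(cfg.seed, stage),
            "inputs": [str(p) for p in inputs],
            "outputs": [str(p) for p in outs],
            "wall_time_s": round(time.time() - t0, 3),
        }

    def fresh(stage: str) -> bool:
        return not force and all(p.exists() for p in outputs[stage])

    ordered = [s for s in ALL_STAGES if s in stages]
    for stage in ordered:
        if fresh(stage):
            log.info("stage %s: outputs exist, skipping", stage)
            continue
        deps = {"reconstruct": "simulate", "denoise-train": "reconstruct",
                "assess": "reconstruct"}.get(stage)
        if deps and not all(p.exists() for p in outputs[deps]):
            if deps in ordered:
                raise RuntimeError(f"internal ordering error: {deps} should "
                                   f"have run before {stage}")
            missing = [str(p) for p in outputs[deps] if not p.exists()]
            raise FileNotFoundError(
                f"stage '{stage}' needs the outputs of '{deps}' "
                f"(missing: {missing}); run that stage first")
        t0 = time.time()
        if stage == "simulate":
            _run_simulate(cfg, out)
            record(stage, t0, [], outputs[stage])
        elif stage == "reconstruct":
            _run_reconstruct(cfg, out)
            record(stage, t0, outputs["simulate"], outputs[stage])
        elif stage == "denoise-train":
            _run_denoise_train(cfg, out)
            record(stage, t0, outputs["reconstruct"], outputs[stage])
        elif stage == "assess":
            _run_assess(cfg, out)
            record(stage, t0, outputs["reconstruct"], outputs[stage])
        log.info("stage %s: done in %.1fs", stage, time.time() - t0)

    with tio.atomic_write(manifest_path) as tmp:
        tmp.write_text(json.dumps(manifest, indent=2))
    return manifest


def _run_simulate(cfg: RunConfig, out: Path) -> None:
    vol, geom, noise = _build_scene(cfg)
    p = cfg.phantom
    spec = PhantomSpec(gvf=p["gvf"], thickness=vol.thickness,
                       texture_seed=child_seed(cfg.seed, "texture"))
    volume, labels = generate_phantom(spec, vol)
    c = p.get("cluster")
    boxes = []
    if c:
        mc = MCClusterSpec(center=tuple(c["center"]),
                           n_specks=c.get("n_specks", 6),
                           speck_diameter_range=tuple(
                               c.get("speck_diameter_range", (0.15, 0.18))),
                           cluster_extent=c.get("cluster_extent", 5.0),
                           contrast=c.get("contrast", 1.5),
                           layout_seed=child_seed(cfg.seed, "layout"))
        volume, gt = insert_mc_cluster(volume, labels, mc, vol)
        boxes.append(gt.box)
    tio.save_volume(out / "phantom.h5", volume, vol)
    with tio.atomic_write(out / "boxes.csv") as tmp:
        lines = ["view,x0,y0,z0,x1,y1,z1"]
        lines += [f"0,{b[0]},{b[1]},{b[2]},{b[3]},{b[4]},{b[5]}"
                  for b in boxes]
        tmp.write_text("\n".join(lines) + "\n")
    sweep = ExposureSweep(factors=tuple(cfg.sweep["factors"]))
    stacks = acquire(volume, geom, noise, sweep,
                     seed=child_seed(cfg.seed, "acquire"), vol=vol)
    for f, stack in stacks.items():
        tio.save_sinogram(out / f"sino_{f:g}.h5", stack)


def _run_reconstruct(cfg: RunConfig, out: Path) -> None:
    vol = VolumeSpec(shape=tuple(cfg.phantom["shape"]))
    method = cfg.recon.get("method", "sart")
    for f in cfg.sweep["factors"]:
        stack = tio.load_sinogram(out / f"sino_{f:g}.h5")
        if method == "sart":
            x = sart_reconstruct(stack, vol,
                                 n_iterations=cfg.recon.get("n_iterations",
                                                            2),
                                 relaxation=cfg.recon.get("relaxation", 0.5))
        else:
            rc = ReconConfig(
                beta_ep=cfg.recon.get("beta_ep", 50.0),
                beta_red=cfg.recon.get("beta_red", 0.0),
                n_iter=cfg.recon.get("n_iter", 3),
                n_inner=cfg.recon.get("n_inner", 3),
                use_dbcn=cfg.recon.get("use_dbcn", True))
            suite = (tio.load_suite(out / "suite")
                     if rc.beta_red > 0 else None)
            x = mdr_reconstruct(stack, vol, rc, suite=suite).image
        tio.save_volume(out / f"recon_{f:g}.h5", x, vol)


def _run_denoise_train(cfg: RunConfig, out: Path) -> None:
    factors = sorted(cfg.sweep["factors"])
    hd_factor = factors[-1]
    hd, _ = tio.load_volume(out / f"recon_{hd_factor:g}.h5")
    ld_volumes = []
    for f in factors[:-1]:
        v, _ = tio.load_volume(out / f"recon_{f:g}.h5")
        ld_volumes.append(v)
    d = cfg.denoiser
    suite = build_suite(
        ld_volumes, [hd] * len(ld_volumes),
        k_groups=min(d.get("k_groups", 2), len(ld_volumes)),
        n_pairs_per_volume=d.get("n_pairs_per_volume", 200),
        patch_size=d.get("patch_size", 32),
        seed=child_seed(cfg.seed, "denoise-train"),
        train_kwargs=dict(epochs=d.get("epochs", 10),
                          arch=dict(depth=d.get("depth", 4),
                                    width=d.get("width", 8))))
    tio.save_suite(out / "suite", suite)


def _read_boxes(path: Path) -> list[tuple[int, ...]]:
    lines = path.read_text().strip().splitlines()[1:]
    return [tuple(int(v) for v in ln.split(",")[1:]) for ln in lines]


def _run_assess(cfg: RunConfig, out: Path) -> None:
    a = cfg.assessment
    boxes = _read_boxes(out / "boxes.csv")
    results = {}
    for f in cfg.sweep["factors"]:
        volume, _ = tio.load_volume(out / f"recon_{f:g}.h5")
        seed = child_seed(cfg.seed, f"assess-{f:g}")
        patches = extract_patches(volume, boxes,
                                  patch_size=a.get("patch_size", 40),
                                  n_negatives=a.get("n_negatives", 12),
                                  seed=seed)
        neg = [p for p in patches if p.label == 0]
        # single-phantom smoke assessment: train and test share the phantom,
        # so no phantom-level split is claimed (sets left empty)
        data = ConditionData(
            condition=f"exposure x{f:g}",
            ne_patches=neg,
            ne_labels=np.array([roi_rms(p.pixels) for p in neg]),
            train_patches=patches, test_patches=patches)
        oc = ObserverConfig(backbone=a.get("backbone", "vgg"),
                            width=a.get("width", 8),
                            epochs=a.get("epochs", 20))
        res = evaluate_condition(data, oc, repeats=a.get("repeats", 2),
                                 seed=seed)
        results[f"{f:g}"] = dict(auc_mean=res.auc_mean, auc_std=res.auc_std,
                                 aucs=list(res.aucs), rms_mean=res.rms_mean)
    with tio.atomic_write(out / "assessment.json") as tmp:
        tmp.write_text(json.dumps(results, indent=2))
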