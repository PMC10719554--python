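"""Comparison harnesses: cost-term ablation and regularization sweep.

The ablation matrix toggles the three cost terms — prewhitened
detector-blur data-fit (off means the plain least-squares data-fit),
edge-preserving penalty, denoising penalty — giving six partial models plus
the full model, all run through the same solver with no code changes. Each
condition is reconstructed, measured for volume RMS noise, and scored by
the observer pipeline, yielding one AUC-vs-RMS point per condition.

The parameter sweep runs the full model over a beta_EP x beta_RED grid and
reports the same point per grid cell.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .assessment import (ConditionData, DetectabilityResult, ObserverConfig,
                         estimate_volume_rms, evaluate_condition,
                         extract_patches, roi_rms)
from .geometry import VolumeSpec
from .noise import SinogramStack
from .recon import ReconConfig, mdr_reconstruct

__all__ = ["ablation_conditions", "run_ablation", "run_parameter_sweep"]


def ablation_conditions(base: ReconConfig) -> dict[str, ReconConfig]:
    """The six partial models plus the full model, as solver configs."""
    b_ep, b_red = base.beta_ep, base.beta_red
    combos = {
        "dbcn_only": (True, 0.0, 0.0),
        "ep_only": (False, b_ep, 0.0),
        "red_only": (False, 0.0, b_red),
        "dbcn+ep": (True, b_ep, 0.0),
        "dbcn+red": (True, 0.0, b_red),
        "ep+red": (False, b_ep, b_red),
        "full_mdr": (True, b_ep, b_red),
    }
    return {name: replace(base, use_dbcn=dbcn, beta_ep=ep, beta_red=red)
            for name, (dbcn, ep, red) in combos.items()}


def _score_volume(name: str, volume: np.ndarray, boxes, observer_config,
                  repeats: int, seed: int, patch_size: int,
                  n_negatives: int) -> DetectabilityResult:
    patches = extract_patches(volume, boxes, patch_size=patch_size,
                              n_negatives=n_negatives, seed=seed)
    neg = [p for p in patches if p.label == 0]
    data = ConditionData(
        condition=name, ne_patches=neg,
        ne_labels=np.array([roi_rms(p.pixels) for p in neg]),
        train_patches=patches, test_patches=patches)
    return evaluate_condition(data, observer_config, repeats=repeats,
                              seed=seed)


def run_ablation(stack: SinogramStack, vol: VolumeSpec, boxes,
                 denoiser, base_config: ReconConfig | None = None,
                 observer_config: ObserverConfig | None = None,
                 repeats: int = 1, seed: int = 0, patch_size: int = 40,
                 n_negatives: int = 12,
                 ) -> dict[str, dict]:
    """Reconstruct and score every ablation condition.

    ``denoiser`` is a callable G(volume) -> volume used whenever the
    denoising penalty is on. Returns, per condition, the solver config
    used, the volume RMS noise, and the observer's detectability result.
    """
    base_config = base_config or ReconConfig()
    results: dict[str, dict] = {}
    for name, cfg in ablation_conditions(base_config).items():
        state = mdr_reconstruct(
            stack, vol, cfg,
            denoiser=denoiser if cfg.beta_red > 0 else None)
        image = state.image
        rms = estimate_volume_rms(image, seed=seed)
        det = _score_volume(name, image, boxes, observer_config, repeats,
                            seed, patch_size, n_negatives)
        results[name] = dict(config=cfg, volume_rms=rms, result=det)
    return results


def run_parameter_sweep(stack: SinogramStack, vol: VolumeSpec, boxes,
                        denoiser, beta_eps, beta_reds,
                        base_config: ReconConfig | None = None,
                        observer_config: ObserverConfig | None = None,
                        repeats: int = 1, seed: int = 0,
                        patch_size: int = 40, n_negatives: int = 12,
                        score: bool = True) -> list[dict]:
    """Full-model grid over regularization weights.

    Returns one entry per (beta_EP, beta_RED) cell with the volume RMS
    noise and, when ``score`` is set, the observer detectability result.
    """
    base_config = base_config or ReconConfig()
    out = []
    for b_ep in beta_eps:
        for b_red in beta_reds:
            cfg = replace(base_config, beta_ep=float(b_ep),
                          beta_red=float(b_red), use_dbcn=True)
            state = mdr_reconstruct(stack, vol, cfg, denoiser=denoiser)
            image = state.image
            entry = dict(beta_ep=float(b_ep), beta_red=float(b_red),
                         volume_rms=estimate_volume_rms(image, seed=seed))
            if score:
                entry["result"] = _score_volume(
                    f"bEP={b_ep:g},bRED={b_red:g}", image, boxes,
                    observer_config, repeats, seed, patch_size, n_negatives)
            out.append(entry)
    return out
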