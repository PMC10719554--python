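"""Task-based image quality assessment.

Two complementary measures drive every comparison in this package:

* **RMS noise** — an analytic ROI-grid estimator (``roi_rms``): 10x10 pixel
  ROIs tiled at 25-pixel spacing, each detrended by a least-squares 2D
  quadratic (6 coefficients), the RMS of the residuals averaged over ROIs,
  with no degrees-of-freedom correction; and a learned counterpart, the
  CNN noise estimator (CNN-NE), a regression network trained on patches
  labeled by the analytic method.
* **Microcalcification-cluster detectability** — a learned model observer
  (CNN-MC) scoring 128x128 (configurable) maximum-intensity-projected,
  background-detrended patches for the presence of a cluster; its test-set
  ROC AUC is the detectability measure. The CNN-MC is transfer-initialized
  from the trained CNN-NE backbone — training it from random weights is
  kept available only as a negative control.

Deployment conventions: every patch score is the mean over the 8 dihedral
transforms of the patch (test-time augmentation); positive-patch scores
are pooled (arithmetic mean) per cluster and view before ROC analysis;
training is repeated (default 5 times) with fresh seeds and AUC is
reported as mean +- std.

The model observers are deliberately capacity-limited (well under 1M
parameters, asserted): an observer strong enough to saturate AUC at 1
cannot discriminate between image conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from . import nn

__all__ = [
    "AssessmentPatch",
    "ObserverModel",
    "ObserverConfig",
    "DetectabilityResult",
    "roi_rms",
    "detrend_quadratic",
    "estimate_volume_rms",
    "extract_patches",
    "build_backbone",
    "train_cnn_ne",
    "train_cnn_mc",
    "score_patches",
    "pool_cluster_scores",
    "roc_auc",
    "evaluate_condition",
    "dihedral_transforms",
]

MAX_OBSERVER_PARAMS = 1_000_000


# ---------------------------------------------------------------------------
# analytic RMS noise
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _quadratic_design_pinv(h: int, w: int) -> np.ndarray:
    """Pseudo-inverse of the 6-column quadratic design on an h x w grid."""
    yy, xx = np.meshgrid(np.arange(h, dtype=float),
                         np.arange(w, dtype=float), indexing="ij")
    x = xx.ravel() - xx.mean()
    y = yy.ravel() - yy.mean()
    design = np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
    return np.linalg.pinv(design)


def detrend_quadratic(patch: np.ndarray) -> np.ndarray:
    """Subtract the least-squares 2D quadratic surface from a patch."""
    p = np.asarray(patch, dtype=float)
    if p.ndim != 2:
        raise ValueError("patch must be 2D")
    pinv = _quadratic_design_pinv(*p.shape)
    coef = pinv @ p.ravel()
    yy, xx = np.meshgrid(np.arange(p.shape[0], dtype=float),
                         np.arange(p.shape[1], dtype=float), indexing="ij")
    x = xx.ravel() - xx.mean()
    y = yy.ravel() - yy.mean()
    fit = (coef[0] + coef[1] * x + coef[2] * y + coef[3] * x * x
           + coef[4] * x * y + coef[5] * y * y)
    return p - fit.reshape(p.shape)


def roi_rms(patch: np.ndarray, roi_size: int = 10, spacing: int = 25,
            ) -> float:
    """ROI-grid RMS noise of a patch, in pixel-value units.

    ROIs of ``roi_size`` x ``roi_size`` pixels are anchored at (0, 0) and
    tiled at ``spacing``-pixel grid steps; ROIs extending past the patch
    are dropped. Each ROI is quadratic-detrended and the RMS of its
    residuals computed with no degrees-of-freedom correction; the mean over
    ROIs is returned. For white noise of standard deviation sigma the
    expected value is sqrt((roi_size^2 - 6)/roi_size^2) * sigma (6 of the
    100 residual degrees of freedom go to the fit), e.g. 9.70 for
    sigma = 10 with the default 10x10 ROI.
    """
    p = np.asarray(patch, dtype=float)
    if p.ndim != 2:
        raise ValueError("patch must be 2D")
    h, w = p.shape
    if h < roi_size or w < roi_size:
        raise ValueError(
            f"patch {p.shape} too small for a {roi_size}x{roi_size} ROI")
    pinv = _quadratic_design_pinv(roi_size, roi_size)
    rois = [p[r:r + roi_size, c:c + roi_size].ravel()
            for r in range(0, h - roi_size + 1, spacing)
            for c in range(0, w - roi_size + 1, spacing)]
    rois = np.array(rois)                      # (n_roi, roi_size^2)
    rois = rois - rois.mean(axis=1, keepdims=True)   # exact 0 on constants
    coef = pinv @ rois.T                       # (6, n_roi)
    yy, xx = np.meshgrid(np.arange(roi_size, dtype=float),
                         np.arange(roi_size, dtype=float), indexing="ij")
    x = xx.ravel() - xx.mean()
    y = yy.ravel() - yy.mean()
    design = np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
    resid = rois - (design @ coef).T
    rms_per_roi = np.sqrt(np.mean(resid**2, axis=1))
    return float(rms_per_roi.mean())


def estimate_volume_rms(volume: np.ndarray, seed: int = 0,
                        n_patches: int = 16, patch_size: int = 40) -> float:
    """Volume-level RMS noise: mean of ``roi_rms`` over seeded random
    in-slice patches."""
    x = np.asarray(volume, dtype=float)
    if x.ndim != 3:
        raise ValueError("volume must be 3D")
    ps = min(patch_size, x.shape[0], x.shape[1])
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_patches):
        ix = rng.integers(0, x.shape[0] - ps + 1)
        iy = rng.integers(0, x.shape[1] - ps + 1)
        iz = rng.integers(0, x.shape[2])
        vals.append(roi_rms(x[ix:ix + ps, iy:iy + ps, iz]))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------

@dataclass
class AssessmentPatch:
    """One observer input patch.

    ``pixels`` is square (128x128 in the full-scale protocol; the size is a
    parameter of :func:`extract_patches`), background-detrended, and — for
    cluster patches and their matched negatives — the maximum intensity
    projection over 3 adjacent slices. Positives carry the identity of
    their cluster for per-cluster score pooling.
    """

    pixels: np.ndarray
    label: int                      # 1 = contains a cluster, 0 = background
    cluster_id: int | None = None
    view_id: int = 0
    is_mip: bool = True

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or (self.pixels.shape[0]
                                     != self.pixels.shape[1]):
            raise ValueError("patch pixels must be square 2D")
        if self.label == 1 and self.cluster_id is None:
            raise ValueError("positive patches must carry a cluster_id")


def _boxes_overlap(a, b) -> bool:
    return all(a[d] < b[d + 3] and b[d] < a[d + 3] for d in range(3))


def _mip_patch(volume: np.ndarray, cx: int, cy: int, zc: int, ps: int,
               mip_slices: int, detrend: bool) -> np.ndarray:
    half = ps // 2
    x0, y0 = cx - half, cy - half
    sl = volume[x0:x0 + ps, y0:y0 + ps,
                zc - mip_slices // 2: zc + mip_slices // 2 + 1]
    patch = sl.max(axis=2) if mip_slices > 1 else sl[:, :, 0]
    return detrend_quadratic(patch) if detrend else patch.copy()


def extract_patches(volume: np.ndarray, boxes: Sequence[tuple],
                    patch_size: int = 128, n_negatives: int = 20,
                    seed: int = 0, mip_slices: int = 3, detrend: bool = True,
                    view_id: int = 0) -> list[AssessmentPatch]:
    """Positive patches tiling each ground-truth box, plus random negatives.

    Positives tile a box on a regular grid with centers separated by the
    patch size in-plane and by 2 slices in depth (alternate planes get
    half-patch offset centers); boxes smaller than the patch yield one
    patch centered on the box. Each patch is the maximum intensity
    projection over ``mip_slices`` slices, then quadratic-detrended.
    Negatives are random, pairwise non-overlapping, and disjoint from every
    box. Deterministic given ``seed``.
    """
    x = np.asarray(volume, dtype=float)
    if x.ndim != 3:
        raise ValueError("volume must be 3D")
    nx, ny, nz = x.shape
    ps = patch_size
    if nx < ps or ny < ps:
        raise ValueError(f"volume slices smaller than patch size {ps}")
    if nz < mip_slices:
        raise ValueError(
            f"volume has {nz} slices; need >= {mip_slices} for the MIP")
    half, hm = ps // 2, mip_slices // 2
    patches: list[AssessmentPatch] = []

    def clamp(v, lo, hi):
        return int(min(max(v, lo), hi))

    for cid, box in enumerate(boxes):
        x0, y0, z0, x1, y1, z1 = box
        if not (0 <= x0 < x1 <= nx and 0 <= y0 < y1 <= ny
                and 0 <= z0 < z1 <= nz):
            raise ValueError(f"box {box} not inside the volume")
        # depth: central slices whose 3-slice MIP stays inside the box if
        # possible, stepping by 2; a thin box gets its central slice
        zcs = list(range(z0 + hm, max(z1 - hm, z0 + hm + 1), 2))
        for plane_idx, zc in enumerate(zcs):
            zc = clamp(zc, hm, nz - 1 - hm)
            offset = (plane_idx % 2) * half
            if x1 - x0 <= ps or y1 - y0 <= ps:
                centers = [(clamp((x0 + x1) // 2, half, nx - half),
                            clamp((y0 + y1) // 2, half, ny - half))]
            else:
                centers = [(cx, cy)
                           for cx in range(x0 + half + offset, x1 - half + 1,
                                           ps)
                           for cy in range(y0 + half + offset, y1 - half + 1,
                                           ps)]
            for cx, cy in centers:
                patches.append(AssessmentPatch(
                    pixels=_mip_patch(x, cx, cy, zc, ps, mip_slices, detrend),
                    label=1, cluster_id=cid, view_id=view_id,
                    is_mip=mip_slices > 1))

    rng = np.random.default_rng(seed)
    taken = [tuple(b) for b in boxes]

    # candidate centers on a patch-spaced grid (pairwise disjoint by
    # construction) visited in random order with a random depth offset;
    # random fill-in afterwards
    oz = int(rng.integers(0, mip_slices))
    grid = [(cx, cy, zc)
            for cx in range(half, nx - half + 1, ps)
            for cy in range(half, ny - half + 1, ps)
            for zc in range(hm + min(oz, max(nz - mip_slices - hm, 0)),
                            nz - hm, mip_slices)]
    rng.shuffle(grid)

    def try_place(cx, cy, zc) -> bool:
        cand = (cx - half, cy - half, zc - hm, cx + half, cy + half,
                zc + hm + 1)
        if any(_boxes_overlap(cand, b) for b in taken):
            return False
        taken.append(cand)
        patches.append(AssessmentPatch(
            pixels=_mip_patch(x, cx, cy, zc, ps, mip_slices, detrend),
            label=0, cluster_id=None, view_id=view_id,
            is_mip=mip_slices > 1))
        return True

    neg_found = 0
    for cx, cy, zc in grid:
        if neg_found >= n_negatives:
            break
        neg_found += try_place(cx, cy, zc)
    attempts = 0
    while neg_found < n_negatives:
        attempts += 1
        if attempts > 500 * max(n_negatives, 1):
            raise ValueError(
                "could not place the requested number of non-overlapping "
                "negative patches")
        neg_found += try_place(int(rng.integers(half, nx - half + 1)),
                               int(rng.integers(half, ny - half + 1)),
                               int(rng.integers(hm, nz - hm)))
    return patches


# ---------------------------------------------------------------------------
# observer networks
# ---------------------------------------------------------------------------

class _ResBlock:
    """Two 3x3 convs with an identity skip and ReLUs."""

    def __init__(self, c: int, rng: np.random.Generator):
        self.c1 = nn.Conv2d(c, c, rng=rng)
        self.r1 = nn.ReLU()
        self.c2 = nn.Conv2d(c, c, rng=rng)
        self.r2 = nn.ReLU()

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x):
        self._x = x
        y = self.c2.forward(self.r1.forward(self.c1.forward(x)))
        return self.r2.forward(y + x)

    def backward(self, gout):
        g = self.r2.backward(gout)
        gx = self.c1.backward(self.r1.backward(self.c2.backward(g)))
        return gx + g


def build_backbone(family: str, width: int = 8,
                   rng: np.random.Generator | None = None,
                   pooling: str = "avg") -> nn.Sequential:
    """One of three small convolutional feature extractors.

    ``vgg``: plain stacked 3x3 convs with stride-2 downsampling;
    ``resnet``: the same trunk with identity-skip blocks; ``convnext``: a
    5x5 spatial conv followed by 1x1 channel-mixing convs per stage. All
    end in global average pooling over ``4 * width`` channels, so the
    networks accept any input size and the feature width is shared for
    transfer between the noise-estimation and detection heads.
    """
    rng = rng or np.random.default_rng(0)
    w = width
    if family == "vgg":
        layers = [
            nn.Conv2d(1, w, rng=rng), nn.ReLU(),
            nn.Conv2d(w, 2 * w, stride=2, rng=rng), nn.ReLU(),
            nn.Conv2d(2 * w, 2 * w, rng=rng), nn.ReLU(),
            nn.Conv2d(2 * w, 4 * w, stride=2, rng=rng), nn.ReLU(),
            nn.Conv2d(4 * w, 4 * w, rng=rng), nn.ReLU(),
        ]
    elif family == "resnet":
        layers = [
            nn.Conv2d(1, w, rng=rng), nn.ReLU(),
            nn.Conv2d(w, 2 * w, stride=2, rng=rng), nn.ReLU(),
            _ResBlock(2 * w, rng),
            nn.Conv2d(2 * w, 4 * w, stride=2, rng=rng), nn.ReLU(),
            _ResBlock(4 * w, rng),
        ]
    elif family == "convnext":
        layers = [
            nn.Conv2d(1, w, k=5, rng=rng), nn.ReLU(),
            nn.Conv2d(w, 2 * w, k=1, rng=rng), nn.ReLU(),
            nn.Conv2d(2 * w, 2 * w, k=5, stride=2, rng=rng), nn.ReLU(),
            nn.Conv2d(2 * w, 4 * w, k=1, rng=rng), nn.ReLU(),
            nn.Conv2d(4 * w, 4 * w, k=5, stride=2, rng=rng), nn.ReLU(),
        ]
    else:
        raise ValueError(f"unknown backbone family {family!r}")
    # joint mean/max pooling keeps sparse bright specks visible in the
    # pooled features ('avg' collapses to plain average pooling)
    if pooling == "avgmax":
        layers.append(nn.GlobalAvgMaxPool())
    elif pooling == "avg":
        layers.append(nn.GlobalAvgPool())
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    return nn.Sequential(layers)


def _n_features(config) -> int:
    return (8 if config.pooling == "avgmax" else 4) * config.width


def _build_head(n_features: int, rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential([nn.Dense(n_features, 16, rng=rng), nn.ReLU(),
                          nn.Dense(16, 1, rng=rng)])


@dataclass
class ObserverConfig:
    """Observer training configuration (desk-scale defaults).

    The full-scale operating point for the noise estimator — 600 epochs,
    batch 2048, learning rate 1e-3 decayed by 0.8 every 20 epochs (300
    epochs / batch 512 / lr 1e-5 decayed every 10 for the detector) — is
    reachable by setting these fields accordingly.
    """

    backbone: str = "vgg"
    width: int = 8
    epochs: int = 30
    batch_size: int = 32
    lr: float = 1e-3
    lr_mc: float = 1e-4       # fine-tuning rate, much smaller than lr
    lr_decay: float = 0.8
    lr_decay_every: int = 20
    pooling: str = "avg"      # 'avg' or 'avgmax' global pooling


@dataclass
class ObserverModel:
    """Backbone + head with provenance. ``head_kind`` is 'ne' (regression,
    nonnegative RMS output) or 'mc' (binary score in [0, 1])."""

    backbone: nn.Sequential
    head: nn.Sequential
    family: str
    width: int
    head_kind: str
    pooling: str = "avg"
    init_provenance: str = "random"
    repeat_seed: int | None = None
    input_scale: float = 1.0
    label_scale: float = 1.0
    training_meta: dict = field(default_factory=dict)

    def n_parameters(self) -> int:
        return self.backbone.n_parameters() + self.head.n_parameters()

    def _raw(self, pixels: np.ndarray) -> np.ndarray:
        x = np.asarray(pixels, dtype=float)[:, None] / self.input_scale
        return self.head.forward(self.backbone.forward(x))[:, 0]

    def predict(self, pixels: np.ndarray) -> np.ndarray:
        """(n, H, W) patches -> per-patch outputs (RMS noise or score)."""
        raw = self._raw(pixels)
        if self.head_kind == "ne":
            return np.maximum(raw, 0.0) * self.label_scale
        return nn.sigmoid(raw)


def _assert_capacity(model: ObserverModel) -> None:
    n = model.n_parameters()
    if n > MAX_OBSERVER_PARAMS:
        raise ValueError(
            f"observer has {n} parameters; capacity is deliberately capped "
            f"at {MAX_OBSERVER_PARAMS} so AUC does not saturate")


def _as_pixel_array(patches) -> np.ndarray:
    if isinstance(patches, np.ndarray):
        return patches.astype(float)
    return np.stack([p.pixels for p in patches]).astype(float)


def train_cnn_ne(patches, labels: Sequence[float],
                 config: ObserverConfig | None = None, seed: int = 0,
                 val_patches=None, val_labels=None) -> ObserverModel:
    """Train the noise-estimation regressor (MSE loss on analytic RMS
    labels). Deterministic given ``seed``.

    With ``val_patches``/``val_labels`` supplied, the weights from the
    epoch with the lowest validation loss are restored at the end (early
    stopping against late-training divergence).
    """
    config = config or ObserverConfig()
    pixels = _as_pixel_array(patches)
    labels = np.asarray(labels, dtype=float)
    if pixels.shape[0] < 1:
        raise ValueError("need at least one training patch")
    if pixels.shape[0] != labels.shape[0]:
        raise ValueError("labels must align with patches")
    rng = np.random.default_rng(seed)
    backbone = build_backbone(config.backbone, config.width, rng,
                              config.pooling)
    head = _build_head(_n_features(config), rng)
    input_scale = float(pixels.std()) or 1.0
    label_scale = float(np.abs(labels).mean()) or 1.0
    model = ObserverModel(backbone=backbone, head=head,
                          family=config.backbone, width=config.width,
                          head_kind="ne", pooling=config.pooling,
                          init_provenance="random",
                          repeat_seed=seed, input_scale=input_scale,
                          label_scale=label_scale)
    _assert_capacity(model)
    x = pixels[:, None] / input_scale
    y = labels / label_scale
    xv = yv = None
    if val_patches is not None:
        xv = _as_pixel_array(val_patches)[:, None] / input_scale
        yv = np.asarray(val_labels, dtype=float) / label_scale
    params = backbone.params() + head.params()
    opt = nn.Adam(params, lr=config.lr)
    n = x.shape[0]
    trace, val_trace = [], []
    best_val, best_weights = np.inf, None
    for epoch in range(config.epochs):
        opt.lr = config.lr * config.lr_decay ** (epoch
                                                 // config.lr_decay_every)
        order = rng.permutation(n)
        ep_loss = 0.0
        for s in range(0, n, config.batch_size):
            idx = order[s:s + config.batch_size]
            pred = head.forward(backbone.forward(x[idx]))[:, 0]
            loss, dpred = nn.mse_loss(pred, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite NE loss at epoch "
                                         f"{epoch}: {trace[-5:]}")
            backbone.zero_grad()
            head.zero_grad()
            backbone.backward(head.backward(dpred[:, None]))
            opt.step()
            ep_loss += loss * len(idx)
        trace.append(ep_loss / n)
        if xv is not None:
            vpred = head.forward(backbone.forward(xv))[:, 0]
            vloss = float(np.mean((vpred - yv)**2))
            val_trace.append(vloss)
            if vloss < best_val:
                best_val = vloss
                best_weights = (backbone.get_weights(), head.get_weights())
    if best_weights is not None:
        backbone.set_weights(best_weights[0])
        head.set_weights(best_weights[1])
    model.training_meta = dict(loss_trace=trace, val_trace=val_trace,
                               seed=seed, config=vars(config).copy())
    return model


def dihedral_transforms(patch: np.ndarray) -> list[np.ndarray]:
    """The 8 rotation/flip variants of a square patch."""
    out = []
    for flip in (False, True):
        q = patch[:, ::-1] if flip else patch
        for k in range(4):
            out.append(np.rot90(q, k))
    return out


def train_cnn_mc(patches, labels: Sequence[int], init: ObserverModel,
                 config: ObserverConfig | None = None, seed: int = 0,
                 transfer: bool = True) -> ObserverModel:
    """Fine-tune the cluster detector (BCE loss) from a trained noise
    estimator.

    The backbone starts from ``init``'s weights (transfer is the default;
    ``transfer=False`` trains from random initialization and exists as the
    negative control). Positive patches are augmented 8-fold by the
    dihedral group each epoch.
    """
    config = config or ObserverConfig()
    if init.head_kind != "ne":
        raise ValueError("init must be a trained noise estimator")
    if (init.family, init.width, init.pooling) != (config.backbone,
                                                    config.width,
                                                    config.pooling):
        raise ValueError(
            f"backbone mismatch: init is {init.family}/{init.width}/"
            f"{init.pooling}, config wants {config.backbone}/"
            f"{config.width}/{config.pooling}")
    pixels = _as_pixel_array(patches)
    labels = np.asarray(labels, dtype=float)
    rng = np.random.default_rng(seed)
    backbone = build_backbone(config.backbone, config.width, rng,
                              config.pooling)
    head = _build_head(_n_features(config), rng)
    if transfer:
        # the detector and estimator nets are identical up to the exit
        # nonlinearity, so the head transfers along with the backbone
        backbone.set_weights(init.backbone.get_weights())
        head.set_weights(init.head.get_weights())
        provenance = "transferred-from-NE"
    else:
        provenance = "random"
    model = ObserverModel(backbone=backbone, head=head,
                          family=config.backbone, width=config.width,
                          head_kind="mc", pooling=config.pooling,
                          init_provenance=provenance,
                          repeat_seed=seed, input_scale=init.input_scale)
    _assert_capacity(model)

    pos = pixels[labels == 1]
    neg = pixels[labels == 0]
    aug_pos = np.concatenate(
        [np.stack(dihedral_transforms(p)) for p in pos]) if len(pos) else \
        np.empty((0,) + pixels.shape[1:])
    x = np.concatenate([aug_pos, neg]) / model.input_scale
    y = np.concatenate([np.ones(len(aug_pos)), np.zeros(len(neg))])
    params = backbone.params() + head.params()
    opt = nn.Adam(params, lr=config.lr_mc)
    n = x.shape[0]
    trace = []
    for epoch in range(config.epochs):
        opt.lr = config.lr_mc * config.lr_decay ** (epoch
                                                    // config.lr_decay_every)
        order = rng.permutation(n)
        ep_loss = 0.0
        for s in range(0, n, config.batch_size):
            idx = order[s:s + config.batch_size]
            logits = head.forward(backbone.forward(x[idx, None]))[:, 0]
            loss, dlog = nn.bce_with_logits_loss(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite MC loss at epoch "
                                         f"{epoch}: {trace[-5:]}")
            backbone.zero_grad()
            head.zero_grad()
            backbone.backward(head.backward(dlog[:, None]))
            opt.step()
            ep_loss += loss * len(idx)
        trace.append(ep_loss / n)
    model.training_meta = dict(
        loss_trace=trace, seed=seed, config=vars(config).copy(),
        augmented_positives_per_epoch=int(len(aug_pos)),
        augmentation_factor=8)
    return model


def score_patches(model: ObserverModel, patches) -> np.ndarray:
    """Per-patch scores with 8-fold test-time augmentation (mean over the
    dihedral transforms of each patch)."""
    if model.head_kind != "mc":
        raise ValueError("scoring requires a cluster-detection model")
    pixels = _as_pixel_array(patches)
    scores = np.zeros(pixels.shape[0])
    for i, p in enumerate(pixels):
        variants = np.stack(dihedral_transforms(p))
        scores[i] = float(model.predict(variants).mean())
    return scores


def pool_cluster_scores(scores: np.ndarray, patches) -> dict:
    """Mean score per (view, cluster) over that cluster's positive patches."""
    pooled: dict[tuple[int, int], list[float]] = {}
    for s, p in zip(scores, patches):
        if p.label == 1:
            pooled.setdefault((p.view_id, p.cluster_id), []).append(float(s))
    return {k: float(np.mean(v)) for k, v in sorted(pooled.items())}


def roc_auc(pos_scores, neg_scores) -> float:
    """AUC = P(pos > neg) + 1/2 P(pos = neg), midrank convention."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be nonempty")
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[:pos.size].sum() - pos.size * (pos.size + 1) / 2.0)
                 / (pos.size * neg.size))


# ---------------------------------------------------------------------------
# condition evaluation
# ---------------------------------------------------------------------------

@dataclass
class DetectabilityResult:
    """AUC mean +- std over repeats, per-repeat AUCs, and the condition's
    mean analytic RMS noise — one point on the AUC-vs-RMS tradeoff plot."""

    condition: str
    auc_mean: float
    auc_std: float
    aucs: tuple[float, ...]
    rms_mean: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc_mean <= 1.0 or self.auc_std < 0:
            raise ValueError("invalid AUC summary")


@dataclass
class ConditionData:
    """Patch sets for one image condition, split by phantom (case).

    ``ne_patches``/``ne_labels`` train the noise estimator;
    ``train_patches`` fine-tune the detector; ``test_patches`` are scored.
    ``*_phantoms`` identify the source phantom of each split for the
    leakage check.
    """

    condition: str
    ne_patches: list
    ne_labels: np.ndarray
    train_patches: list
    test_patches: list
    train_phantoms: frozenset = frozenset()
    test_phantoms: frozenset = frozenset()


def evaluate_condition(data: ConditionData,
                       config: ObserverConfig | None = None,
                       repeats: int = 5, seed: int = 0,
                       transfer: bool = True) -> DetectabilityResult:
    """Train and test the observer pipeline for one image condition.

    Per repeat (fresh seed): train the noise estimator, transfer-initialize
    and fine-tune the detector, score the test patches with test-time
    augmentation, pool positives per cluster and view, and compute the ROC
    AUC of pooled-positive vs negative-patch scores. Splits sharing a
    phantom are rejected as leakage.
    """
    if data.train_phantoms & data.test_phantoms:
        raise ValueError(
            "patch-set leakage: phantoms "
            f"{sorted(data.train_phantoms & data.test_phantoms)} appear in "
            "both the training and test splits")
    config = config or ObserverConfig()
    train_labels = np.array([p.label for p in data.train_patches])
    aucs = []
    seeds = np.random.SeedSequence(seed).spawn(repeats)
    for r in range(repeats):
        rseed = int(seeds[r].generate_state(1)[0] % (2**31))
        ne = train_cnn_ne(data.ne_patches, data.ne_labels, config, rseed)
        mc = train_cnn_mc(data.train_patches, train_labels, ne, config,
                          rseed, transfer=transfer)
        scores = score_patches(mc, data.test_patches)
        pooled = pool_cluster_scores(scores, data.test_patches)
        neg_scores = [s for s, p in zip(scores, data.test_patches)
                      if p.label == 0]
        aucs.append(roc_auc(list(pooled.values()), neg_scores))
    neg_rms = [roi_rms(p.pixels) for p in data.test_patches if p.label == 0]
    aucs_arr = np.asarray(aucs)
    return DetectabilityResult(
        condition=data.condition,
        auc_mean=float(aucs_arr.mean()),
        auc_std=float(aucs_arr.std()),
        aucs=tuple(float(a) for a in aucs),
        rms_mean=float(np.mean(neg_rms)))


def plot_tradeoff(results: Sequence[DetectabilityResult], path: str) -> None:
    """AUC-vs-RMS tradeoff figure: one errorbar point per condition."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for r in results:
        ax.errorbar(r.rms_mean, r.auc_mean, yerr=r.auc_std, fmt="o",
                    capsize=3, label=r.condition)
    ax.set_xlabel("RMS noise (pixel values)")
    ax.set_ylabel("Cluster detection AUC")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
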