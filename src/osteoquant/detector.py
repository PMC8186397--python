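"""Single-shot detector for TRAP-stained cell patches.

A one-pass convolutional detector in the SSD family: a backbone extracts a
pyramid of feature maps, and four detection heads -- one per pyramid level
-- predict, at every feature-map position and for every anchor (default
box) attached to it, a class distribution over the four cell types plus
background and a 4-vector of box offsets.  Predictions are decoded against
the anchors, confidence-filtered, and pruned by class-wise non-maximum
suppression.

Using four detection heads rather than the six of generic SSD removes the
coarsest anchor scales: detected objects are cells spanning 51-383 μm, and
boxes spanning large sections of a patch would be nonsense for culture
images.  Ground-truth boxes are squares (the tightest square around each
annotated polygon), so anchors are square too, at three geometric
sub-scales per head.

The network itself runs on the numpy layers of :mod:`osteoquant.nn`; the
backbone is pluggable through :class:`DetectorConfig` (a VGG16-scale stack
for the full-resolution profile, a small 4-block stack for desk-scale
work).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np
from PIL import Image

from .annotation import BBox, CellType
from .patches import PatchSample
from . import nn


class TrainingError(RuntimeError):
    pass


#: Detector class index 0 is background; cell types occupy 1..4 in this order.
CLASS_ORDER: tuple[CellType, ...] = (
    CellType.PREOSTEOCLAST,
    CellType.OSTEOCLAST_I,
    CellType.OSTEOCLAST_II,
    CellType.GHOST,
)
_TYPE_TO_INDEX = {t: i + 1 for i, t in enumerate(CLASS_ORDER)}


@dataclass(frozen=True)
class DetectorConfig:
    """Architecture and inference hyperparameters.

    ``backbone_channels`` lists the output channels of successive stride-2
    conv blocks; ``head_blocks`` gives the (0-based) blocks whose outputs
    feed detection heads.  ``base_scales`` are per-head anchor sides as a
    fraction of the input; each is expanded into ``n_sub_scales`` geometric
    sub-scales (step 2^(1/3)) times ``aspect_ratios``.

    ``um_per_input_px`` is the physical size of one *network input* pixel
    for the nominal inference patch (native patch side / input_size times
    the native μm/px); it makes the 51-383 μm size-coverage claim a
    checkable property of a config rather than a constant.
    """

    input_size: int = 300
    backbone_channels: tuple[int, ...] = (64, 128, 256, 512, 512, 512)
    extra_conv_blocks: tuple[int, ...] = ()
    head_blocks: tuple[int, ...] = (2, 3, 4, 5)
    base_scales: tuple[float, ...] = (0.07, 0.14, 0.28, 0.56)
    n_sub_scales: int = 3
    aspect_ratios: tuple[float, ...] = (1.0,)
    n_cell_classes: int = 4
    use_batchnorm: bool = False
    match_iou: float = 0.5
    nms_iou: float = 0.45
    confidence_threshold: float = 0.5
    top_k: int = 200
    um_per_input_px: float | None = None

    def __post_init__(self) -> None:
        if len(self.head_blocks) != 4:
            raise ValueError("the detector uses exactly 4 detection heads")
        if len(self.base_scales) != len(self.head_blocks):
            raise ValueError("one base scale per head required")
        if list(self.base_scales) != sorted(self.base_scales):
            raise ValueError("head scales must increase strictly")

    @property
    def n_classes_with_bg(self) -> int:
        return self.n_cell_classes + 1

    @property
    def anchors_per_position(self) -> int:
        return self.n_sub_scales * len(self.aspect_ratios)

    def feature_sizes(self) -> list[int]:
        """Feature-map side length at each backbone block (stride-2 chain)."""
        sizes = []
        s = self.input_size
        for _ in self.backbone_channels:
            s = math.ceil(s / 2)
            sizes.append(s)
        return sizes

    def head_feature_sizes(self) -> list[int]:
        sizes = self.feature_sizes()
        return [sizes[b] for b in self.head_blocks]

    def anchor_physical_range(self) -> tuple[float, float]:
        """(min, max) anchor side in μm for the configured pixel scale."""
        if self.um_per_input_px is None:
            raise ValueError(
                "um_per_input_px not set; physical coverage check needs a "
                "pixel scale"
            )
        step = 2.0 ** (1.0 / 3.0)
        smallest = self.base_scales[0]
        largest = self.base_scales[-1] * step ** (self.n_sub_scales - 1)
        px = self.input_size * self.um_per_input_px
        return smallest * px, min(largest, 1.0) * px


def full_profile(um_per_input_px: float | None = None) -> DetectorConfig:
    """Full-scale profile: input 300, VGG16-scale backbone, feature maps
    38², 19², 10², 5² feeding the four heads."""
    return DetectorConfig(um_per_input_px=um_per_input_px)


def desk_profile(um_per_input_px: float | None = 875.0 / 160.0) -> DetectorConfig:
    """Desk-scale profile for CPU runs: input 160, small batch-normalized
    backbone with extra convs in the middle blocks, feature maps 20², 10²,
    5², 3².  The default pixel scale corresponds to 7 μm/px wells tiled
    8x8 at 1000 px (125 px native tiles resized to 160)."""
    return DetectorConfig(
        input_size=160,
        backbone_channels=(24, 48, 64, 64, 64, 64),
        extra_conv_blocks=(1, 2),
        head_blocks=(2, 3, 4, 5),
        base_scales=(0.055, 0.11, 0.22, 0.44),
        use_batchnorm=True,
        match_iou=0.45,
        um_per_input_px=um_per_input_px,
    )


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings.  The full-scale run uses 120,000 iterations at
    batch 32 with Adam at lr 1e-5 (suited to a pretrained backbone); the
    desk default is 2,000 iterations at batch 8 with lr 1e-3 for a randomly
    initialized small net."""

    iterations: int = 2_000
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    checkpoint_interval: int = 0  # 0 = no intermediate checkpoints
    checkpoint_dir: str | None = None
    neg_pos_ratio: int = 3
    grad_clip: float = 10.0
    log_every: int = 10
    lr_schedule: str = "step"  # "step" (/10 at 75%), "cosine", "constant"
    warmup_iterations: int = 50

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("iterations, batch_size, learning_rate must be positive")


def full_training_profile(seed: int = 0) -> TrainingConfig:
    return TrainingConfig(iterations=120_000, batch_size=32,
                          learning_rate=1e-5, seed=seed,
                          lr_schedule="constant", warmup_iterations=0)


# ---------------------------------------------------------------------------
# Geometry: IoU and NMS


def iou(a: BBox, b: BBox) -> float:
    """Intersection-over-union of two boxes; 1 iff identical, 0 iff disjoint."""
    inter = a.intersection(b)
    if inter is None:
        return 0.0
    ia = inter.area
    return ia / (a.area + b.area - ia)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two (N,4) / (M,4) corner-form box arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        return np.zeros((a.shape[0], b.shape[0]))
    x0 = np.maximum(a[:, None, 0], b[None, :, 0])
    y0 = np.maximum(a[:, None, 1], b[None, :, 1])
    x1 = np.minimum(a[:, None, 2], b[None, :, 2])
    y1 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x1 - x0, 0, None) * np.clip(y1 - y0, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return inter / np.maximum(union, 1e-12)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float = 0.45) -> np.ndarray:
    """Greedy non-maximum suppression for one class.

    Returns indices of kept boxes in descending score order; no surviving
    pair overlaps beyond ``iou_threshold``.
    """
    boxes = np.asarray(boxes, dtype=float)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    keep: list[int] = []
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        rest = order[1:]
        ious = iou_matrix(boxes[i : i + 1], boxes[rest])[0]
        order = rest[ious <= iou_threshold]
    return np.asarray(keep, dtype=int)


# ---------------------------------------------------------------------------
# Anchors


@dataclass(frozen=True)
class AnchorSet:
    """Anchor boxes in normalized image coordinates.

    ``corners``: (A, 4) [x0, y0, x1, y1], clipped to the unit square;
    ``centers``: (A, 4) [cx, cy, w, h] derived from the clipped corners;
    ``head_index``: (A,) which detection head each anchor belongs to.
    """

    corners: np.ndarray
    centers: np.ndarray
    head_index: np.ndarray

    def __len__(self) -> int:
        return self.corners.shape[0]


def generate_anchors(cfg: DetectorConfig) -> AnchorSet:
    """Deterministic anchor grid for a config.

    Each head places ``anchors_per_position`` square-ish anchors at the
    center of every feature-map cell; anchor count is a pure function of
    the config, independent of image content.
    """
    step = 2.0 ** (1.0 / 3.0)
    corners = []
    heads = []
    for h_idx, (fsize, base) in enumerate(
        zip(cfg.head_feature_sizes(), cfg.base_scales)
    ):
        cy, cx = np.meshgrid(
            (np.arange(fsize) + 0.5) / fsize,
            (np.arange(fsize) + 0.5) / fsize,
            indexing="ij",
        )
        shapes = [
            (base * step**k * math.sqrt(ar), base * step**k / math.sqrt(ar))
            for k in range(cfg.n_sub_scales)
            for ar in cfg.aspect_ratios
        ]
        # position-major, anchor-minor: matches the head-output row layout
        per_pos = np.empty((fsize, fsize, len(shapes), 4))
        for a_idx, (w, h) in enumerate(shapes):
            per_pos[:, :, a_idx, 0] = cx - w / 2
            per_pos[:, :, a_idx, 1] = cy - h / 2
            per_pos[:, :, a_idx, 2] = cx + w / 2
            per_pos[:, :, a_idx, 3] = cy + h / 2
        box = per_pos.reshape(-1, 4)
        corners.append(box)
        heads.append(np.full(box.shape[0], h_idx, dtype=int))
    c = np.clip(np.concatenate(corners, axis=0), 0.0, 1.0)
    centers = np.stack(
        [
            (c[:, 0] + c[:, 2]) / 2,
            (c[:, 1] + c[:, 3]) / 2,
            c[:, 2] - c[:, 0],
            c[:, 3] - c[:, 1],
        ],
        axis=1,
    )
    return AnchorSet(corners=c, centers=centers, head_index=np.concatenate(heads))


# ---------------------------------------------------------------------------
# Box codec (center-offset / log-size, variances 0.1 / 0.2)

CENTER_VARIANCE = 0.1
SIZE_VARIANCE = 0.2


def _corners_to_centers(boxes: np.ndarray) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=float)
    return np.stack(
        [
            (boxes[:, 0] + boxes[:, 2]) / 2,
            (boxes[:, 1] + boxes[:, 3]) / 2,
            boxes[:, 2] - boxes[:, 0],
            boxes[:, 3] - boxes[:, 1],
        ],
        axis=1,
    )


def _centers_to_corners(boxes: np.ndarray) -> np.ndarray:
    return np.stack(
        [
            boxes[:, 0] - boxes[:, 2] / 2,
            boxes[:, 1] - boxes[:, 3] / 2,
            boxes[:, 0] + boxes[:, 2] / 2,
            boxes[:, 1] + boxes[:, 3] / 2,
        ],
        axis=1,
    )


def encode_boxes(boxes_corner: np.ndarray, anchors_center: np.ndarray) -> np.ndarray:
    """Encode matched corner-form boxes against anchors as SSD offsets:
    ``t = [(cx-acx)/(aw*v_c), (cy-acy)/(ah*v_c), log(w/aw)/v_s, log(h/ah)/v_s]``.
    """
    g = _corners_to_centers(boxes_corner)
    if np.any(g[:, 2:] <= 0):
        raise ValueError("boxes must have positive width and height")
    a = np.asarray(anchors_center, dtype=float)
    t_xy = (g[:, :2] - a[:, :2]) / (a[:, 2:] * CENTER_VARIANCE)
    t_wh = np.log(g[:, 2:] / a[:, 2:]) / SIZE_VARIANCE
    return np.concatenate([t_xy, t_wh], axis=1)


def decode_boxes(offsets: np.ndarray, anchors_center: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_boxes`; returns corner-form boxes."""
    t = np.asarray(offsets, dtype=float)
    a = np.asarray(anchors_center, dtype=float)
    cxy = t[:, :2] * CENTER_VARIANCE * a[:, 2:] + a[:, :2]
    wh = np.exp(np.clip(t[:, 2:] * SIZE_VARIANCE, None, 12.0)) * a[:, 2:]
    return _centers_to_corners(np.concatenate([cxy, wh], axis=1))


# ---------------------------------------------------------------------------
# Matching and loss


def match_anchors(
    anchors: AnchorSet, gt_boxes: np.ndarray, iou_threshold: float = 0.5
) -> np.ndarray:
    """Assign each anchor a ground-truth index or background (-1).

    Two-stage SSD matching: (i) bipartite -- every ground-truth box claims
    its best-IoU anchor (ties to the lowest anchor index), guaranteeing at
    least one positive per object; (ii) every remaining anchor whose best
    IoU with any ground truth reaches ``iou_threshold`` is positive for
    that ground truth.
    """
    n_anchors = len(anchors)
    assignment = np.full(n_anchors, -1, dtype=int)
    gt = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    if gt.shape[0] == 0:
        return assignment
    ious = iou_matrix(anchors.corners, gt)  # (A, G)
    best_gt = ious.argmax(axis=1)
    best_iou = ious[np.arange(n_anchors), best_gt]
    assignment[best_iou >= iou_threshold] = best_gt[best_iou >= iou_threshold]
    # bipartite step overrides thresholding
    for g in range(gt.shape[0]):
        assignment[int(ious[:, g].argmax())] = g
    return assignment


@dataclass
class MultiboxLoss:
    total: float
    conf: float
    loc: float
    n_pos: int
    dlogits: np.ndarray
    doffsets: np.ndarray


def multibox_loss(
    class_logits: np.ndarray,
    box_offsets: np.ndarray,
    assignment: np.ndarray,
    gt_labels: np.ndarray,
    loc_targets: np.ndarray,
    neg_pos_ratio: int = 3,
) -> MultiboxLoss:
    """SSD multibox loss for one image, with analytic gradients.

    ``loss = (L_conf + L_loc) / N_pos`` where L_loc is smooth-L1 over the
    positive anchors' encoded offsets and L_conf is cross-entropy over the
    positives plus the hardest negatives (those with the largest background
    cross-entropy), capped at ``neg_pos_ratio * N_pos``.  With no positives
    the localization term is 0 and the confidence term runs over at most
    ``neg_pos_ratio`` hardest negatives (normalizer 1).
    """
    assignment = np.asarray(assignment)
    pos = assignment >= 0
    n_pos = int(pos.sum())
    n_anchors = class_logits.shape[0]

    targets = np.zeros(n_anchors, dtype=int)
    if n_pos:
        targets[pos] = np.asarray(gt_labels)[assignment[pos]]

    ce, dce = nn.cross_entropy_with_grad(class_logits, targets)

    neg_cap = neg_pos_ratio * max(n_pos, 1)
    neg_losses = np.where(pos, -np.inf, ce)
    n_neg = min(neg_cap, n_anchors - n_pos)
    neg_sel = np.zeros(n_anchors, dtype=bool)
    if n_neg > 0:
        hardest = np.argsort(-neg_losses, kind="stable")[:n_neg]
        neg_sel[hardest] = True

    conf_mask = pos | neg_sel
    l_conf = float(ce[conf_mask].sum())

    dlogits = np.zeros_like(dce)
    dlogits[conf_mask] = dce[conf_mask]

    doffsets = np.zeros_like(box_offsets, dtype=float)
    l_loc = 0.0
    if n_pos:
        sl, dsl = nn.smooth_l1_with_grad(box_offsets[pos], loc_targets[pos])
        l_loc = float(sl.sum())
        doffsets[pos] = dsl

    norm = max(n_pos, 1)
    return MultiboxLoss(
        total=(l_conf + l_loc) / norm,
        conf=l_conf / norm,
        loc=l_loc / norm,
        n_pos=n_pos,
        dlogits=dlogits / norm,
        doffsets=doffsets / norm,
    )


# ---------------------------------------------------------------------------
# Detections


@dataclass(frozen=True)
class Detection:
    """One predicted cell: box (patch or well pixels), class, confidence."""

    bbox: BBox
    cell_type: CellType
    score: float

    def shift(self, dx: float, dy: float) -> "Detection":
        return Detection(self.bbox.shift(dx, dy), self.cell_type, self.score)


# ---------------------------------------------------------------------------
# The model


def _resize_rgb(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of an HxWx3 uint8 image to size x size."""
    if image.shape[0] == size and image.shape[1] == size:
        return image
    return np.asarray(
        Image.fromarray(image).resize((size, size), Image.BILINEAR)
    )


def _normalize(image: np.ndarray) -> np.ndarray:
    """uint8 HWC -> float32 CHW in [-1, 1]."""
    x = image.astype(np.float32) / 127.5 - 1.0
    return np.ascontiguousarray(x.transpose(2, 0, 1))


@dataclass
class TrainingResult:
    """Outcome of a training run: the per-iteration loss log and where
    checkpoints were written."""

    log: list[dict]
    checkpoints: list[str]
    final_loss: float

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.log)

    def smoothed_loss(self, window: int = 50) -> np.ndarray:
        losses = np.array([row["loss"] for row in self.log])
        if losses.size < window:
            return losses
        kernel = np.ones(window) / window
        return np.convolve(losses, kernel, mode="valid")


class OsteoclastDetector:
    """Patch-level cell detector: build from a config, ``fit`` on a stream
    of annotated patches, ``detect_patch`` on new crops."""

    def __init__(self, config: DetectorConfig, seed: int = 0):
        self.config = config
        self.anchors = generate_anchors(config)
        self._build(seed)

    # -- architecture -------------------------------------------------
    def _build(self, seed: int) -> None:
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD37EC7]))
        self.segments: list[nn.Sequential] = []
        self.cls_heads: list[nn.Conv2d] = []
        self.loc_heads: list[nn.Conv2d] = []
        c_in = 3
        start = 0
        for head_i, block_end in enumerate(cfg.head_blocks):
            layers: list[nn.Layer] = []
            for b in range(start, block_end + 1):
                c_out = cfg.backbone_channels[b]
                layers.append(nn.Conv2d(c_in, c_out, 3, stride=2, rng=rng))
                if cfg.use_batchnorm:
                    layers.append(nn.BatchNorm2d(c_out))
                layers.append(nn.ReLU())
                if b in cfg.extra_conv_blocks:
                    layers.append(nn.Conv2d(c_out, c_out, 3, stride=1, rng=rng))
                    if cfg.use_batchnorm:
                        layers.append(nn.BatchNorm2d(c_out))
                    layers.append(nn.ReLU())
                c_in = c_out
            self.segments.append(nn.Sequential(layers))
            start = block_end + 1
            a = cfg.anchors_per_position
            self.cls_heads.append(
                nn.Conv2d(c_in, a * cfg.n_classes_with_bg, 3, stride=1, rng=rng)
            )
            self.loc_heads.append(nn.Conv2d(c_in, a * 4, 3, stride=1, rng=rng))

    def _head_modules(self):
        for seg in self.segments:
            yield seg
        for h in self.cls_heads:
            yield nn.Sequential([h])
        for h in self.loc_heads:
            yield nn.Sequential([h])

    def parameters(self):
        params = []
        for i, mod in enumerate(self._head_modules()):
            for name, value, grad in mod.parameters():
                params.append((f"m{i}.{name}", value, grad))
        return params

    def buffers(self):
        out = []
        for i, mod in enumerate(self._head_modules()):
            for name, value in mod.buffers():
                out.append((f"m{i}.{name}", value))
        return out

    # -- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True):
        """Run a (N,3,S,S) batch; returns logits (N,A,C+1), offsets (N,A,4)."""
        cfg = self.config
        n = x.shape[0]
        feats = []
        h = x
        for seg in self.segments:
            h = seg.forward(h, train=train)
            feats.append(h)
        logits, offs = [], []
        self._head_shapes = []
        for f, ch, lh in zip(feats, self.cls_heads, self.loc_heads):
            cl = ch.forward(f, train=train)
            lo = lh.forward(f, train=train)
            self._head_shapes.append((cl.shape, lo.shape))
            # (N, A*k, H, W) -> (N, H*W*A, k)
            logits.append(_head_to_rows(cl, cfg.n_classes_with_bg))
            offs.append(_head_to_rows(lo, 4))
        return np.concatenate(logits, axis=1), np.concatenate(offs, axis=1)

    def backward(self, dlogits: np.ndarray, doffsets: np.ndarray) -> None:
        cfg = self.config
        # split gradient rows back per head
        sizes = [
            s * s * cfg.anchors_per_position for s in cfg.head_feature_sizes()
        ]
        idx = np.cumsum([0] + sizes)
        dfeat_from_above = None
        dfeats = []
        for i, (ch, lh) in enumerate(zip(self.cls_heads, self.loc_heads)):
            dcl = _rows_to_head(
                dlogits[:, idx[i] : idx[i + 1]], self._head_shapes[i][0]
            )
            dlo = _rows_to_head(
                doffsets[:, idx[i] : idx[i + 1]], self._head_shapes[i][1]
            )
            dfeats.append(ch.backward(dcl) + lh.backward(dlo))
        for i in range(len(self.segments) - 1, -1, -1):
            d = dfeats[i]
            if dfeat_from_above is not None:
                d = d + dfeat_from_above
            dfeat_from_above = self.segments[i].backward(d)

    # -- target preparation -------------------------------------------
    def _encode_sample(self, sample: PatchSample):
        """Resize a patch to the input size and encode its boxes as
        per-anchor classification and localization targets."""
        cfg = self.config
        img = _normalize(_resize_rgb(sample.image, cfg.input_size))
        h, w = sample.image.shape[:2]
        labels = np.zeros(0, dtype=int)
        gt_norm = np.zeros((0, 4))
        if sample.boxes:
            gt_norm = np.array(
                [
                    [b.x_min / w, b.y_min / h, b.x_max / w, b.y_max / h]
                    for b, _t in sample.boxes
                ]
            )
            gt_norm = np.clip(gt_norm, 0.0, 1.0)
            ok = (gt_norm[:, 2] - gt_norm[:, 0] > 1e-4) & (
                gt_norm[:, 3] - gt_norm[:, 1] > 1e-4
            )
            gt_norm = gt_norm[ok]
            labels = np.array(
                [_TYPE_TO_INDEX[t] for (_b, t), keep in zip(sample.boxes, ok) if keep],
                dtype=int,
            )
        assignment = match_anchors(self.anchors, gt_norm, cfg.match_iou)
        loc_targets = np.zeros((len(self.anchors), 4))
        pos = assignment >= 0
        if pos.any():
            loc_targets[pos] = encode_boxes(
                gt_norm[assignment[pos]], self.anchors.centers[pos]
            )
        return img, assignment, labels, loc_targets

    # -- training ------------------------------------------------------
    def fit(
        self,
        dataset: Iterable[PatchSample],
        tcfg: TrainingConfig,
    ) -> TrainingResult:
        """Train on a stream of patch samples.

        Consumes ``iterations * batch_size`` samples from ``dataset``;
        raises :class:`TrainingError` on an exhausted stream or a NaN loss.
        Runs are reproducible: same dataset stream + same config => same
        loss sequence to float tolerance.
        """
        it = iter(dataset)
        optimizer = nn.Adam(self.parameters(), lr=tcfg.learning_rate)
        log: list[dict] = []
        checkpoints: list[str] = []
        loss_val = math.nan
        for iteration in range(1, tcfg.iterations + 1):
            batch = []
            for _ in range(tcfg.batch_size):
                try:
                    batch.append(next(it))
                except StopIteration:
                    raise TrainingError(
                        f"dataset exhausted at iteration {iteration}"
                    ) from None
            encoded = [self._encode_sample(s) for s in batch]
            x = np.stack([e[0] for e in encoded])
            logits, offsets = self.forward(x, train=True)

            dlogits = np.zeros_like(logits)
            doffsets = np.zeros_like(offsets)
            tot = conf = loc = 0.0
            n_pos_total = 0
            for i, (_img, assignment, labels, loc_t) in enumerate(encoded):
                ml = multibox_loss(
                    logits[i].astype(np.float64),
                    offsets[i].astype(np.float64),
                    assignment,
                    labels,
                    loc_t,
                    tcfg.neg_pos_ratio,
                )
                tot += ml.total
                conf += ml.conf
                loc += ml.loc
                n_pos_total += ml.n_pos
                dlogits[i] = ml.dlogits / tcfg.batch_size
                doffsets[i] = ml.doffsets / tcfg.batch_size
            loss_val = tot / tcfg.batch_size
            if not np.isfinite(loss_val):
                raise TrainingError(f"non-finite loss at iteration {iteration}")

            self.backward(dlogits, doffsets)
            _clip_gradients(self.parameters(), tcfg.grad_clip)
            optimizer.lr = _lr_at(tcfg, iteration)
            optimizer.step()

            if iteration % tcfg.log_every == 0 or iteration == 1:
                log.append(
                    {
                        "iteration": iteration,
                        "loss": loss_val,
                        "conf_loss": conf / tcfg.batch_size,
                        "loc_loss": loc / tcfg.batch_size,
                        "n_pos": n_pos_total,
                    }
                )
            if (
                tcfg.checkpoint_interval
                and tcfg.checkpoint_dir
                and iteration % tcfg.checkpoint_interval == 0
            ):
                path = os.path.join(
                    tcfg.checkpoint_dir, f"checkpoint_{iteration:07d}.npz"
                )
                self.save(path)
                checkpoints.append(path)
        return TrainingResult(log=log, checkpoints=checkpoints, final_loss=loss_val)

    # -- inference -----------------------------------------------------
    def detect_patch(self, image: np.ndarray) -> list[Detection]:
        """Detect cells in one patch; boxes in the patch's native pixels.

        Decodes predictions, drops scores below the confidence threshold,
        applies class-wise NMS, and keeps at most ``top_k`` detections.
        """
        cfg = self.config
        h, w = image.shape[:2]
        x = _normalize(_resize_rgb(image, cfg.input_size))[None]
        logits, offsets = self.forward(x, train=False)
        probs = nn.softmax(logits[0].astype(np.float64), axis=1)
        boxes = decode_boxes(offsets[0].astype(np.float64), self.anchors.centers)
        out: list[Detection] = []
        for ci, ctype in enumerate(CLASS_ORDER, start=1):
            scores = probs[:, ci]
            sel = scores >= cfg.confidence_threshold
            if not sel.any():
                continue
            keep = nms(boxes[sel], scores[sel], cfg.nms_iou)
            sel_boxes = boxes[sel][keep]
            sel_scores = scores[sel][keep]
            for b, s in zip(sel_boxes, sel_scores):
                x0 = float(np.clip(b[0], 0, 1)) * w
                y0 = float(np.clip(b[1], 0, 1)) * h
                x1 = float(np.clip(b[2], 0, 1)) * w
                y1 = float(np.clip(b[3], 0, 1)) * h
                if x1 - x0 < 1e-3 or y1 - y0 < 1e-3:
                    continue
                out.append(Detection(BBox(x0, y0, x1, y1), ctype, float(s)))
        out.sort(key=lambda d: -d.score)
        return out[: cfg.top_k]

    # -- persistence ----------------------------------------------------
    def save(self, path: str | os.PathLike) -> None:
        """Single-file checkpoint: weights + embedded config + version."""
        from . import __version__

        arrays = {name: value for name, value, _g in self.parameters()}
        arrays.update({f"buf_{name}": value for name, value in self.buffers()})
        meta = {"config": asdict(self.config), "version": __version__}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "OsteoclastDetector":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg_dict = meta["config"]
            for key in ("backbone_channels", "extra_conv_blocks", "head_blocks",
                        "base_scales", "aspect_ratios"):
                cfg_dict[key] = tuple(cfg_dict[key])
            model = cls(DetectorConfig(**cfg_dict), seed=0)
            for name, value, _g in model.parameters():
                value[...] = data[name]
            for name, value in model.buffers():
                value[...] = data[f"buf_{name}"]
        return model


def _head_to_rows(x: np.ndarray, k: int) -> np.ndarray:
    """(N, A*k, H, W) head output -> (N, H*W*A, k) prediction rows."""
    n, ak, h, w = x.shape
    a = ak // k
    # channel layout: anchor-major then component, matching anchor order
    return (
        x.reshape(n, a, k, h, w).transpose(0, 3, 4, 1, 2).reshape(n, h * w * a, k)
    )


def _rows_to_head(rows: np.ndarray, head_shape) -> np.ndarray:
    n, ak, h, w = head_shape
    k = rows.shape[-1]
    a = ak // k
    return (
        rows.reshape(n, h, w, a, k).transpose(0, 3, 4, 1, 2).reshape(n, ak, h, w)
    ).astype(np.float32)


def _lr_at(tcfg: TrainingConfig, iteration: int) -> float:
    """Linear warmup, then a step drop (/10 at 75% of the run), cosine
    decay to lr/20, or a constant rate."""
    base = tcfg.learning_rate
    if tcfg.warmup_iterations and iteration <= tcfg.warmup_iterations:
        return base * iteration / tcfg.warmup_iterations
    if tcfg.lr_schedule == "step":
        return base / 10.0 if iteration > 0.75 * tcfg.iterations else base
    if tcfg.lr_schedule != "cosine":
        return base
    span = max(tcfg.iterations - tcfg.warmup_iterations, 1)
    t = (iteration - tcfg.warmup_iterations) / span
    floor = base / 20.0
    return floor + (base - floor) * 0.5 * (1.0 + math.cos(math.pi * t))


def _clip_gradients(params, max_norm: float) -> None:
    if not max_norm:
        return
    total = math.sqrt(sum(float((g**2).sum()) for _n, _v, g in params))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for _n, _v, g in params:
            g *= scale
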