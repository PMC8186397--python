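"""Patch sampling, augmentation, and tiling.

Training a detector needs thousands of annotated examples, but annotating a
full culture takes hours, so only a handful of wells are available.  Cells
are tiny relative to the whole culture, so any small window of a well is
itself a perfectly annotated training image.  Random sub-patches -- 10-15%
of the well's width and height, positioned uniformly -- therefore amplify a
few wells into an effectively unbounded training stream (about 1.8 billion
distinct patches for a 1,000 x 1,000 px well), further diversified by
photometric distortion, vertical flips, and right-angle rotations.

Inference uses the complementary deterministic operation: tiling a well
into a fixed grid of non-overlapping patches (8 x 8 = 64 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .annotation import BBox, CellType, WellAnnotation, tightest_square_bbox


@dataclass(frozen=True)
class PatchSpec:
    """Location of a patch inside a well image (top-left corner + size)."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError(f"patch must be at least 1x1, got {self.w}x{self.h}")
        if self.x < 0 or self.y < 0:
            raise ValueError("patch origin must be non-negative")

    def as_bbox(self) -> BBox:
        return BBox(self.x, self.y, self.x + self.w, self.y + self.h)


@dataclass(frozen=True)
class AugmentationConfig:
    """Ranges for the three augmentation families.

    Photometric distortions jitter brightness (additive, on 0-1 intensity),
    hue (additive, on the 0-1 hue circle) and saturation (multiplicative);
    geometric augmentations are vertical flips and rotations by multiples
    of 90 degrees.  Boxes are exactly remapped under geometry and untouched
    by photometry.
    """

    brightness_delta: tuple[float, float] = (-0.08, 0.08)
    hue_delta: tuple[float, float] = (-0.03, 0.03)
    saturation_factor: tuple[float, float] = (0.85, 1.15)
    vertical_flip_prob: float = 0.5
    rotation_set: tuple[int, ...] = (0, 90, 180, 270)

    def __post_init__(self) -> None:
        if not 0.0 <= self.vertical_flip_prob <= 1.0:
            raise ValueError("vertical_flip_prob must be in [0, 1]")
        if any(r % 90 != 0 for r in self.rotation_set):
            raise ValueError("rotations must be multiples of 90 degrees")


#: Augmentation disabled; used for evaluation streams.
NO_AUGMENTATION = AugmentationConfig(
    brightness_delta=(0.0, 0.0),
    hue_delta=(0.0, 0.0),
    saturation_factor=(1.0, 1.0),
    vertical_flip_prob=0.0,
    rotation_set=(0,),
)


@dataclass
class PatchSample:
    """One training example: an image crop plus its clipped, re-offset
    ground-truth boxes (patch coordinates) and class labels."""

    image: np.ndarray
    boxes: list[tuple[BBox, CellType]]
    well_id: str
    spec: PatchSpec
    augmentation: str = ""


def sample_random_patch(
    image_w: int,
    image_h: int,
    f_min: float = 0.10,
    f_max: float = 0.15,
    rng: np.random.Generator | None = None,
) -> PatchSpec:
    """Draw a uniformly random patch covering 10-15% (by default) of the
    well's width and height.

    Width and height are drawn independently and uniformly over the integer
    sides in ``[ceil(f_min*dim), floor(f_max*dim)]``; the top-left corner is
    uniform over all positions keeping the patch inside the image.
    """
    if not (0.0 < f_min <= f_max <= 1.0):
        raise ValueError("need 0 < f_min <= f_max <= 1")
    rng = rng if rng is not None else np.random.default_rng()
    w_lo, w_hi = int(np.ceil(f_min * image_w)), int(np.floor(f_max * image_w))
    h_lo, h_hi = int(np.ceil(f_min * image_h)), int(np.floor(f_max * image_h))
    if w_lo < 1 or h_lo < 1 or w_lo > w_hi or h_lo > h_hi:
        raise ValueError(
            f"image {image_w}x{image_h} too small for patch fractions "
            f"[{f_min}, {f_max}]"
        )
    w = int(rng.integers(w_lo, w_hi + 1))
    h = int(rng.integers(h_lo, h_hi + 1))
    x = int(rng.integers(0, image_w - w + 1))
    y = int(rng.integers(0, image_h - h + 1))
    return PatchSpec(x, y, w, h)


def count_patch_space(
    image_w: int, image_h: int, f_min: float = 0.10, f_max: float = 0.15
) -> int:
    """Exact number of distinct (w, h, x, y) patches the random sampler can
    produce: sum over admissible integer sides of the number of positions,
    i.e. ``sum_w (W-w+1) * sum_h (H-h+1)``."""
    if not (0.0 < f_min <= f_max <= 1.0):
        raise ValueError("need 0 < f_min <= f_max <= 1")
    w_lo, w_hi = int(np.ceil(f_min * image_w)), int(np.floor(f_max * image_w))
    h_lo, h_hi = int(np.ceil(f_min * image_h)), int(np.floor(f_max * image_h))
    if w_lo < 1 or h_lo < 1 or w_lo > w_hi or h_lo > h_hi:
        raise ValueError("no admissible patch size")
    n_x = sum(image_w - w + 1 for w in range(w_lo, w_hi + 1))
    n_y = sum(image_h - h + 1 for h in range(h_lo, h_hi + 1))
    return n_x * n_y


def crop_with_annotations(
    image: np.ndarray,
    cells: Sequence[tuple[BBox, CellType]],
    spec: PatchSpec,
    keep_threshold: float = 0.25,
    well_id: str = "",
) -> PatchSample:
    """Crop a patch and carry over the ground-truth boxes that meaningfully
    intersect it.

    Boxes intersecting the patch are clipped to it and re-offset to patch
    coordinates; a clipped box is kept iff its remaining area is at least
    ``keep_threshold`` of the original box area.  This avoids training on
    slivers of cells cut by the patch border while keeping most split cells.
    """
    crop = image[spec.y : spec.y + spec.h, spec.x : spec.x + spec.w]
    patch_box = spec.as_bbox()
    kept: list[tuple[BBox, CellType]] = []
    for box, ctype in cells:
        inter = box.intersection(patch_box)
        if inter is None:
            continue
        if inter.area / box.area >= keep_threshold:
            kept.append((inter.shift(-spec.x, -spec.y), ctype))
    return PatchSample(image=crop, boxes=kept, well_id=well_id, spec=spec)


# ---------------------------------------------------------------------------
# Augmentation


def _rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    import skimage.color

    return skimage.color.rgb2hsv(img)


def _hsv_to_rgb(img: np.ndarray) -> np.ndarray:
    import skimage.color

    return skimage.color.hsv2rgb(img)


def _photometric(img: np.ndarray, db: float, dh: float, fs: float) -> np.ndarray:
    """Apply brightness/hue/saturation jitter to a uint8 RGB image."""
    if db == 0.0 and dh == 0.0 and fs == 1.0:
        return img
    f = img.astype(np.float64) / 255.0
    hsv = _rgb_to_hsv(f)
    hsv[..., 0] = (hsv[..., 0] + dh) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * fs, 0.0, 1.0)
    out = _hsv_to_rgb(hsv) + db
    return (np.clip(out, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def _flip_box_vertical(box: BBox, h: float) -> BBox:
    return BBox(box.x_min, h - box.y_max, box.x_max, h - box.y_min)


def _rot90_box(box: BBox, w: float, h: float, k: int) -> BBox:
    """Box under k counter-clockwise 90-degree rotations of a w x h image
    (numpy rot90 convention); output is in the rotated image's frame."""
    b = box
    for _ in range(k % 4):
        # (x, y) -> (y, w - x): ccw rotation maps width onto the y axis
        b = BBox(b.y_min, w - b.x_max, b.y_max, w - b.x_min)
        w, h = h, w
    return b


def augment(
    sample: PatchSample,
    cfg: AugmentationConfig,
    rng: np.random.Generator | None = None,
) -> PatchSample:
    """Randomly photometrically and geometrically augment a patch sample.

    Photometric changes leave boxes untouched; flips and right-angle
    rotations remap boxes exactly.  Class labels never change.
    """
    rng = rng if rng is not None else np.random.default_rng()
    img = sample.image
    boxes = list(sample.boxes)
    h, w = img.shape[:2]
    desc = []

    db = float(rng.uniform(*cfg.brightness_delta))
    dh = float(rng.uniform(*cfg.hue_delta))
    fs = float(rng.uniform(*cfg.saturation_factor))
    img = _photometric(img, db, dh, fs)
    if (db, dh, fs) != (0.0, 0.0, 1.0):
        desc.append(f"photo(b={db:+.3f},h={dh:+.3f},s={fs:.3f})")

    if rng.random() < cfg.vertical_flip_prob:
        img = img[::-1].copy()
        boxes = [(_flip_box_vertical(b, h), c) for b, c in boxes]
        desc.append("vflip")

    rot = int(rng.choice(cfg.rotation_set))
    if rot % 360 != 0:
        k = rot // 90
        boxes = [(_rot90_box(b, w, h, k), c) for b, c in boxes]
        img = np.rot90(img, k).copy()
        desc.append(f"rot{rot}")

    return PatchSample(
        image=img,
        boxes=boxes,
        well_id=sample.well_id,
        spec=sample.spec,
        augmentation="+".join(desc),
    )


# ---------------------------------------------------------------------------
# Deterministic tiling for inference


def tile_image(
    image: np.ndarray, grid_rows: int = 8, grid_cols: int = 8
) -> list[tuple[PatchSpec, np.ndarray]]:
    """Split an image into a row-major grid of non-overlapping tiles that
    cover it exactly; the default 8x8 grid gives the 64 inference patches
    per culture.  Remainders go to the last row/column."""
    from .annotation import region_grid

    h, w = image.shape[:2]
    tiles = []
    for x, y, tw, th in region_grid(w, h, grid_rows, grid_cols):
        tiles.append((PatchSpec(x, y, tw, th), image[y : y + th, x : x + tw]))
    return tiles


# ---------------------------------------------------------------------------
# Training-set construction


def well_gt_boxes(well: WellAnnotation) -> list[tuple[BBox, CellType]]:
    """Ground-truth (tightest-square box, class) pairs in well coordinates."""
    out = []
    for cell, _rid in well.iter_cells_well_coords():
        out.append(
            (tightest_square_bbox(cell.polygon, well.width, well.height),
             cell.cell_type)
        )
    return out


def build_training_set(
    wells: Sequence[tuple[np.ndarray, WellAnnotation]],
    n_patches: int,
    cfg: AugmentationConfig | None = None,
    seed: int = 0,
    f_min: float = 0.10,
    f_max: float = 0.15,
    keep_threshold: float = 0.25,
) -> Iterator[PatchSample]:
    """Stream ``n_patches`` augmented training patches from annotated wells.

    Wells are chosen uniformly; each draw samples a random patch, clips the
    well's ground-truth boxes to it, and augments.  Fully reproducible from
    ``seed``; the rng is split per stage so enabling or disabling
    augmentation does not perturb the patch positions.
    """
    if not wells:
        raise ValueError("need at least one annotated well")
    cfg = cfg if cfg is not None else AugmentationConfig()
    root = np.random.SeedSequence(seed)
    ss_pos, ss_aug = root.spawn(2)
    rng_pos = np.random.default_rng(ss_pos)
    rng_aug = np.random.default_rng(ss_aug)

    gt_cache = [well_gt_boxes(ann) for _img, ann in wells]

    for _ in range(n_patches):
        idx = int(rng_pos.integers(0, len(wells)))
        image, ann = wells[idx]
        spec = sample_random_patch(ann.width, ann.height, f_min, f_max, rng_pos)
        sample = crop_with_annotations(
            image, gt_cache[idx], spec, keep_threshold, well_id=ann.well_id
        )
        yield augment(sample, cfg, rng_aug)


def manifest_row(sample: PatchSample) -> dict:
    """Audit record of one training patch for the dataset manifest CSV."""
    return {
        "well_id": sample.well_id,
        "x": sample.spec.x,
        "y": sample.spec.y,
        "w": sample.spec.w,
        "h": sample.spec.h,
        "augmentation": sample.augmentation,
        "n_boxes": len(sample.boxes),
    }
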