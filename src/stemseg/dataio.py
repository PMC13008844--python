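"""Dataset plumbing: polygon annotations, plant-level stratified splitting,
paired augmentation, and the Pascal VOC directory layout.

Conventions used throughout: 0-based (row, col) pixel indexing, and the
pixel-center rule for rasterization — pixel (row, col) is foreground iff its
center (col + 0.5, row + 0.5) lies inside a target polygon under the
nonzero winding rule.

The train/validation split operates on whole plants, never on images: every
view of a plant follows the plant into its partition, which removes the
near-duplicate leakage that four rotated views of the same specimen would
otherwise create.  Within each morphology class the requested fraction of
plants is assigned to training (largest-remainder rounding so the overall
total equals round(ratio * n_plants)), using a seeded shuffle.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import resize as skresize
from skimage.transform import rotate as skrotate

from .synthgen import AcquisitionManifest, ManifestRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PolygonAnnotation",
    "SplitResult",
    "AugmentConfig",
    "polygons_to_mask",
    "read_labelme",
    "stratified_plant_split",
    "augment_pair",
    "write_voc_layout",
    "read_voc_layout",
    "load_pair",
]


# -- polygon annotations -----------------------------------------------------


@dataclass(frozen=True)
class PolygonAnnotation:
    """A labelled closed polygon; points are (x, y) = (col, row) pixel
    coordinates, implicitly closed."""

    label: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.points) < 3:
            raise ValueError(f"polygon {self.label!r} needs >= 3 points, got {len(self.points)}")


def polygons_to_mask(
    annotations: list[PolygonAnnotation],
    height: int,
    width: int,
    target_label: str,
) -> np.ndarray:
    """Rasterize all polygons with the target label into a {0,1} mask.

    A pixel is foreground iff its center lies inside any matching polygon
    under the nonzero winding rule.
    """
    if height < 1 or width < 1:
        raise ValueError("mask dimensions must be positive")
    mask = np.zeros((height, width), dtype=np.uint8)
    cx = np.arange(width) + 0.5  # pixel-center x per column
    cy = np.arange(height) + 0.5
    px = np.broadcast_to(cx[None, :], (height, width))
    py = np.broadcast_to(cy[:, None], (height, width))
    for ann in annotations:
        if ann.label != target_label:
            continue
        wn = np.zeros((height, width), dtype=int)
        pts = np.asarray(ann.points, dtype=float)
        for (x1, y1), (x2, y2) in zip(pts, np.roll(pts, -1, axis=0)):
            is_left = (x2 - x1) * (py - y1) - (px - x1) * (y2 - y1)
            upward = (y1 <= py) & (py < y2) & (is_left > 0)
            downward = (y2 <= py) & (py < y1) & (is_left < 0)
            wn += upward.astype(int) - downward.astype(int)
        mask |= (wn != 0).astype(np.uint8)
    return mask


def read_labelme(path: str | Path) -> list[PolygonAnnotation]:
    """Parse a LabelMe JSON file; only polygon shapes are kept."""
    data = json.loads(Path(path).read_text())
    annotations = []
    for shape in data.get("shapes", []):
        kind = shape.get("shape_type", "polygon")
        if kind != "polygon":
            logger.warning("ignoring non-polygon shape %r of type %r in %s", shape.get("label"), kind, path)
            continue
        annotations.append(
            PolygonAnnotation(shape["label"], tuple((float(x), float(y)) for x, y in shape["points"]))
        )
    return annotations


# -- plant-level stratified split --------------------------------------------


@dataclass(frozen=True)
class SplitResult:
    train_plants: frozenset[str]
    val_plants: frozenset[str]
    ratio: float
    seed: int

    def __post_init__(self):
        if self.train_plants & self.val_plants:
            raise ValueError("train and validation plant sets overlap")


def _largest_remainder(quotas: dict[str, float], total: int) -> dict[str, int]:
    base = {c: int(np.floor(q)) for c, q in quotas.items()}
    residual = total - sum(base.values())
    # hand out the remaining units by descending fractional part; ties by
    # larger quota then name, for platform-stable determinism
    order = sorted(quotas, key=lambda c: (-(quotas[c] - base[c]), -quotas[c], c))
    for c in order[:residual]:
        base[c] += 1
    return base


def stratified_plant_split(
    manifest: AcquisitionManifest,
    ratio: float,
    seed: int,
) -> SplitResult:
    """Split plants into train/validation, stratified by morphology class.

    Within each class, plants are shuffled with the seeded generator and the
    first k assigned to training, where the per-class k come from
    largest-remainder rounding of ratio * class_size constrained to a total
    of round(ratio * n_plants).  Deterministic for a fixed seed.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"ratio must lie in [0, 1], got {ratio}")
    plant_cls = manifest.plant_classes()  # raises on a plant with two classes
    by_class: dict[str, list[str]] = {}
    for pid in sorted(plant_cls):
        by_class.setdefault(plant_cls[pid], []).append(pid)
    n_total = len(plant_cls)
    target_total = int(np.floor(ratio * n_total + 0.5))
    quotas = {c: ratio * len(pids) for c, pids in by_class.items()}
    take = _largest_remainder(quotas, target_total)
    rng = np.random.default_rng(seed)
    train: set[str] = set()
    for cls in sorted(by_class):
        pids = np.array(by_class[cls])
        rng.shuffle(pids)
        train.update(pids[: take[cls]])
    val = set(plant_cls) - train
    return SplitResult(frozenset(train), frozenset(val), ratio, seed)


# -- paired augmentation ------------------------------------------------------


@dataclass(frozen=True)
class AugmentConfig:
    """Which augmentations may fire and their parameter ranges.

    Geometric transforms (rotation, crop, flip) are applied with identical
    parameters to image and mask (mask resampled nearest-neighbor);
    photometric transforms (HSV perturbation, Gaussian noise) touch the
    image only.  Each enabled op fires independently with probability
    ``prob``.
    """

    ops: frozenset[str] = frozenset({"rotation", "random_crop", "horizontal_flip", "hsv_perturb", "gaussian_noise"})
    prob: float = 0.5
    rotation_deg: float = 15.0
    crop_min_area: float = 0.8
    hue_delta: float = 10.0 / 360.0
    sat_delta: float = 0.2
    val_delta: float = 0.2
    noise_sigma: float = 10.0 / 255.0

    _KNOWN = frozenset({"rotation", "random_crop", "horizontal_flip", "hsv_perturb", "gaussian_noise"})

    def __post_init__(self):
        unknown = self.ops - self._KNOWN
        if unknown:
            raise ValueError(f"unknown augmentation ops {sorted(unknown)}")


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    config: AugmentConfig,
    rng_seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a random augmentation pipeline to an image/mask pair.

    Deterministic for a fixed seed.  Returns (uint8 image, {0,1} mask).
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError(f"image {image.shape[:2]} and mask {mask.shape} sizes differ")
    rng = np.random.default_rng(rng_seed)
    img = image.astype(np.float64) / 255.0
    msk = (mask > 0).astype(np.uint8)
    h, w = msk.shape

    if "horizontal_flip" in config.ops and rng.random() < config.prob:
        img = img[:, ::-1].copy()
        msk = msk[:, ::-1].copy()
    if "rotation" in config.ops and rng.random() < config.prob:
        angle = rng.uniform(-config.rotation_deg, config.rotation_deg)
        img = skrotate(img, angle, order=1, preserve_range=True)
        msk = skrotate(msk.astype(float), angle, order=0, preserve_range=True).astype(np.uint8)
    if "random_crop" in config.ops and rng.random() < config.prob:
        area = rng.uniform(config.crop_min_area, 1.0)
        scale = np.sqrt(area)
        ch, cw = max(int(h * scale), 1), max(int(w * scale), 1)
        r0 = int(rng.integers(0, h - ch + 1))
        c0 = int(rng.integers(0, w - cw + 1))
        img = skresize(img[r0 : r0 + ch, c0 : c0 + cw], (h, w), order=1, anti_aliasing=False)
        msk = skresize(
            msk[r0 : r0 + ch, c0 : c0 + cw].astype(float), (h, w), order=0, anti_aliasing=False
        ).astype(np.uint8)
    if "hsv_perturb" in config.ops and rng.random() < config.prob:
        hsv = rgb2hsv(img.clip(0, 1))
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-config.hue_delta, config.hue_delta)) % 1.0
        hsv[..., 1] = (hsv[..., 1] * (1 + rng.uniform(-config.sat_delta, config.sat_delta))).clip(0, 1)
        hsv[..., 2] = (hsv[..., 2] * (1 + rng.uniform(-config.val_delta, config.val_delta))).clip(0, 1)
        img = hsv2rgb(hsv)
    if "gaussian_noise" in config.ops and rng.random() < config.prob:
        sigma = rng.uniform(0, config.noise_sigma)
        img = img + rng.normal(0, sigma, size=img.shape)

    return (img.clip(0, 1) * 255).round().astype(np.uint8), msk


# -- Pascal VOC layout --------------------------------------------------------


def _basename(rec: ManifestRecord) -> str:
    return f"{rec.plant_id}_{rec.morphology_class}_{rec.view_index}"


def write_voc_layout(manifest: AcquisitionManifest, split: SplitResult, root: str | Path) -> None:
    """Emit JPEGImages/, SegmentationClass/ and ImageSets/Segmentation lists.

    Images are converted to JPEG; masks are copied as {0,1} PNGs.  One
    basename per line in train.txt / val.txt, grouped by the plant-level
    split.
    """
    root = Path(root)
    jpeg = root / "JPEGImages"
    segcls = root / "SegmentationClass"
    sets = root / "ImageSets" / "Segmentation"
    for d in (jpeg, segcls, sets):
        d.mkdir(parents=True, exist_ok=True)
    train_lines, val_lines = [], []
    src_root = manifest.root or Path(".")
    for rec in manifest.records:
        base = _basename(rec)
        img_src = Path(src_root) / rec.image_path
        mask_src = Path(src_root) / rec.mask_path
        if img_src.exists():
            Image.open(img_src).convert("RGB").save(jpeg / f"{base}.jpg", quality=95)
        if mask_src.exists():
            shutil.copyfile(mask_src, segcls / f"{base}.png")
        (train_lines if rec.plant_id in split.train_plants else val_lines).append(base)
    (sets / "train.txt").write_text("\n".join(train_lines) + ("\n" if train_lines else ""))
    (sets / "val.txt").write_text("\n".join(val_lines) + ("\n" if val_lines else ""))
    meta = {"ratio": split.ratio, "seed": split.seed}
    (root / "split.json").write_text(json.dumps(meta, indent=1))


def read_voc_layout(root: str | Path) -> tuple[AcquisitionManifest, SplitResult]:
    """Inverse of :func:`write_voc_layout` on (manifest, split)."""
    root = Path(root)
    sets = root / "ImageSets" / "Segmentation"
    if not sets.is_dir():
        raise FileNotFoundError(f"missing {sets}")
    records: list[ManifestRecord] = []
    train, val = set(), set()
    for name, bucket in (("train.txt", train), ("val.txt", val)):
        listing = sets / name
        if not listing.exists():
            raise FileNotFoundError(f"missing {listing}")
        for base in listing.read_text().split():
            pid, cls, view = base.rsplit("_", 2)
            records.append(
                ManifestRecord(pid, cls, int(view), f"JPEGImages/{base}.jpg", f"SegmentationClass/{base}.png")
            )
            bucket.add(pid)
    views = max(r.view_index for r in records) + 1
    meta = {"ratio": len(train) / max(len(train) + len(val), 1), "seed": 0}
    if (root / "split.json").exists():
        meta.update(json.loads((root / "split.json").read_text()))
    manifest = AcquisitionManifest(sorted(records, key=lambda r: (r.plant_id, r.view_index)), views, root=root)
    return manifest, SplitResult(frozenset(train), frozenset(val), meta["ratio"], meta["seed"])


# -- training pairs -----------------------------------------------------------


def load_pair(
    image_path: str | Path,
    mask_path: str | Path,
    input_size: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Read an (image, mask) pair as (3 x H x W float32 in [0,1], H x W uint8),
    optionally resized to input_size (bilinear image, nearest mask)."""
    img = np.asarray(Image.open(image_path).convert("RGB"), dtype=np.float32) / 255.0
    msk = (np.asarray(Image.open(mask_path).convert("L")) > 0).astype(np.uint8)
    if input_size is not None and img.shape[:2] != (input_size, input_size):
        img = skresize(img, (input_size, input_size), order=1, anti_aliasing=False).astype(np.float32)
        msk = skresize(msk.astype(float), (input_size, input_size), order=0).astype(np.uint8)
    return np.moveaxis(img, -1, 0).copy(), msk
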