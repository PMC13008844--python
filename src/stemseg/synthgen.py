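"""Synthetic mature-plant imagery with exact ground truth.

Real mature soybean images are hard to evaluate against because only manual
stem-length measurements exist.  This module renders a controllable
stand-in: one curved, tapering main stem per plant (a cubic Bezier swept
with linearly interpolated width) on a near-black background, pod-like
elliptical occluders whose hue sits within +/-10 degrees of the stem hue,
optional side branches defining three morphology classes (simple = 0
branches, double = 1, complex >= 2), and an axis-aligned ruler of known
physical length for scale calibration.  Each plant is rendered from four
views related by 90-degree planar rotations, and every sample carries the
exact centerline arc length in centimetres, so the full
segmentation-to-measurement pipeline can be scored without external data.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import draw as skdraw
from skimage import measure as skmeasure
from skimage.color import hsv2rgb

__all__ = [
    "MORPHOLOGY_CLASSES",
    "PlantSpec",
    "SyntheticSample",
    "ManifestRecord",
    "AcquisitionManifest",
    "MorphologyError",
    "RenderError",
    "make_plant_spec",
    "render_sample",
    "build_manifest",
    "bezier_points",
    "bezier_arc_length",
]

MORPHOLOGY_CLASSES = ("simple", "double", "complex")
_BRANCH_RANGE = {"simple": (0, 0), "double": (1, 1), "complex": (2, 4)}


class MorphologyError(ValueError):
    """Unknown plant morphology class."""


class RenderError(RuntimeError):
    """A sample could not be rendered within the canvas constraints."""


# -- Bezier geometry ---------------------------------------------------------


def bezier_points(control: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """Evaluate a cubic Bezier at parameters ``ts``; (len(ts), 2) array."""
    p0, p1, p2, p3 = np.asarray(control, dtype=float)
    t = ts[:, None]
    u = 1.0 - t
    return u**3 * p0 + 3 * u**2 * t * p1 + 3 * u * t**2 * p2 + t**3 * p3


def bezier_arc_length(control: np.ndarray, n_samples: int = 4096) -> float:
    """Numeric arc length by dense polyline integration (n_samples >= 1000)."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    pts = bezier_points(control, np.linspace(0.0, 1.0, n_samples))
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


# -- domain types ------------------------------------------------------------


@dataclass(frozen=True)
class PlantSpec:
    """Geometry of one synthetic plant in canvas (row, col) coordinates."""

    plant_id: str
    morphology_class: str
    stem_control_points: tuple[tuple[float, float], ...]  # 4 points
    base_width: float
    apex_width: float
    branch_specs: tuple[tuple[tuple[float, float], ...], ...]
    pod_count: int
    rng_seed: int
    canvas: tuple[int, int]

    def __post_init__(self):
        if self.morphology_class not in MORPHOLOGY_CLASSES:
            raise MorphologyError(f"unknown morphology class {self.morphology_class!r}")
        if not self.base_width >= self.apex_width >= 1.0:
            raise ValueError("widths must satisfy base >= apex >= 1 px")
        lo, hi = _BRANCH_RANGE[self.morphology_class]
        if not lo <= len(self.branch_specs) <= hi:
            raise ValueError(
                f"{self.morphology_class} plants need {lo}..{hi} branches, "
                f"got {len(self.branch_specs)}"
            )
        h, w = self.canvas
        pts = np.asarray(self.stem_control_points)
        if (pts[:, 0] < 0).any() or (pts[:, 0] >= h).any() or (pts[:, 1] < 0).any() or (pts[:, 1] >= w).any():
            raise ValueError("stem control points must lie inside the canvas")


@dataclass
class SyntheticSample:
    image: np.ndarray  # H x W x 3 uint8
    mask: np.ndarray  # H x W uint8 in {0,1}; 1 = main stem
    centerline: np.ndarray  # (n, 2) int (row, col), ordered base -> apex
    true_length_cm: float
    px_per_cm: float
    ruler_endpoints: tuple[tuple[float, float], tuple[float, float]]
    plant_id: str
    view_index: int
    morphology_class: str = ""

    def metadata(self) -> dict:
        return {
            "plant_id": self.plant_id,
            "view_index": self.view_index,
            "morphology_class": self.morphology_class,
            "true_length_cm": self.true_length_cm,
            "px_per_cm": self.px_per_cm,
            "ruler_endpoints": [list(p) for p in self.ruler_endpoints],
        }


@dataclass(frozen=True)
class ManifestRecord:
    plant_id: str
    morphology_class: str
    view_index: int
    image_path: str
    mask_path: str


@dataclass
class AcquisitionManifest:
    records: list[ManifestRecord]
    views_per_plant: int
    root: Path | None = None

    @property
    def plants(self) -> int:
        return len({r.plant_id for r in self.records})

    def plant_classes(self) -> dict[str, str]:
        """plant_id -> morphology class; rejects inconsistent labelling."""
        out: dict[str, str] = {}
        for r in self.records:
            if r.plant_id in out and out[r.plant_id] != r.morphology_class:
                raise ValueError(f"plant {r.plant_id} appears with two morphology classes")
            out[r.plant_id] = r.morphology_class
        return out

    def validate(self) -> None:
        per_plant: dict[str, int] = {}
        for r in self.records:
            per_plant[r.plant_id] = per_plant.get(r.plant_id, 0) + 1
        bad = {p: n for p, n in per_plant.items() if n != self.views_per_plant}
        if bad:
            raise ValueError(f"plants without exactly {self.views_per_plant} views: {bad}")
        self.plant_classes()

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["plant_id", "morphology_class", "view_index", "image_path", "mask_path"])
            for r in self.records:
                writer.writerow([r.plant_id, r.morphology_class, r.view_index, r.image_path, r.mask_path])

    @classmethod
    def read_csv(cls, path: str | Path) -> "AcquisitionManifest":
        path = Path(path)
        records = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                records.append(
                    ManifestRecord(
                        row["plant_id"],
                        row["morphology_class"],
                        int(row["view_index"]),
                        row["image_path"],
                        row["mask_path"],
                    )
                )
        views = max((r.view_index for r in records), default=-1) + 1
        return cls(records, views, root=path.parent)


# -- spec construction -------------------------------------------------------


def _clip_to_disc(pt: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    d = pt - center
    r = np.linalg.norm(d)
    if r > radius:
        pt = center + d * (radius / r)
    return pt


def make_plant_spec(
    morphology_class: str,
    rng_seed: int,
    canvas: tuple[int, int] = (512, 512),
    plant_id: str | None = None,
) -> PlantSpec:
    """Sample a random plant of the requested morphology class.

    Deterministic for a fixed seed.  All geometry is confined to the disc
    inscribed in the canvas (minus a width margin) so that every 90-degree
    view rotation keeps the plant on canvas; the stem spans at least half
    the canvas height.
    """
    if morphology_class not in MORPHOLOGY_CLASSES:
        raise MorphologyError(f"unknown morphology class {morphology_class!r}")
    h, w = canvas
    if h < 64 or w < 64:
        raise ValueError(f"canvas must be at least 64x64, got {canvas}")
    rng = np.random.default_rng(rng_seed)
    mindim = min(h, w)
    # ~2% of the frame, as in downscaled real captures, but never below 4 px
    # so the stem stays resolvable when tests render at reduced canvas sizes
    base_width = max(4.0, rng.uniform(0.018, 0.03) * mindim)
    apex_width = max(1.5, base_width * rng.uniform(0.3, 0.55))
    center = np.array([h / 2.0, w / 2.0])
    radius = mindim / 2.0 - base_width / 2.0 - max(3.0, 0.03 * mindim)

    for _ in range(64):
        u0, u3 = rng.uniform(0.8, 0.95, size=2)
        x0 = rng.uniform(-0.6, 0.6) * np.sqrt(max(radius**2 - (u0 * radius) ** 2, 0.0))
        x3 = rng.uniform(-0.6, 0.6) * np.sqrt(max(radius**2 - (u3 * radius) ** 2, 0.0))
        p0 = center + np.array([u0 * radius, x0])  # base, near canvas bottom
        p3 = center + np.array([-u3 * radius, x3])  # apex
        if (p0[0] - p3[0]) < 0.5 * h:
            continue
        axis = p3 - p0
        perp = np.array([-axis[1], axis[0]])
        perp /= np.linalg.norm(perp)
        p1 = _clip_to_disc(p0 + axis / 3.0 + perp * rng.uniform(-0.2, 0.2) * radius, center, radius)
        p2 = _clip_to_disc(p0 + 2.0 * axis / 3.0 + perp * rng.uniform(-0.2, 0.2) * radius, center, radius)
        break
    else:
        raise RenderError(f"could not place a stem spanning half of canvas {canvas}")
    stem = np.array([p0, p1, p2, p3])

    lo, hi = _BRANCH_RANGE[morphology_class]
    n_branches = int(rng.integers(lo, hi + 1))
    branches = []
    stem_dense = bezier_points(stem, np.linspace(0, 1, 256))
    for _ in range(n_branches):
        t = rng.uniform(0.25, 0.75)
        a = stem_dense[int(t * 255)]
        tangent = stem_dense[min(int(t * 255) + 1, 255)] - a
        tangent /= max(np.linalg.norm(tangent), 1e-9)
        normal = np.array([-tangent[1], tangent[0]]) * rng.choice([-1.0, 1.0])
        length = rng.uniform(0.3, 0.55) * radius
        out_dir = normal * 0.8 + tangent * rng.uniform(-0.5, -0.1)  # branches lean upward
        out_dir /= np.linalg.norm(out_dir)
        b0 = a
        b3 = _clip_to_disc(a + out_dir * length, center, radius)
        b1 = _clip_to_disc(a + out_dir * length / 3 + normal * rng.uniform(-0.1, 0.1) * length, center, radius)
        b2 = _clip_to_disc(a + out_dir * 2 * length / 3 + normal * rng.uniform(-0.1, 0.1) * length, center, radius)
        branches.append(tuple(map(tuple, (b0, b1, b2, b3))))

    return PlantSpec(
        plant_id=plant_id or f"plant_{rng_seed}",
        morphology_class=morphology_class,
        stem_control_points=tuple(map(tuple, stem)),
        base_width=float(base_width),
        apex_width=float(apex_width),
        branch_specs=tuple(branches),
        pod_count=int(rng.integers(5, 12)),
        rng_seed=int(rng_seed),
        canvas=(int(h), int(w)),
    )


# -- rendering ---------------------------------------------------------------


def _rotate_points(pts: np.ndarray, center: np.ndarray, quarter_turns: int) -> np.ndarray:
    """Exact planar rotation by 90 deg * quarter_turns about ``center``."""
    c = [1, 0, -1, 0][quarter_turns % 4]
    s = [0, 1, 0, -1][quarter_turns % 4]
    d = pts - center
    return np.stack([c * d[:, 0] - s * d[:, 1], s * d[:, 0] + c * d[:, 1]], axis=1) + center


def _stamp_band(
    canvas_shape: tuple[int, int],
    control: np.ndarray,
    width_from: float,
    width_to: float,
    step: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Union of discs of linearly interpolated radius swept along the Bezier.

    Returns (band mask, arc-length fraction map used for color shading).
    """
    h, w = canvas_shape
    length = bezier_arc_length(control, 2048)
    n = max(int(np.ceil(length / step)) + 1, 2)
    pts = bezier_points(control, np.linspace(0, 1, n))
    fracs = np.linspace(0, 1, n)
    radii = 0.5 * (width_from + (width_to - width_from) * fracs)
    band = np.zeros((h, w), dtype=bool)
    shade = np.zeros((h, w), dtype=float)
    for (r, c), rad, f in zip(pts, radii, fracs):
        rr, cc = skdraw.disk((r, c), max(rad, 0.75), shape=(h, w))
        band[rr, cc] = True
        shade[rr, cc] = f
    return band, shade


def _band_extent(control: np.ndarray, half_width: float) -> tuple[float, float, float, float]:
    pts = bezier_points(np.asarray(control), np.linspace(0, 1, 512))
    return (
        float(pts[:, 0].min() - half_width),
        float(pts[:, 0].max() + half_width),
        float(pts[:, 1].min() - half_width),
        float(pts[:, 1].max() + half_width),
    )


def render_sample(
    spec: PlantSpec,
    view_index: int,
    canvas: tuple[int, int] | None = None,
    px_per_cm: float | None = None,
    ruler_cm: float = 15.0,
) -> SyntheticSample:
    """Render one view of a plant; the mask covers the main stem only.

    The view applies a planar rotation of 90 deg x view_index to the plant
    geometry before rasterization.  Pods are drawn over the stem (true
    occluders, excluded from the mask) but are re-placed if they would fully
    sever the visible stem band.  ``true_length_cm`` is the numeric arc
    length of the main-stem Bezier divided by ``px_per_cm``.
    """
    if view_index not in (0, 1, 2, 3):
        raise ValueError(f"view_index must be 0..3, got {view_index}")
    h, w = canvas if canvas is not None else spec.canvas
    if px_per_cm is None:
        px_per_cm = 20.0 * min(h, w) / 512.0
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    rng = np.random.default_rng([spec.rng_seed % (2**31), view_index, 9173])
    center = np.array([h / 2.0, w / 2.0])

    stem = _rotate_points(np.asarray(spec.stem_control_points, dtype=float), center, view_index)
    branches = [
        _rotate_points(np.asarray(b, dtype=float), center, view_index) for b in spec.branch_specs
    ]
    rmin, rmax, cmin, cmax = _band_extent(stem, spec.base_width / 2.0)
    if rmin < 0 or cmin < 0 or rmax >= h or cmax >= w:
        raise RenderError(f"stem leaves the {h}x{w} canvas after rotation by {90 * view_index} deg")

    arc_px = bezier_arc_length(stem, 4096)
    true_length_cm = arc_px / px_per_cm

    # background: near-black with mild sensor noise
    img = rng.normal(0.012, 0.006, size=(h, w, 3)).clip(0.0, 1.0)

    # ruler: axis-aligned bar with alternating centimetre ticks, top margin
    ruler_px = ruler_cm * px_per_cm
    if ruler_px > w - 8:
        ruler_cm = max(1.0, np.floor((w - 8) / px_per_cm))
        ruler_px = ruler_cm * px_per_cm
        if ruler_px > w - 8:
            raise RenderError("canvas too small to place a 1 cm ruler at this px_per_cm")
    th = max(2, h // 64)
    r0, c0 = 1, 4.0
    ruler_endpoints = ((r0 + th / 2.0, c0), (r0 + th / 2.0, c0 + ruler_px))
    cols = np.arange(int(np.floor(c0)), int(np.ceil(c0 + ruler_px)) + 1)
    cm_idx = np.floor((cols - c0) / px_per_cm).astype(int)
    tone = np.where(cm_idx % 2 == 0, 0.92, 0.55)
    img[r0 : r0 + th, cols] = tone[None, :, None]

    stem_hue = rng.uniform(0.08, 0.13)  # tan/brown of a mature stem
    stem_sat = rng.uniform(0.45, 0.65)
    stem_val = rng.uniform(0.45, 0.65)

    for b in branches:
        bband, bshade = _stamp_band((h, w), b, spec.base_width * 0.6, max(spec.apex_width * 0.6, 1.0))
        col = hsv2rgb(
            np.array([[[stem_hue + 0.01, stem_sat * 0.9, stem_val * rng.uniform(0.85, 1.0)]]])
        )[0, 0]
        img[bband] = col * (1.0 - 0.25 * bshade[bband])[:, None]

    band, shade = _stamp_band((h, w), stem, spec.base_width, spec.apex_width)
    stem_rgb = hsv2rgb(np.array([[[stem_hue, stem_sat, stem_val]]]))[0, 0]
    img[band] = stem_rgb * (1.0 - 0.3 * shade[band])[:, None]
    mask = band.astype(np.uint8)
    if mask.sum() == 0:
        raise RenderError("empty stem mask")

    # centerline: ordered pixels along the Bezier, base -> apex
    n_cl = max(int(arc_px * 2), 32)
    cl = np.round(bezier_points(stem, np.linspace(0, 1, n_cl))).astype(int)
    keep = np.ones(len(cl), dtype=bool)
    keep[1:] = np.any(cl[1:] != cl[:-1], axis=1)
    centerline = cl[keep]

    # pods: occluders drawn over the stem, never severing the visible band
    anchor_fracs = np.linspace(0.05, 0.95, 64)
    anchors = bezier_points(stem, anchor_fracs)
    radii = 0.5 * (spec.base_width + (spec.apex_width - spec.base_width) * anchor_fracs)
    tangents = np.gradient(anchors, axis=0)
    pod_count = spec.pod_count
    for _ in range(20):
        cover = np.zeros((h, w), dtype=bool)
        pods = []
        for _ in range(pod_count):
            i = int(rng.integers(0, len(anchors)))
            tan = tangents[i] / max(np.linalg.norm(tangents[i]), 1e-9)
            nrm = np.array([-tan[1], tan[0]]) * rng.choice([-1.0, 1.0])
            a = rng.uniform(0.05, 0.09) * min(h, w) / 2.0
            b_ax = a * rng.uniform(0.3, 0.5)
            # sit beside the stem so the pod clips the band edge instead of
            # crossing it: the visible band must stay connected
            centre = anchors[i] + nrm * (b_ax * rng.uniform(0.6, 0.9) + radii[i] * rng.uniform(0.0, 0.5))
            # major axis along the stem tangent: skimage's rotation aligns the
            # r_radius axis with direction (cos a, sin a) in (row, col)
            angle = np.arctan2(tan[1], tan[0]) + rng.uniform(-0.35, 0.35)
            rr, cc = skdraw.ellipse(centre[0], centre[1], a, b_ax, shape=(h, w), rotation=angle)
            cover[rr, cc] = True
            hue = (stem_hue + rng.uniform(-10.0, 10.0) / 360.0) % 1.0
            col = hsv2rgb(np.array([[[hue, stem_sat * rng.uniform(0.8, 1.1), stem_val * rng.uniform(0.8, 1.1)]]]))[0, 0]
            pods.append((rr, cc, col.clip(0, 1)))
        visible = band & ~cover
        if visible.any() and skmeasure.label(visible, connectivity=2).max() == 1:
            for rr, cc, col in pods:
                img[rr, cc] = col
            break
        pod_count = max(pod_count - 1, 0)  # relax until the band stays connected

    image = (img.clip(0, 1) * 255).round().astype(np.uint8)
    if not mask[centerline[:, 0], centerline[:, 1]].all():
        raise RenderError("centerline escaped the rendered stem band")
    return SyntheticSample(
        image=image,
        mask=mask,
        centerline=centerline,
        true_length_cm=float(true_length_cm),
        px_per_cm=float(px_per_cm),
        ruler_endpoints=ruler_endpoints,
        plant_id=spec.plant_id,
        view_index=view_index,
        morphology_class=spec.morphology_class,
    )


# -- dataset emission --------------------------------------------------------


def _plant_seeds(rng_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(rng_seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def build_manifest(
    class_counts: dict[str, int],
    views_per_plant: int = 4,
    rng_seed: int = 0,
    out_dir: str | Path = ".",
    canvas: tuple[int, int] = (512, 512),
    px_per_cm: float | None = None,
    render: bool = True,
) -> AcquisitionManifest:
    """Generate a plant dataset and its CSV manifest.

    Produces ``sum(class_counts) * views_per_plant`` records.  With
    ``render=False`` only the manifest metadata is produced (no pixel data
    is written) — sufficient for split accounting at scale.
    """
    unknown = set(class_counts) - set(MORPHOLOGY_CLASSES)
    if unknown:
        raise MorphologyError(f"unknown morphology classes {sorted(unknown)}")
    if any(v < 0 for v in class_counts.values()):
        raise ValueError("class counts must be non-negative")
    if not 1 <= views_per_plant <= 4:
        raise ValueError("views_per_plant must be between 1 and 4")
    out = Path(out_dir)
    if render:
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
    else:
        out.mkdir(parents=True, exist_ok=True)

    classes = [c for c in MORPHOLOGY_CLASSES for _ in range(class_counts.get(c, 0))]
    seeds = _plant_seeds(rng_seed, len(classes))
    records: list[ManifestRecord] = []
    for i, (cls, seed) in enumerate(zip(classes, seeds)):
        plant_id = f"plant_{i:04d}"
        spec = make_plant_spec(cls, seed, canvas, plant_id=plant_id) if render else None
        for view in range(views_per_plant):
            img_rel = f"images/{plant_id}_{cls}_{view}.png"
            mask_rel = f"masks/{plant_id}_{cls}_{view}.png"
            if render:
                sample = render_sample(spec, view, canvas, px_per_cm)
                Image.fromarray(sample.image).save(out / img_rel)
                Image.fromarray(sample.mask).save(out / mask_rel)
                (out / f"images/{plant_id}_{cls}_{view}.json").write_text(
                    json.dumps(sample.metadata(), indent=1)
                )
            records.append(ManifestRecord(plant_id, cls, view, img_rel, mask_rel))
    manifest = AcquisitionManifest(records, views_per_plant, root=out)
    manifest.write_csv(out / "manifest.csv")
    return manifest
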