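"""Calibrated stem-length measurement from a binary mask.

The pipeline maps a segmented main-stem mask to a physical length in three
steps: (1) scale calibration from an in-frame ruler, r = RL_real/RL_pixel
(cm per pixel); (2) skeletonization — morphological closing, reduction of
the largest connected component to a one-pixel centerline, and extraction of
the longest geodesic path between skeleton endpoints (side spurs produced by
pods or branches are thereby discarded); (3) pixel path length as the sum of
Euclidean steps between consecutive skeleton pixels, converted to
centimetres with r.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage.measure import label as sklabel
from skimage.morphology import closing as _gray_closing, disk, skeletonize

__all__ = [
    "CalibrationScale",
    "SkeletonPath",
    "Measurement",
    "calibrate",
    "extract_skeleton",
    "path_length_px",
    "measure",
]

_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class CalibrationScale:
    """Ruler span in pixels, its physical length, and the cm/px factor."""

    rl_pixel: float
    rl_real_cm: float

    def __post_init__(self):
        if self.rl_pixel <= 0:
            raise ValueError("ruler pixel span must be positive")
        if self.rl_real_cm <= 0:
            raise ValueError("ruler physical length must be positive")

    @property
    def r(self) -> float:
        """Conversion factor in cm per pixel."""
        return self.rl_real_cm / self.rl_pixel


@dataclass(frozen=True)
class SkeletonPath:
    """Ordered single-pixel centerline; consecutive points are 8-neighbors."""

    points: tuple[tuple[int, int], ...]

    def __post_init__(self):
        pts = self.points
        if len(set(pts)) != len(pts):
            raise ValueError("skeleton path revisits a pixel")
        for (r1, c1), (r2, c2) in zip(pts, pts[1:]):
            if max(abs(r1 - r2), abs(c1 - c2)) != 1:
                raise ValueError("consecutive skeleton points must be 8-neighbors")

    def __len__(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=int)


@dataclass(frozen=True)
class Measurement:
    l_pixel: float
    l_real_cm: float
    skeleton: SkeletonPath
    scale: CalibrationScale


def calibrate(
    ruler: np.ndarray | tuple,
    real_length_cm: float,
) -> CalibrationScale:
    """Derive the cm/px factor from a ruler mask or an endpoint pair.

    For a mask, the pixel span is the maximum pairwise Euclidean distance
    between foreground pixel centers (computed on the convex hull); for an
    endpoint pair ((r1, c1), (r2, c2)) it is their distance.
    """
    if real_length_cm <= 0:
        raise ValueError("ruler physical length must be positive")
    ruler_arr = np.asarray(ruler, dtype=float)
    if ruler_arr.shape == (2, 2):
        span = float(np.linalg.norm(ruler_arr[0] - ruler_arr[1]))
        if span == 0:
            raise ValueError("coincident ruler endpoints")
        return CalibrationScale(span, float(real_length_cm))
    if ruler_arr.ndim != 2:
        raise ValueError("ruler must be a 2-D mask or a pair of endpoints")
    pts = np.argwhere(ruler_arr > 0).astype(float)
    if len(pts) == 0:
        raise ValueError("empty ruler mask")
    if len(pts) == 1:
        raise ValueError("ruler mask spans zero pixels")
    if len(pts) > 3:
        try:  # the diameter is attained on the convex hull
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear masks: hull is degenerate, use all points
            pass
    span = float(pdist(pts).max())
    if span == 0:
        raise ValueError("ruler mask spans zero pixels")
    return CalibrationScale(span, float(real_length_cm))


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    """8-connectivity graph over skeleton pixels, edge weight 1 or sqrt(2)."""
    g = nx.Graph()
    pixels = np.argwhere(skel)
    pixel_set = {tuple(p) for p in pixels}
    g.add_nodes_from(pixel_set)
    for r, c in pixel_set:
        for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):  # forward half-stencil
            nb = (r + dr, c + dc)
            if nb in pixel_set:
                g.add_edge((r, c), nb, weight=_SQRT2 if dr and dc else 1.0)
    return g


def _longest_geodesic(g: nx.Graph) -> list[tuple[int, int]]:
    """Maximum-weight shortest path between skeleton endpoints.

    Endpoints (degree-1 nodes) are enumerated exhaustively; skeletons without
    two endpoints (cycles) fall back to a double-sweep farthest-point search.
    """
    if g.number_of_nodes() == 1:
        return list(g.nodes)
    endpoints = [n for n, d in g.degree() if d == 1]
    if len(endpoints) >= 2:
        best = (-1.0, None, None)
        for src in endpoints:
            dist, _ = nx.single_source_dijkstra(g, src)
            for dst in endpoints:
                if dst in dist and dist[dst] > best[0]:
                    best = (dist[dst], src, dst)
        return nx.dijkstra_path(g, best[1], best[2])
    start = next(iter(g.nodes))
    dist1, _ = nx.single_source_dijkstra(g, start)
    far1 = max(dist1.items(), key=lambda kv: kv[1])[0]
    dist2, paths = nx.single_source_dijkstra(g, far1)
    far2 = max(dist2.items(), key=lambda kv: kv[1])[0]
    return paths[far2]


def extract_skeleton(mask: np.ndarray, closing_radius: int | None = None) -> SkeletonPath:
    """Centerline of the largest component of a binary mask.

    Applies morphological closing (disc of ``closing_radius``; default 2 px
    at 512 px image size, scaled proportionally), thins to a one-pixel
    skeleton, and returns the longest geodesic path between endpoints of the
    skeleton's 8-connected graph.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    binary = mask > 0
    if closing_radius is None:
        closing_radius = max(1, round(2 * min(mask.shape) / 512))
    if closing_radius > 0:
        binary = _gray_closing(binary, disk(closing_radius)).astype(bool)
    if not binary.any():
        raise ValueError("mask is empty after closing")
    labels = sklabel(binary, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    skel = skeletonize(labels == largest)
    if not skel.any():
        raise ValueError("skeleton is empty")
    graph = _skeleton_graph(skel)
    components = list(nx.connected_components(graph))
    if len(components) > 1:  # thinning artifacts: keep the dominant piece
        graph = graph.subgraph(max(components, key=len)).copy()
    path = _longest_geodesic(graph)
    return SkeletonPath(tuple((int(r), int(c)) for r, c in path))


def path_length_px(path: SkeletonPath) -> float:
    """Sum of Euclidean distances between consecutive path points; 0 for a
    single point."""
    pts = path.as_array()
    if len(pts) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def measure(
    mask: np.ndarray,
    scale: CalibrationScale,
    closing_radius: int | None = None,
) -> Measurement:
    """Full mask-to-centimetres measurement: L_real = L_pixel * r."""
    skeleton = extract_skeleton(mask, closing_radius)
    l_px = path_length_px(skeleton)
    return Measurement(l_px, l_px * scale.r, skeleton, scale)
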