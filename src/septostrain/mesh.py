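"""Septal tracking mesh.

The septum is segmented as a simple, elongated polygon (an approximately
band-shaped region). Over that region an 11 radial x 31 longitudinal
grid of tracking points is generated, obeying a local coordinate frame:
the longitudinal direction follows the band's medial axis (the wall's
long axis), the radial direction is perpendicular to it (across the wall
thickness).

Construction: the polygon is rasterized and its medial axis extracted;
branch pixels with low boundary clearance (corner artefacts) are pruned;
the longest skeleton path is smoothed with a parametric spline, extended
to the band ends, and resampled into 31 equidistant stations. At each
station 11 points are placed across the thickness along the local
normal, inset slightly from the boundary so every mesh point lies
strictly inside the segmentation.

Coordinates are (x, y) pixels, 0-based, x rightward and y downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.interpolate import splev, splprep
from shapely.geometry import LineString, Point, Polygon
from skimage.draw import polygon as _raster_polygon
from skimage.morphology import medial_axis

from .errors import SegmentationError

__all__ = ["SeptalMesh", "build_mesh"]

_MIN_AREA_PX2 = 50.0
_MIN_ASPECT = 1.5


@dataclass
class SeptalMesh:
    """An n_radial x n_longitudinal grid of tracking points.

    Attributes
    ----------
    points:
        ``(n_radial, n_longitudinal, 2)`` array of (x, y) pixel
        coordinates.
    longitudinal:
        Per-point unit tangent of the band's long axis.
    radial:
        Per-point unit normal (longitudinal rotated +90 degrees).
    segmentation:
        The closed segmentation polygon, ``(m, 2)`` of (x, y).
    arc_length:
        Per-point arc-length coordinate (px) along its own radial row,
        measured from the first station. This is the independent
        coordinate of the least-squares strain estimator.
    """

    points: np.ndarray
    longitudinal: np.ndarray
    radial: np.ndarray
    segmentation: np.ndarray
    arc_length: np.ndarray

    @property
    def n_radial(self) -> int:
        return self.points.shape[0]

    @property
    def n_longitudinal(self) -> int:
        return self.points.shape[1]

    @classmethod
    def from_grid(cls, points: np.ndarray, segmentation: np.ndarray) -> "SeptalMesh":
        """Derive local frames and arc lengths from a point grid."""
        points = np.asarray(points, dtype=float)
        if points.ndim != 3 or points.shape[2] != 2:
            raise ValueError("points must have shape (n_radial, n_long, 2)")
        tang = np.gradient(points, axis=1)
        norms = np.linalg.norm(tang, axis=2, keepdims=True)
        if np.any(norms < 1e-12):
            raise SegmentationError("degenerate mesh: coincident stations")
        longitudinal = tang / norms
        radial = np.stack(
            [-longitudinal[..., 1], longitudinal[..., 0]], axis=-1
        )
        steps = np.linalg.norm(np.diff(points, axis=1), axis=2)
        arc = np.concatenate(
            [np.zeros((points.shape[0], 1)), np.cumsum(steps, axis=1)], axis=1
        )
        return cls(
            points=points,
            longitudinal=longitudinal,
            radial=radial,
            segmentation=np.asarray(segmentation, dtype=float),
            arc_length=arc,
        )


def _longest_skeleton_path(skel: np.ndarray) -> np.ndarray:
    """Ordered (row, col) pixels of the longest path through a skeleton."""
    rows, cols = np.nonzero(skel)
    nodes = list(zip(rows.tolist(), cols.tolist()))
    node_set = set(nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for r, c in nodes:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nb = (r + dr, c + dc)
                if nb in node_set:
                    g.add_edge((r, c), nb, weight=float(np.hypot(dr, dc)))
    if g.number_of_nodes() == 0:
        raise SegmentationError("empty skeleton")
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp).copy()
    ends = [n for n in g.nodes if g.degree(n) <= 1]
    if len(ends) < 2:
        ends = list(g.nodes)[:8]  # cyclic/blob skeleton: sample candidates
    best: tuple[float, list] = (-1.0, [])
    for i, a in enumerate(ends):
        lengths, paths = nx.single_source_dijkstra(g, a, weight="weight")
        for b in ends[i + 1 :]:
            if b in lengths and lengths[b] > best[0]:
                best = (lengths[b], paths[b])
    if len(best[1]) < 4:
        raise SegmentationError("segmentation too small to carry a medial axis")
    return np.asarray(best[1], dtype=float)


def _cross_section(
    poly: Polygon, p: np.ndarray, normal: np.ndarray, reach: float
) -> tuple[float, float]:
    """Extent (t_lo, t_hi) of the polygon along the normal through p."""
    line = LineString([p - reach * normal, p + reach * normal])
    inter = line.intersection(poly)
    if inter.is_empty:
        raise SegmentationError("mesh station fell outside the segmentation")
    pieces = getattr(inter, "geoms", [inter])
    station = Point(p)
    seg = min(pieces, key=lambda geom: geom.distance(station))
    coords = np.asarray(seg.coords, dtype=float)
    t = (coords - p) @ normal
    return float(t.min()), float(t.max())


def build_mesh(
    segmentation: np.ndarray,
    n_radial: int = 11,
    n_longitudinal: int = 31,
) -> SeptalMesh:
    """Generate the tracking mesh over a septal segmentation polygon.

    Parameters
    ----------
    segmentation:
        ``(m, 2)`` array of (x, y) pixel vertices of a simple
        (non-self-intersecting), elongated polygon.
    n_radial, n_longitudinal:
        Grid size; the default 11 x 31 yields 341 tracking points.
    """
    seg = np.asarray(segmentation, dtype=float)
    if seg.ndim != 2 or seg.shape[1] != 2 or len(seg) < 3:
        raise SegmentationError("segmentation must be an (m, 2) vertex array")
    poly = Polygon(seg)
    if not poly.is_valid:
        raise SegmentationError("segmentation polygon is self-intersecting")
    if poly.area < _MIN_AREA_PX2:
        raise SegmentationError(
            f"segmentation area {poly.area:.1f} px^2 below minimum {_MIN_AREA_PX2}"
        )
    rect = poly.minimum_rotated_rectangle
    rc = np.asarray(rect.exterior.coords)
    side_a = np.linalg.norm(rc[1] - rc[0])
    side_b = np.linalg.norm(rc[2] - rc[1])
    aspect = max(side_a, side_b) / max(min(side_a, side_b), 1e-9)
    if aspect < _MIN_ASPECT:
        raise SegmentationError(
            f"segmentation not band-like (aspect {aspect:.2f} < {_MIN_ASPECT})"
        )

    # --- rasterize and take the medial axis -------------------------------
    minx, miny, maxx, maxy = poly.bounds
    ox, oy = int(np.floor(minx)) - 2, int(np.floor(miny)) - 2
    w = int(np.ceil(maxx)) - ox + 3
    h = int(np.ceil(maxy)) - oy + 3
    rr, cc = _raster_polygon(seg[:, 1] - oy, seg[:, 0] - ox, shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    if mask.sum() < _MIN_AREA_PX2:
        raise SegmentationError("rasterized segmentation is degenerate")
    # fixed rng: medial_axis breaks skeletonization ties randomly otherwise,
    # which would make mesh construction non-reproducible
    skel, dist = medial_axis(mask, return_distance=True, rng=0)
    clearance = dist[skel]
    keep = skel & (dist >= 0.8 * np.median(clearance))
    if keep.sum() < 4:
        keep = skel
    path_rc = _longest_skeleton_path(keep)
    # trim residual corner stubs: low-clearance pixels at the path ends
    path_clear = dist[path_rc[:, 0].astype(int), path_rc[:, 1].astype(int)]
    cutoff = 0.95 * np.median(path_clear)
    max_trim = max(1, len(path_rc) // 7)
    lo = 0
    while lo < max_trim and path_clear[lo] < cutoff:
        lo += 1
    hi = len(path_rc)
    while hi > len(path_rc) - max_trim and path_clear[hi - 1] < cutoff:
        hi -= 1
    path_rc = path_rc[lo:hi]
    path_xy = np.stack([path_rc[:, 1] + ox, path_rc[:, 0] + oy], axis=1)

    # --- smooth centerline, extend to the band ends, resample -------------
    step = max(1, len(path_xy) // 100)
    pts = path_xy[::step]
    if len(pts) < 4:
        pts = path_xy
    try:
        tck, _ = splprep([pts[:, 0], pts[:, 1]], s=2.0 * len(pts), k=min(3, len(pts) - 1))
    except Exception as exc:  # pragma: no cover - splprep failure is degenerate input
        raise SegmentationError(f"medial-axis spline fit failed: {exc}") from exc
    u = np.linspace(0.0, 1.0, 200)
    cx, cy = splev(u, tck)
    center = np.stack([cx, cy], axis=1)

    inner = poly.buffer(-0.3)
    if inner.is_empty:
        inner = poly

    def _extend(anchor: np.ndarray, direction: np.ndarray) -> np.ndarray:
        direction = direction / max(np.linalg.norm(direction), 1e-12)
        out = []
        p = anchor.copy()
        for _ in range(400):
            p = p + 0.5 * direction
            if not inner.contains(Point(p)):
                break
            out.append(p.copy())
        return np.asarray(out).reshape(-1, 2)

    head = _extend(center[0], center[0] - center[4])
    tail = _extend(center[-1], center[-1] - center[-5])
    center = np.concatenate([head[::-1], center, tail], axis=0)

    seglen = np.linalg.norm(np.diff(center, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    stations_s = np.linspace(0.0, s[-1], n_longitudinal)
    sx = np.interp(stations_s, s, center[:, 0])
    sy = np.interp(stations_s, s, center[:, 1])
    stations = np.stack([sx, sy], axis=1)
    tang = np.gradient(stations, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)

    # --- points across the thickness --------------------------------------
    reach = 3.0 * float(dist.max()) + 3.0
    grid = np.empty((n_radial, n_longitudinal, 2), dtype=float)
    for j in range(n_longitudinal):
        t_lo, t_hi = _cross_section(poly, stations[j], normal[j], reach)
        span = t_hi - t_lo
        inset = 0.04 * span + 0.3
        if t_hi - inset <= t_lo + inset:
            raise SegmentationError("segmentation too thin for the radial grid")
        offsets = np.linspace(t_lo + inset, t_hi - inset, n_radial)
        grid[:, j, :] = stations[j] + offsets[:, None] * normal[j]

    mesh = SeptalMesh.from_grid(grid, seg)
    flat = mesh.points.reshape(-1, 2)
    shell = poly.buffer(1e-6)
    if not all(shell.contains(Point(p)) for p in flat):
        raise SegmentationError("mesh construction placed points outside the polygon")
    return mesh
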