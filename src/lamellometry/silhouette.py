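"""Silhouette geometry engine.

A :class:`Silhouette` is the 2D outline of one primary olfactory lamella
together with its secondary folds, held both as a binary raster mask and as a
closed polygon in physical units (mm).  All downstream complexity indexes are
derived from four geometric primitives computed here: the boundary and area of
the silhouette and of its convex hull (:func:`measure_hull`), the medial-axis
skeleton and its branch count (:func:`skeletonize_silhouette`), and the
boundary corners classified into convex vertices and notches
(:func:`detect_corners`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon as ShapelyPolygon
from shapely.geometry.polygon import orient
from skimage import draw as skdraw
from skimage import measure as skmeasure
from skimage.morphology import skeletonize as _sk_skeletonize

__all__ = [
    "Silhouette",
    "HullSummary",
    "SkeletonGraph",
    "Corner",
    "CornerSet",
    "InvalidSilhouetteError",
    "load_silhouette",
    "measure_hull",
    "skeletonize_silhouette",
    "detect_corners",
]


class InvalidSilhouetteError(ValueError):
    """Raised when an input mask or polygon violates the silhouette contract."""


# ---------------------------------------------------------------------------
# Silhouette container
# ---------------------------------------------------------------------------


@dataclass
class Silhouette:
    """One lamella silhouette: raster mask and/or polygon, with physical scale.

    Parameters
    ----------
    polygon
        ``(n, 2)`` array of ``(x, y)`` vertices in mm, ordered counter-clockwise,
        implicitly closed (first vertex not repeated).
    scale
        Physical length of one pixel side, mm/px.  Only meaningful when the
        silhouette carries (or will be rasterized to) a mask.
    mask
        Optional binary raster, foreground = tissue.  ``None`` for pure polygon
        input; :meth:`to_mask` rasterizes on demand.
    id
        Specimen / lamella label.
    holes_filled
        True when interior background components were filled on ingestion.
    from_raster
        True when the polygon was traced from a raster boundary (such
        boundaries are smoothed before corner detection).
    """

    polygon: np.ndarray
    scale: float = 1.0
    mask: np.ndarray | None = None
    id: str | None = None
    holes_filled: bool = False
    from_raster: bool = False
    _shapely: ShapelyPolygon | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise InvalidSilhouetteError(f"scale must be > 0, got {self.scale}")
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise InvalidSilhouetteError("polygon must be an (n>=3, 2) array")
        sp = ShapelyPolygon(poly)
        if not sp.is_valid or not sp.is_simple:
            raise InvalidSilhouetteError("polygon is self-intersecting or degenerate")
        if sp.area == 0:
            raise InvalidSilhouetteError("polygon has zero area")
        sp = orient(sp, sign=1.0)  # CCW exterior
        self.polygon = np.asarray(sp.exterior.coords)[:-1]
        self._shapely = sp

    @property
    def shapely(self) -> ShapelyPolygon:
        """The silhouette as a CCW shapely polygon (mm coordinates)."""
        return self._shapely

    @property
    def area(self) -> float:
        """Polygon area, mm^2."""
        return self._shapely.area

    @property
    def perimeter(self) -> float:
        """Polygon boundary length, mm."""
        return self._shapely.length

    @classmethod
    def from_mask(
        cls,
        mask: np.ndarray,
        scale: float,
        id: str | None = None,
        simplify_px: float = 1.0,
    ) -> "Silhouette":
        """Build a silhouette from a binary raster.

        The foreground must be a single connected component; interior holes are
        filled with a warning.  The boundary is traced with marching squares at
        the 0.5 level and simplified with tolerance ``simplify_px`` pixels,
        which suppresses the pixel staircase that would otherwise inflate the
        perimeter (and with it the amplitude of vibration).
        """
        if scale <= 0:
            raise InvalidSilhouetteError(f"scale must be > 0, got {scale}")
        m = np.asarray(mask) > 0
        if not m.any():
            raise InvalidSilhouetteError("mask is empty")
        labelled, n_comp = ndimage.label(m)
        if n_comp != 1:
            raise InvalidSilhouetteError(
                f"mask has {n_comp} foreground components; expected exactly 1"
            )
        filled = ndimage.binary_fill_holes(m)
        holes_filled = bool((filled & ~m).any())
        if holes_filled:
            warnings.warn(
                "interior holes in mask were filled; the analysis concerns the "
                "outer epithelial boundary",
                stacklevel=2,
            )
        m = filled
        # pad so marching squares closes the contour at image borders
        padded = np.pad(m, 1)
        contours = skmeasure.find_contours(padded.astype(float), 0.5)
        contour = max(contours, key=len)
        contour = skmeasure.approximate_polygon(contour, tolerance=simplify_px)
        # (row, col) in padded frame -> (x, y) mm; x = col, y = row
        xy = np.column_stack([contour[:, 1] - 1.0, contour[:, 0] - 1.0]) * scale
        if np.allclose(xy[0], xy[-1]):
            xy = xy[:-1]
        return cls(
            polygon=xy,
            scale=scale,
            mask=m,
            id=id,
            holes_filled=holes_filled,
            from_raster=True,
        )

    def to_mask(self, scale: float | None = None) -> np.ndarray:
        """Rasterize the polygon to a binary mask at ``scale`` mm/px."""
        if scale is None or scale == self.scale:
            if self.mask is not None:
                return self.mask
            scale = self.scale
        poly = self.polygon / scale
        xmin, ymin = np.floor(poly.min(axis=0)).astype(int)
        shift = np.array([xmin, ymin]) - 1
        poly = poly - shift
        h = int(np.ceil(poly[:, 1].max())) + 2
        w = int(np.ceil(poly[:, 0].max())) + 2
        rr, cc = skdraw.polygon(poly[:, 1], poly[:, 0], shape=(h, w))
        m = np.zeros((h, w), dtype=bool)
        m[rr, cc] = True
        return m

    def scaled(self, k: float) -> "Silhouette":
        """Return a copy with all coordinates multiplied by ``k``."""
        return Silhouette(
            polygon=self.polygon * k,
            scale=self.scale * k,
            mask=self.mask,
            id=self.id,
            holes_filled=self.holes_filled,
            from_raster=self.from_raster,
        )


def load_silhouette(path: str | Path, scale: float = 1.0, id: str | None = None) -> Silhouette:
    """Load a silhouette from a raster image (PNG/TIFF) or a polygon CSV.

    Raster files must be single-channel with two grey levels (0 = background).
    Polygon CSVs have a ``x_mm,y_mm`` header and one vertex per row, closure
    implicit.  ``scale`` (mm/px) applies to rasters only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if id is None:
        id = path.stem
    if path.suffix.lower() == ".csv":
        import pandas as pd

        df = pd.read_csv(path)
        if df.shape[0] < 3:
            raise InvalidSilhouetteError("polygon CSV needs at least 3 vertices")
        cols = [c for c in df.columns if c.lower() in ("x_mm", "x")], [
            c for c in df.columns if c.lower() in ("y_mm", "y")
        ]
        if not cols[0] or not cols[1]:
            raise InvalidSilhouetteError("polygon CSV must have x_mm,y_mm columns")
        xy = df[[cols[0][0], cols[1][0]]].to_numpy(float)
        if np.allclose(xy[0], xy[-1]):
            xy = xy[:-1]
        return Silhouette(polygon=xy, scale=scale, id=id)
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    levels = np.unique(img)
    if len(levels) > 2:
        raise InvalidSilhouetteError(
            f"raster has {len(levels)} grey levels; expected a binary mask"
        )
    return Silhouette.from_mask(img > levels.min(), scale=scale, id=id)


# ---------------------------------------------------------------------------
# Convex hull summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HullSummary:
    """Boundary lengths and areas of a silhouette and its convex hull (mm, mm^2)."""

    boundary_silhouette: float  # P_s
    boundary_hull: float  # P_h
    area_silhouette: float  # A_s
    area_hull: float  # A_h

    def __post_init__(self) -> None:
        vals = (
            self.boundary_silhouette,
            self.boundary_hull,
            self.area_silhouette,
            self.area_hull,
        )
        if any(v <= 0 for v in vals):
            raise InvalidSilhouetteError("hull summary requires strictly positive measures")


def measure_hull(s: Silhouette) -> HullSummary:
    """Boundary and area of the silhouette and of its convex hull.

    Guarantees ``P_h <= P_s`` and ``A_s <= A_h`` (equality iff the silhouette
    is convex); the convex hull is the shortest closed curve enclosing the
    shape, so its perimeter cannot exceed the silhouette boundary.
    """
    sp = s.shapely
    if sp.area == 0:
        raise InvalidSilhouetteError("degenerate (zero-area) silhouette")
    hull = sp.convex_hull
    return HullSummary(
        boundary_silhouette=sp.length,
        boundary_hull=min(hull.length, sp.length),
        area_silhouette=sp.area,
        area_hull=max(hull.area, sp.area),
    )


# ---------------------------------------------------------------------------
# Skeleton graph
# ---------------------------------------------------------------------------

_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SkeletonGraph:
    """Topological summary of a one-pixel-wide 8-connected skeleton.

    ``nodes`` maps a node id to ``(kind, pixels)`` with kind ``"endpoint"``
    (one skeleton neighbour) or ``"junction"`` (>= 3 neighbours; 8-adjacent
    junction pixels are merged into a single node).  ``edges`` holds the pixel
    paths connecting nodes.  ``n_branches`` is the number of edges — the
    quantity the secondary-fold branching index normalizes.
    """

    nodes: dict[int, tuple[str, list[tuple[int, int]]]]
    edges: list[list[tuple[int, int]]]
    skeleton: np.ndarray

    @property
    def n_branches(self) -> int:
        return max(1, len(self.edges)) if self.skeleton.any() else 0

    @property
    def n_endpoints(self) -> int:
        return sum(1 for kind, _ in self.nodes.values() if kind == "endpoint")

    @property
    def n_junctions(self) -> int:
        return sum(1 for kind, _ in self.nodes.values() if kind == "junction")


def _neighbour_counts(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant")


def _build_graph(skel: np.ndarray) -> SkeletonGraph:
    counts = _neighbour_counts(skel)
    endpoint_px = skel & (counts == 1)
    junction_px = skel & (counts >= 3)
    node_px = endpoint_px | junction_px

    # merge 8-adjacent junction pixels into single nodes
    node_labels = np.zeros(skel.shape, dtype=int)
    lab_j, n_j = ndimage.label(junction_px, structure=np.ones((3, 3)))
    node_labels[junction_px] = lab_j[junction_px]
    nodes: dict[int, tuple[str, list[tuple[int, int]]]] = {}
    for j in range(1, n_j + 1):
        nodes[j] = ("junction", [tuple(p) for p in np.argwhere(lab_j == j)])
    next_id = n_j + 1
    for p in np.argwhere(endpoint_px):
        node_labels[tuple(p)] = next_id
        nodes[next_id] = ("endpoint", [tuple(p)])
        next_id += 1

    # isolated single pixel: one degenerate node
    if skel.sum() == 1:
        p = tuple(np.argwhere(skel)[0])
        return SkeletonGraph(
            nodes={1: ("endpoint", [p])}, edges=[[p]], skeleton=skel
        )

    visited = np.zeros(skel.shape, dtype=bool)
    edges: list[list[tuple[int, int]]] = []

    def neighbours(p):
        r, c = p
        for dr, dc in _NEIGH:
            rr, cc = r + dr, c + dc
            if 0 <= rr < skel.shape[0] and 0 <= cc < skel.shape[1] and skel[rr, cc]:
                yield (rr, cc)

    # trace paths starting from each node pixel
    for p in map(tuple, np.argwhere(node_px)):
        for q in neighbours(p):
            if node_labels[q]:
                # direct node-node contact between different nodes
                if node_labels[q] != node_labels[p] and node_labels[p] < node_labels[q]:
                    edges.append([p, q])
                continue
            if visited[q]:
                continue
            path = [p, q]
            visited[q] = True
            prev, cur = p, q
            while True:
                nxt = [
                    t
                    for t in neighbours(cur)
                    if t != prev and not (node_labels[t] and node_labels[t] == node_labels[prev])
                ]
                # prefer unvisited non-node continuation
                cont = [t for t in nxt if not node_labels[t] and not visited[t]]
                node_hit = [t for t in nxt if node_labels[t]]
                if node_hit:
                    path.append(node_hit[0])
                    break
                if not cont:
                    break  # dead end (shouldn't happen on clean skeletons)
                prev, cur = cur, cont[0]
                path.append(cur)
                visited[cur] = True
            edges.append(path)

    # dedupe edges traced from both ends
    seen = set()
    unique_edges = []
    for path in edges:
        key = (path[0], path[-1], len(path))
        rkey = (path[-1], path[0], len(path))
        if key in seen or rkey in seen:
            continue
        seen.add(key)
        unique_edges.append(path)

    # pure cycles (no nodes at all) count as one branch each
    if not nodes and skel.any():
        lab_c, n_c = ndimage.label(skel, structure=np.ones((3, 3)))
        for j in range(1, n_c + 1):
            unique_edges.append([tuple(p) for p in np.argwhere(lab_c == j)])

    return SkeletonGraph(nodes=nodes, edges=unique_edges, skeleton=skel)


def skeletonize_silhouette(
    s: Silhouette, prune_px: int = 3, scale: float | None = None
) -> SkeletonGraph:
    """Skeletonize the silhouette mask and build its branch graph.

    Topology-preserving thinning (8-connectivity) followed by graph
    construction with endpoints and junctions as nodes.  Spur branches shorter
    than ``prune_px`` pixels are removed before the final graph is built:
    unpruned spurs double-count rasterization noise as secondary-fold
    branches.
    """
    mask = s.to_mask(scale)
    if not mask.any():
        raise InvalidSilhouetteError("empty mask")
    skel = _sk_skeletonize(mask)
    graph = _build_graph(skel)
    if prune_px > 0:
        changed = True
        while changed:
            changed = False
            for path in graph.edges:
                if len(path) - 1 >= prune_px:
                    continue
                kinds = []
                for end in (path[0], path[-1]):
                    kind = None
                    for _, (k, pixels) in graph.nodes.items():
                        if end in pixels:
                            kind = k
                            break
                    kinds.append(kind)
                # prune only endpoint->junction spurs
                if "endpoint" in kinds and "junction" in kinds:
                    ep_idx = 0 if kinds[0] == "endpoint" else -1
                    drop = path[:-1] if ep_idx == 0 else path[1:]
                    for p in drop:
                        skel[p] = False
                    changed = True
            if changed:
                graph = _build_graph(skel)
    return graph


# ---------------------------------------------------------------------------
# Corner detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Corner:
    point: tuple[float, float]
    interior_angle: float  # degrees
    kind: str  # "vertex_convex" | "notch"


@dataclass(frozen=True)
class CornerSet:
    """Boundary corners classified as convex vertices or notches.

    ``n_vertices`` counts every detected corner (notches included, as in the
    polygonal model where notches are a subset of the vertices);
    ``n_notches`` counts reflex corners (interior angle > 180 deg).
    ``too_few`` flags corner sets with fewer than 4 corners, for which the
    frequency of vibration is undefined.
    """

    corners: tuple[Corner, ...]

    @property
    def n_vertices(self) -> int:
        return len(self.corners)

    @property
    def n_notches(self) -> int:
        return sum(1 for c in self.corners if c.kind == "notch")

    @property
    def too_few(self) -> bool:
        return self.n_vertices < 4


def _smooth_closed(poly: np.ndarray, sigma: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter1d

    return np.column_stack(
        [gaussian_filter1d(poly[:, j], sigma=sigma, mode="wrap") for j in (0, 1)]
    )


def detect_corners(
    s: Silhouette,
    angle_threshold: float = 30.0,
    smooth_sigma: float = 2.0,
) -> CornerSet:
    """Detect boundary corners by the turning-angle criterion.

    A vertex of the (simplified) polygon is a corner when the boundary
    direction changes by more than ``angle_threshold`` degrees there.  Corners
    are classified by interior angle: > 180 deg is a notch (reflex corner),
    otherwise a convex vertex.  For raster-traced boundaries the vertex chain
    is first Gaussian-smoothed (sigma in pixels) to control sensitivity; exact
    polygon inputs are used as-is.
    """
    if not (0 < angle_threshold < 90):
        raise ValueError("angle_threshold must be in (0, 90) degrees")
    poly = s.polygon
    if s.from_raster and smooth_sigma > 0:
        # smoothing is meant for dense per-pixel traces; a simplified polygon
        # already has one vertex per real corner and must not be rounded off
        seg = np.linalg.norm(np.diff(poly, axis=0, append=poly[:1]), axis=1)
        if seg.mean() < 1.5 * s.scale:
            poly = _smooth_closed(poly, smooth_sigma)
    n = len(poly)
    prev = np.roll(poly, 1, axis=0)
    nxt = np.roll(poly, -1, axis=0)
    v_in = poly - prev
    v_out = nxt - poly
    cross = v_in[:, 0] * v_out[:, 1] - v_in[:, 1] * v_out[:, 0]
    dot = (v_in * v_out).sum(axis=1)
    turn = np.degrees(np.arctan2(cross, dot))  # signed; + = left turn (CCW convex)
    corners = []
    for i in range(n):
        if abs(turn[i]) > angle_threshold:
            interior = 180.0 - turn[i]  # CCW polygon: left turn -> interior < 180
            kind = "notch" if interior > 180.0 else "vertex_convex"
            corners.append(
                Corner(point=(poly[i, 0], poly[i, 1]), interior_angle=interior, kind=kind)
            )
    cs = CornerSet(corners=tuple(corners))
    if cs.too_few:
        warnings.warn(
            f"only {cs.n_vertices} corners detected; frequency of vibration undefined",
            stacklevel=2,
        )
    return cs
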