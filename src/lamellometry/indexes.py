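"""Dimensionless 2D shape-complexity indexes for lamella silhouettes.

The composite complexity score used here treats the silhouette boundary as a
"vibrating" polygon: the *frequency* of vibration is driven by the ratio of
notches (reflex corners) to vertices, the *amplitude* by the excess of the
boundary over the convex-hull perimeter, and the *deviation* by the area
missing relative to the convex hull.  The composite index is

    B = 0.8 * amplitude * frequency + 0.2 * deviation

which is 0 for convex shapes and approaches (but never reaches) 1 for highly
convoluted ones.  Independently, the secondary-fold branching index divides
the skeleton branch count by the number of secondary folds: values near 2
indicate unbranched folds, near 3-4 folds with a few branches, and near 7
highly branched folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .silhouette import (
    CornerSet,
    HullSummary,
    Silhouette,
    detect_corners,
    measure_hull,
    skeletonize_silhouette,
)

__all__ = [
    "ShapeIndexes",
    "frequency_of_vibration",
    "amplitude_of_vibration",
    "deviation_from_convex_hull",
    "brinkhoff_index",
    "branching_index",
    "classify_branching",
    "compute_shape_indexes",
    "BRANCHING_CLASS_CUTS",
]


def frequency_of_vibration(n_vertices: int, n_notches: int) -> float:
    """Frequency of vibration from vertex and notch counts.

    With the normalized notch count ``nu = n_notches / (n_vertices - 3)`` the
    frequency is the quartic ``16*(nu - 0.5)**4 - 8*(nu - 0.5)**2 + 1``, which
    is 0 at nu in {0, 1}, 1 at nu = 0.5 and symmetric about 0.5.  Undefined
    for polygons with fewer than 4 vertices.
    """
    if n_vertices < 4:
        raise ValueError(
            f"frequency of vibration undefined for n_vertices={n_vertices} < 4"
        )
    if n_notches < 0:
        raise ValueError("n_notches must be >= 0")
    nu = n_notches / (n_vertices - 3)
    if nu > 1:
        warnings.warn(
            f"normalized notch count nu={nu:.3f} > 1 is outside the formula's "
            "intended range; value computed anyway",
            stacklevel=2,
        )
    x = nu - 0.5
    return 16.0 * x**4 - 8.0 * x**2 + 1.0


def amplitude_of_vibration(h: HullSummary) -> float:
    """(P_s - P_h) / P_s: relative boundary excess over the convex hull."""
    if h.boundary_hull > h.boundary_silhouette:
        raise ValueError(
            "inconsistent geometry: hull perimeter exceeds silhouette perimeter"
        )
    return (h.boundary_silhouette - h.boundary_hull) / h.boundary_silhouette


def deviation_from_convex_hull(h: HullSummary) -> float:
    """(A_h - A_s) / A_h: relative area missing from the convex hull."""
    if h.area_silhouette > h.area_hull:
        raise ValueError("inconsistent geometry: silhouette area exceeds hull area")
    return (h.area_hull - h.area_silhouette) / h.area_hull


def brinkhoff_index(frequency: float, amplitude: float, deviation: float) -> float:
    """Composite complexity: 0.8 * amplitude * frequency + 0.2 * deviation."""
    for name, v in (
        ("frequency", frequency),
        ("amplitude", amplitude),
        ("deviation", deviation),
    ):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    return 0.8 * amplitude * frequency + 0.2 * deviation


def branching_index(n_branches: int, n_secondary_folds: int) -> float:
    """Skeleton branch count normalized by the number of secondary folds."""
    if n_secondary_folds < 1:
        raise ValueError("branching index needs at least one secondary fold")
    return n_branches / n_secondary_folds


#: cut points between the verbal cluster centres 2, 3-4 and 7
BRANCHING_CLASS_CUTS = (2.75, 5.5)


def classify_branching(i_br: float) -> str:
    """Assign a branching index to the nearest of the three fold morphologies.

    ``unbranched`` (index near 2), ``few_branches`` (near 3-4) or
    ``highly_branched`` (near 7), with cut points at 2.75 and 5.5 — the
    midpoints between the cluster centres.
    """
    if i_br <= 0:
        raise ValueError("branching index must be positive")
    lo, hi = BRANCHING_CLASS_CUTS
    if i_br < lo:
        return "unbranched"
    if i_br < hi:
        return "few_branches"
    return "highly_branched"


@dataclass(frozen=True)
class ShapeIndexes:
    """Per-silhouette record of the complexity indexes and their raw counts."""

    frequency: float
    amplitude: float
    deviation: float
    brinkhoff: float
    n_vertices: int
    n_notches: int
    n_branches: int
    n_secondary_folds: int | None = None

    @property
    def branching(self) -> float | None:
        if self.n_secondary_folds is None:
            return None
        return branching_index(self.n_branches, self.n_secondary_folds)

    @property
    def branching_class(self) -> str | None:
        b = self.branching
        return None if b is None else classify_branching(b)


def count_folds_from_skeleton(graph) -> int:
    """Heuristic fold count: endpoint branches hanging off the skeleton.

    This estimator (branches incident on the central axis) is an extension
    beyond the annotated/ground-truth fold counts and is intentionally rough;
    prefer an explicit ``n_secondary_folds`` whenever one is available.
    """
    return max(1, graph.n_endpoints - 2)


def compute_shape_indexes(
    s: Silhouette,
    n_secondary_folds: int | None = None,
    angle_threshold: float = 30.0,
    smooth_sigma: float = 2.0,
    prune_px: int = 3,
    raster_scale: float | None = None,
) -> ShapeIndexes:
    """Run the full 2D pipeline on one silhouette.

    Computes hull measures, corners, skeleton branches and the derived
    indexes.  ``n_secondary_folds`` normally comes from annotation or the
    synthetic generator's ground truth; when omitted it is estimated from the
    skeleton endpoints (a labelled extension, see
    :func:`count_folds_from_skeleton`).
    """
    hull = measure_hull(s)
    corners: CornerSet = detect_corners(
        s, angle_threshold=angle_threshold, smooth_sigma=smooth_sigma
    )
    graph = skeletonize_silhouette(s, prune_px=prune_px, scale=raster_scale)
    amplitude = amplitude_of_vibration(hull)
    deviation = deviation_from_convex_hull(hull)
    if corners.too_few:
        # frequency undefined (flagged by detect_corners); such shapes are in
        # practice convex or near-convex, so the vibration term contributes 0
        frequency = float("nan")
        f_term = 0.0
    else:
        frequency = frequency_of_vibration(corners.n_vertices, corners.n_notches)
        f_term = min(frequency, 1.0)
    n_sf = n_secondary_folds
    if n_sf is None:
        n_sf = count_folds_from_skeleton(graph)
    return ShapeIndexes(
        frequency=frequency,
        amplitude=amplitude,
        deviation=deviation,
        brinkhoff=brinkhoff_index(f_term, amplitude, deviation),
        n_vertices=corners.n_vertices,
        n_notches=corners.n_notches,
        n_branches=graph.n_branches,
        n_secondary_folds=n_sf,
    )
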