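"""Trajectory shape metrics: minimum-bounding-box aspect ratio and explored area.

Both metrics are invariant under rigid motions of the track.  The aspect
ratio uses the minimum-area *rotated* rectangle (rotating calipers over the
convex hull), not the axis-aligned box, so an elongated track scores the
same whatever its orientation.  The explored area is the convex-hull area
divided by the number of time points — a per-frame measure of territory
covered that rewards spread-out (free) tracks over compact (trapped) ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint

from .tracks import Trajectory

#: Width floor (um) used to report an aspect ratio for collinear tracks.
DEGENERATE_WIDTH_FLOOR = 1e-6


@dataclass(frozen=True)
class GeometryMetrics:
    aspect_ratio: float
    explored_area: float
    degenerate: bool


def min_bounding_box_sides(points: np.ndarray) -> tuple[float, float]:
    """Side lengths (long, short) of the minimum-area rotated rectangle."""
    mp = MultiPoint(points)
    rect = mp.minimum_rotated_rectangle
    if rect.geom_type != "Polygon":  # collinear or single point
        length = rect.length if rect.geom_type == "LineString" else 0.0
        return float(length), 0.0
    cx, cy = rect.exterior.coords.xy
    corners = np.column_stack([cx, cy])[:4]
    s1 = float(np.hypot(*(corners[1] - corners[0])))
    s2 = float(np.hypot(*(corners[2] - corners[1])))
    return max(s1, s2), min(s1, s2)


def aspect_ratio(traj: Trajectory) -> GeometryMetrics:
    """Length/width of the minimum-area bounding rectangle (>= 1).

    Collinear point sets are flagged degenerate and the ratio is reported
    against a 1e-6 um width floor; fully coincident points give NaN.
    """
    pts = traj.xy
    if len(pts) < 3:
        raise ValueError("aspect_ratio needs at least 3 points")
    long_side, short_side = min_bounding_box_sides(pts)
    if long_side == 0.0:
        return GeometryMetrics(np.nan, 0.0, True)
    if short_side <= DEGENERATE_WIDTH_FLOOR:
        return GeometryMetrics(long_side / DEGENERATE_WIDTH_FLOOR,
                               _hull_area(pts) / len(pts), True)
    return GeometryMetrics(long_side / short_side,
                           _hull_area(pts) / len(pts), False)


def _hull_area(pts: np.ndarray) -> float:
    hull = MultiPoint(pts).convex_hull
    return float(getattr(hull, "area", 0.0))


def explored_area(traj: Trajectory) -> float:
    """Convex-hull area (um^2) divided by the number of time points."""
    pts = traj.xy
    if len(pts) < 3:
        raise ValueError("explored_area needs at least 3 points")
    area = _hull_area(pts)
    if area == 0.0:
        warnings.warn(f"track {traj.track_id}: collinear points, hull area 0",
                      stacklevel=2)
    return area / len(pts)


def geometry_metrics(traj: Trajectory) -> GeometryMetrics:
    """Aspect ratio and explored area in one pass."""
    return aspect_ratio(traj)
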