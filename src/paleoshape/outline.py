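"""Crown-outline pseudolandmarks.

A tooth crown outline is a closed planar polygon extracted at the
cervical plane, oriented so that +y points buccally and the lingual
side is parallel to the x axis.  Shape is captured by 24 equiangularly
spaced radial pseudolandmarks: rays from the area centroid, the first
directed buccally along +y, successive rays advancing clockwise (when
the occlusal view of a left tooth is considered).  Pseudolandmark
configurations are centred and scaled to unit centroid size — no
rotation step, since orientation is standardized by the axis
convention — giving Procrustes shape coordinates suitable for PCA.

Right teeth are mirrored to the left-side convention before sampling.
For non-star-shaped outlines a ray can cross the boundary more than
once; the intersection farthest from the centroid is used (molar
crowns are near-convex, so this rarely triggers, but the rule is fixed
and deterministic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "OutlinePolygon",
    "area_centroid",
    "radial_pseudolandmarks",
    "normalize_outline",
    "mirror_right_to_left",
]

DEFAULT_N_PSEUDOLANDMARKS = 24


@dataclass
class OutlinePolygon:
    """Closed planar crown outline (cervical-plane projection).

    Vertices are ordered; closure is implicit (the last vertex connects
    to the first).  ``side`` is "left" or "right"; the sampling
    convention assumes left-side orientation with +y buccal.
    """

    specimen_id: str
    vertices: np.ndarray
    side: str = "left"
    group_label: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be (n, 2)")
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if not self.polygon.is_valid:
            raise ValueError("polygon is self-intersecting")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


def area_centroid(poly: OutlinePolygon | np.ndarray) -> np.ndarray:
    """Area-based centroid of the crown outline (first moment / area)."""
    p = poly.polygon if isinstance(poly, OutlinePolygon) else Polygon(
        np.asarray(poly, float))
    if p.area == 0:
        raise ValueError("degenerate outline: zero area")
    c = p.centroid
    return np.array([c.x, c.y])


def radial_pseudolandmarks(poly: OutlinePolygon,
                           n: int = DEFAULT_N_PSEUDOLANDMARKS) -> np.ndarray:
    """Sample n equiangular radial pseudolandmarks from the area centroid.

    Ray k points at angle 90° − k·(360/n)° (standard math convention):
    the first ray is buccal (+y) and successive rays advance clockwise.
    Each pseudolandmark is the boundary intersection of its ray; if a
    ray crosses the boundary several times, the crossing farthest from
    the centroid is taken.
    """
    shp = poly.polygon
    c = area_centroid(poly)
    if not shp.contains(Point(c)):
        raise ValueError("area centroid lies outside the outline; radial "
                         "sampling is undefined")
    # ray length safely beyond the outline
    vmax = np.max(np.linalg.norm(poly.vertices - c, axis=1))
    reach = 2.0 * vmax
    boundary = LineString(np.vstack([poly.vertices, poly.vertices[:1]]))
    out = np.empty((n, 2))
    for k in range(n):
        theta = np.deg2rad(90.0 - k * 360.0 / n)
        direction = np.array([np.cos(theta), np.sin(theta)])
        ray = LineString([c, c + reach * direction])
        hit = ray.intersection(boundary)
        if hit.is_empty:
            raise ValueError("ray missed the boundary (invalid polygon)")
        pts = []
        for geom in getattr(hit, "geoms", [hit]):
            if geom.geom_type == "Point":
                pts.append([geom.x, geom.y])
            else:  # ray grazing along an edge: take its endpoints
                pts.extend(np.asarray(geom.coords))
        pts = np.asarray(pts)
        far = np.argmax(np.linalg.norm(pts - c, axis=1))
        out[k] = pts[far]
    return out


def normalize_outline(points: np.ndarray) -> np.ndarray:
    """Centre pseudolandmarks and scale to unit centroid size.

    No rotation is applied: orientation is already standardized by the
    buccal/+y digitization convention, so centring + unit scaling alone
    yields Procrustes shape coordinates.  Idempotent.
    """
    points = np.asarray(points, float)
    c = points.mean(axis=0)
    centred = points - c
    size = np.sqrt((centred ** 2).sum())
    if size == 0:
        raise ValueError("degenerate point set: zero centroid size")
    return centred / size


def mirror_right_to_left(poly: OutlinePolygon) -> OutlinePolygon:
    """Mirror a right-side outline into the left-side convention.

    Reflects x ↦ −x and reverses the vertex order so the traversal
    handedness matches the original; the side flag is flipped.  Applied
    to a left outline it is a no-op (with a warning).
    """
    if poly.side == "left":
        warnings.warn("outline is already left-sided; mirroring skipped",
                      stacklevel=2)
        return OutlinePolygon(poly.specimen_id, poly.vertices.copy(),
                              side="left", group_label=poly.group_label)
    v = poly.vertices.copy()
    v[:, 0] = -v[:, 0]
    v = v[::-1]
    return OutlinePolygon(poly.specimen_id, v, side="left",
                          group_label=poly.group_label)
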