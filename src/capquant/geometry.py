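"""Closed-contour primitives for segmented vessel cross-sections.

Every contour is a simple closed polygon in the imaging plane, coordinates in
millimetres.  A cross-section (:class:`SliceContours`) carries a lumen contour,
an outer-wall contour, zero or more lipid-core contours and the in-plane
direction from the lumen centroid toward the myocardium.  Slices are analysed
independently; there is no z coordinate.

Geometric predicates (simplicity, containment, intersection) delegate to
shapely; arc-length resampling and the shoelace centroid are implemented here
because downstream code needs exact control over start points and tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Optional, Sequence

import numpy as np
from shapely.geometry import LinearRing, LineString, Point, Polygon

#: Absolute tolerance for geometric predicates, in mm.
GEOM_TOL = 1e-9


class ContourError(ValueError):
    """Base class for invalid contour geometry."""


class SelfIntersectionError(ContourError):
    """A contour polygon crosses itself."""


class LumenOutsideWallError(ContourError):
    """The lumen contour is not contained in the wall contour."""


class LipidOutsideWallError(ContourError):
    """A lipid contour is not contained in the wall contour."""


class LipidOverlapsLumenError(ContourError):
    """A lipid contour overlaps the lumen interior."""


class DegenerateContourError(ContourError):
    """A contour with (numerically) zero perimeter or area."""


@dataclass(frozen=True)
class ClosedContour:
    """An implicitly closed polygon: the last point connects back to the first.

    Parameters
    ----------
    points
        ``(n, 2)`` array of vertices in mm, ``n >= 4`` after dropping an
        explicit closing point if one is present.  Consecutive duplicate
        vertices are rejected.
    role
        One of ``"lumen"``, ``"wall"``, ``"lipid"`` (informational).
    """

    points: np.ndarray
    role: str = "lumen"

    def __post_init__(self) -> None:
        pts = np.array(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ContourError("contour points must form an (n, 2) array")
        if not np.all(np.isfinite(pts)):
            raise ContourError("contour coordinates must be finite")
        if len(pts) > 1 and float(np.hypot(*(pts[0] - pts[-1]))) <= GEOM_TOL:
            pts = pts[:-1]  # closure is implicit
        if len(pts) < 4:
            raise ContourError("a closed contour needs at least 4 distinct points")
        gaps = np.hypot(*np.diff(np.vstack([pts, pts[:1]]), axis=0).T)
        if np.any(gaps <= GEOM_TOL):
            raise ContourError("consecutive duplicate points are forbidden")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def closed_points(self) -> np.ndarray:
        """Vertices with the first point appended, for polyline traversal."""
        return np.vstack([self.points, self.points[:1]])

    @property
    def perimeter(self) -> float:
        d = np.diff(self.closed_points, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    @property
    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def centroid(self) -> np.ndarray:
        """Area centroid (shoelace formula); vertex mean for degenerate areas."""
        x, y = self.points[:, 0], self.points[:, 1]
        cross = x * np.roll(y, -1) - np.roll(x, -1) * y
        area = cross.sum() / 2.0
        if abs(area) <= GEOM_TOL:
            return self.points.mean(axis=0)
        cx = float(np.sum((x + np.roll(x, -1)) * cross) / (6.0 * area))
        cy = float(np.sum((y + np.roll(y, -1)) * cross) / (6.0 * area))
        return np.array([cx, cy])

    @property
    def ring(self) -> LinearRing:
        return LinearRing(self.points)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.points)

    def is_simple(self) -> bool:
        return bool(self.polygon.is_valid)

    def oriented_ccw(self) -> "ClosedContour":
        """Return a copy with positive (counterclockwise) signed area."""
        if self.signed_area > 0:
            return self
        return ClosedContour(self.points[::-1].copy(), self.role)

    def canonical(self) -> "ClosedContour":
        """Counterclockwise orientation, starting at the max-x vertex.

        The start anchor makes stored point order reproducible across
        reads/writes; it is a storage convention, not a measurement anchor.
        """
        ccw = self.oriented_ccw()
        start = int(np.argmax(ccw.points[:, 0]))
        return ClosedContour(np.roll(ccw.points, -start, axis=0), ccw.role)


@dataclass(frozen=True)
class SliceContours:
    """One segmented cross-section of a vessel in one imaging modality."""

    slice_id: str
    modality: str
    lumen: ClosedContour
    wall: ClosedContour
    lipids: Sequence[ClosedContour] = ()
    myocardium_angle: float = 0.0  # radians, from lumen centroid toward myocardium

    def __post_init__(self) -> None:
        object.__setattr__(self, "lipids", tuple(self.lipids))
        if not np.isfinite(self.myocardium_angle):
            raise ContourError("myocardium angle must be finite")


def validate_slice(slc: SliceContours) -> SliceContours:
    """Check slice invariants and return a canonically oriented copy.

    Each contour must be a simple polygon of nonzero area; the lumen must lie
    inside the wall; every lipid must lie inside the wall without overlapping
    the lumen interior (boundary contact is allowed).  Contours in the returned
    slice are counterclockwise and start at their max-x vertex.
    """
    named = [(slc.lumen, "lumen"), (slc.wall, "wall")]
    named += [(lip, f"lipid[{i}]") for i, lip in enumerate(slc.lipids)]
    for contour, name in named:
        # simplicity first: a bow-tie has zero shoelace area but is a
        # self-intersection problem, not a degeneracy
        if not contour.is_simple():
            raise SelfIntersectionError(f"{name} contour is self-intersecting")
        if abs(contour.signed_area) <= GEOM_TOL:
            raise DegenerateContourError(f"{name} contour has zero area")

    wall_poly = slc.wall.polygon
    lumen_poly = slc.lumen.polygon
    if not wall_poly.contains(lumen_poly):
        raise LumenOutsideWallError(
            f"slice {slc.slice_id!r}: lumen is not inside the wall contour"
        )
    for i, lip in enumerate(slc.lipids):
        lip_poly = lip.polygon
        if not wall_poly.contains(lip_poly):
            raise LipidOutsideWallError(
                f"slice {slc.slice_id!r}: lipid[{i}] is not inside the wall contour"
            )
        if lip_poly.intersection(lumen_poly).area > GEOM_TOL:
            raise LipidOverlapsLumenError(
                f"slice {slc.slice_id!r}: lipid[{i}] overlaps the lumen interior"
            )

    return replace(
        slc,
        lumen=slc.lumen.canonical(),
        wall=slc.wall.canonical(),
        lipids=tuple(lip.canonical() for lip in slc.lipids),
    )


def _resample_at(contour: ClosedContour, n: int, s0: float) -> np.ndarray:
    """``n`` points at equal arc-length spacing, starting at arc position ``s0``."""
    closed = contour.closed_points
    seg = np.diff(closed, axis=0)
    cum = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    perim = float(cum[-1])
    if perim <= GEOM_TOL:
        raise DegenerateContourError("cannot resample a zero-perimeter contour")
    s = (s0 + perim * np.arange(n) / n) % perim
    return np.column_stack(
        [np.interp(s, cum, closed[:, 0]), np.interp(s, cum, closed[:, 1])]
    )


def resample_closed(contour: ClosedContour, n: int) -> ClosedContour:
    """Resample a contour to exactly ``n`` points at equal arc-length spacing.

    Output points lie on the original polyline; the first output point is the
    contour's stored start point.
    """
    if n < 4:
        raise ValueError("resampling needs n >= 4")
    return ClosedContour(_resample_at(contour, n, 0.0), contour.role)


def _iter_atomic(geom) -> Iterator:
    if hasattr(geom, "geoms"):
        for sub in geom.geoms:
            yield from _iter_atomic(sub)
    else:
        yield geom


def first_intersection(
    segment: tuple, contour: ClosedContour
) -> Optional[tuple[np.ndarray, float]]:
    """Nearest intersection of a segment with a contour boundary.

    Returns ``(point, distance)`` where ``distance`` is measured from the
    segment's first endpoint, or ``None`` when the segment misses the boundary.
    When the segment overlaps an edge, the nearest endpoint of the overlap is
    reported.
    """
    p0 = np.asarray(segment[0], dtype=float)
    p1 = np.asarray(segment[1], dtype=float)
    if float(np.hypot(*(p1 - p0))) <= GEOM_TOL:
        raise ValueError("segment endpoints must be distinct")
    inter = contour.ring.intersection(LineString([p0, p1]))
    if inter.is_empty:
        return None
    best: Optional[np.ndarray] = None
    best_d = np.inf
    for geom in _iter_atomic(inter):
        for coord in np.asarray(geom.coords)[:, :2]:
            d = float(np.hypot(coord[0] - p0[0], coord[1] - p0[1]))
            if d < best_d:
                best, best_d = np.asarray(coord, dtype=float), d
    assert best is not None
    return best, best_d
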