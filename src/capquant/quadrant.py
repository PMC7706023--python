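"""The four-quarter even-spacing method for wall and cap thickness.

The lumen contour is divided into 100 points at equal arc-length spacing and
split into four 25-point quarters, with quarter 1 (Q1) centred on the side
facing the myocardium.  The four wall dividing points are the points on the
wall polyline at shortest distance from the lumen dividing points; each wall
quarter is then subdivided into 25 equal-arc-length parts so every lumen point
has an index-matched wall point.  Wall thickness at a point is the Euclidean
distance between a lumen point and its matched wall point.  Cap thickness is
the portion of that connecting segment between the lumen and the nearest lipid
boundary; points whose connector crosses a lipid core are "cap points".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LinearRing, Point

from .geometry import (
    GEOM_TOL,
    ClosedContour,
    SliceContours,
    _resample_at,
    first_intersection,
    validate_slice,
)

#: Number of lumen sample points per slice.
N_POINTS = 100
#: Points per quarter.
PER_QUARTER = N_POINTS // 4


class QuadrantError(ValueError):
    """Base class for four-quarter method failures."""


class WrongPointCountError(QuadrantError):
    """Point count is not divisible into four equal quarters."""


class DegenerateWallError(QuadrantError):
    """Wall dividing points collapse onto one location."""


@dataclass
class RadialProfile:
    """Index-matched lumen/wall sampling of one slice with thickness fields.

    ``cap_thickness[i]`` is NaN wherever ``is_cap_point[i]`` is False; where
    present it never exceeds ``wall_thickness[i]`` (the lipid edge lies on the
    lumen-to-wall connector).
    """

    slice_id: str
    modality: str
    lumen_pts: np.ndarray       # (N_POINTS, 2) mm
    wall_pts: np.ndarray        # (N_POINTS, 2) mm
    quarter: np.ndarray         # (N_POINTS,) int in {1,2,3,4}
    wall_thickness: np.ndarray  # (N_POINTS,) mm
    cap_thickness: np.ndarray   # (N_POINTS,) mm, NaN off cap points
    is_cap_point: np.ndarray    # (N_POINTS,) bool
    dividing_indices: tuple[int, int, int, int] = (0, 25, 50, 75)

    def __post_init__(self) -> None:
        n = len(self.lumen_pts)
        for name in ("wall_pts", "quarter", "wall_thickness", "cap_thickness", "is_cap_point"):
            if len(getattr(self, name)) != n:
                raise QuadrantError(f"profile field {name!r} length mismatch")
        if not np.array_equal(np.isfinite(self.cap_thickness), self.is_cap_point):
            raise QuadrantError("cap_thickness must be finite exactly at cap points")

    @property
    def n_points(self) -> int:
        return len(self.lumen_pts)

    @property
    def n_cap_points(self) -> int:
        return int(self.is_cap_point.sum())

    @property
    def cap_values(self) -> np.ndarray:
        """Cap thickness at the slice's cap points (mm)."""
        return self.cap_thickness[self.is_cap_point]

    def min_cap(self) -> Optional[float]:
        vals = self.cap_values
        return float(vals.min()) if vals.size else None

    def mean_cap(self) -> Optional[float]:
        vals = self.cap_values
        return float(vals.mean()) if vals.size else None

    def to_frame(self) -> pd.DataFrame:
        """Per-point measurement table (one row per lumen point)."""
        return pd.DataFrame(
            {
                "slice_id": self.slice_id,
                "modality": self.modality,
                "pt_idx": np.arange(self.n_points),
                "quarter": [f"Q{q}" for q in self.quarter],
                "wall_thickness_mm": self.wall_thickness,
                "is_cap_point": self.is_cap_point,
                "cap_thickness_mm": self.cap_thickness,
            }
        )


def assign_quarters(
    lumen_pts: np.ndarray,
    myocardium_angle: float,
    centroid: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Label evenly spaced lumen points with quarters Q1..Q4.

    Q1 is the 25-point arc centred on the point whose direction from the lumen
    centroid is angularly closest to ``myocardium_angle``; Q2..Q4 follow in the
    contour's (counterclockwise) point order.  Returns the labels (ints 1..4)
    and the four dividing indices (first index of each quarter).
    """
    pts = np.asarray(lumen_pts, dtype=float)
    n = len(pts)
    if n < 8 or n % 4 != 0:
        raise WrongPointCountError(f"need a point count divisible by 4, got {n}")
    per = n // 4
    if centroid is None:
        centroid = ClosedContour(pts).centroid
    ang = np.arctan2(pts[:, 1] - centroid[1], pts[:, 0] - centroid[0])
    delta = np.abs(np.angle(np.exp(1j * (ang - myocardium_angle))))
    center = int(np.argmin(delta))
    start = (center - per // 2) % n
    labels = (((np.arange(n) - start) % n) // per + 1).astype(np.int8)
    dividing = tuple(int((start + per * k) % n) for k in range(4))
    return labels, dividing  # type: ignore[return-value]


def match_wall(
    lumen_pts: np.ndarray,
    dividing_indices: Sequence[int],
    wall: ClosedContour,
) -> tuple[np.ndarray, np.ndarray]:
    """Index-matched wall points via shortest-distance dividing points.

    Each wall dividing point is the foot of minimum distance from its lumen
    dividing point to the wall polyline (ties resolved to the lowest arc-length
    position, shapely's projection rule).  Wall quarters are traversed in the
    lumen's rotational sense and subdivided into ``n/4`` equal-arc-length
    parts.  Returns ``(wall_pts, wall_dividing_pts)``.
    """
    lumen_pts = np.asarray(lumen_pts, dtype=float)
    n = len(lumen_pts)
    per = n // 4
    ring = LinearRing(wall.oriented_ccw().points)
    perim = float(ring.length)

    s_div = np.array(
        [float(ring.project(Point(lumen_pts[k]))) for k in dividing_indices]
    )
    wall_div = shapely.get_coordinates(shapely.line_interpolate_point(ring, s_div))
    for a in range(4):
        for b in range(a + 1, 4):
            if float(np.hypot(*(wall_div[a] - wall_div[b]))) <= GEOM_TOL:
                raise DegenerateWallError(
                    "wall dividing points collapse onto the same location"
                )
    spans = np.array([(s_div[(k + 1) % 4] - s_div[k]) % perim for k in range(4)])
    if np.any(spans <= GEOM_TOL):
        raise DegenerateWallError("a wall quarter has zero arc length")

    offset = (np.arange(n) - dividing_indices[0]) % n
    q_idx = offset // per
    local = offset % per
    s_all = (s_div[q_idx] + spans[q_idx] * local / per) % perim
    wall_pts = shapely.get_coordinates(shapely.line_interpolate_point(ring, s_all))
    return wall_pts, wall_div


def measure_wall_thickness(lumen_pts: np.ndarray, wall_pts: np.ndarray) -> np.ndarray:
    """Elementwise Euclidean distance between matched lumen and wall points."""
    d = np.asarray(wall_pts, dtype=float) - np.asarray(lumen_pts, dtype=float)
    return np.hypot(d[:, 0], d[:, 1])


def measure_cap_thickness(
    lumen_pts: np.ndarray,
    wall_pts: np.ndarray,
    lipids: Sequence[ClosedContour],
) -> tuple[np.ndarray, np.ndarray]:
    """Cap thickness along each lumen-to-wall connector.

    A point is a cap point when its connector crosses at least one lipid
    boundary; cap thickness is the distance from the lumen point to the
    nearest lipid edge over all lipid cores (the edge "near the lumen").
    """
    n = len(lumen_pts)
    cap = np.full(n, np.nan)
    if lipids:
        for i in range(n):
            best = np.inf
            for lip in lipids:
                hit = first_intersection((lumen_pts[i], wall_pts[i]), lip)
                if hit is not None and hit[1] < best:
                    best = hit[1]
            if np.isfinite(best):
                cap[i] = best
    return cap, np.isfinite(cap)


def quantify_slice(
    slc: SliceContours, *, n_points: int = N_POINTS, validate: bool = True
) -> RadialProfile:
    """Run the full four-quarter pipeline on one slice.

    The lumen resampling is anchored where the myocardium-direction ray from
    the lumen centroid crosses the lumen boundary, so sample locations rotate
    rigidly with the data and measurements are invariant under rigid motions.
    """
    if validate:
        slc = validate_slice(slc)
    lumen = slc.lumen.oriented_ccw()
    centroid = lumen.centroid

    extent = float(np.max(np.hypot(*(lumen.points - centroid).T))) + 1.0
    ray_end = centroid + extent * np.array(
        [np.cos(slc.myocardium_angle), np.sin(slc.myocardium_angle)]
    )
    hit = first_intersection((centroid, ray_end), lumen)
    if hit is None:
        raise QuadrantError(
            f"slice {slc.slice_id!r}: myocardium ray misses the lumen boundary"
        )
    s0 = float(lumen.ring.project(Point(hit[0])))

    lumen_pts = _resample_at(lumen, n_points, s0)
    labels, dividing = assign_quarters(lumen_pts, slc.myocardium_angle, centroid)
    wall_pts, _ = match_wall(lumen_pts, dividing, slc.wall)
    wall_t = measure_wall_thickness(lumen_pts, wall_pts)
    cap_t, is_cap = measure_cap_thickness(lumen_pts, wall_pts, slc.lipids)
    return RadialProfile(
        slice_id=slc.slice_id,
        modality=slc.modality,
        lumen_pts=lumen_pts,
        wall_pts=wall_pts,
        quarter=labels,
        wall_thickness=wall_t,
        cap_thickness=cap_t,
        is_cap_point=is_cap,
        dividing_indices=dividing,
    )
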