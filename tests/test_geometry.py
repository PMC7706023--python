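"""Contour validation, arc-length resampling and segment intersection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capquant import (
    ClosedContour,
    ContourError,
    DegenerateContourError,
    LipidOverlapsLumenError,
    LumenOutsideWallError,
    SelfIntersectionError,
    SliceContours,
    first_intersection,
    resample_closed,
    validate_slice,
)

from conftest import annular_band, circle_points


class TestClosedContour:
    def test_rejects_too_few_points(self):
        with pytest.raises(ContourError):
            ClosedContour([[0, 0], [1, 0], [0, 1]])

    def test_rejects_nonfinite_and_duplicates(self):
        with pytest.raises(ContourError):
            ClosedContour([[0, 0], [1, 0], [np.nan, 1], [0, 1]])
        with pytest.raises(ContourError):
            ClosedContour([[0, 0], [1, 0], [1, 0], [0, 1], [0, 0.5]])

    def test_drops_explicit_closure_point(self):
        c = ClosedContour([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]])
        assert c.n_points == 4
        assert c.perimeter == pytest.approx(4.0)

    def test_signed_area_and_orientation(self):
        square = ClosedContour([[0, 0], [1, 0], [1, 1], [0, 1]])
        assert square.signed_area == pytest.approx(1.0)
        cw = ClosedContour(square.points[::-1])
        assert cw.signed_area == pytest.approx(-1.0)
        assert cw.oriented_ccw().signed_area == pytest.approx(1.0)

    def test_centroid_of_offset_circle(self):
        c = ClosedContour(circle_points(2.0, center=(3.0, -1.0)))
        assert c.centroid == pytest.approx([3.0, -1.0], abs=1e-9)

    def test_canonical_starts_at_max_x(self):
        pts = circle_points(1.0)
        rolled = ClosedContour(np.roll(pts, 37, axis=0)[::-1])
        canon = rolled.canonical()
        assert canon.signed_area > 0
        assert np.argmax(canon.points[:, 0]) == 0


class TestValidateSlice:
    def test_accepts_nested_circles(self, annulus_slice):
        out = validate_slice(annulus_slice)
        assert out.lumen.signed_area > 0 and out.wall.signed_area > 0

    def test_lumen_outside_wall(self):
        slc = SliceContours(
            "bad", "OCT",
            lumen=ClosedContour(circle_points(3.0), "lumen"),
            wall=ClosedContour(circle_points(2.5), "wall"),
        )
        with pytest.raises(LumenOutsideWallError):
            validate_slice(slc)

    def test_bowtie_lumen_is_self_intersecting(self):
        bowtie = ClosedContour([[0, 0], [1, 1], [1, 0], [0, 1]])
        # oracle: brute-force check that two non-adjacent edges cross
        assert _edges_cross(bowtie.points)
        slc = SliceContours(
            "bad", "OCT", lumen=bowtie, wall=ClosedContour(circle_points(5.0), "wall")
        )
        with pytest.raises(SelfIntersectionError):
            validate_slice(slc)

    def test_lipid_overlapping_lumen(self):
        slc = SliceContours(
            "bad", "OCT",
            lumen=ClosedContour(circle_points(1.5), "lumen"),
            wall=ClosedContour(circle_points(2.5), "wall"),
            lipids=(ClosedContour(annular_band(1.2, 1.8, -0.5, 0.5), "lipid"),),
        )
        with pytest.raises(LipidOverlapsLumenError):
            validate_slice(slc)


class TestResample:
    def test_circle_to_four_points(self):
        c = ClosedContour(circle_points(1.0)).canonical()
        out = resample_closed(c, 4)
        angles = np.sort(np.arctan2(out.points[:, 1], out.points[:, 0]))
        gaps = np.diff(np.concatenate([angles, [angles[0] + 2 * np.pi]]))
        assert gaps == pytest.approx(np.full(4, np.pi / 2), abs=1e-6)

    def test_square_to_eight_points_gap_half(self):
        sq = ClosedContour([[0, 0], [1, 0], [1, 1], [0, 1]])
        out = resample_closed(sq, 8)
        segs = np.diff(out.closed_points, axis=0)
        assert np.hypot(segs[:, 0], segs[:, 1]) == pytest.approx(np.full(8, 0.5))

    @pytest.mark.parametrize("n", [7, 100])
    def test_equal_arc_gaps_on_irregular_polygon(self, n):
        rng = np.random.default_rng(42)
        th = np.sort(rng.uniform(0, 2 * np.pi, 7))
        r = rng.uniform(1.0, 2.0, 7)
        poly = ClosedContour(np.column_stack([r * np.cos(th), r * np.sin(th)]))
        out = resample_closed(poly, n)
        # oracle: cumulative arc length of output points along the source polyline
        gaps = _arc_gaps_along(poly, out.points)
        assert gaps == pytest.approx(np.full(n, poly.perimeter / n), rel=1e-9)

    def test_idempotent_on_evenly_spaced_contour(self):
        # a regular polygon already has equal arc gaps, so resampling to the
        # same point count must reproduce it
        c = ClosedContour(circle_points(1.3, n=60))
        again = resample_closed(c, 60)
        assert np.allclose(c.points, again.points, atol=1e-9)

    def test_perimeter_preserved_on_smooth_shape(self):
        c = ClosedContour(circle_points(2.0, n=512))
        out = resample_closed(c, 100)
        assert abs(out.perimeter - c.perimeter) / c.perimeter < 0.005

    def test_zero_perimeter_rejected_at_construction(self):
        with pytest.raises(ContourError):
            ClosedContour(np.zeros((5, 2)))


class TestFirstIntersection:
    def test_radial_ray_vs_circle(self):
        circle = ClosedContour(circle_points(2.0, n=512))
        hit = first_intersection(((0.0, 0.0), (3.0, 0.0)), circle)
        assert hit is not None
        point, dist = hit
        assert point == pytest.approx([2.0, 0.0], abs=1e-3)
        assert dist == pytest.approx(2.0, abs=1e-3)

    def test_segment_outside_polygon(self):
        circle = ClosedContour(circle_points(1.0))
        assert first_intersection(((5.0, 5.0), (6.0, 5.0)), circle) is None

    def test_coincident_endpoints_rejected(self):
        circle = ClosedContour(circle_points(1.0))
        with pytest.raises(ValueError):
            first_intersection(((1.0, 1.0), (1.0, 1.0)), circle)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_edge_by_edge_oracle(self, seed):
        rng = np.random.default_rng(seed)
        th = np.sort(rng.uniform(0, 2 * np.pi, rng.integers(4, 9)))
        if np.min(np.diff(th)) < 1e-3:
            return
        poly = ClosedContour(np.column_stack([np.cos(th), np.sin(th)]))
        p0 = rng.uniform(-2, 2, 2)
        p1 = rng.uniform(-2, 2, 2)
        if np.hypot(*(p1 - p0)) < 1e-6:
            return
        hit = first_intersection((p0, p1), poly)
        oracle = _brute_force_first_hit(p0, p1, poly.closed_points)
        if oracle is None:
            assert hit is None
        else:
            assert hit is not None
            assert hit[1] == pytest.approx(oracle, abs=1e-9)
            assert 0.0 <= hit[1] <= np.hypot(*(p1 - p0)) + 1e-12


def _brute_force_first_hit(p0, p1, closed_pts):
    """Smallest intersection distance from p0 over all polygon edges."""
    best = None
    d = p1 - p0
    for a, b in zip(closed_pts[:-1], closed_pts[1:]):
        e = b - a
        denom = d[0] * e[1] - d[1] * e[0]
        if abs(denom) < 1e-15:
            continue
        t = ((a[0] - p0[0]) * e[1] - (a[1] - p0[1]) * e[0]) / denom
        u = ((a[0] - p0[0]) * d[1] - (a[1] - p0[1]) * d[0]) / denom
        if -1e-12 <= t <= 1 + 1e-12 and -1e-12 <= u <= 1 + 1e-12:
            dist = t * np.hypot(*d)
            if best is None or dist < best:
                best = dist
    return best


def _edges_cross(pts):
    closed = np.vstack([pts, pts[:1]])
    n = len(pts)
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            if _segments_intersect(closed[i], closed[i + 1], closed[j], closed[j + 1]):
                return True
    return False


def _segments_intersect(a, b, c, d):
    def orient(p, q, r):
        return np.sign((q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0]))

    return (
        orient(a, b, c) != orient(a, b, d) and orient(c, d, a) != orient(c, d, b)
    )


def _arc_gaps_along(contour, sample_pts):
    """Arc-length gaps between consecutive samples, measured on the polyline."""
    closed = contour.closed_points
    seg = np.diff(closed, axis=0)
    cum = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    perim = cum[-1]

    def arc_pos(p):
        best, best_s = np.inf, 0.0
        for k, (a, b) in enumerate(zip(closed[:-1], closed[1:])):
            e = b - a
            L2 = e @ e
            t = np.clip(((p - a) @ e) / L2, 0, 1)
            q = a + t * e
            d = np.hypot(*(p - q))
            if d < best:
                best, best_s = d, cum[k] + t * np.sqrt(L2)
        return best_s

    s = np.array([arc_pos(p) for p in sample_pts])
    gaps = np.diff(np.concatenate([s, [s[0] + perim]]))
    return np.mod(gaps, perim)
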