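"""Geometry primitives against closed forms and independent oracles."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import ConvexHull as QhullHull

from rsaquant import (DegenerateInputError, Polygon, center_of_mass,
                      convex_hull, extent, hull_centroid, point_at_arclength,
                      point_at_fraction, polyline_length, resample,
                      signed_area)

# ---------------------------------------------------------------------------
# oracles


def segment_sum_length(pts):
    """Brute-force per-segment length sum."""
    return sum(math.dist(pts[i], pts[i + 1]) for i in range(len(pts) - 1))


def line_integral_com(polylines):
    """Exact centre of mass of polylines under uniform linear density:
    per-segment midpoint weighted by segment length."""
    weighted = np.zeros(2)
    total = 0.0
    for pts in polylines:
        pts = np.asarray(pts, float)
        seg = np.diff(pts, axis=0)
        lens = np.hypot(seg[:, 0], seg[:, 1])
        mids = 0.5 * (pts[:-1] + pts[1:])
        weighted += (lens[:, None] * mids).sum(axis=0)
        total += lens.sum()
    return weighted / total


def brute_force_hull_vertices(pts, tol=1e-12):
    """O(n^3) hull: (i, j) is a hull edge iff every other point lies on one
    side of the directed line i->j; hull vertices are the edge endpoints."""
    pts = np.asarray(pts, float)
    n = len(pts)
    verts = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            cross = d[0] * (pts[:, 1] - pts[i, 1]) - d[1] * (pts[:, 0] - pts[i, 0])
            if np.all(cross >= -tol) or np.all(cross <= tol):
                verts.add(i)
                verts.add(j)
    return np.array(sorted(verts))


def fan_area(vertices):
    """Triangulation-fan area from vertex 0 (signed)."""
    v = np.asarray(vertices, float)
    total = 0.0
    for i in range(1, len(v) - 1):
        a, b = v[i] - v[0], v[i + 1] - v[0]
        total += 0.5 * (a[0] * b[1] - a[1] * b[0])
    return total


def random_convex_polygon(rng, n=12, scale=100.0):
    pts = rng.uniform(0, scale, size=(n * 4, 2))
    return convex_hull(pts).vertices


def random_polyline(rng, n=50, scale=100.0):
    return np.cumsum(rng.normal(0, scale / n, size=(n, 2)), axis=0)


# ---------------------------------------------------------------------------
# polyline_length / resample / point_at_fraction


@pytest.mark.parametrize("pts, expected", [
    ([(0, 0), (0, 10)], 10.0),
    ([(0, 0), (3, 4)], 5.0),
    ([(2, 7)], 0.0),
    ([(0, 0), (1, 0), (1, 1)], 2.0),
])
def test_polyline_length_closed_forms(pts, expected):
    assert polyline_length(pts) == pytest.approx(expected, abs=1e-12)


def test_polyline_length_matches_segment_sum_oracle(rng):
    for _ in range(20):
        pts = random_polyline(rng)
        assert polyline_length(pts) == pytest.approx(
            segment_sum_length(pts), rel=1e-9)


def test_resample_straight_segment_unit_interval():
    sampled = resample([(0, 0), (0, 10)], 1.0)
    assert len(sampled.points) == 11
    np.testing.assert_allclose(sampled.points[:, 1], np.arange(11.0))


def test_resample_retains_terminal_point():
    sampled = resample([(0, 0), (0, 10)], 3.0)
    np.testing.assert_allclose(sampled.points[:, 1], [0, 3, 6, 9, 10])


def test_resample_regular_spacing_except_last(rng):
    pts = random_polyline(rng)
    sampled = resample(pts, 2.5)
    gaps = np.hypot(*np.diff(sampled.points, axis=0).T)
    assert np.all(gaps[:-1] <= 2.5 + 1e-6)
    np.testing.assert_allclose(sampled.points[0], pts[0])
    np.testing.assert_allclose(sampled.points[-1], pts[-1])


def test_resampled_length_converges_to_original(rng):
    pts = random_polyline(rng, n=30)
    total = polyline_length(pts)
    errors = []
    for interval in (1.0, 0.1, 0.01):
        resampled_len = polyline_length(resample(pts, interval).points)
        # chords only shorten, by at most one interval per interior corner
        assert resampled_len <= total + 1e-9
        err = total - resampled_len
        assert err <= (len(pts) - 2) * interval
        errors.append(err)
    assert errors[0] >= errors[1] >= errors[2]
    assert errors[2] < 0.1


def test_resample_rejects_bad_interval():
    with pytest.raises(ValueError):
        resample([(0, 0), (0, 10)], 0.0)
    with pytest.raises(DegenerateInputError):
        resample([(1, 1), (1, 1)], 1.0)


def test_point_at_fraction_endpoints_and_midpoint():
    pts = [(0, 0), (0, 1)]
    assert point_at_fraction(pts, 0.0) == (0.0, 0.0)
    assert point_at_fraction(pts, 1.0) == (0.0, 1.0)
    assert point_at_fraction(pts, 0.5) == (0.0, 0.5)
    with pytest.raises(ValueError):
        point_at_fraction(pts, 1.5)


def test_point_at_fraction_matches_dense_sampling_oracle(rng):
    pts = random_polyline(rng)
    total = polyline_length(pts)
    dense = resample(pts, total / 200000).points
    for f in (0.1, 0.25, 0.5, 0.9, 1.0):
        p = point_at_fraction(pts, f)
        idx = int(round(f * (len(dense) - 1)))
        np.testing.assert_allclose(p, dense[idx], atol=1e-2)


def test_point_at_arclength_clamps_beyond_tip():
    pts = [(0, 0), (0, 10)]
    assert point_at_arclength(pts, 50.0, clamp=True) == (0.0, 10.0)
    with pytest.raises(ValueError):
        point_at_arclength(pts, 50.0)


# ---------------------------------------------------------------------------
# centre of mass


def test_center_of_mass_uniform_rod_is_midpoint():
    com = center_of_mass([[(0, 0), (0, 100)]], 1.0)
    assert com == pytest.approx((0.0, 50.0), abs=1e-9)


def test_center_of_mass_mirror_symmetric_pair_is_centred():
    left = [(0, 0), (-30, 40)]
    right = [(0, 0), (30, 40)]
    com = center_of_mass([left, right], 1.0)
    assert com.x == pytest.approx(0.0, abs=1e-9)


def test_center_of_mass_matches_line_integral_oracle(rng):
    for _ in range(10):
        polys = [random_polyline(rng, n=20) + rng.uniform(-50, 50, 2)
                 for _ in range(3)]
        com = center_of_mass(polys, 1.0)
        oracle = line_integral_com(polys)
        assert math.dist(com, oracle) < 0.5


def test_center_of_mass_rejects_zero_length():
    with pytest.raises(DegenerateInputError):
        center_of_mass([[(1, 1), (1, 1)]], 1.0)


# ---------------------------------------------------------------------------
# convex hull / area / centroid


def test_hull_of_square_with_interior_points(rng):
    corners = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
    interior = rng.uniform(1, 9, size=(10, 2))
    hull = convex_hull(np.vstack([corners, interior]))
    assert not hull.degenerate
    assert {tuple(v) for v in hull.vertices} == {tuple(c) for c in corners}


def test_hull_of_collinear_points_is_degenerate():
    pts = [(i, 2.0 * i) for i in range(5)]
    hull = convex_hull(pts)
    assert hull.degenerate
    assert {tuple(v) for v in hull.vertices} == {(0.0, 0.0), (4.0, 8.0)}
    assert signed_area(hull) == 0.0


def test_hull_matches_brute_force_oracle(rng):
    for _ in range(20):
        pts = rng.uniform(0, 100, size=(200, 2))
        ours = {tuple(v) for v in convex_hull(pts).vertices}
        oracle = {tuple(pts[i]) for i in brute_force_hull_vertices(pts)}
        assert ours == oracle


def test_hull_matches_qhull(rng):
    for _ in range(20):
        pts = rng.normal(0, 30, size=(150, 2))
        ours = {tuple(v) for v in convex_hull(pts).vertices}
        qhull = {tuple(pts[i]) for i in QhullHull(pts).vertices}
        assert ours == qhull


def test_signed_area_square_orientation():
    ccw = [(0, 0), (1, 0), (1, 1), (0, 1)]
    assert signed_area(ccw) == pytest.approx(1.0)
    assert signed_area(ccw[::-1]) == pytest.approx(-1.0)


def test_signed_area_triangle_magnitude():
    assert abs(signed_area([(0, 0), (1, 0), (0, 1)])) == pytest.approx(0.5)


def test_signed_area_matches_fan_triangulation_oracle(rng):
    for _ in range(20):
        verts = random_convex_polygon(rng)
        assert signed_area(verts) == pytest.approx(fan_area(verts), rel=1e-9)


def test_hull_centroid_unit_square():
    sq = Polygon(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
    assert hull_centroid(sq) == pytest.approx((0.5, 0.5), abs=1e-12)


def test_hull_centroid_triangle_is_vertex_mean():
    assert hull_centroid(np.array([[0, 0], [3, 0], [0, 3]], float)) \
        == pytest.approx((1.0, 1.0), abs=1e-12)


def points_in_convex(vertices, pts, atol=1e-12):
    """Vectorised point-in-convex-CCW-polygon test."""
    v = np.asarray(vertices, float)
    w = np.roll(v, -1, axis=0)
    edge = w - v
    rel = pts[:, None, :] - v[None, :, :]
    cross = edge[None, :, 0] * rel[:, :, 1] - edge[None, :, 1] * rel[:, :, 0]
    return np.all(cross >= -atol, axis=1)


def test_hull_centroid_matches_monte_carlo_oracle(rng):
    verts = random_convex_polygon(rng)
    lo, hi = verts.min(axis=0), verts.max(axis=0)
    draws = rng.uniform(lo, hi, size=(10 ** 6, 2))
    mc = draws[points_in_convex(verts, draws)].mean(axis=0)
    c = hull_centroid(Polygon(verts))
    scale = float(np.max(hi - lo))
    assert math.dist(c, mc) / scale < 1e-3


def test_degenerate_hull_centroid_is_vertex_mean():
    hull = convex_hull([(0, 0), (0, 4), (0, 8)])
    assert hull.degenerate
    assert hull_centroid(hull) == pytest.approx((0.0, 4.0))


def test_extent_single_vertical_root():
    w, d = extent([(5, 0), (5, 80)], (5, 0))
    assert (w, d) == (0.0, 80.0)


def test_extent_symmetric_fan():
    L = 50.0
    pts = np.vstack([np.array([[0, 0], [L, L]]), np.array([[0, 0], [-L, L]])])
    w, d = extent(pts, (0, 0))
    assert w == pytest.approx(2 * L)
    assert d == pytest.approx(L)


# ---------------------------------------------------------------------------
# invariance properties

finite = st.floats(-1e3, 1e3, allow_nan=False)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(dx=finite, dy=finite, seed=st.integers(0, 2 ** 16))
def test_translation_equivariance(dx, dy, seed):
    r = np.random.default_rng(seed)
    polys = [random_polyline(r, n=15) for _ in range(3)]
    shifted = [p + np.array([dx, dy]) for p in polys]
    com0 = np.array(center_of_mass(polys, 1.0))
    com1 = np.array(center_of_mass(shifted, 1.0))
    np.testing.assert_allclose(com1, com0 + [dx, dy], atol=1e-6)
    cloud0, cloud1 = np.vstack(polys), np.vstack(shifted)
    h0, h1 = convex_hull(cloud0), convex_hull(cloud1)
    assert signed_area(h1) == pytest.approx(signed_area(h0), rel=1e-9, abs=1e-6)
    c0, c1 = np.array(hull_centroid(h0)), np.array(hull_centroid(h1))
    np.testing.assert_allclose(c1, c0 + [dx, dy], atol=1e-6)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(angle=st.floats(0, 2 * math.pi), seed=st.integers(0, 2 ** 16))
def test_rotation_invariance_of_length_and_area(angle, seed):
    r = np.random.default_rng(seed)
    pts = random_polyline(r, n=25)
    rot = np.array([[math.cos(angle), -math.sin(angle)],
                    [math.sin(angle), math.cos(angle)]])
    rotated = pts @ rot.T
    assert polyline_length(rotated) == pytest.approx(
        polyline_length(pts), rel=1e-9)
    assert abs(signed_area(convex_hull(rotated))) == pytest.approx(
        abs(signed_area(convex_hull(pts))), rel=1e-6)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2 ** 16), n=st.integers(4, 60))
def test_hull_contains_all_points_and_both_centres(seed, n):
    r = np.random.default_rng(seed)
    pts = r.uniform(-50, 50, size=(n, 2))
    hull = convex_hull(pts)
    if hull.degenerate:
        return
    for p in pts:
        assert hull.contains(p, atol=1e-7)
    assert hull.contains(hull_centroid(hull), atol=1e-7)
    assert hull.contains(center_of_mass([pts], 1.0)
                         if len(pts) > 1 else pts[0], atol=1e-7)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2 ** 16))
def test_hull_minimality_every_vertex_needed(seed):
    r = np.random.default_rng(seed)
    pts = r.normal(0, 20, size=(40, 2))
    hull = convex_hull(pts)
    if hull.degenerate:
        return
    for i, v in enumerate(hull.vertices):
        reduced = Polygon(np.delete(hull.vertices, i, axis=0))
        if len(reduced.vertices) < 3:
            continue
        # the removed vertex itself must fall outside the reduced hull
        assert not reduced.contains(v, atol=1e-9)
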