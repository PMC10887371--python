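"""Alpha-shape areas: oracle equivalence, limits, monotonicity, selection."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull, Delaunay

from glufield import (
    AlphaShapeQuantifier,
    DEFAULT_ALPHAS,
    EmptyInputError,
    ParameterError,
    SelectionError,
    alpha_shape_area,
    area_vs_alpha_sweep,
    select_alpha,
)
from glufield.alphashape import AlphaSweepResult

RIGHT_TRIANGLE = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])


def brute_force_area(points, alpha):
    """Independent per-triangle circumradius filter (vertex-coordinate form)."""
    tri = Delaunay(points)
    total = 0.0
    for s in tri.simplices:
        (ax, ay), (bx, by), (cx, cy) = points[s]
        d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if d == 0.0:
            continue
        ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
              + (cx**2 + cy**2) * (ay - by)) / d
        uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
              + (cx**2 + cy**2) * (bx - ax)) / d
        r2 = (ax - ux) ** 2 + (ay - uy) ** 2
        if r2 <= alpha:
            total += abs(
                (bx - ax) * (cy - ay) - (cx - ax) * (by - ay)
            ) / 2.0
    return total


class TestAlphaShapeArea:
    def test_right_triangle_retained(self):
        # circumradius² of the right triangle is 5000 nm²
        shape = alpha_shape_area(RIGHT_TRIANGLE, alpha=10_000.0)
        assert shape.area == pytest.approx(5000.0)
        assert len(shape.triangles) == 1
        assert len(shape.boundary) == 3

    def test_right_triangle_below_threshold(self):
        assert alpha_shape_area(RIGHT_TRIANGLE, alpha=4000.0).area == 0.0

    def test_inclusive_at_equality(self):
        assert alpha_shape_area(RIGHT_TRIANGLE, alpha=5000.0).area == pytest.approx(5000.0)

    def test_matches_brute_force_oracle(self, rng):
        pts = rng.uniform(0, 500, (200, 2))
        area = alpha_shape_area(pts, 40_000.0).area
        assert area == pytest.approx(brute_force_area(pts, 40_000.0), rel=1e-12)

    def test_convex_hull_limit(self, rng):
        pts = rng.uniform(0, 1000, (80, 2))
        shape = alpha_shape_area(pts, alpha=1e12)
        hull = ConvexHull(pts).volume
        assert shape.area == pytest.approx(hull, rel=1e-9)

    @pytest.mark.parametrize("n", [0, 1, 2])
    def test_too_few_points_degenerate(self, n):
        shape = alpha_shape_area(np.zeros((n, 2)), alpha=100.0)
        assert shape.degenerate and shape.area == 0.0

    def test_collinear_degenerate(self):
        pts = np.c_[np.arange(10.0), 2 * np.arange(10.0)]
        shape = alpha_shape_area(pts, alpha=1e9)
        assert shape.degenerate and shape.area == 0.0

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ParameterError):
            alpha_shape_area(RIGHT_TRIANGLE, alpha=0.0)

    def test_monotone_in_alpha(self, rng):
        pts = rng.uniform(0, 300, (60, 2))
        areas = [alpha_shape_area(pts, a).area for a in (100, 400, 1600, 6400, 25_600)]
        assert all(a1 <= a2 for a1, a2 in zip(areas, areas[1:]))

    def test_scale_equivariance(self, rng):
        pts = rng.uniform(0, 200, (50, 2))
        a1 = alpha_shape_area(pts, 2000.0).area
        a2 = alpha_shape_area(3.0 * pts, 9.0 * 2000.0).area
        assert a2 == pytest.approx(9.0 * a1, rel=1e-9)


class TestAreaVsAlphaSweep:
    def test_grid_enumeration(self):
        assert len(DEFAULT_ALPHAS) == 40
        assert DEFAULT_ALPHAS[0] == 25.0 and DEFAULT_ALPHAS[-1] == 40_000.0
        assert 9025.0 in DEFAULT_ALPHAS  # x = 95

    def test_single_triangle_is_step_function(self):
        res = area_vs_alpha_sweep([RIGHT_TRIANGLE])
        expected = np.where(DEFAULT_ALPHAS >= 5000.0, 5000.0 / 1e6, 0.0)
        assert np.allclose(res.median_area, expected)

    def test_median_nondecreasing_on_synthetic_clusters(self, fifty_cluster_point_sets):
        res = area_vs_alpha_sweep(fifty_cluster_point_sets)
        assert (np.diff(res.median_area) >= -1e-15).all()

    def test_per_cluster_sweep_matches_pointwise_evaluation(self, rng):
        # the cumulative-sum fast path equals direct thresholding
        pts = rng.uniform(0, 400, (120, 2))
        res = area_vs_alpha_sweep([pts])
        direct = [alpha_shape_area(pts, a).area / 1e6 for a in DEFAULT_ALPHAS]
        assert np.allclose(res.median_area, direct, rtol=1e-12)

    def test_all_degenerate_raises(self):
        with pytest.raises(EmptyInputError):
            area_vs_alpha_sweep([np.zeros((2, 2))])


def _sweep_from_medians(medians):
    m = np.asarray(medians, float)
    pct = np.full(len(m), np.nan)
    prev = m[:-1]
    pct[1:] = np.where(prev > 0, 100 * (m[1:] - prev) / prev, np.nan)
    return AlphaSweepResult(
        alphas=DEFAULT_ALPHAS[: len(m)],
        median_area=m,
        q25=m,
        q75=m,
        pct_increase=pct,
    )


class TestSelectAlpha:
    def test_first_step_below_threshold_wins(self):
        # increases 12%, 8%, 4.9%, 3% -> the 4.9% step (4th alpha = 400)
        m = [1.0, 1.12, 1.12 * 1.08, 1.12 * 1.08 * 1.049, 1.12 * 1.08 * 1.049 * 1.03]
        res = _sweep_from_medians(m)
        assert select_alpha(res, 5.0) == DEFAULT_ALPHAS[3]

    def test_no_qualifying_step_raises(self):
        m = [1.0 * 1.06**k for k in range(10)]
        with pytest.raises(SelectionError):
            select_alpha(_sweep_from_medians(m), 5.0)

    def test_first_alpha_never_selectable(self):
        res = _sweep_from_medians([1.0, 1.001])
        assert select_alpha(res, 5.0) == DEFAULT_ALPHAS[1]

    def test_matches_independent_rule_implementation(self, fifty_cluster_point_sets):
        res = area_vs_alpha_sweep(fifty_cluster_point_sets)
        got = select_alpha(res, 5.0)
        # independent re-implementation of the stopping rule
        expected = None
        for i in range(1, len(res.alphas)):
            prev, cur = res.median_area[i - 1], res.median_area[i]
            if prev > 0 and 100.0 * (cur - prev) / prev < 5.0:
                expected = res.alphas[i]
                break
        assert got == expected


class TestAlphaShapeQuantifier:
    def test_fit_selects_then_transform_measures(self, fifty_cluster_point_sets):
        q = AlphaShapeQuantifier().fit(fifty_cluster_point_sets)
        areas = q.transform(fifty_cluster_point_sets)
        assert len(areas) == 50 and (areas >= 0).all()
        assert q.alpha_ in DEFAULT_ALPHAS

    def test_fixed_alpha_skips_sweep(self, rng):
        pts = [rng.uniform(0, 300, (50, 2))]
        q = AlphaShapeQuantifier(alpha=9025.0).fit(pts)
        assert q.alpha_ == 9025.0 and q.sweep_ is None
        assert q.transform(pts)[0] == pytest.approx(
            alpha_shape_area(pts[0], 9025.0).area / 1e6
        )

    def test_get_set_params(self):
        q = AlphaShapeQuantifier()
        q.set_params(threshold_pct=3.0)
        assert q.get_params()["threshold_pct"] == 3.0
        with pytest.raises(ParameterError):
            q.set_params(bogus=1)
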