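import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy.interpolate import splev

from arborgeom.decompose import SegmentPath
from arborgeom.spline import (
    DomainError,
    basis,
    basis_derivative,
    evaluate,
    fit_segment,
    select_degree,
)
from arborgeom import synth


class TestSelectDegree:
    @pytest.mark.parametrize(
        "n,expected",
        [(2, 1), (3, 2), (4, 3), (5, 3), (6, 5), (7, 5), (100, 5)],
    )
    def test_degree_rule(self, n, expected):
        assert select_degree(n) == expected

    def test_below_two_points_rejected(self):
        with pytest.raises(ValueError):
            select_degree(1)

    def test_degree_four_never_selected(self):
        assert all(select_degree(n) != 4 for n in range(2, 200))


class TestBasis:
    def test_degree_zero_is_half_open_indicator(self):
        knots = [0.0, 1.0, 2.0]
        assert basis(0, 0, knots, 0.5) == 1.0
        assert basis(0, 0, knots, 0.0) == 1.0  # left end included
        assert basis(0, 0, knots, 1.0) == 0.0  # right end excluded
        assert basis(0, 0, knots, 1.5) == 0.0
        assert basis(1, 0, knots, 1.5) == 1.0

    def test_degree_one_triangle(self):
        knots = [0.0, 1.0, 2.0]
        assert basis(0, 1, knots, 0.5) == pytest.approx(0.5)
        assert basis(0, 1, knots, 1.0) == pytest.approx(1.0)
        assert basis(0, 1, knots, 1.5) == pytest.approx(0.5)

    @given(
        interior=hst.lists(
            hst.floats(0.05, 0.95), min_size=0, max_size=6, unique=True
        ),
        p=hst.integers(1, 5),
        frac=hst.floats(0.001, 0.999),
    )
    @settings(max_examples=100, deadline=None)
    def test_partition_of_unity(self, interior, p, frac):
        # clamped knot vector on [0, 1] with arbitrary interior knots
        knots = np.concatenate(
            [np.zeros(p + 1), np.sort(interior), np.ones(p + 1)]
        )
        x = frac  # strictly inside the active interval
        total = sum(
            basis(j, p, knots, x) for j in range(len(knots) - p - 1)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_invalid_index_rejected(self):
        with pytest.raises(IndexError):
            basis(5, 1, [0.0, 1.0, 2.0], 0.5)


class TestBasisDerivative:
    def test_triangle_slopes(self):
        knots = [0.0, 2.0, 4.0]
        assert basis_derivative(0, 1, knots, 0.5) == pytest.approx(0.5)
        assert basis_derivative(0, 1, knots, 3.0) == pytest.approx(-0.5)

    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(0)
        p = 3
        knots = np.concatenate([np.zeros(p + 1), [0.3, 0.6], np.ones(p + 1)])
        h = 1e-5
        x = rng.uniform(0.05, 0.95, size=100)
        for j in range(len(knots) - p - 1):
            fd = (basis(j, p, knots, x + h) - basis(j, p, knots, x - h)) / (2 * h)
            an = basis_derivative(j, p, knots, x)
            assert np.allclose(an, fd, rtol=1e-5, atol=1e-6)

    def test_order_beyond_degree_is_zero(self):
        knots = np.concatenate([np.zeros(3), [0.5], np.ones(3)])
        x = np.linspace(0.01, 0.99, 17)
        assert np.all(basis_derivative(0, 2, knots, x, order=3) == 0.0)


class TestFitSegment:
    def test_two_points_give_the_line(self):
        seg = SegmentPath(np.array([[0, 0, 0], [3, 4, 0]], float), "terminal")
        curve = fit_segment(seg)
        assert curve.degree == 1
        mid = evaluate(curve, seg.L / 2)
        assert np.allclose(mid, [1.5, 2.0, 0.0], atol=1e-12)

    def test_interpolates_helix_points(self, helix_segment):
        curve = fit_segment(helix_segment)
        assert curve.degree == 5
        u = helix_segment.chord_parameters()
        resid = np.abs(evaluate(curve, u) - helix_segment.points).max()
        assert resid <= 1e-6

    def test_endpoints_are_first_and_last_points(self, helix_segment):
        curve = fit_segment(helix_segment)
        assert np.allclose(evaluate(curve, 0.0), helix_segment.points[0], atol=1e-9)
        assert np.allclose(
            evaluate(curve, curve.L), helix_segment.points[-1], atol=1e-9
        )

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 12])
    def test_interpolation_at_every_point_count(self, n):
        rng = np.random.default_rng(n)
        pts = np.cumsum(rng.uniform(0.5, 1.5, size=(n, 3)), axis=0)
        seg = SegmentPath(pts, "collateral")
        curve = fit_segment(seg)
        assert curve.degree == select_degree(n)
        resid = np.abs(evaluate(curve, seg.chord_parameters()) - pts).max()
        assert resid <= 1e-6

    def test_degree_override_forces_linear(self, helix_segment):
        curve = fit_segment(helix_segment, degree=1)
        assert curve.degree == 1


class TestEvaluate:
    def test_first_derivative_of_straight_segment_is_unit_direction(self):
        seg = SegmentPath(np.array([[0, 0, 0], [3, 4, 0]], float), "terminal")
        curve = fit_segment(seg)
        d1 = evaluate(curve, 2.0, order=1)
        assert np.allclose(d1, [0.6, 0.8, 0.0], atol=1e-12)

    def test_higher_orders_vanish_on_degree_one(self, path3):
        from arborgeom.decompose import decompose_arbor

        seg = decompose_arbor(path3)[0]
        curve = fit_segment(seg, degree=1)
        assert np.all(evaluate(curve, 1.0, order=2) == 0.0)
        assert np.all(evaluate(curve, 1.0, order=3) == 0.0)

    def test_outside_domain_raises(self, helix_segment):
        curve = fit_segment(helix_segment)
        with pytest.raises(DomainError):
            evaluate(curve, -1.0)
        with pytest.raises(DomainError):
            evaluate(curve, curve.L + 1.0)

    @pytest.mark.parametrize("order", [0, 1, 2, 3])
    def test_matches_scipy_splev_oracle(self, helix_segment, order):
        # independent route: FITPACK's own evaluator on the same tck
        curve = fit_segment(helix_segment)
        t = np.linspace(0.0, curve.L, 53)
        mine = evaluate(curve, t, order=order)
        tck = (curve.knots, list(curve.coefficients.T), curve.degree)
        ref = np.stack(splev(t, tck, der=order), axis=1)
        assert np.allclose(mine, ref, rtol=1e-8, atol=1e-8)

    def test_third_derivative_continuous_across_interior_knots(self, helix_segment):
        curve = fit_segment(helix_segment)
        interior = curve.knots[
            (curve.knots > curve.knots[curve.degree])
            & (curve.knots < curve.knots[-curve.degree - 1])
        ]
        eps = 1e-6
        for knot in np.unique(interior)[:10]:
            lo = evaluate(curve, knot - eps, order=3)
            hi = evaluate(curve, knot + eps, order=3)
            assert np.allclose(lo, hi, rtol=1e-3, atol=1e-4)
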