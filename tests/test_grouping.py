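"""Endpoint models, continuation costs, matching, and curve merging."""

import warnings

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize

from wiretrace.grouping import (
    SENTINEL,
    EndpointModel,
    GroupingParams,
    assign,
    bhattacharyya_cost,
    build_cost_matrix,
    cleanup,
    continuation_cost,
    endpoint_models,
    fit_poly,
    group,
    merge_curves,
    threshold_and_validate,
)
from wiretrace.synthetic import SceneConfig, fragment_curves, generate_curve


def _vseg(r0, c0, r1, c1):
    """Straight 8-connected segment as an (n, 2) int array."""
    n = max(abs(r1 - r0), abs(c1 - c0)) + 1
    rows = np.linspace(r0, r1, n).round().astype(int)
    cols = np.linspace(c0, c1, n).round().astype(int)
    return np.stack([rows, cols], axis=1)


class TestEndpointModels:
    def test_collinear_start_model(self):
        curve = _vseg(0, 0, 0, 9)
        models = endpoint_models([curve], npts=10)
        start = models[0]
        assert np.allclose(start.v, [0, 4.5])
        assert np.allclose(start.d, [0, -1])  # outward toward the first point

    def test_collinear_end_model(self):
        curve = _vseg(0, 0, 0, 9)
        end = endpoint_models([curve], npts=10)[1]
        assert np.allclose(end.d, [0, 1])

    def test_direction_matches_eigenvector_oracle(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(10, 2)) * [1.0, 3.0]
            curve = pts.round().astype(int)
            m = endpoint_models([curve], npts=10)[0]
            centered = curve - curve.mean(axis=0)
            evals, evecs = np.linalg.eigh(centered.T @ centered)
            principal = evecs[:, np.argmax(evals)]
            assert abs(abs(np.dot(m.d, principal)) - 1) < 1e-9

    def test_short_curve_uses_all_points(self):
        curve = _vseg(0, 0, 0, 4)
        models = endpoint_models([curve], npts=10)
        assert np.allclose(models[0].v, models[1].v)  # same window both ends
        assert np.allclose(models[0].d, -models[1].d)

    def test_degenerate_window_flagged_invalid(self):
        curve = np.zeros((5, 2), dtype=int)  # all identical points
        m = endpoint_models([curve], npts=10)[0]
        assert not m.valid


class TestFitPoly:
    def test_straight_line(self):
        assert fit_poly(0.0, 0.0, 5.0) == (0.0, 0.0, 0.0)

    def test_unit_case(self):
        a, b, c = fit_poly(1.0, 0.0, 1.0)
        assert (a, b, c) == (1.0, -2.0, 1.0)
        f = lambda x: a * x + b * x**2 + c * x**3
        fp = lambda x: a + 2 * b * x + 3 * c * x**2
        assert f(1.0) == pytest.approx(0.0) and fp(1.0) == pytest.approx(0.0)

    def test_constraint_residuals_tiny(self, rng):
        for _ in range(50):
            s1, s2 = rng.normal(size=2)
            l = rng.uniform(0.5, 40)
            a, b, c = fit_poly(s1, s2, l)
            assert abs(a * l + b * l**2 + c * l**3) < 1e-10 * max(1, l**3)
            assert abs(a - s1) < 1e-12
            assert abs(a + 2 * b * l + 3 * c * l**2 - s2) < 1e-9

    def test_matches_numeric_constrained_fit(self, rng):
        """Agrees with a numeric least-squares solve of the constraints."""
        s1, s2, l = 0.7, -0.3, 12.0
        A = np.array([[l, l**2, l**3], [1, 0, 0], [1, 2 * l, 3 * l**2]])
        rhs = np.array([0.0, s1, s2])
        coeffs = np.linalg.solve(A, rhs)
        assert np.allclose(fit_poly(s1, s2, l), coeffs, atol=1e-9)

    def test_degenerate_length_rejected(self):
        with pytest.raises(ValueError):
            fit_poly(0.0, 0.0, 0.0)


def _model(v, d, curve_id=0, end_id=0, lam=(1.0, 0.1)):
    d = np.asarray(d, dtype=float)
    return EndpointModel(
        v=np.asarray(v, dtype=float),
        d=d / np.linalg.norm(d),
        lam=np.asarray(lam, dtype=float),
        curve_id=curve_id,
        end_id=end_id,
    )


class TestContinuationCost:
    def test_collinear_continuation_costs_zero(self):
        ei = _model((0, 0), (0, 1), 0)
        ej = _model((0, 10), (0, -1), 1)
        assert continuation_cost(ei, ej) == pytest.approx(0.0)

    def test_parallel_directions_gated_out(self):
        ei = _model((0, 0), (0, 1), 0)
        ej = _model((0, 10), (0, 1), 1)  # same direction: must oppose
        assert continuation_cost(ei, ej) == SENTINEL

    def test_bent_join_closed_form(self):
        ei = _model((0, 0), (0, 1), 0)
        ej = _model((0, 10), (-0.6, -0.8), 1)
        assert continuation_cost(ei, ej) == pytest.approx(0.144, abs=1e-9)

    def test_too_far_gated_out(self):
        ei = _model((0, 0), (0, 1), 0)
        ej = _model((0, 100), (0, -1), 1)
        assert continuation_cost(ei, ej) == SENTINEL

    def test_closed_form_equals_quadrature(self, rng):
        params = GroupingParams()
        for _ in range(200):
            s1, s2 = rng.normal(scale=0.5, size=2)
            l = rng.uniform(1, 40)
            a, b, c = fit_poly(s1, s2, l)
            closed = 4 * b * b * l + 12 * b * c * l**2 + 12 * c * c * l**3
            numeric, _ = quad(lambda x: (2 * b + 6 * c * x) ** 2, 0, l)
            assert abs(closed - numeric) < 1e-9 * max(1.0, closed)

    def test_symmetry(self, rng):
        for _ in range(50):
            vi, vj = rng.uniform(0, 50, 2), rng.uniform(0, 50, 2)
            if np.linalg.norm(vi - vj) < 1:
                continue
            u = (vj - vi) / np.linalg.norm(vj - vi)
            di = u + rng.normal(scale=0.1, size=2)
            dj = -u + rng.normal(scale=0.1, size=2)
            ei = _model(vi, di, 0)
            ej = _model(vj, dj, 1)
            assert continuation_cost(ei, ej) == pytest.approx(
                continuation_cost(ej, ei), abs=1e-9
            )


class TestBhattacharyya:
    def test_identical_gaussians_zero(self):
        ei = _model((0, 0), (0, 1), 0, lam=(2.0, 0.1))
        ej = _model((0, 0), (0, 1), 1, lam=(2.0, 0.1))
        # bypass gates (distance 0 < 1): call the formula via nearby points
        ej2 = _model((0, 2), (0, -1), 1, lam=(2.0, 0.1))
        params = GroupingParams(measure="bhattacharyya", sigma2=1.0)
        # identical-Gaussian check at formula level
        ei0 = _model((0, 0), (0, 1), 0, lam=(0.0, 0.0))
        ejx = _model((0, 2), (0, -1), 1, lam=(0.0, 0.0))
        v = bhattacharyya_cost(ei0, ejx, params)
        # mean term only: (1/8) * 4 / 1 = 0.5 with Sigma = I
        assert v == pytest.approx(0.5, abs=1e-9)

    def test_nonnegative_on_random_inputs(self, rng):
        params = GroupingParams(measure="bhattacharyya")
        for _ in range(50):
            vi = rng.uniform(0, 30, 2)
            u = rng.normal(size=2)
            u /= np.linalg.norm(u)
            vj = vi + rng.uniform(2, 30) * u
            ei = _model(vi, u, 0, lam=rng.uniform(0, 5, 2))
            ej = _model(vj, -u, 1, lam=rng.uniform(0, 5, 2))
            assert bhattacharyya_cost(ei, ej, params) >= 0

    def test_gates_apply(self):
        params = GroupingParams(measure="bhattacharyya")
        ei = _model((0, 0), (0, 1), 0)
        ej = _model((0, 100), (0, -1), 1)
        assert bhattacharyya_cost(ei, ej, params) == SENTINEL


class TestCostMatrix:
    def test_single_curve_all_sentinel(self):
        models = endpoint_models([_vseg(0, 0, 0, 20)], npts=10)
        M = build_cost_matrix(models)
        assert (M == SENTINEL).all()

    def test_two_collinear_fragments_single_facing_pair(self):
        curves = [_vseg(5, 0, 5, 20), _vseg(5, 30, 5, 50)]
        M = build_cost_matrix(endpoint_models(curves, 10))
        sub = np.argwhere(M < SENTINEL)
        # exactly one unordered pair: end of curve 0 (idx 1) <-> start of curve 1 (idx 2)
        assert sorted(map(tuple, sub)) == [(1, 2), (2, 1)]
        assert M[1, 2] == pytest.approx(0.0, abs=1e-9)

    def test_matrix_symmetric(self):
        rng = np.random.default_rng(5)
        cfg = SceneConfig(height=200, width=200)
        curve = generate_curve(cfg, rng)
        frags = fragment_curves([curve], 3.0, (5, 15), rng)
        M = build_cost_matrix(endpoint_models(frags, 10))
        assert np.allclose(M, M.T, atol=1e-9)


class TestAssign:
    def test_two_by_two(self):
        sigma = assign(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert list(sigma) == [0, 1]

    def test_matches_brute_force(self, rng):
        from itertools import permutations

        for _ in range(50):
            n = int(rng.integers(2, 9))
            M = rng.uniform(0, 10, (n, n))
            sigma = assign(M)
            best = min(
                sum(M[i, p[i]] for i in range(n)) for p in permutations(range(n))
            )
            assert sum(M[i, sigma[i]] for i in range(n)) == pytest.approx(best)


class TestValidate:
    def test_mutual_pairs_kept(self):
        sigma = np.array([1, 0, 3, 2])
        M = np.zeros((4, 4))
        v = threshold_and_validate(sigma, M, tau=10)
        assert list(v) == [1, 0, 3, 2]

    def test_three_cycle_voided(self):
        sigma = np.array([1, 2, 0])
        v = threshold_and_validate(sigma, np.zeros((3, 3)), tau=10)
        assert list(v) == [-1, -1, -1]

    def test_costly_match_voided(self):
        sigma = np.array([1, 0])
        M = np.array([[0.0, 99.0], [99.0, 0.0]])
        v = threshold_and_validate(sigma, M, tau=10)
        assert list(v) == [-1, -1]

    def test_involution_property(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 10))
            sigma = rng.permutation(n)
            M = rng.uniform(0, 20, (n, n))
            v = threshold_and_validate(sigma, M, tau=10)
            for i, j in enumerate(v):
                if j >= 0:
                    assert v[j] == i and M[i, j] <= 10


class TestMergeCurves:
    def test_forward_forward_merge(self):
        c1 = _vseg(0, 0, 0, 9)
        c2 = _vseg(0, 20, 0, 29)
        # end of c1 (idx 1) matched to start of c2 (idx 2)
        v = np.array([-1, 2, 1, -1])
        out = merge_curves([c1, c2], v)
        assert len(out) == 1 and len(out[0]) == 20
        assert tuple(out[0][0]) == (0, 0) and tuple(out[0][-1]) == (0, 29)

    def test_reversed_storage_merge(self):
        c1 = _vseg(0, 0, 0, 9)
        c2 = _vseg(0, 29, 0, 20)  # stored right-to-left
        # end of c1 (idx 1) matched to END model of c2 (idx 3)
        v = np.array([-1, 3, -1, 1])
        out = merge_curves([c1, c2], v)
        assert len(out) == 1 and len(out[0]) == 20
        assert tuple(out[0][0]) == (0, 0) and tuple(out[0][-1]) == (0, 29)

    def test_empty_matching_is_identity(self):
        curves = [_vseg(0, 0, 0, 5), _vseg(3, 0, 3, 5)]
        out = merge_curves(curves, np.full(4, -1))
        assert len(out) == 2
        for a, b in zip(out, curves):
            assert np.array_equal(a, b)

    def test_each_input_used_exactly_once(self, rng):
        curves = [_vseg(2 * i, 0, 2 * i, 9) for i in range(4)]
        v = np.full(8, -1)
        v[1], v[2] = 2, 1  # chain curves 0-1
        out = merge_curves(curves, v)
        total = sum(len(c) for c in out)
        assert total == sum(len(c) for c in curves)
        assert len(out) == 3

    def test_cycle_broken_with_warning(self):
        c1 = _vseg(0, 0, 0, 9)
        c2 = _vseg(2, 0, 2, 9)
        # both end pairs matched: a closed ring
        v = np.array([2, 3, 0, 1])
        M = np.zeros((4, 4))
        M[1, 3] = M[3, 1] = 5.0  # costlier link
        with pytest.warns(UserWarning, match="ring"):
            out = merge_curves([c1, c2], v, M)
        assert len(out) == 1 and len(out[0]) == 20


class TestGroup:
    def test_single_curve_unchanged(self):
        cfg = SceneConfig(height=200, width=200)
        curve = generate_curve(cfg, np.random.default_rng(2))
        out = group([curve])
        assert len(out) == 1 and np.array_equal(out[0], curve)

    def test_recovers_fragmented_curve(self):
        rng = np.random.default_rng(8)
        cfg = SceneConfig(height=300, width=300)
        curve = generate_curve(cfg, rng)
        frags = fragment_curves([curve], 3.0, (5, 18), rng)
        assert len(frags) >= 2
        out = group(frags)
        assert len(out) == 1

    def test_far_parallel_curves_not_merged(self):
        c1 = _vseg(10, 0, 10, 80)
        c2 = _vseg(90, 0, 90, 80)  # separated by 80 px > dmax = 40
        out = group([c1, c2])
        assert len(out) == 2

    def test_point_conservation(self):
        rng = np.random.default_rng(21)
        cfg = SceneConfig(height=300, width=300)
        curve = generate_curve(cfg, rng)
        frags = fragment_curves([curve], 2.0, (5, 15), rng)
        out = group(frags)
        in_pts = sorted(map(tuple, np.concatenate(frags)))
        out_pts = sorted(map(tuple, np.concatenate(out)))
        assert in_pts == out_pts

    def test_curve_count_never_increases(self):
        rng = np.random.default_rng(33)
        cfg = SceneConfig(height=300, width=300)
        curve = generate_curve(cfg, rng)
        curves = fragment_curves([curve], 4.0, (5, 15), rng)
        params = GroupingParams(nit=1)
        counts = [len(curves)]
        for _ in range(4):
            curves = group(curves, params)
            counts.append(len(curves))
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestCleanup:
    def test_lmin_zero_identity(self):
        curves = [_vseg(0, 0, 0, 4), _vseg(0, 0, 0, 60)]
        assert len(cleanup(curves, 0)) == 2

    def test_short_curves_removed(self):
        curves = [_vseg(0, 0, 0, 4), _vseg(2, 0, 2, 49)]
        out = cleanup(curves, 40)
        assert len(out) == 1 and len(out[0]) == 50

    def test_negative_lmin_rejected(self):
        with pytest.raises(ValueError):
            cleanup([], -1)
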