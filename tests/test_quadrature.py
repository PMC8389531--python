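"""Clenshaw-Curtis rules, tensor grids, combination technique, moments."""

import itertools

import numpy as np
import pytest

from uqmd.quadrature import (
    SparseGridPlan,
    clenshaw_curtis_rule,
    combination_coefficients,
    grid_moments,
    interpolate,
    lagrange_basis,
    rule_size,
    sparse_quadrature,
    tensor_grid,
)


class TestRule1D:
    def test_level_zero_is_midpoint(self):
        r = clenshaw_curtis_rule(0)
        assert r.points.tolist() == [0.5]
        assert r.weights.tolist() == [1.0]

    def test_level_one_weights_are_simpson(self):
        r = clenshaw_curtis_rule(1)
        np.testing.assert_allclose(r.points, [0.0, 0.5, 1.0], atol=1e-15)
        np.testing.assert_allclose(r.weights, [1 / 6, 2 / 3, 1 / 6], atol=1e-15)

    @pytest.mark.parametrize("level,size", [(0, 1), (1, 3), (2, 5), (3, 9), (5, 33)])
    def test_growth_rule(self, level, size):
        assert rule_size(level) == size
        assert clenshaw_curtis_rule(level).size == size

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            clenshaw_curtis_rule(-1)

    @pytest.mark.parametrize("level", range(0, 6))
    def test_weights_sum_to_one(self, level):
        assert abs(clenshaw_curtis_rule(level).weights.sum() - 1.0) < 1e-12

    @pytest.mark.parametrize("level", range(0, 6))
    def test_points_increasing_symmetric(self, level):
        p = clenshaw_curtis_rule(level).points
        assert np.all(np.diff(p) > 0)
        np.testing.assert_allclose(p + p[::-1], 1.0, rtol=0, atol=2.3e-16)

    @pytest.mark.parametrize("level", range(0, 5))
    def test_nesting_is_exact(self, level):
        coarse = set(clenshaw_curtis_rule(level).points.tolist())
        fine = set(clenshaw_curtis_rule(level + 1).points.tolist())
        assert coarse <= fine  # bitwise set inclusion, no tolerance

    @pytest.mark.parametrize("level", range(0, 5))
    def test_polynomial_exactness(self, level):
        r = clenshaw_curtis_rule(level)
        for k in range(r.size):
            exact = 1.0 / (k + 1)  # integral of x^k on [0, 1]
            assert abs(r.weights @ r.points**k - exact) < 1e-10


class TestLagrangeBasis:
    def test_cardinality(self):
        r = clenshaw_curtis_rule(1)
        assert lagrange_basis(r, 1, 0.5) == pytest.approx(1.0)
        assert lagrange_basis(r, 0, 0.5) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        r = clenshaw_curtis_rule(1)
        # (0.25-0.5)(0.25-1) / ((0-0.5)(0-1)) = 0.375
        assert lagrange_basis(r, 0, 0.25) == pytest.approx(0.375)

    def test_index_out_of_range(self):
        r = clenshaw_curtis_rule(1)
        with pytest.raises(ValueError):
            lagrange_basis(r, 3, 0.5)


class TestTensorGrid:
    def test_level22_has_25_points(self):
        assert tensor_grid((2, 2)).size == 25

    def test_all_midpoint(self):
        g = tensor_grid((0, 0, 0))
        assert g.points == [(0.5, 0.5, 0.5)]

    def test_mixed_orders(self):
        g = tensor_grid((1, 0))
        assert g.size == 3
        assert all(p[1] == 0.5 for p in g.points)

    @pytest.mark.parametrize("index", [(0,), (2, 1), (1, 0, 2)])
    def test_weights_sum_to_one(self, index):
        assert abs(tensor_grid(index).weights.sum() - 1.0) < 1e-12


def random_admissible_set(rng, d, n_extra):
    """Grow a random downward-closed index set by admissible accretion."""
    from uqmd.adaptive import admissible_candidates

    s = {(0,) * d}
    for _ in range(n_extra):
        cands = sorted(admissible_candidates(s))
        s.add(cands[rng.integers(len(cands))])
    return s


class TestCombinationCoefficients:
    def test_single_index(self):
        assert combination_coefficients([(0, 0)]) == {(0, 0): 1}

    def test_l_shape(self):
        c = combination_coefficients([(0, 0), (1, 0), (0, 1)])
        assert c == {(0, 0): -1, (1, 0): 1, (0, 1): 1}

    def test_full_box_telescopes_to_corner(self):
        c = combination_coefficients([(0, 0), (1, 0), (0, 1), (1, 1)])
        assert c[(1, 1)] == 1
        assert all(v == 0 for l, v in c.items() if l != (1, 1))

    def test_non_admissible_rejected(self):
        with pytest.raises(ValueError):
            combination_coefficients([(0, 0), (1, 1)])

    @pytest.mark.parametrize("seed", range(8))
    def test_coefficients_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        s = random_admissible_set(rng, d=rng.integers(1, 4), n_extra=6)
        assert sum(combination_coefficients(s).values()) == 1


class TestInterpolate:
    def test_partition_of_unity(self):
        rng = np.random.default_rng(0)
        s = random_admissible_set(rng, 3, 5)
        plan = SparseGridPlan.from_index_set(s)
        ones = {p: 1.0 for p in plan.unique_points}
        for x in rng.uniform(size=(100, 3)):
            assert interpolate(plan, ones, x) == pytest.approx(1.0, abs=1e-12)

    def test_linear_function_reproduced(self):
        plan = SparseGridPlan.from_index_set([(0, 0), (1, 0), (0, 1)])
        vals = {p: p[0] for p in plan.unique_points}
        assert interpolate(plan, vals, (0.25, 0.9)) == pytest.approx(0.25)

    def test_collocation_values_reproduced(self):
        rng = np.random.default_rng(1)
        s = random_admissible_set(rng, 2, 5)
        plan = SparseGridPlan.from_index_set(s)
        vals = {p: float(rng.normal()) for p in plan.unique_points}
        for p in plan.unique_points:
            assert interpolate(plan, vals, p) == pytest.approx(vals[p], abs=1e-9)

    def test_full_box_equals_single_tensor_interpolant(self):
        L, d = 2, 2
        full = list(itertools.product(range(L + 1), repeat=d))
        plan = SparseGridPlan.from_index_set(full)
        f = lambda p: np.sin(3 * p[0]) + p[1] ** 2
        vals = {p: f(p) for p in plan.unique_points}
        corner = tensor_grid((L,) * d)
        rng = np.random.default_rng(2)
        for x in rng.uniform(size=(20, d)):
            # direct tensor-product interpolation at the corner index
            from uqmd.quadrature import _basis_row

            rows = [_basis_row(r, xi) for r, xi in zip(corner.rules, x)]
            fv = np.array([f(p) for p in corner.points]).reshape(corner.shape)
            direct = fv
            for row in rows:
                direct = np.tensordot(row, direct, axes=([0], [0]))
            assert interpolate(plan, vals, x) == pytest.approx(float(direct), abs=1e-12)

    def test_missing_value_raises(self):
        plan = SparseGridPlan.from_index_set([(0,), (1,)])
        with pytest.raises(KeyError):
            interpolate(plan, {(0.5,): 1.0}, (0.3,))


class TestGridMoments:
    def test_constant(self):
        plan = SparseGridPlan.from_index_set([(0, 0)])
        mean, var = grid_moments(plan, {p: 3.0 for p in plan.unique_points})
        assert (mean, var) == (3.0, 0.0)

    def test_uniform_linear(self):
        plan = SparseGridPlan.from_index_set([(0,), (1,)])
        vals = {p: p[0] for p in plan.unique_points}
        mean, var = grid_moments(plan, vals)
        assert mean == pytest.approx(0.5)
        assert var == pytest.approx(1 / 12)

    def test_sum_of_uniforms(self):
        full = [(0, 0), (1, 0), (0, 1), (1, 1)]
        plan = SparseGridPlan.from_index_set(full)
        vals = {p: p[0] + p[1] for p in plan.unique_points}
        mean, var = grid_moments(plan, vals)
        assert mean == pytest.approx(1.0)
        assert var == pytest.approx(1 / 6)

    def test_variance_against_monte_carlo(self):
        # surrogate is exact for this cubic on a level-2 full box, so the
        # plan variance must agree with plain MC on the true function
        full = list(itertools.product(range(3), repeat=2))
        plan = SparseGridPlan.from_index_set(full)
        f = lambda p: p[0] ** 2 + 0.5 * p[0] * p[1] - p[1] ** 3
        vals = {p: f(p) for p in plan.unique_points}
        _, var = grid_moments(plan, vals)
        rng = np.random.default_rng(3)
        samples = np.array([f(p) for p in rng.uniform(size=(10**6, 2))])
        mc_var = samples.var(ddof=1)
        centered = (samples - samples.mean()) ** 2
        se = centered.std(ddof=1) / np.sqrt(samples.size)
        assert abs(var - mc_var) < 3 * se


class TestSerialization:
    def test_plan_json_round_trip(self):
        plan = SparseGridPlan.from_index_set([(0, 0), (1, 0), (0, 1), (1, 1), (2, 0)])
        clone = SparseGridPlan.from_json(plan.to_json())
        assert clone.index_set == plan.index_set
        assert clone.coefficients == plan.coefficients
        assert clone.unique_points == plan.unique_points

    def test_points_dataframe_columns(self):
        plan = SparseGridPlan.from_index_set([(0, 0), (1, 0)])
        df = plan.points_dataframe(["temperature", "cutoff"])
        assert list(df.columns) == ["temperature", "cutoff"]
        assert len(df) == plan.n_points
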