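"""Hypergeometric forward model, burden inversion and spread summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mpmburden import (
    BurdenDistribution,
    SubSurfaceGrid,
    build_forward_matrix,
    hypergeom_pmf,
    invert_burden,
    residual_probability,
    spread_fraction,
    spread_quantile,
    spread_quantiles,
    survival_function,
)


class TestHypergeomPmf:
    def test_no_affected_subsurfaces(self):
        assert hypergeom_pmf(0, 4000, 0, 13) == 1.0

    def test_saturated(self):
        assert hypergeom_pmf(13, 4000, 4000, 13) == 1.0

    def test_product_formula_oracle(self):
        # P(x=0 | N=4000, K=400, n=13) = prod_{i=0..12} (3600-i)/(4000-i)
        oracle = np.prod([(3600 - i) / (4000 - i) for i in range(13)])
        assert hypergeom_pmf(0, 4000, 400, 13) == pytest.approx(oracle, rel=1e-12)

    @pytest.mark.parametrize("x,N,K,n", [(0, 10, 11, 3), (0, 10, 2, 11), (4, 10, 2, 3)])
    def test_domain_errors(self, x, N, K, n):
        with pytest.raises(ValueError):
            hypergeom_pmf(x, N, K, n)


class TestForwardMatrix:
    def test_columns_stochastic_at_reference_size(self, H4000):
        sums = H4000.values.sum(axis=0)
        assert np.max(np.abs(sums - 1.0)) < 1e-10

    def test_extreme_columns_are_point_masses(self, H4000):
        np.testing.assert_allclose(H4000.values[:, 0], np.eye(14)[0], atol=1e-14)
        np.testing.assert_allclose(H4000.values[:, -1], np.eye(14)[13], atol=1e-14)

    def test_support_zeros(self, H_tiny):
        # x cannot exceed K, nor can misses exceed N-K
        assert H_tiny.values[2, 1] == 0.0  # x=2 > K=1
        assert H_tiny.values[0, 5] == 0.0  # 3 misses impossible with N-K=1

    def test_more_draws_than_subsurfaces_rejected(self, tiny_grid):
        with pytest.raises(ValueError):
            build_forward_matrix(tiny_grid, n_draws=7)


class TestInversion:
    def test_point_mass_at_zero_inverts_exactly(self, H4000):
        burden = invert_burden(np.eye(14)[0], H4000)
        assert burden.p[0] == pytest.approx(1.0, abs=1e-6)
        assert residual_probability(burden) == pytest.approx(0.0, abs=1e-6)

    def test_forward_then_invert_recovers_tail_probability(self, H4000):
        p_true = np.zeros(4001)
        p_true[0], p_true[500] = 0.3, 0.7
        q = H4000.values @ p_true
        burden = invert_burden(q, H4000)
        assert burden.residual_fit <= 1e-10
        assert residual_probability(burden) == pytest.approx(0.7, abs=0.02)

    def test_matches_brute_force_simplex_grid_on_tiny_instance(self, H_tiny):
        """Exhaustive grid over the simplex (step 0.05) on N=6, n=3."""
        H = H_tiny.values
        q = np.array([0.55, 0.25, 0.15, 0.05])
        best = np.inf
        units = 20  # 1 / 0.05
        for cuts in itertools.combinations(range(units + 6), 6):
            parts = np.diff((-1,) + cuts + (units + 6,)) - 1
            p = np.asarray(parts, dtype=float) / units
            best = min(best, float(np.sum((H @ p - q) ** 2)))
        burden = invert_burden(q, H_tiny)
        assert burden.residual_fit <= best + 1e-12
        assert best - burden.residual_fit <= 0.05**2

    def test_deterministic_re_solve(self, H4000, ref_q):
        a = invert_burden(ref_q, H4000)
        b = invert_burden(ref_q, H4000)
        np.testing.assert_array_equal(a.p, b.p)
        assert residual_probability(a) == residual_probability(b)

    def test_rejects_malformed_q(self, H4000):
        with pytest.raises(ValueError):
            invert_burden(np.full(14, 0.5), H4000)
        with pytest.raises(ValueError):
            invert_burden(np.ones(5) / 5, H4000)


class TestSurvivalAndQuantiles:
    def test_point_mass_at_zero_has_null_survival(self):
        burden = BurdenDistribution(p=np.eye(7)[0], residual_fit=0.0)
        S = survival_function(burden)
        assert np.all(S == 0.0)
        assert spread_quantile(S, 0.5) == 0

    def test_three_point_enumeration(self):
        burden = BurdenDistribution(p=np.array([0.5, 0.3, 0.2]), residual_fit=0.0)
        np.testing.assert_allclose(survival_function(burden), [0.5, 0.2, 0.0])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=50))
    def test_monotone_and_tail_sum_identity(self, weights):
        p = np.asarray(weights) / np.sum(weights)
        burden = BurdenDistribution(p=p, residual_fit=0.0)
        S = survival_function(burden)
        assert np.all(np.diff(S) <= 1e-15)
        assert S[-1] == 0.0
        # E[K] = sum_{n>=0} P(K > n)
        assert S.sum() == pytest.approx(burden.mean(), abs=1e-9)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=50))
    def test_quantiles_monotone_in_alpha(self, weights):
        p = np.asarray(weights) / np.sum(weights)
        S = survival_function(BurdenDistribution(p=p, residual_fit=0.0))
        alphas = [0.05, 0.25, 0.5, 0.75, 0.95]
        values = [spread_quantile(S, a) for a in alphas]
        assert all(b <= a for a, b in zip(values, values[1:]))

    def test_alpha_domain(self):
        S = survival_function(BurdenDistribution(p=np.eye(3)[0], residual_fit=0.0))
        for alpha in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                spread_quantile(S, alpha)


class TestSpreadFraction:
    @pytest.mark.parametrize(
        "n, expected", [(69, 0.01725), (105, 0.02625), (0, 0.0)]
    )
    def test_reference_grid_fractions(self, grid4000, n, expected):
        assert spread_fraction(n, grid4000) == pytest.approx(expected, abs=1e-12)

    def test_rounding_to_printed_percentages(self, grid4000):
        assert round(100 * spread_fraction(69, grid4000), 1) == 1.7
        assert round(100 * spread_fraction(105, grid4000), 2) == 2.62

    def test_out_of_range(self, grid4000):
        with pytest.raises(ValueError):
            spread_fraction(4001, grid4000)
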