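"""Core model: probabilities, surfaces, information, marginal likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from scipy.special import logit

from bifactor_grm import (
    ItemParams,
    QuadratureGrid,
    boundary_probability,
    category_probabilities,
    evaluate_surface,
    expected_item_score,
    inflexion_line,
    item_information,
    marginal_information_curve,
    marginal_log_likelihood,
    reverse_coded_params,
)
from bifactor_grm.model import ParameterError

from conftest import item_params_strategy, theta_coord


def make_item(a_g, a_s, intercepts, item_id="it"):
    return ItemParams(item_id, a_g, a_s, np.asarray(intercepts, float))


class TestBoundaryProbability:
    @pytest.mark.parametrize(
        "a_g,a_s,d,theta,expected",
        [
            (1.0, 0.0, [0.0], (0.0, 0.0), 0.5),
            (1.0, 1.0, [-1.0], (1.0, 1.0), 0.7310586),
            (2.0, 1.0, [0.5], (-0.5, 0.0), 0.3775407),  # logistic(-0.5)
        ],
    )
    def test_logistic_closed_form(self, a_g, a_s, d, theta, expected):
        p = make_item(a_g, a_s, d)
        assert boundary_probability(p, 1, theta) == pytest.approx(expected, abs=1e-6)

    def test_limits_and_monotonicity(self):
        p = make_item(1.0, 1.0, [-2.0])
        assert boundary_probability(p, 1, (40.0, 0.0)) == pytest.approx(1.0, abs=1e-12)
        probs = [boundary_probability(p, 1, (t, 0.0)) for t in np.linspace(-6, 6, 25)]
        assert np.all(np.diff(probs) > 0)

    def test_invalid_boundary_raises(self):
        p = make_item(1.0, 0.0, [1.0, -1.0])
        with pytest.raises(IndexError):
            boundary_probability(p, 3, (0.0, 0.0))
        with pytest.raises(IndexError):
            boundary_probability(p, 0, (0.0, 0.0))


class TestCategoryProbabilities:
    def test_binary_item_splits_at_boundary(self):
        p = make_item(1.0, 0.0, [0.0])
        assert category_probabilities(p, (0.0, 0.0)) == pytest.approx([0.5, 0.5])

    def test_three_category_example(self):
        p = make_item(1.0, 0.0, [1.0, -1.0])
        probs = category_probabilities(p, (0.0, 0.0))
        assert probs == pytest.approx([0.2689, 0.4622, 0.2689], abs=2e-4)

    def test_nondecreasing_intercepts_rejected(self):
        with pytest.raises(ParameterError):
            make_item(1.0, 0.0, [-1.0, 1.0])
        with pytest.raises(ParameterError):
            make_item(1.0, 0.0, [1.0, 1.0])

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(params=item_params_strategy(), tg=theta_coord, ts=theta_coord)
    def test_simplex_property(self, params, tg, ts):
        """Probabilities are non-negative and sum to one everywhere."""
        probs = category_probabilities(params, (tg, ts))
        assert np.all(probs >= 0)
        assert abs(probs.sum() - 1.0) <= 1e-12

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(params=item_params_strategy(signed_slopes=False), ts=theta_coord)
    def test_extreme_categories_monotone_in_general_trait(self, params, ts):
        grid = np.linspace(-6, 6, 13)
        first = [category_probabilities(params, (t, ts))[0] for t in grid]
        last = [category_probabilities(params, (t, ts))[-1] for t in grid]
        assert np.all(np.diff(first) <= 1e-15)
        assert np.all(np.diff(last) >= -1e-15)


class TestExpectedScore:
    def test_symmetric_item_at_origin(self):
        p = make_item(1.0, 0.0, [1.0, -1.0])
        assert expected_item_score(p, (0.0, 0.0)) == pytest.approx(2.0)

    def test_weighted_sum_example(self):
        p = make_item(1.0, 0.0, [1.0, -1.0])
        assert expected_item_score(p, (1.0, 0.0)) == pytest.approx(2.3808, abs=1e-4)

    def test_bounds_and_limit(self):
        p = make_item(1.5, 0.8, [2.0, 0.0, -2.0])
        assert expected_item_score(p, (50.0, 50.0)) == pytest.approx(4.0, abs=1e-9)
        for t in np.random.default_rng(0).uniform(-6, 6, size=(20, 2)):
            val = expected_item_score(p, tuple(t))
            assert 1.0 <= val <= 4.0


class TestInflexionLine:
    def test_points_on_line_have_half_probability(self):
        p = make_item(1.0, 1.0, [0.0])
        a_g, a_s, d = inflexion_line(p, 1)
        assert (a_g, a_s, d) == (1.0, 1.0, 0.0)
        assert boundary_probability(p, 1, (2.0, -2.0)) == pytest.approx(0.5, abs=1e-12)

    def test_line_solves_linear_equation(self):
        p = make_item(2.0, 0.0, [-1.0])
        a_g, a_s, d = inflexion_line(p, 1)
        theta_g = -d / a_g  # a_s = 0 so the line is theta_g = 0.5
        assert theta_g == pytest.approx(0.5)
        assert boundary_probability(p, 1, (theta_g, 3.3)) == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_when_both_slopes_zero(self):
        p = make_item(0.0, 0.0, [1.0])
        with pytest.raises(ParameterError):
            inflexion_line(p, 1)


class TestItemInformation:
    def test_zero_slopes_give_zero_matrix(self):
        p = make_item(0.0, 0.0, [1.0, -1.0])
        assert np.allclose(item_information(p, (0.3, -0.8)), 0.0)

    def test_single_factor_concentrates_information(self):
        p = make_item(1.7, 0.0, [0.5])
        info = item_information(p, (0.2, 1.1))
        assert info[0, 0] > 0
        assert info[0, 1] == info[1, 0] == info[1, 1] == 0

    def test_matches_expected_negative_hessian(self, rng):
        """Fisher information equals E[-H log P] by finite differences."""
        h = 1e-5
        for _ in range(25):
            k = rng.integers(2, 8)
            d = np.sort(rng.uniform(-3, 3, size=k - 1))[::-1]
            d += np.linspace(0.3 * (k - 1), 0, k - 1)  # enforce strict gaps
            p = make_item(rng.uniform(-2.5, 2.5), rng.uniform(-2.5, 2.5), d)
            theta = rng.uniform(-3, 3, size=2)

            def logp(tg, ts):
                return np.log(category_probabilities(p, (tg, ts)))

            probs = category_probabilities(p, tuple(theta))
            hess = np.empty((2, 2))
            f0 = logp(*theta)
            hess_cc = np.empty((2, 2, len(probs)))
            for a in range(2):
                for b in range(2):
                    e_a = np.array([h, 0.0]) if a == 0 else np.array([0.0, h])
                    e_b = np.array([h, 0.0]) if b == 0 else np.array([0.0, h])
                    fpp = logp(*(theta + e_a + e_b))
                    fpm = logp(*(theta + e_a - e_b))
                    fmp = logp(*(theta - e_a + e_b))
                    fmm = logp(*(theta - e_a - e_b))
                    hess_cc[a, b] = (fpp - fpm - fmp + fmm) / (4 * h * h)
            expected_neg_hess = -np.einsum("c,abc->ab", probs, hess_cc)
            assert np.allclose(item_information(p, tuple(theta)), expected_neg_hess, atol=1e-4)


class TestMarginalInformationCurve:
    def test_zero_slope_is_flat_zero(self):
        curve = marginal_information_curve(0.0, [1.0, -1.0], np.linspace(-4, 4, 33))
        assert np.allclose(curve, 0.0)

    def test_symmetric_intercepts_give_symmetric_curve(self):
        axis = np.linspace(-5, 5, 41)
        curve = marginal_information_curve(1.3, [2.0, 0.0, -2.0], axis)
        assert np.allclose(curve, curve[::-1], atol=1e-12)

    def test_dichotomous_closed_form(self):
        """K=2 reduces to a^2 P* (1-P*)."""
        a, d = 1.7, -0.4
        axis = np.linspace(-4, 4, 21)
        pstar = 1 / (1 + np.exp(-(a * axis + d)))
        assert np.allclose(
            marginal_information_curve(a, [d], axis), a * a * pstar * (1 - pstar), atol=1e-12
        )


class TestSurfaces:
    def test_pointwise_consistency_with_scalar_ops(self):
        p = make_item(1.4, 0.9, [1.5, 0.0, -1.5])
        sg = evaluate_surface(p, "expected_score", [0.7], [-0.3])
        assert sg.values[0, 0] == pytest.approx(expected_item_score(p, (0.7, -0.3)))
        sg = evaluate_surface(p, "category_probability", [0.7], [-0.3], category=2)
        assert sg.values[0, 0] == pytest.approx(category_probabilities(p, (0.7, -0.3))[1])
        sg = evaluate_surface(p, "information", [0.7], [-0.3])
        a = np.array([1.4, 0.9])
        v = a / np.linalg.norm(a)
        assert sg.values[0, 0] == pytest.approx(v @ item_information(p, (0.7, -0.3)) @ v)

    def test_compensatory_structure_of_expected_score(self):
        """A deficit on one trait is offset by surplus on the other: the top
        score is reachable with low general/high specific and vice versa, and
        the surface is constant along the compensation line."""
        p = make_item(2.0, 1.8, [2.0, 0.7, -0.7, -2.0])
        K = p.n_categories
        assert expected_item_score(p, (6.0, -2.0)) > 0.95 * K  # high general compensates
        assert expected_item_score(p, (-2.0, 6.0)) > 0.95 * K  # high specific compensates
        assert expected_item_score(p, (-6.0, -6.0)) < 1.05
        # exact compensation: moving along a_g*dt1 + a_s*dt2 = 0 changes nothing
        base = expected_item_score(p, (0.5, -1.0))
        shifted = expected_item_score(p, (0.5 - 1.8, -1.0 + 2.0))
        assert shifted == pytest.approx(base, abs=1e-12)
        sg = evaluate_surface(p, "expected_score", np.linspace(-6, 6, 25), np.linspace(-6, 6, 25))
        assert np.all(sg.values >= 1.0) and np.all(sg.values <= K)

    def test_first_category_probability_decreases_along_both_axes(self):
        p = make_item(1.8, 1.2, [2.0, 0.0, -2.0])
        sg = evaluate_surface(p, "category_probability", np.linspace(-5, 5, 21),
                              np.linspace(-5, 5, 21), category=1)
        assert np.all(np.diff(sg.values, axis=0) <= 1e-15)
        assert np.all(np.diff(sg.values, axis=1) <= 1e-15)
        assert np.all(sg.values >= 0) and np.all(sg.values <= 1)

    def test_unknown_kind_rejected(self):
        p = make_item(1.0, 1.0, [0.0])
        with pytest.raises(ValueError, match="kind"):
            evaluate_surface(p, "reliability", [0.0], [0.0])

    def test_information_surface_nonnegative(self):
        p = make_item(2.4, 1.1, [3.0, 1.0, -1.0, -3.0])
        sg = evaluate_surface(p, "information", np.linspace(-6, 6, 17), np.linspace(-6, 6, 17))
        assert np.all(sg.values >= 0)


class TestReverseCodingSymmetry:
    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(params=item_params_strategy(), tg=theta_coord, ts=theta_coord)
    def test_category_probabilities_reindex_exactly(self, params, tg, ts):
        """x -> K+1-x with the mapped parameters flips the probability vector."""
        flipped = reverse_coded_params(params)
        p_orig = category_probabilities(params, (tg, ts))
        p_flip = category_probabilities(flipped, (tg, ts))
        assert np.allclose(p_orig, p_flip[::-1], atol=1e-12)

    def test_double_map_is_identity(self):
        p = make_item(1.3, -0.7, [2.0, -0.5, -1.5])
        q = reverse_coded_params(reverse_coded_params(p))
        assert q.slope_general == p.slope_general
        assert q.slope_specific == p.slope_specific
        assert np.allclose(q.intercepts, p.intercepts)


class TestMarginalLogLikelihood:
    def grid(self):
        return QuadratureGrid.gauss_hermite(21)

    def test_zero_slopes_collapse_to_intercept_multinomial(self):
        """With zero slopes the integrals vanish and the likelihood is closed-form."""
        d = np.array([1.2, -0.3])
        p = make_item(0.0, 0.0, d)
        probs = category_probabilities(p, (0.0, 0.0))
        codes = np.array([[0], [1], [1], [2], [0]])
        ll = marginal_log_likelihood([p], [0], codes, self.grid())
        expected = sum(np.log(probs[c]) for c in codes[:, 0])
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_flat_extra_item_shifts_by_n_log_k(self):
        """An uninformative uniform item contributes exactly n*log(1/K)."""
        rng = np.random.default_rng(3)
        base = [make_item(1.5, 0.8, [1.0, -1.0], "a"), make_item(1.2, 1.1, [0.5, -0.5], "b")]
        codes = rng.integers(0, 3, size=(40, 2))
        ll0 = marginal_log_likelihood(base, [0, 0], codes, self.grid())
        K = 4
        flat_d = logit(1 - np.arange(1, K) / K)  # uniform-implied intercepts
        flat = make_item(0.0, 0.0, flat_d, "flat")
        codes3 = np.column_stack([codes, rng.integers(0, K, size=40)])
        ll1 = marginal_log_likelihood(base + [flat], [0, 0, 0], codes3, self.grid())
        assert ll1 - ll0 == pytest.approx(40 * np.log(1.0 / K), abs=1e-9)

    def test_monte_carlo_oracle_toy_battery(self):
        """Quadrature likelihood agrees with brute-force 2-D Monte Carlo."""
        items = [
            make_item(1.6, 0.9, [1.0, -0.8], "a"),
            make_item(1.1, 1.3, [0.4], "b"),
            make_item(0.8, 0.5, [1.5, 0.2, -1.2], "c"),
        ]
        rng = np.random.default_rng(42)
        n, n_draws = 15, 200_000
        codes = np.column_stack(
            [rng.integers(0, p.n_categories, size=n) for p in items]
        )
        ll_quad = marginal_log_likelihood(items, [0, 0, 0], codes, self.grid())

        tg = rng.standard_normal(n_draws)
        ts = rng.standard_normal(n_draws)
        total, var_log = 0.0, 0.0
        for i in range(n):
            lik = np.ones(n_draws)
            for j, p in enumerate(items):
                z = p.slope_general * tg[:, None] + p.slope_specific * ts[:, None] + p.intercepts
                pstar = 1 / (1 + np.exp(-z))
                cum = np.hstack([np.ones((n_draws, 1)), pstar, np.zeros((n_draws, 1))])
                pcat = cum[:, :-1] - cum[:, 1:]
                lik *= pcat[:, codes[i, j]]
            est = lik.mean()
            se = lik.std(ddof=1) / np.sqrt(n_draws)
            total += np.log(est)
            var_log += (se / est) ** 2
        assert abs(ll_quad - total) <= 3.0 * np.sqrt(var_log)

    def test_reverse_coded_data_and_params_invariant(self):
        items = [make_item(1.5, 0.9, [1.1, -0.4], "a"), make_item(1.0, -0.6, [0.3], "b")]
        rng = np.random.default_rng(9)
        codes = np.column_stack([rng.integers(0, p.n_categories, size=30) for p in items])
        ll = marginal_log_likelihood(items, [0, 0], codes, self.grid())
        flipped = [reverse_coded_params(p) for p in items]
        codes_flip = np.column_stack(
            [(p.n_categories - 1) - codes[:, j] for j, p in enumerate(items)]
        )
        ll_flip = marginal_log_likelihood(flipped, [0, 0], codes_flip, self.grid())
        assert ll_flip == pytest.approx(ll, abs=1e-8)

    def test_out_of_range_code_rejected(self):
        p = make_item(1.0, 0.0, [0.0])
        with pytest.raises(ValueError, match="out of range"):
            marginal_log_likelihood([p], [0], np.array([[3]]), self.grid())


class TestQuadrature:
    def test_normalised_and_symmetric(self):
        g = QuadratureGrid.gauss_hermite(21)
        assert g.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(g.weights > 0)
        assert np.allclose(g.nodes, -g.nodes[::-1])
        # integrates low-order moments of N(0,1) exactly
        assert g.nodes @ g.weights == pytest.approx(0.0, abs=1e-12)
        assert (g.nodes**2) @ g.weights == pytest.approx(1.0, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            QuadratureGrid.gauss_hermite(3)
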