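"""Per-item resource optimization, regime thresholds, allocation policies."""

import numpy as np
import pytest
from scipy.optimize import minimize

from rrwm import (
    AllocationPolicy,
    CostSpec,
    ModelParams,
    allocate_display,
    expected_behavioral_cost,
    optimal_resource,
    p0_bisect,
    thresholds,
    total_resource_curve,
)
from rrwm.allocator import optimal_resource_many

from _oracles import brute_force_optimal_resource


def power_cost_fn(beta):
    return lambda eps: np.abs(eps) ** beta


@pytest.fixture(scope="module")
def quad_params():
    return ModelParams(lambda_=0.01, tau=0.0, cost=CostSpec("power", 2.0))


class TestOptimalResource:
    def test_zero_probability_invests_nothing(self, quad_params):
        assert optimal_resource(0.0, quad_params) == 0.0

    def test_no_neural_cost_is_unbounded(self):
        params = ModelParams(lambda_=0.0, tau=0.0, cost=CostSpec("power", 2.0))
        assert optimal_resource(0.5, params) == np.inf
        assert optimal_resource(0.0, params) == 0.0

    def test_brute_force_oracle(self, quad_params):
        J_ref, _ = brute_force_optimal_resource(0.25, 0.01, 0.0, power_cost_fn(2.0))
        assert optimal_resource(0.25, quad_params) == pytest.approx(J_ref, rel=5e-3)

    def test_brute_force_oracle_variable_precision(self):
        params = ModelParams(lambda_=0.0088, tau=7.4, cost=CostSpec("power", 0.61))
        J_ref, _ = brute_force_optimal_resource(0.25, 0.0088, 7.4, power_cost_fn(0.61))
        assert optimal_resource(0.25, params) == pytest.approx(J_ref, rel=5e-3)

    def test_monotone_in_probing_probability(self, quad_params):
        js = optimal_resource_many(np.array([0.125, 0.25, 0.5]), quad_params)
        assert js[0] <= js[1] <= js[2]

    def test_grid_refinement_close_to_exact(self, e6_params):
        ps = np.array([0.125, 0.25, 0.5, 1.0])
        exact = optimal_resource_many(ps, e6_params, refine="exact")
        fast = optimal_resource_many(ps, e6_params, refine="grid")
        assert fast == pytest.approx(exact, rel=1e-2)

    def test_heavier_neural_cost_weakly_lowers_investment(self, e6_params):
        doubled = ModelParams(lambda_=2 * e6_params.lambda_, tau=e6_params.tau,
                              cost=e6_params.cost)
        for p in (0.1, 0.3, 1.0):
            assert optimal_resource(p, doubled) <= optimal_resource(p, e6_params) + 1e-9

    def test_invalid_probability_rejected(self, quad_params):
        with pytest.raises(ValueError):
            optimal_resource(1.5, quad_params)


class TestThresholds:
    def test_equal_precision_never_ignores_items(self, quad_params):
        th = thresholds(quad_params)
        assert th.p0 == 0.0
        # bisection cross-check: even the smallest probed p warrants encoding
        assert p0_bisect(quad_params) == pytest.approx(1e-6)

    def test_no_neural_cost_always_unbounded(self):
        params = ModelParams(lambda_=0.0, tau=0.0, cost=CostSpec("power", 2.0))
        th = thresholds(params)
        assert th.p0 == 0.0 and th.p_inf == 0.0

    @pytest.mark.parametrize("lam,tau,beta", [(0.01, 20.0, 2.0), (0.0088, 7.4, 0.61)])
    def test_variable_precision_positive_threshold(self, lam, tau, beta):
        params = ModelParams(lambda_=lam, tau=tau, cost=CostSpec("power", beta))
        th = thresholds(params)
        pb = p0_bisect(params)
        assert pb > 0.001
        # the ratio form (continuous-mixture boundary derivative) and the
        # bisection probe of the discretized model agree up to the
        # discretization bias
        assert th.p0 == pytest.approx(pb, rel=0.05, abs=1e-3)

    def test_ordering(self, e6_params):
        th = thresholds(e6_params)
        assert 0.0 <= th.p0 <= th.p_inf

    def test_regime_structure_along_p(self):
        # zero below p0, then finite and nondecreasing (Fig-1-style sweep)
        params = ModelParams(lambda_=0.0088, tau=7.4, cost=CostSpec("power", 0.61))
        p0 = p0_bisect(params)
        ps = np.linspace(1e-4, 1.0, 60)
        js = optimal_resource_many(ps, params, refine="grid")
        assert np.all(js[ps < p0 - 1e-3] == 0.0)
        pos = js[ps > p0 + 1e-3]
        assert np.all(pos > 0)
        assert np.all(np.diff(pos) >= -1e-6 * np.maximum(pos[:-1], 1.0))


class TestAllocateDisplay:
    def test_rational_equal_probabilities_equal_split(self, e6_params):
        policy = AllocationPolicy("rational")
        J = allocate_display([0.25] * 4, policy, e6_params)
        assert np.allclose(J, J[0]) and J[0] > 0

    def test_emrich_proportionality(self, quad_params):
        policy = AllocationPolicy("emrich_proportional", J_total=8.0)
        J = allocate_display([0.75, 0.25], policy, quad_params)
        assert J.tolist() == [6.0, 2.0]

    def test_fixed_equal_and_power_law(self, quad_params):
        J = allocate_display([0.25] * 4, AllocationPolicy("fixed_equal", J_total=8.0),
                             quad_params)
        assert J.tolist() == [2.0] * 4
        J = allocate_display([0.25] * 4, AllocationPolicy("power_law", J1=12.0, a=1.0),
                             quad_params)
        assert J.tolist() == [3.0] * 4

    def test_nonparametric_lookup_and_miss(self, quad_params):
        policy = AllocationPolicy("nonparametric", table=((0.25, 4.0), (0.5, 9.0)))
        J = allocate_display([0.5, 0.25], policy, quad_params)
        assert J.tolist() == [9.0, 4.0]
        with pytest.raises(KeyError):
            allocate_display([0.1], policy, quad_params)

    def test_bays_equal_probabilities_equal_split(self, e6_params):
        policy = AllocationPolicy("bays_fixed_total", J_total=12.0)
        J = allocate_display([0.25] * 4, policy, e6_params)
        assert J == pytest.approx(np.full(4, 3.0), rel=1e-3)

    def test_bays_matches_constrained_optimizer(self, e6_params):
        # independent oracle: SLSQP on the same constrained problem
        p = np.array([0.5, 1 / 6, 1 / 6, 1 / 6])
        J_total = 10.0
        policy = AllocationPolicy("bays_fixed_total", J_total=J_total)
        J_pkg = allocate_display(p, policy, e6_params)

        def obj(J):
            return sum(pi * expected_behavioral_cost(max(j, 0.0), e6_params.tau,
                                                     e6_params.cost)
                       for pi, j in zip(p, J))

        res = minimize(obj, x0=np.full(4, J_total / 4), method="SLSQP",
                       bounds=[(0, J_total)] * 4,
                       constraints=[{"type": "eq", "fun": lambda J: J.sum() - J_total}],
                       options={"maxiter": 200, "ftol": 1e-12})
        assert res.success
        assert J_pkg == pytest.approx(res.x, rel=0.01, abs=0.02)
        assert J_pkg.sum() == pytest.approx(J_total, rel=1e-9)

    def test_bays_given_rational_total_reproduces_rational_split(self, e6_params):
        p = np.array([0.5, 1 / 6, 1 / 6, 1 / 6])
        J_rat = allocate_display(p, AllocationPolicy("rational"), e6_params)
        policy = AllocationPolicy("bays_fixed_total", J_total=float(J_rat.sum()))
        J_bays = allocate_display(p, policy, e6_params)
        assert J_bays == pytest.approx(J_rat, rel=0.01)

    def test_incentive_weights_scale_relevance(self, e6_params):
        # u_i * p_i enters exactly like a probing probability
        J_w = allocate_display([0.5, 0.5], AllocationPolicy("rational"), e6_params,
                               weights=[1.0, 0.5])
        J_p = allocate_display([0.5, 0.25], AllocationPolicy("rational"), e6_params)
        assert J_w == pytest.approx(J_p)

    def test_invalid_inputs(self, quad_params):
        with pytest.raises(ValueError):
            allocate_display([1.5], AllocationPolicy("rational"), quad_params)
        with pytest.raises(ValueError):
            allocate_display([0.5], AllocationPolicy("rational"), quad_params,
                             weights=[-1.0])


class TestTotalResourceCurve:
    def test_set_size_and_p_parameterizations_coincide(self, e6_params):
        by_n = total_resource_curve(e6_params, set_sizes=[1, 2, 4, 8])
        by_p = total_resource_curve(e6_params, p_grid=[1.0, 0.5, 0.25, 0.125])
        assert by_n.total == pytest.approx(by_p.total, rel=1e-6)

    def test_interior_peak_at_fitted_scale_parameters(self):
        # non-monotonic total resource at representative fitted values
        params = ModelParams(lambda_=3.2e-3, tau=8.2, cost=CostSpec("power", 0.106))
        curve = total_resource_curve(params, set_sizes=range(1, 9))
        assert 1 < curve.peak < 8

    def test_quadratic_equal_precision_total_is_monotone(self, quad_params):
        # documented regime: at (lambda=0.01, beta=2, tau->0) the total
        # rises over N = 1..8; the decreasing branch only starts at much
        # larger set sizes
        curve = total_resource_curve(quad_params, set_sizes=range(1, 9))
        assert np.all(np.diff(curve.total) > 0)
        assert curve.peak == 8

    def test_requires_exactly_one_axis(self, quad_params):
        with pytest.raises(ValueError):
            total_resource_curve(quad_params)
        with pytest.raises(ValueError):
            total_resource_curve(quad_params, set_sizes=[1], p_grid=[0.5])
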