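"""Closed-form fixed-sample-size optimum and its numerical verification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smartalloc import (
    BALANCED,
    ObjectiveWeights,
    ResponseRates,
    compound_criterion,
    optimal_design_fixed_n,
    optimal_first_stage,
    optimal_second_stage,
    oracle_fixed_n,
)
from smartalloc.variance import compound_criterion_unit

probs = st.floats(min_value=0.05, max_value=0.95)
weights4 = st.tuples(*[st.floats(min_value=0.05, max_value=1.0)] * 4)


class TestSecondStage:
    @pytest.mark.parametrize(
        "weights, expected",
        [
            ((0.25, 0.25, 0.25, 0.25), (0.50, 0.50)),
            ((0.70, 0.10, 0.10, 0.10), (0.67, 0.67)),
            ((0.10, 0.10, 0.10, 0.70), (0.33, 0.33)),
        ],
    )
    def test_neyman_shares_match_worked_example(self, weights, expected):
        p2, p3 = optimal_second_stage(ObjectiveWeights(*weights))
        assert (round(p2, 2), round(p3, 2)) == expected

    def test_exact_value_is_sqrt_ratio(self):
        p2, _ = optimal_second_stage(ObjectiveWeights(0.70, 0.10, 0.10, 0.10))
        assert p2 == pytest.approx(
            np.sqrt(0.8) / (np.sqrt(0.8) + np.sqrt(0.2)), abs=1e-12
        )

    @given(w=weights4)
    def test_complementarity_of_weight_block_swaps(self, w):
        l13, l14, l23, l24 = w
        p2, p3 = optimal_second_stage(ObjectiveWeights(l13, l14, l23, l24))
        # swapping (l13,l14) <-> (l23,l24) mirrors p2
        p2s, _ = optimal_second_stage(ObjectiveWeights(l23, l24, l13, l14))
        assert p2s == pytest.approx(1.0 - p2, abs=1e-12)
        # swapping (l13,l23) <-> (l14,l24) mirrors p3
        _, p3s = optimal_second_stage(ObjectiveWeights(l14, l13, l24, l23))
        assert p3s == pytest.approx(1.0 - p3, abs=1e-12)

    @given(w=weights4, bump=st.floats(min_value=0.01, max_value=0.5))
    def test_monotonicity_in_weights(self, w, bump):
        l13, l14, l23, l24 = w
        p2, p3 = optimal_second_stage(ObjectiveWeights(l13, l14, l23, l24))
        p2b, _ = optimal_second_stage(ObjectiveWeights(l13 + bump, l14, l23, l24))
        _, p3b = optimal_second_stage(ObjectiveWeights(l13, l14, l23 + bump, l24))
        assert p2b > p2  # p2* strictly increases in l13
        assert p3b > p3  # p3* strictly increases in l23

    def test_boundary_weight_block_warns(self):
        with pytest.warns(UserWarning):
            p2, p3 = optimal_second_stage(ObjectiveWeights(1, 0, 0, 0))
        assert (p2, p3) == (1.0, 1.0)


class TestFirstStage:
    def test_mid_rates_equal_weights(self):
        w = ObjectiveWeights(0.25, 0.25, 0.25, 0.25)
        p1 = optimal_first_stage(w, ResponseRates(0.25, 0.40), 0.5, 0.5)
        assert p1 == pytest.approx(0.5112, abs=5e-4)
        assert round(p1, 2) == 0.51

    def test_high_rates_equal_weights(self):
        # sqrt(A)/(sqrt(A)+sqrt(B)) with A = 4 - 2*gamma1, B = 4 - 2*gamma2
        w = ObjectiveWeights(0.25, 0.25, 0.25, 0.25)
        p1 = optimal_first_stage(w, ResponseRates(0.40, 0.55), 0.5, 0.5)
        a, b = 3.2, 2.9
        assert p1 == pytest.approx(np.sqrt(a) / (np.sqrt(a) + np.sqrt(b)), abs=1e-12)
        assert p1 == pytest.approx(0.5123, abs=5e-4)

    @given(gamma=probs, p=probs)
    def test_equal_rates_with_symmetric_weights_balance_first_stage(self, gamma, p):
        w = ObjectiveWeights(0.3, 0.2, 0.2, 0.3)  # l13 = l24, l14 = l23
        p1 = optimal_first_stage(w, ResponseRates(gamma, gamma), p, 1.0 - p)
        assert p1 == pytest.approx(0.5, abs=1e-12)


class TestComposedOptimum:
    def test_single_emphasis_low_rates(self):
        opt = optimal_design_fixed_n(
            ObjectiveWeights(0.70, 0.10, 0.10, 0.10), ResponseRates(0.15, 0.25)
        )
        assert round(opt.design.p2, 2) == 0.67
        assert round(opt.design.p3, 2) == 0.67
        assert opt.design.p1 == pytest.approx(0.5061, abs=5e-4)
        assert round(opt.re_balanced, 2) == 0.91

    def test_single_objective_boundary_limit(self):
        with pytest.warns(UserWarning):
            opt = optimal_design_fixed_n(
                ObjectiveWeights(1, 0, 0, 0), ResponseRates(0.2, 0.3)
            )
        assert opt.design.as_tuple() == (0.5, 1.0, 1.0)

    @given(w=weights4, g1=probs, g2=probs)
    def test_never_worse_than_balanced(self, w, g1, g2):
        weights = ObjectiveWeights(*w)
        rates = ResponseRates(g1, g2)
        opt = optimal_design_fixed_n(weights, rates)
        phi_opt = compound_criterion(opt.design, rates, weights).phi
        phi_bal = compound_criterion(BALANCED, rates, weights).phi
        assert phi_opt <= phi_bal * (1 + 1e-12)

    def test_optimum_does_not_depend_on_n(self):
        # minimizing Phi at any fixed N yields the same proportions
        from scipy.optimize import minimize

        from smartalloc import AllocationDesign, TrialScale

        w = ObjectiveWeights(0.4, 0.3, 0.2, 0.1)
        rates = ResponseRates(0.3, 0.5)
        argmins = []
        for n in (10, 100, 10000):
            res = minimize(
                lambda x: compound_criterion(
                    AllocationDesign(*x), rates, w, TrialScale(1.0, n)
                ).phi,
                np.array([0.5, 0.5, 0.5]),
                method="L-BFGS-B",
                bounds=[(1e-6, 1 - 1e-6)] * 3,
                options={"ftol": 1e-15, "gtol": 1e-12},
            )
            argmins.append(res.x)
        assert np.allclose(argmins[0], argmins[1], atol=1e-5)
        assert np.allclose(argmins[0], argmins[2], atol=1e-5)

    @given(w=weights4, g1=probs, g2=probs)
    @settings(max_examples=25)
    def test_gradient_stationarity_at_interior_optimum(self, w, g1, g2):
        weights = ObjectiveWeights(*w)
        rates = ResponseRates(g1, g2)
        opt = optimal_design_fixed_n(weights, rates)
        x = np.array(opt.design.as_tuple())
        eps = 1e-6
        grad = np.zeros(3)
        from smartalloc import AllocationDesign

        for i in range(3):
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            grad[i] = (
                compound_criterion_unit(AllocationDesign(*xp), rates, weights)
                - compound_criterion_unit(AllocationDesign(*xm), rates, weights)
            ) / (2 * eps)
        # central differences: O(eps^2) truncation plus cancellation noise
        assert np.linalg.norm(grad) < 1e-4


class TestOracle:
    def test_equal_weights_second_stage_balanced(self):
        d = oracle_fixed_n(
            ObjectiveWeights(0.25, 0.25, 0.25, 0.25), ResponseRates(0.3, 0.45)
        )
        assert d.p2 == pytest.approx(0.5, abs=1e-5)
        assert d.p3 == pytest.approx(0.5, abs=1e-5)

    def test_combined_emphasis_second_stage_third(self):
        d = oracle_fixed_n(
            ObjectiveWeights(0.10, 0.10, 0.10, 0.70), ResponseRates(0.15, 0.25)
        )
        assert d.p2 == pytest.approx(1 / 3, abs=1e-4)
        assert d.p3 == pytest.approx(1 / 3, abs=1e-4)

    def test_agrees_with_closed_form_on_random_draws(self):
        # a small pilot of the full verification (the deep run lives in the
        # acceptance suite)
        rng = np.random.default_rng(7)
        for _ in range(10):
            w = ObjectiveWeights(*rng.uniform(0.05, 1.0, size=4))
            rates = ResponseRates(*rng.uniform(0.05, 0.95, size=2))
            closed = optimal_design_fixed_n(w, rates).design
            oracle = oracle_fixed_n(w, rates)
            assert np.allclose(closed.as_tuple(), oracle.as_tuple(), atol=1e-4)
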