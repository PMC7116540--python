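"""Spending-based boundary derivation, group-size search, and design search."""

import numpy as np
import pytest
from scipy import stats

import oracles
import gspoisson as gp
from gspoisson import exact, spending


class TestDeriveBoundaries:
    def test_normal_single_stage_quantile(self, osah_problem):
        plan = gp.SpendingPlan((0.2,), (0.05,))
        design = gp.derive_boundaries(50, plan, osah_problem, "normal")
        assert design.r[0] == pytest.approx(float(stats.norm.ppf(0.95)), abs=1e-9)
        assert design.a[0] == design.r[0]

    def test_crossing_boundaries_return_infeasible_value(self, tiny_problem):
        # heavy stage-1 spending on an easy effect: the futility boundary
        # implied by pi_A1 overtakes the efficacy boundary implied by pi_R1
        plan = gp.SpendingPlan((0.29, 0.01), (0.19, 0.01))
        result = gp.derive_boundaries(9, plan, tiny_problem, "exact")
        assert isinstance(result, gp.Infeasible)
        assert result.stage == 1

    def test_exact_derivation_is_reproducible(self, osah_problem):
        plan = gp.SpendingPlan((0.1, 0.1), (0.015, 0.035))
        d1 = gp.derive_boundaries(40, plan, osah_problem, "exact")
        d2 = gp.derive_boundaries(40, plan, osah_problem, "exact")
        assert d1 == d2

    def test_exact_stagewise_spending_is_respected(self, osah_problem):
        plan = gp.SpendingPlan((0.1, 0.1), (0.015, 0.035))
        design = gp.derive_boundaries(40, plan, osah_problem, "exact")
        # stage-1 rejection spending within pi_R1, and r_1 is minimal
        value, _ = exact.exact_max_error(
            gp.GroupSequentialDesign(1, 40, (design.r[0],), (design.r[0],), "exact"),
            osah_problem,
            "typeI",
        )
        assert value <= plan.pi_R[0] + 1e-12
        value_below, _ = exact.exact_max_error(
            gp.GroupSequentialDesign(1, 40, (design.r[0] - 1,), (design.r[0] - 1,), "exact"),
            osah_problem,
            "typeI",
        )
        assert value_below > plan.pi_R[0]

    def test_front_loading_rejection_spending_lowers_r1(self, osah_problem):
        lo = gp.derive_boundaries(40, gp.SpendingPlan((0.1, 0.1), (0.01, 0.04)), osah_problem, "exact")
        hi = gp.derive_boundaries(40, gp.SpendingPlan((0.1, 0.1), (0.04, 0.01)), osah_problem, "exact")
        assert hi.r[0] <= lo.r[0]

    def test_nonconforming_plan_rejected(self, osah_problem):
        with pytest.raises(ValueError):
            gp.derive_boundaries(40, gp.SpendingPlan((0.1, 0.1), (0.05, 0.05)), osah_problem, "exact")


class TestFindGroupSize:
    def test_tiny_problem_returns_minimal_group_size(self, tiny_problem):
        plan = gp.SpendingPlan((0.3,), (0.2,))
        design = gp.find_group_size(plan, tiny_problem, "exact", n_cap=50)
        assert isinstance(design, gp.GroupSequentialDesign)
        beta_val, _ = exact.exact_max_error(design, tiny_problem, "typeII")
        assert beta_val <= tiny_problem.beta + 1e-10
        # minimality: every smaller n fails the power requirement
        for n in range(1, design.n):
            d = gp.derive_boundaries(n, plan, tiny_problem, "exact")
            if isinstance(d, gp.Infeasible):
                continue
            b, _ = exact.exact_max_error(d, tiny_problem, "typeII")
            assert b > tiny_problem.beta

    def test_unreachable_power_reports_best_achieved(self, osah_problem):
        plan = gp.SpendingPlan((0.2,), (0.05,))
        result = gp.find_group_size(plan, osah_problem, "exact", n_cap=10)
        assert isinstance(result, gp.GroupSizeSearchFailure)
        assert result.best_beta is not None and result.best_beta > osah_problem.beta


class TestOptimalityScore:
    def test_single_term_is_the_null_ess(self, tiny_problem):
        design = gp.GroupSequentialDesign(2, 2, (2, 3), (4, 3), "exact")
        score = gp.optimality_score(design, gp.OptimalityWeights(1, 0, 0), tiny_problem)
        assert score == pytest.approx(exact.exact_ess(design, tiny_problem.ess_null_rates))

    def test_scaling_weights_scales_score(self, tiny_problem):
        design = gp.GroupSequentialDesign(2, 2, (2, 3), (4, 3), "exact")
        w = gp.OptimalityWeights(1 / 3, 1 / 3, 1 / 3)
        w2 = gp.OptimalityWeights(2 / 3, 2 / 3, 2 / 3)
        s1 = gp.optimality_score(design, w, tiny_problem)
        s2 = gp.optimality_score(design, w2, tiny_problem)
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_weights_requiring_an_ess_term(self):
        with pytest.raises(ValueError, match="w1 \\+ w2"):
            gp.OptimalityWeights(0, 0, 1)


class TestGridSearch:
    def test_degenerate_grid_returns_its_design(self, tiny_problem):
        plan = gp.SpendingPlan((0.15, 0.15), (0.1, 0.1))
        ranked = gp.grid_search([plan], gp.OptimalityWeights(1, 0, 0), tiny_problem, "exact", K=2, n_cap=30)
        assert len(ranked) == 1
        assert ranked[0].plan == plan
        direct = gp.find_group_size(plan, tiny_problem, "exact", n_cap=30)
        assert ranked[0].design == direct

    def test_winner_minimizes_score_and_controls_errors(self, tiny_problem):
        grid = [
            gp.SpendingPlan((0.15, 0.15), (0.1, 0.1)),
            gp.SpendingPlan((0.1, 0.2), (0.05, 0.15)),
            gp.SpendingPlan((0.2, 0.1), (0.15, 0.05)),
        ]
        ranked = gp.grid_search(grid, gp.OptimalityWeights(1, 0, 0), tiny_problem, "exact", K=2, n_cap=30)
        assert ranked, "at least one plan should be feasible"
        scores = [x.score for x in ranked]
        assert scores == sorted(scores)
        for x in ranked:
            a_val, _ = exact.exact_max_error(x.design, tiny_problem, "typeI")
            b_val, _ = exact.exact_max_error(x.design, tiny_problem, "typeII")
            assert a_val <= tiny_problem.alpha + 1e-10
            assert b_val <= tiny_problem.beta + 1e-10

    def test_study_grids_have_expected_shape(self, osah_problem):
        grid2 = gp.two_stage_spending_grid(osah_problem)
        assert len(grid2) == 81
        for plan in grid2:
            plan.validate_for(osah_problem)
        grid3 = gp.three_stage_spending_grid(osah_problem)
        for plan in grid3:
            plan.validate_for(osah_problem)
        assert all(len(p.pi_A) == 3 for p in grid3)


class TestExhaustiveSearch:
    def test_matches_brute_force_oracle(self, tiny_problem):
        plan = gp.SpendingPlan((0.3,), (0.2,))
        n_fixed = gp.find_group_size(plan, tiny_problem, "exact", n_cap=50).n
        limits = gp.SearchLimits(epsilon=1e-3, n_max_factor=1.5)
        design = gp.exhaustive_search_k2(
            tiny_problem, gp.OptimalityWeights(1, 0, 0), limits=limits, n_fixed=n_fixed
        )
        oracle = oracles.brute_force_k2_search(
            lam=2.0, delta=1.5, alpha=0.2, beta=0.3, lam_ess=2.0, eps=1e-3, n_fixed=n_fixed
        )
        assert oracle is not None
        assert (design.n, design.a, design.r) == (oracle["n"], oracle["a"], oracle["r"])
        score = gp.optimality_score(design, gp.OptimalityWeights(1, 0, 0), tiny_problem)
        assert score == pytest.approx(float(oracle["score"]), abs=1e-9)

    def test_shrinking_epsilon_cannot_worsen_the_optimum(self, tiny_problem):
        w = gp.OptimalityWeights(1, 0, 0)
        d_wide = gp.exhaustive_search_k2(
            tiny_problem, w, limits=gp.SearchLimits(epsilon=1e-4, n_max_factor=1.5), n_fixed=4
        )
        d_narrow = gp.exhaustive_search_k2(
            tiny_problem, w, limits=gp.SearchLimits(epsilon=1e-3, n_max_factor=1.5), n_fixed=4
        )
        assert gp.optimality_score(d_wide, w, tiny_problem) <= gp.optimality_score(
            d_narrow, w, tiny_problem
        ) + 1e-12

    def test_returned_design_controls_both_error_rates(self, tiny_problem):
        design = gp.exhaustive_search_k2(
            tiny_problem,
            gp.OptimalityWeights(0, 1, 0),
            limits=gp.SearchLimits(epsilon=1e-3, n_max_factor=1.5),
            n_fixed=4,
        )
        a_val, _ = exact.exact_max_error(design, tiny_problem, "typeI")
        b_val, _ = exact.exact_max_error(design, tiny_problem, "typeII")
        assert a_val <= tiny_problem.alpha + 1e-10
        assert b_val <= tiny_problem.beta + 1e-10
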