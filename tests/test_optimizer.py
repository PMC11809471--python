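"""Payoff table, scalarized solve and Pareto machinery on small instances."""

import warnings

import numpy as np
import pytest

from forestopt import (ConstraintSpec, ObjectiveSpec, ScalarizationParams,
                       StandInfo, asf_value, build_base_model, check_dominance,
                       compile_problem, compute_payoff, solve_scalarized)

from conftest import make_table


class TestBuildBaseModel:
    def test_variable_and_simplex_counts(self):
        records = {("s1", r, 2020): {"v": 1.0} for r in "ABC"}
        records |= {("s2", r, 2020): {"v": 1.0} for r in "ABC"}
        records |= {("s3", r, 2020): {"v": 1.0} for r in "AB"}
        table = make_table(records)
        stands = [StandInfo(s) for s in ("s1", "s2", "s3")]
        model = build_base_model(table, stands)
        assert model.n_variables == 8
        simplex = [r for r in model.rows if r.name.startswith("simplex")]
        assert len(simplex) == 3
        assert all(r.lb == r.ub == 1.0 for r in simplex)

    def test_binary_mode_marks_allocation_integral(self):
        table = make_table({("s1", r, 2020): {"v": 1.0} for r in "AB"})
        model = build_base_model(table, [StandInfo("s1")], binary=True)
        assert all(model.integer)

    def test_stand_without_metadata_rejected(self):
        table = make_table({("s1", "A", 2020): {"v": 1.0}})
        with pytest.raises(ValueError, match="s1"):
            build_base_model(table, [])


class TestPayoff:
    def test_toy_matrix_ideal_nadir(self, toy_table, toy_stands, toy_objectives):
        model, compiled = compile_problem(toy_table, toy_stands, toy_objectives)
        payoff = compute_payoff(model, compiled)
        np.testing.assert_allclose(payoff.matrix, [[10.0, 0.0], [0.0, 8.0]],
                                   atol=1e-9)
        np.testing.assert_allclose(payoff.ideal, [10.0, 8.0], atol=1e-9)
        np.testing.assert_allclose(payoff.nadir, [0.0, 0.0], atol=1e-9)

    def test_single_objective_ideal_equals_nadir(self, toy_table, toy_stands):
        model, compiled = compile_problem(
            toy_table, toy_stands,
            [ObjectiveSpec(key="h", indicator="harvest", temporal="firstYear")])
        payoff = compute_payoff(model, compiled)
        assert payoff.matrix.shape == (1, 1)
        assert payoff.ideal[0] == payoff.nadir[0] == pytest.approx(10.0)

    def test_identical_objectives_give_identical_rows(self, toy_table, toy_stands):
        specs = [ObjectiveSpec(key=k, indicator="harvest", temporal="firstYear")
                 for k in ("a", "b")]
        model, compiled = compile_problem(toy_table, toy_stands, specs)
        payoff = compute_payoff(model, compiled)
        np.testing.assert_allclose(payoff.matrix[0], payoff.matrix[1], atol=1e-9)
        np.testing.assert_allclose(payoff.ideal, payoff.nadir, atol=1e-9)

    def test_diagonal_column_maximality(self, toy_table, toy_stands, toy_objectives):
        model, compiled = compile_problem(toy_table, toy_stands, toy_objectives)
        payoff = compute_payoff(model, compiled)
        for j in range(2):
            assert payoff.matrix[j, j] >= payoff.matrix[:, j].max() - 1e-6
        assert (payoff.ideal >= payoff.nadir - 1e-12).all()


class TestScalarized:
    def solve_toy(self, toy_table, toy_stands, toy_objectives, ref, eps=None):
        model, compiled = compile_problem(toy_table, toy_stands, toy_objectives)
        payoff = compute_payoff(model, compiled)
        return solve_scalarized(model, compiled, payoff, ref, eps=eps), payoff

    def test_ideal_reference_splits_the_stand(self, toy_table, toy_stands,
                                              toy_objectives):
        sol, _ = self.solve_toy(toy_table, toy_stands, toy_objectives,
                                {"harvest": 10.0, "deadwood": 8.0})
        assert sol.status == "optimal"
        assert sol.shares[("s1", "A")] == pytest.approx(0.5, abs=1e-6)
        assert sol.objective_values["harvest"] == pytest.approx(5.0, abs=1e-6)
        assert sol.objective_values["deadwood"] == pytest.approx(4.0, abs=1e-6)
        assert sol.achievements["harvest"] == pytest.approx(0.5, abs=1e-6)

    def test_feasible_reference_point_met_exactly(self, toy_table, toy_stands,
                                                  toy_objectives):
        sol, _ = self.solve_toy(toy_table, toy_stands, toy_objectives,
                                {"harvest": 5.0, "deadwood": 4.0})
        assert sol.alpha == pytest.approx(0.0, abs=1e-9)
        assert sol.objective_values["harvest"] == pytest.approx(5.0, abs=1e-6)

    def test_epsilon_restricts_the_tradeoff(self, toy_table, toy_stands,
                                            toy_objectives):
        sol, _ = self.solve_toy(toy_table, toy_stands, toy_objectives,
                                {"harvest": 10.0, "deadwood": 8.0},
                                eps={"harvest": 8.0})
        assert sol.objective_values["harvest"] == pytest.approx(8.0, abs=1e-6)
        assert sol.objective_values["deadwood"] == pytest.approx(1.6, abs=1e-6)

    def test_single_objective_returns_ideal(self, toy_table, toy_stands):
        model, compiled = compile_problem(
            toy_table, toy_stands,
            [ObjectiveSpec(key="h", indicator="harvest", temporal="firstYear")])
        payoff = compute_payoff(model, compiled)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate range is expected here
            sol = solve_scalarized(model, compiled, payoff, {"h": 3.0})
        assert sol.objective_values["h"] == pytest.approx(10.0, abs=1e-6)

    def test_reference_outside_bounds_is_clamped_with_warning(
            self, toy_table, toy_stands, toy_objectives):
        model, compiled = compile_problem(toy_table, toy_stands, toy_objectives)
        payoff = compute_payoff(model, compiled)
        with pytest.warns(UserWarning, match="clamped"):
            sol = solve_scalarized(model, compiled, payoff,
                                   {"harvest": 99.0, "deadwood": -5.0})
        assert sol.status == "optimal"

    def test_shares_form_a_simplex_per_stand(self, toy_table, toy_stands,
                                             toy_objectives):
        sol, _ = self.solve_toy(toy_table, toy_stands, toy_objectives,
                                {"harvest": 10.0, "deadwood": 8.0})
        total = sum(v for (s, _), v in sol.shares.items() if s == "s1")
        assert total == pytest.approx(1.0, abs=1e-6)
        assert all(v >= -1e-9 for v in sol.shares.values())

    def test_scale_invariance_of_alpha(self, toy_table, toy_stands, toy_objectives):
        sol, _ = self.solve_toy(toy_table, toy_stands, toy_objectives,
                                {"harvest": 7.0, "deadwood": 3.0})
        scaled = make_table({
            ("s1", "A", 2020): {"harvest": 10000.0, "deadwood": 0.0},
            ("s1", "B", 2020): {"harvest": 0.0, "deadwood": 8.0},
        })
        sol2, _ = self.solve_toy(scaled, toy_stands, toy_objectives,
                                 {"harvest": 7000.0, "deadwood": 3.0})
        assert sol2.alpha == pytest.approx(sol.alpha, abs=1e-6)

    def test_raising_epsilon_never_raises_alpha(self, toy_table, toy_stands,
                                                toy_objectives):
        ref = {"harvest": 10.0, "deadwood": 8.0}
        alphas = []
        for eps in (None, {"harvest": 6.0}, {"harvest": 9.0}):
            sol, _ = self.solve_toy(toy_table, toy_stands, toy_objectives, ref, eps)
            alphas.append(sol.alpha)
        assert alphas[1] <= alphas[0] + 1e-6
        assert alphas[2] <= alphas[1] + 1e-6

    def test_mismatched_payoff_rejected(self, toy_table, toy_stands, toy_objectives):
        model, compiled = compile_problem(toy_table, toy_stands, toy_objectives)
        payoff = compute_payoff(model, compiled)
        payoff.keys = ["other", "keys"]
        with pytest.raises(ValueError, match="different objective set"):
            solve_scalarized(model, compiled, payoff, {})


class TestDominance:
    def test_interior_point_not_dominated_by_vertices(self):
        assert not check_dominance([5, 4], [[10, 0], [0, 8]])

    def test_strictly_worse_point_is_dominated(self):
        assert check_dominance([4, 3], [[5, 4]])

    def test_equal_vector_does_not_dominate(self):
        assert not check_dominance([5, 4], [[5, 4]])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            check_dominance([1, 2], [[1, 2, 3]])


def test_large_rho_warns():
    with pytest.warns(UserWarning, match="rho"):
        ScalarizationParams(rho=0.01)


def test_asf_value_matches_hand_computation():
    v = asf_value([5.0, 4.0], [10.0, 8.0], [10.0, 8.0], rho=1e-6)
    assert v == pytest.approx(-0.5 + 1e-6 * (0.5 + 0.5))
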