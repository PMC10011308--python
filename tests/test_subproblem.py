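import numpy as np
import pytest

from rosterfatigue.lns import initial_solution
from rosterfatigue.model import Instance, count_gmf_occurrences, rhe_matrix, validate
from rosterfatigue.subproblem import Mode, NeighborhoodMask, solve_subproblem


class TestFeasibilityMode:
    def test_solves_and_validates(self, toy_instance):
        res = solve_subproblem(
            toy_instance, None,
            NeighborhoodMask.all_free(toy_instance.n_nurses, toy_instance.n_days),
            None, Mode.FEASIBILITY,
        )
        assert res.status in ("optimal", "feasible")
        assert validate(res.roster, toy_instance) == []

    def test_all_off_acceptable_when_nothing_required(self):
        inst = Instance(
            nurse_profiles=(1, 1), n_days=7,
            coverage={"D": 0, "E": 0, "N": 0},
            min_total_hours=0.0, max_total_hours=60.0,
        )
        res = solve_subproblem(
            inst, None, NeighborhoodMask.all_free(2, 7), None, Mode.FEASIBILITY
        )
        assert res.roster is not None
        assert validate(res.roster, inst) == []

    def test_infeasible_signal(self):
        # both nurses must work all 7 days -> exceeds 5 consecutive work days
        inst = Instance(
            nurse_profiles=(1, 1), n_days=7,
            coverage={"D": 1, "E": 1, "N": 0},
            min_total_hours=0.0, max_total_hours=8.5 * 7,
        )
        res = solve_subproblem(
            inst, None, NeighborhoodMask.all_free(2, 7), None, Mode.FEASIBILITY
        )
        assert res.status == "infeasible" and res.roster is None


class TestMasking:
    def test_all_fixed_returns_incumbent(self, toy_instance, table1):
        incumbent = initial_solution(toy_instance)
        res = solve_subproblem(
            toy_instance, table1,
            NeighborhoodMask.all_fixed(toy_instance.n_nurses, toy_instance.n_days),
            incumbent, Mode.MIN_GMF,
        )
        assert res.roster.assignments == incumbent.assignments

    def test_fixed_cells_conserved(self, toy_instance, table1):
        incumbent = initial_solution(toy_instance)
        free = np.zeros((toy_instance.n_nurses, toy_instance.n_days), dtype=bool)
        free[0, :] = True
        free |= incumbent.as_array() == "O"
        res = solve_subproblem(
            toy_instance, table1, NeighborhoodMask(free), incumbent, Mode.MIN_GMF
        )
        if res.roster is not None:
            out, inc = res.roster.as_array(), incumbent.as_array()
            assert (out[~free] == inc[~free]).all()


class TestFatigueModes:
    def test_min_gmf_never_worsens(self, toy_instance, table1):
        incumbent = initial_solution(toy_instance)
        inc_gmf = rhe_matrix(incumbent, toy_instance, table1).gmf
        res = solve_subproblem(
            toy_instance, table1,
            NeighborhoodMask.all_free(toy_instance.n_nurses, toy_instance.n_days),
            incumbent, Mode.MIN_GMF, time_limit=10,
        )
        if res.roster is not None:
            assert validate(res.roster, toy_instance) == []
            assert rhe_matrix(res.roster, toy_instance, table1).gmf <= inc_gmf + 1e-9

    def test_solver_scores_match_lookup_recomputation(self, toy_instance, table1):
        """The fatigue the solver enforces is exactly what rhe recomputes."""
        incumbent = initial_solution(toy_instance)
        res = solve_subproblem(
            toy_instance, table1,
            NeighborhoodMask.all_free(toy_instance.n_nurses, toy_instance.n_days),
            incumbent, Mode.MIN_GMF, time_limit=10, max_descents=2,
        )
        assert res.roster is not None
        # every value in the recomputed matrix is a table value for that profile
        mat = rhe_matrix(res.roster, toy_instance, table1)
        table_vals = set(np.round(table1.distinct_values([1]), 12))
        assert all(round(v, 12) in table_vals for v in mat.values.ravel())

    def test_min_occurrences_respects_bound_and_reduces(self, toy_instance, table1):
        incumbent = initial_solution(toy_instance)
        f = rhe_matrix(incumbent, toy_instance, table1)
        gmf = f.gmf
        occ = count_gmf_occurrences(f, gmf)
        res = solve_subproblem(
            toy_instance, table1,
            NeighborhoodMask.all_free(toy_instance.n_nurses, toy_instance.n_days),
            incumbent, Mode.MIN_OCCURRENCES, gmf_bound=gmf, time_limit=15,
        )
        assert res.roster is not None
        f2 = rhe_matrix(res.roster, toy_instance, table1)
        assert f2.values.max() <= gmf + 1e-9
        assert count_gmf_occurrences(f2, gmf) <= occ
        assert validate(res.roster, toy_instance) == []

    def test_fatigue_modes_need_table(self, toy_instance):
        with pytest.raises(ValueError):
            solve_subproblem(
                toy_instance, None,
                NeighborhoodMask.all_free(6, 14), None, Mode.MIN_GMF
            )


class TestRandomizedAgreement:
    """Many solved subproblems, every returned roster validator-clean."""

    N_CASES = 60

    def test_random_neighbourhoods_zero_violations(self, toy_instance, table1):
        incumbent = initial_solution(toy_instance)
        rng = np.random.default_rng(42)
        for case in range(self.N_CASES):
            free = np.zeros((toy_instance.n_nurses, toy_instance.n_days), dtype=bool)
            nurses = rng.choice(toy_instance.n_nurses, size=rng.integers(1, 4), replace=False)
            for n in nurses:
                free[n, :] = True
            free |= incumbent.as_array() == "O"
            mode = [Mode.FEASIBILITY, Mode.MIN_GMF, Mode.MIN_OCCURRENCES][case % 3]
            gmf = rhe_matrix(incumbent, toy_instance, table1).gmf
            res = solve_subproblem(
                toy_instance, table1, NeighborhoodMask(free), incumbent, mode,
                gmf_bound=gmf if mode is Mode.MIN_OCCURRENCES else None,
                time_limit=5, max_descents=2,
            )
            if mode is not Mode.MIN_GMF:
                # the incumbent itself is a solution, so one must come back
                assert res.roster is not None, f"case {case}"
            if res.roster is not None:
                assert validate(res.roster, toy_instance) == [], f"case {case}"
                if res.roster.assignments != incumbent.assignments and case % 5 == 0:
                    incumbent = res.roster  # drift the incumbent around
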