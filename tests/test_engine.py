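import numpy as np
import pytest

from volepom import VoleParams
from volepom.engine import (FitState, Scenario, hill_climb, make_scenario,
                            perturb, run_replicates, sensitivity_sweep,
                            sequential_pom, SENSITIVITY_PARAMS)


class TestPerturb:
    def test_single_parameter_candidate_count(self, params):
        cands = perturb(params, subset=("V10",))
        assert 1 <= len(cands) <= 6

    def test_v10_twenty_percent(self, params):
        cands = perturb(params, subset=("V10",), fractions=(0.20,))
        values = sorted(c.daily_mortality for c in cands)
        assert values == pytest.approx([0.002, 0.003])

    def test_integer_day_parameter_rounded(self, params):
        cands = perturb(params, subset=("V15",), fractions=(0.05,))
        values = sorted(c.earliest_breed_day for c in cands)
        assert values == [76, 84]

    def test_duplicates_removed(self, params):
        # 1% of an integer parameter rounds back onto itself
        cands = perturb(params, subset=("V4",), fractions=(0.01,))
        assert len(cands) == 0

    def test_infinite_v16_skipped(self, params):
        assert perturb(params, subset=("V16",)) == []


class TestHillClimb:
    def test_already_converged_returns_immediately(self, params):
        calls = []

        def objective(p):
            calls.append(1)
            return 0.0

        state = hill_climb(objective, params, budget=10, tolerance=0.01)
        assert state.converged
        assert len(calls) == 1

    def test_zero_budget_keeps_initial_params(self, params):
        state = hill_climb(lambda p: 1.0, params, budget=0, tolerance=0.0)
        assert state.params is params

    def test_convex_objective_matches_grid_search(self):
        """Greedy descent lands within one perturbation step of the optimum
        found by exhaustive search over the same candidate lattice."""
        target = {"V9": 0.0605, "V10": 0.00275}  # +10% of the defaults

        def objective(p):
            return (abs(p.get_v("V9") - target["V9"]) / target["V9"]
                    + abs(p.get_v("V10") - target["V10"]) / target["V10"])

        p0 = VoleParams()
        state = hill_climb(objective, p0, budget=30, tolerance=0.0,
                           subset=("V9", "V10"), fractions=(0.05, 0.10))
        # exhaustive oracle over the reachable two-step lattice
        best = min(
            (objective(c2), c2)
            for c1 in [p0] + perturb(p0, ("V9", "V10"), (0.05, 0.10))
            for c2 in [c1] + perturb(c1, ("V9", "V10"), (0.05, 0.10))
        )[0]
        assert state.objective <= best + 0.11  # within one 5-10% step

    def test_forbidden_set_never_revisited(self, params):
        seen = []

        def objective(p):
            key = round(p.get_v("V9"), 8)
            seen.append(key)
            return abs(p.get_v("V9") - 0.02)

        state = FitState(params)
        forbidden = params.with_v("V9", 0.055 * 0.95)
        state.forbid(forbidden)
        hill_climb(objective, params, budget=2, subset=("V9",),
                   fractions=(0.05,), state=state)
        assert round(0.055 * 0.95, 8) not in seen


class TestSequentialPom:
    def test_all_targets_met_single_pass(self, params):
        evaluators = {i: (lambda p, i=i: (0.0, True)) for i in range(1, 5)}
        state, report = sequential_pom(evaluators, params)
        assert report["passed"].all()
        assert state.blocking_pattern is None

    def test_later_set_failure_forbids_parameterization(self, params):
        attempts = {"n": 0}

        def eval2(p):
            attempts["n"] += 1
            return (5.0, attempts["n"] > 1)  # fails once, then passes

        evaluators = {1: lambda p: (0.0, True), 2: eval2,
                      3: lambda p: (0.0, True), 4: lambda p: (0.0, True)}
        state, report = sequential_pom(evaluators, params, max_cycles=3)
        assert len(state.forbidden) >= 1
        assert report["passed"].all()

    def test_report_covers_all_four_sets(self, params):
        evaluators = {i: (lambda p: (0.0, True)) for i in range(1, 5)}
        _, report = sequential_pom(evaluators, params)
        assert sorted(report["set"]) == [1, 2, 3, 4]


class TestSensitivitySweep:
    def test_parameterization_count(self, params):
        table = sensitivity_sweep(params, lambda p: {"d": 0.0}, n_values=11)
        # 14 finite parameters (V16 infinite is excluded) x 11 values
        finite = [v for v in SENSITIVITY_PARAMS
                  if np.isfinite(params.get_v(v))]
        assert len(table) == len(finite) * 11

    def test_grid_spans_eighty_percent(self, params):
        table = sensitivity_sweep(params, lambda p: {"d": 0.0},
                                  parameter_ids=("V10",))
        vals = sorted(table["value"])
        assert vals[0] == pytest.approx(0.0005)
        assert vals[-1] == pytest.approx(0.0045)

    def test_center_value_reproduces_fitted_deviation(self, params):
        def evaluator(p):
            return {"d": abs(p.get_v("V10") - params.get_v("V10"))}

        table = sensitivity_sweep(params, evaluator, parameter_ids=("V10",))
        center = table[table["value"] == params.get_v("V10")]
        assert len(center) == 1
        assert center["d"].iloc[0] == 0.0

    def test_overall_deviance_capped_at_one(self, params):
        table = sensitivity_sweep(params, lambda p: {"d": 7.5},
                                  parameter_ids=("V10",), n_values=3)
        assert (table["overall"] == 1.0).all()


class TestScenarios:
    def test_burn_in_shorter_than_run_enforced(self):
        with pytest.raises(ValueError):
            Scenario("set1_block", "homogeneous_block", years_total=5,
                     years_burn_in=5)

    def test_predators_rejected_for_background_scenarios(self):
        from volepom.predation import PredatorParams
        with pytest.raises(ValueError, match="background"):
            Scenario("set1_block", "homogeneous_block",
                     predators=PredatorParams())

    def test_scale_factor_recorded_in_outputs(self):
        sc = make_scenario("set1_block")
        assert 0 < sc.scale_factor < 1

    def test_fitting_below_minimum_replicates_warns(self, small_block):
        sc = make_scenario("set1_block")
        sc.landscape_args = {"dims": 60}
        sc.years_total, sc.years_burn_in = 2, 1
        with pytest.warns(UserWarning, match="ten replicates"):
            run_replicates(sc, VoleParams(), n_reps=1, base_seed=0,
                           fitting=True)
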