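"""Scenario runner, replicate manager, sequential calibration, sensitivity.

The calibration procedure fits the four pattern sets in sequence — block
scenario patterns first, then habitat densities, dispersal, and cycling —
re-checking earlier sets after any parameter change and never revisiting a
parameterization already found wanting (the forbidden set).  Candidate
moves are one-at-a-time relative perturbations; acceptance is greedy
(hill climbing) on a scalar mean-deviation objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import HabitatClass, generate_landscape
from .params import VoleParams
from .patterns import (PatternTargets, age_structure_props, cycle_metrics,
                       female_density, mid_month_days, sex_ratio)
from .predation import PredatorParams, background_mortality_mode
from .sim import Simulation
from .trapping import TrapGridSpec, build_trap_grids, dispersal_stats

__all__ = ["Scenario", "FitState", "make_scenario", "run_replicates",
           "perturb", "hill_climb", "sequential_pom", "sensitivity_sweep",
           "SENSITIVITY_PARAMS"]

#: Parameters included in the one-at-a-time sensitivity protocol.
SENSITIVITY_PARAMS = tuple(f"V{i}" for i in range(1, 16))


@dataclass
class Scenario:
    """One pattern-set testing protocol at a given scale.

    ``scale_factor`` < 1 shrinks landscape and durations relative to the
    full protocol and is recorded in every output so scaled runs are never
    silently compared to full-scale targets.
    """

    id: str
    landscape_kind: str
    landscape_args: dict = field(default_factory=dict)
    years_total: int = 10
    years_burn_in: int = 5
    weather_profile: str = "finland_like"
    predators: PredatorParams | None = None
    traps: bool = False
    scale_factor: float = 1.0
    record_patch: bool = False
    vole_immigration: int = 0

    def __post_init__(self):
        if not self.years_burn_in < self.years_total:
            raise ValueError("burn-in must be shorter than the run")
        self.predators = background_mortality_mode(self.id, self.predators)

    def build_grid(self, seed: int = 0):
        return generate_landscape(self.landscape_kind, seed=seed,
                                  **self.landscape_args)


def make_scenario(set_id: str, full_scale: bool = False,
                  n_patches: int = 1,
                  predators: PredatorParams | None = None) -> Scenario:
    """Desk-scale scenario presets (``full_scale=True`` restores the
    printed protocol durations)."""
    if set_id == "set1_block":
        return Scenario("set1_block", "homogeneous_block",
                        {"dims": 200},
                        years_total=20 if full_scale else 10,
                        years_burn_in=10 if full_scale else 5,
                        weather_profile="finland_like",
                        scale_factor=1.0 if full_scale else 0.5)
    if set_id == "set2_mosaic":
        return Scenario("set2_mosaic", "mosaic",
                        {"dims": (1000, 1000) if full_scale else (500, 500)},
                        years_total=30 if full_scale else 8,
                        years_burn_in=20 if full_scale else 4,
                        weather_profile="denmark_like",
                        scale_factor=1.0 if full_scale else 0.25,
                        record_patch=True)
    if set_id == "set3_trapmeadow":
        return Scenario("set3_trapmeadow", "trap_meadow", {},
                        years_total=12 if full_scale else 7,
                        years_burn_in=10 if full_scale else 5,
                        weather_profile="denmark_like",
                        traps=True,
                        scale_factor=1.0 if full_scale else 0.6)
    if set_id == "set4_patches":
        # patch spacing sets the predator-prey coupling between patches:
        # the 3-patch landscape is drawn tighter so patches couple weakly
        desk_dims = (500, 500) if n_patches == 3 else (700, 700)
        return Scenario("set4_patches", "patches",
                        {"dims": (1000, 1000) if full_scale else desk_dims,
                         "n_patches": n_patches,
                         "patch_frac": 0.25},
                        years_total=50, years_burn_in=10,
                        weather_profile="denmark_like",
                        predators=predators,
                        scale_factor=1.0 if full_scale else 0.49,
                        vole_immigration=10)
    raise ValueError(f"unknown scenario {set_id!r}")


def _evaluate_run(scenario: Scenario, result, targets: PatternTargets) -> dict:
    """Scenario-appropriate pattern statistics for one replicate."""
    stats: dict = {"scale_factor": scenario.scale_factor}
    burn = scenario.years_burn_in
    if scenario.id == "set1_block":
        area = result.grid.area_ha(HabitatClass.GRASSLAND_UNMANAGED)
        stats["sex_ratio_day90"] = sex_ratio(result.counts, 90,
                                             targets.census_window_days, burn)
        stats["sex_ratio_day200"] = sex_ratio(result.counts, 200,
                                              targets.census_window_days, burn)
        stats["female_density"] = female_density(result.counts, area, 200,
                                                 targets.census_window_days,
                                                 burn)
        if result.snapshots:
            for sex_label, key in (("M", "age_structure_m"),
                                   ("F", "age_structure_f")):
                stats[key] = age_structure_props(
                    result.snapshots, sex_label, targets.age_class_edges,
                    targets.age_structure_months)
    elif scenario.id == "set3_trapmeadow":
        stats["dispersal"] = dispersal_stats(result.captures)
    elif scenario.id == "set4_patches":
        stats["cycle"] = cycle_metrics(result.annual_peaks(burn))
    return stats


def run_replicates(scenario: Scenario, params: VoleParams | None = None,
                   n_reps: int = 10, base_seed: int = 0,
                   targets: PatternTargets | None = None,
                   fitting: bool = False) -> dict:
    """Run ``n_reps`` independent seeds and aggregate pattern statistics.

    Replicate k uses seed ``base_seed + k``.  Returns per-replicate
    statistics, their across-replicate means, and dispersion for numeric
    entries.
    """
    if fitting and n_reps < 10:
        warnings.warn("fitting requires a minimum of ten replicates; "
                      f"got {n_reps}")
    params = params or VoleParams()
    targets = targets or PatternTargets()
    grid = scenario.build_grid(seed=base_seed)
    snapshot_days = None
    if scenario.id == "set1_block":
        snapshot_days = mid_month_days(targets.age_structure_months,
                                       scenario.years_total,
                                       scenario.years_burn_in)
    traps = build_trap_grids(
        TrapGridSpec().centered(grid.width_m, grid.height_m)) \
        if scenario.traps else None
    per_rep = []
    for k in range(n_reps):
        sim = Simulation(
            grid, params, years=scenario.years_total,
            seed=base_seed + k,
            weather_profile=scenario.weather_profile,
            predators=scenario.predators,
            predator_start_year=3 if scenario.predators else 0,
            vole_immigration=scenario.vole_immigration,
            traps=traps,
            capture_start_year=scenario.years_burn_in if scenario.traps else None,
            record_patch=scenario.record_patch,
            snapshot_days=snapshot_days)
        try:
            result = sim.run()
        except Exception as exc:  # pragma: no cover - replicate diagnostics
            raise RuntimeError(f"replicate {k} (seed {base_seed + k}) "
                               f"failed: {exc}") from exc
        per_rep.append(_evaluate_run(scenario, result, targets))
    agg: dict = {"per_replicate": per_rep, "n_reps": n_reps,
                 "scale_factor": scenario.scale_factor}
    numeric_keys = [k for k in per_rep[0]
                    if isinstance(per_rep[0][k], (int, float))]
    for key in numeric_keys:
        vals = np.array([r[key] for r in per_rep], dtype=float)
        agg[key] = float(vals.mean())
        agg[key + "_sd"] = float(vals.std(ddof=1)) if n_reps > 1 else 0.0
    return agg


# ---------------------------------------------------------------------------
# calibration machinery
# ---------------------------------------------------------------------------

def _param_key(params: VoleParams) -> tuple:
    return tuple(round(float(params.get_v(v)), 10)
                 for v in VoleParams._V_NAMES
                 if np.isfinite(params.get_v(v)))


@dataclass
class FitState:
    """Calibration trajectory: current best, history, forbidden set."""

    params: VoleParams
    objective: float = float("inf")
    history: list = field(default_factory=list)     # append-only
    forbidden: set = field(default_factory=set)
    converged: bool = False
    blocking_pattern: str | None = None

    def record(self, params: VoleParams, value: float, accepted: bool) -> None:
        self.history.append({"key": _param_key(params), "objective": value,
                             "accepted": accepted})

    def forbid(self, params: VoleParams) -> None:
        self.forbidden.add(_param_key(params))

    def is_forbidden(self, params: VoleParams) -> bool:
        return _param_key(params) in self.forbidden


def perturb(params: VoleParams, subset=None,
            fractions=(0.05, 0.10, 0.20)) -> list[VoleParams]:
    """One-at-a-time candidates at +/- the given fractions of each value.

    Integer-valued parameters are rounded; candidates identical to the
    current value (after rounding) are dropped, as are duplicates.
    """
    subset = subset or SENSITIVITY_PARAMS
    out = []
    seen = {_param_key(params)}
    for vname in subset:
        base = params.get_v(vname)
        if not np.isfinite(base):
            continue
        for frac in fractions:
            for sign in (+1, -1):
                cand = params.with_v(vname, base * (1 + sign * frac))
                key = _param_key(cand)
                if key not in seen:
                    seen.add(key)
                    out.append(cand)
    return out


def hill_climb(objective, params: VoleParams, budget: int = 20,
               tolerance: float = 0.0, subset=None,
               fractions=(0.05, 0.10, 0.20),
               state: FitState | None = None) -> FitState:
    """Greedy one-at-a-time descent of a scalar deviation objective.

    Each iteration evaluates all perturbation candidates (skipping the
    forbidden set) and accepts the best strict improvement; stops at the
    tolerance, the budget, or when no candidate improves.
    """
    state = state or FitState(params)
    current = objective(params)
    state.objective = current
    state.params = params
    state.record(params, current, True)
    if current <= tolerance:
        state.converged = True
        return state
    for _ in range(budget):
        best_val = current
        best_p = None
        for cand in perturb(state.params, subset, fractions):
            if state.is_forbidden(cand):
                continue
            val = objective(cand)
            state.record(cand, val, False)
            if val < best_val:
                best_val = val
                best_p = cand
        if best_p is None:
            break
        state.params = best_p
        state.objective = best_val
        current = best_val
        state.history[-1]["accepted"] = True
        if current <= tolerance:
            state.converged = True
            break
    return state


def sequential_pom(evaluators: dict, params0: VoleParams,
                   tolerances: dict | None = None,
                   budget_per_set: int = 10,
                   max_cycles: int = 5) -> tuple[FitState, pd.DataFrame]:
    """Sequential gated calibration across the four pattern sets.

    ``evaluators`` maps set id (1..4) to a callable ``params -> (deviation,
    passed)``.  Set 1 is fitted to tolerance first; each later set is then
    checked, with failures sending the search back to set 1 under the
    constraint that previously failed parameterizations are excluded.
    Returns the final state and a per-set report.
    """
    tolerances = tolerances or {1: 0.02, 2: 0.0, 3: 0.0, 4: 0.0}
    state = FitState(params0)
    set_ids = sorted(evaluators)

    def fit_set1(st: FitState) -> FitState:
        obj = lambda p: evaluators[1](p)[0]
        return hill_climb(obj, st.params, budget=budget_per_set,
                          tolerance=tolerances.get(1, 0.02), state=st)

    report_rows = []
    for cycle in range(max_cycles):
        state = fit_set1(state)
        dev1, ok1 = evaluators[1](state.params)
        if not ok1 and not state.converged:
            state.blocking_pattern = "set1"
            break
        advanced = True
        for sid in set_ids[1:]:
            dev, ok = evaluators[sid](state.params)
            if not ok:
                # exclude this parameterization and resume fitting set 1
                state.forbid(state.params)
                state.converged = False
                state.blocking_pattern = f"set{sid}"
                advanced = False
                break
        if advanced:
            state.blocking_pattern = None
            break
    for sid in set_ids:
        dev, ok = evaluators[sid](state.params)
        report_rows.append({"set": sid, "deviation": dev, "passed": ok})
    report = pd.DataFrame(report_rows)
    if state.blocking_pattern is not None and not report["passed"].all():
        state.converged = False
    return state, report


def sensitivity_sweep(params_fitted: VoleParams, evaluator,
                      parameter_ids=SENSITIVITY_PARAMS, n_values: int = 11,
                      rel_range: float = 0.8) -> pd.DataFrame:
    """One-at-a-time sweep: each parameter at ``n_values`` equally spaced
    values spanning +/- ``rel_range`` of its fitted value (center included).

    ``evaluator(params) -> dict`` returns proportional deviations of the
    response variables; an ``overall`` mean deviance is added, capped at 1.0.
    """
    rows = []
    for vname in parameter_ids:
        base = params_fitted.get_v(vname)
        if not np.isfinite(base):
            continue
        grid = base * (1.0 + np.linspace(-rel_range, rel_range, n_values))
        for val in grid:
            try:
                cand = params_fitted.with_v(vname, val)
            except ValueError:
                # candidate violates a structural constraint (e.g. inverted
                # radius bounds); recorded but not evaluated
                rows.append({"parameter": vname, "value": val,
                             "invalid": True})
                continue
            try:
                devs = evaluator(cand)
            except Exception:
                devs = {}
            row = {"parameter": vname, "value": cand.get_v(vname)}
            row.update({k: float(v) for k, v in devs.items()})
            if devs:
                overall = float(np.mean([abs(v) for v in devs.values()]))
                row["overall"] = min(1.0, overall)
            rows.append(row)
    return pd.DataFrame(rows)
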