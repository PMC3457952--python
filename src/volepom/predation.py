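"""Specialist predators with a delayed numerical response.

Small mustelid-like specialists: they need a relatively high local vole
density to survive, a lower one to reproduce (once per year), disperse a
short distance after a few days of unsuccessful hunting, and starve after a
longer run of failure.  Predator abundance therefore tracks vole abundance
with a lag, which is the mechanism that generates multi-annual cycles.

Everywhere else (the age-structure, habitat-density and trapping scenarios)
predation is folded into the daily background mortality (V10) and predators
must stay disabled; :func:`background_mortality_mode` guards that contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel as K

__all__ = ["PredatorParams", "strong_specialist", "weak_specialist",
           "background_mortality_mode"]


@dataclass
class PredatorParams:
    """Configuration for the specialist predator agents.

    Magnitudes are desk-scale defaults chosen to produce the three cycling
    regimes on the simple patch landscapes; the qualitative constraints are
    high survive threshold, low reproduce threshold, short-range dispersal
    after a few unsuccessful days.
    """

    home_range_radius: float = 40.0        # m
    daily_kill_cap: int = 1                # voles/day
    survive_threshold: float = 30.0        # voles within home range
    reproduce_threshold: float = 40.0      # voles within home range
    unsuccessful_days_before_dispersal: int = 4
    starvation_days: int = 75
    dispersal_step: float = 60.0           # m
    repro_start_doy: int = 100
    repro_end_doy: int = 240
    max_predators: int = 400
    initial_predators: int = 4
    immigration_floor: int = 1             # predators topped up each spring
    litter_size: int = 6                   # offspring per annual reproduction

    def __post_init__(self):
        if self.survive_threshold < 0 or self.reproduce_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if self.unsuccessful_days_before_dispersal < 1:
            raise ValueError("dispersal trigger must be >= 1 day")

    def to_array(self) -> np.ndarray:
        PP = np.zeros(K.NQ_PARAMS)
        PP[K.Q_HOME_R] = self.home_range_radius
        PP[K.Q_KILL_CAP] = self.daily_kill_cap
        PP[K.Q_SURVIVE_THRESH] = self.survive_threshold
        PP[K.Q_REPRO_THRESH] = self.reproduce_threshold
        PP[K.Q_UNSUCC_DISP] = self.unsuccessful_days_before_dispersal
        PP[K.Q_STARVE_DAYS] = self.starvation_days
        PP[K.Q_DISP_STEP] = self.dispersal_step
        PP[K.Q_REPRO_START] = self.repro_start_doy
        PP[K.Q_REPRO_END] = self.repro_end_doy
        PP[K.Q_MAX_PREDS] = self.max_predators
        PP[K.Q_IMMIGRATION] = self.immigration_floor
        PP[K.Q_LITTER] = self.litter_size
        return PP


def strong_specialist() -> PredatorParams:
    """Strong numerical response: drives deep, regular cycles."""
    return PredatorParams()


def weak_specialist() -> PredatorParams:
    """Weaker numerical response: shallower, less regular fluctuations."""
    return PredatorParams(survive_threshold=45.0, reproduce_threshold=90.0,
                          starvation_days=35, litter_size=3,
                          initial_predators=2)


#: Scenario ids whose protocols exclude predators (their mortality is part
#: of the background rate V10).
_NO_PREDATOR_SCENARIOS = {"set1_block", "set2_mosaic", "set3_trapmeadow"}


def background_mortality_mode(scenario_id: str,
                              predators: PredatorParams | None) -> PredatorParams | None:
    """Validate the predator setting against the scenario contract.

    Returns the predator configuration to use (None = background-only mode);
    raises if predators are requested for a scenario whose protocol folds
    predation into background mortality.
    """
    if scenario_id in _NO_PREDATOR_SCENARIOS and predators is not None:
        raise ValueError(
            f"scenario {scenario_id!r} uses background mortality only; "
            "predators must be disabled")
    return predators
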