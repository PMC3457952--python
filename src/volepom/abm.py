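"""Individual-level behavioural rules.

These are the readable, unit-testable forms of the decision rules the
compiled scheduler (:mod:`volepom._kernel`) applies per agent per day:
maturation, territory acceptability, eviction, mate choice, mortality
hazards, density dependence, restlessness and infanticide.  The full daily
schedule over a world state is driven by :class:`volepom.sim.Simulation`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernel as K
from .landscape import HabitatGrid, VegetationState
from .params import MONTH_DAYS, VoleParams

__all__ = [
    "Vole", "territory_acceptable", "can_evict", "choose_mate", "maturation",
    "daily_death_probability", "daily_mortality", "density_effects_active",
    "male_restlessness", "infanticide_success_prob", "infanticide_attempt",
    "draw_lifespan_days", "draw_offspring_sex",
]


@dataclass
class Vole:
    """One agent; stage is derived from age and the sex-specific maturity age."""

    id: int
    sex: str                      # "F" | "M"
    age: int                      # days
    location: tuple[float, float]
    natal_location: tuple[float, float] = None
    birth_day: int = 0
    territory: tuple[tuple[float, float], float] | None = None  # (center, radius)
    assigned_lifespan: int = 10 ** 9
    mother_id: int | None = None
    dispersing: bool = False

    @property
    def stage(self) -> str:
        return "adult" if self.is_adult(VoleParams()) else "juvenile"

    def is_adult(self, params: VoleParams) -> bool:
        cut = (params.female_min_repro_age if self.sex == "F"
               else params.male_min_repro_age)
        return self.age >= cut


def maturation(vole: Vole, params: VoleParams) -> str:
    """Life stage from age: adult at V1 (males) / V2 (females); idempotent."""
    return "adult" if vole.is_adult(params) else "juvenile"


def territory_acceptable(center: tuple[int, int], sex: str,
                         grid: HabitatGrid, veg: VegetationState,
                         params: VoleParams,
                         occupancy: np.ndarray | None = None,
                         occupancy_adult_f: np.ndarray | None = None,
                         breeding_season: bool = False,
                         self_here: bool = False,
                         quality_multiplier_field: np.ndarray | None = None,
                         ) -> tuple[bool, int]:
    """Scan radii from the sex-specific minimum up; return (acceptable, radius).

    A radius is acceptable when mean cell quality (class base quality x
    patch digestibility) times the quality multiplier V3 reaches 1.0, the
    local occupant count stays below the sex-scaled density threshold, and
    (for adult males in the breeding season, if enabled) an adult female
    lies within the radius.
    """
    from .sim import Simulation

    h, w = grid.codes.shape
    occ = occupancy if occupancy is not None else np.zeros((h, w), np.int32)
    occ_af = (occupancy_adult_f if occupancy_adult_f is not None
              else np.zeros((h, w), np.int32))
    baseq = np.ascontiguousarray(
        np.array([_baseq_of(grid, p) for p in range(grid.n_patches)]))
    qmul = (quality_multiplier_field if quality_multiplier_field is not None
            else np.ones((h, w)))
    P = Simulation._param_array(params)
    r = K._settle_scan(int(center[0]), int(center[1]),
                       0 if sex == "F" else 1, breeding_season, self_here,
                       baseq, np.ascontiguousarray(veg.digestibility),
                       qmul, grid.patch_ids, occ.astype(np.int32),
                       occ_af.astype(np.int32),
                       K.RING_DY, K.RING_DX, K.RING_PTR, P)
    return (r > 0), int(r)


def _baseq_of(grid: HabitatGrid, pid: int) -> float:
    from .landscape import BASE_QUALITY, HabitatClass
    return BASE_QUALITY[HabitatClass(int(grid.patch_class[pid]))]


def can_evict(older_age: int, younger_age: int, overlap_fraction: float,
              same_sex: bool, params: VoleParams, sex: str = "M") -> bool:
    """Same-sex eviction: territory overlap > 50% plus an age advantage.

    Males need the full V8 age gap before they can evict a younger male;
    females only need to be older.  The overlap fraction is measured over
    the evictee's (younger vole's) territory.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction outside [0, 1]")
    min_gap = params.eviction_age_gap if sex == "M" else 1
    return (same_sex and overlap_fraction > 0.5
            and (older_age - younger_age) >= min_gap)


def choose_mate(female_location: tuple[float, float],
                candidate_males: list) -> int | None:
    """Nearest male whose territory contains the female; ties to lowest id.

    ``candidate_males``: iterable of (id, ((cx, cy), radius)).
    """
    fx, fy = female_location
    best = None
    for mid, ((cx, cy), radius) in candidate_males:
        d = math.hypot(cx - fx, cy - fy)
        if d <= radius:
            key = (d, mid)
            if best is None or key < best[0]:
                best = (key, mid)
    return None if best is None else best[1]


def daily_death_probability(params: VoleParams, dispersed_today: bool) -> float:
    """Combined daily hazard: independent background (V10) and dispersal (V9)."""
    p_survive = (1.0 - params.daily_mortality)
    if dispersed_today:
        p_survive *= (1.0 - params.dispersal_mortality)
    return 1.0 - p_survive


def daily_mortality(vole: Vole, dispersed_today: bool, params: VoleParams,
                    rng: np.random.Generator) -> bool:
    """True if the vole dies today (hazards plus the lifespan limit)."""
    if vole.age > vole.assigned_lifespan:
        return True
    return rng.random() < daily_death_probability(params, dispersed_today)


def draw_lifespan_days(params: VoleParams, rng: np.random.Generator) -> int:
    """Physiological lifespan ~ Normal(15, 3) months, truncated at 1 day."""
    d = rng.normal(params.lifespan_mean_months * MONTH_DAYS,
                   params.lifespan_sd_months * MONTH_DAYS)
    return max(1, int(round(d)))


def draw_offspring_sex(rng: np.random.Generator) -> str:
    """Even sex ratio at weaning."""
    return "M" if rng.random() < 0.5 else "F"


def density_effects_active(local_count: int, sex: str,
                           params: VoleParams) -> bool:
    """Crowding effects apply once the local count reaches the scaled V13.

    The threshold scales with the ratio of the sex-specific minimum
    territory area to the female minimum territory area.
    """
    if local_count < 0:
        raise ValueError("local_count must be non-negative")
    return local_count >= params.scaled_density_threshold(sex)


def male_restlessness(overlapping_females: int, params: VoleParams,
                      rng: np.random.Generator) -> bool:
    """A breeding-season male with no overlapping females moves w.p. V12."""
    if overlapping_females > 0:
        return False
    return rng.random() < params.male_move_prob_no_females


def infanticide_success_prob(litter_age_days: float,
                             params: VoleParams) -> float:
    """Success declines linearly with pup age, reaching 0 at weaning."""
    return max(0.0, 1.0 - litter_age_days / params.weaning_age)


def infanticide_attempt(litter_age_days: int, params: VoleParams,
                        rng: np.random.Generator) -> bool:
    """True if an encountered unweaned litter is killed.

    An attempt happens with probability V17; it succeeds with probability
    falling from 1 at birth to 0 at weaning age.  Weaned litters are out of
    reach (the pups are independent agents).
    """
    if litter_age_days >= params.weaning_age:
        return False
    if rng.random() >= params.infanticide_prob:
        return False
    return rng.random() < infanticide_success_prob(litter_age_days, params)
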