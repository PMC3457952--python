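"""Simulation driver: world state assembly and the day loop.

:class:`Simulation` owns the struct-of-arrays world state and advances it
through the compiled daily scheduler.  A run is fully determined by
(landscape, parameters, weather profile, seed): the single RNG stream is
seeded once at construction and every stochastic event draws from it in a
fixed documented order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel as K
from .io import synthetic_weather
from .landscape import (BASE_QUALITY, GROWTH_INCREMENT, HabitatClass,
                        HabitatGrid, WeatherSeries, breeding_window,
                        quality_field)
from .params import MONTH_DAYS, VoleParams
from .predation import PredatorParams

__all__ = ["Simulation", "SimResult", "run_scenario"]

#: Initial seeding density, voles per hectare of habitat.
INIT_DENSITY_PER_HA = 40.0

@dataclass
class SimResult:
    """Outputs of one run."""

    counts: pd.DataFrame            # per day: males, females, adult_m, adult_f, predators
    deaths: dict
    captures: pd.DataFrame | None
    snapshots: list                 # list of (day, ages, sexes) arrays
    patch_counts: np.ndarray | None  # (days, n_patches) total voles
    grid: HabitatGrid
    params: VoleParams
    overflow: int = 0
    born: tuple = (0, 0)            # weaned recruits (females, males)

    @property
    def total(self) -> np.ndarray:
        return (self.counts["males"] + self.counts["females"]).to_numpy()

    def annual_peaks(self, burn_in_years: int = 0) -> np.ndarray:
        """Peak daily abundance per simulated year after burn-in."""
        tot = self.total
        years = len(tot) // 365
        peaks = [tot[y * 365:(y + 1) * 365].max() for y in range(years)]
        return np.asarray(peaks[burn_in_years:], dtype=float)


class Simulation:
    def __init__(self, grid: HabitatGrid, params: VoleParams | None = None,
                 years: int = 10, seed: int = 0,
                 weather_profile: str = "finland_like",
                 weather: list[WeatherSeries] | None = None,
                 predators: PredatorParams | None = None,
                 predator_start_year: int = 0,
                 vole_immigration: int = 0,
                 traps: np.ndarray | None = None,
                 capture_start_year: int | None = None,
                 record_patch: bool = False,
                 snapshot_days: list[int] | None = None,
                 init_density: float = INIT_DENSITY_PER_HA):
        self.grid = grid
        self.params = params or VoleParams()
        self.years = years
        self.n_days = years * 365
        self.seed = int(seed)
        self.predators = predators
        self.predator_start_year = predator_start_year
        self.vole_immigration = int(vole_immigration)
        self.t = 0

        p = self.params
        h, w = grid.codes.shape
        self._patch = grid.patch_ids
        npatch = grid.n_patches
        self._baseq_p = np.array(
            [BASE_QUALITY[HabitatClass(int(c))] for c in grid.patch_class])
        self._growth_p = np.array(
            [GROWTH_INCREMENT[HabitatClass(int(c))] for c in grid.patch_class])
        self._barrier = grid.barrier_mask().astype(np.uint8)
        # within-class quality heterogeneity; one realization per replicate
        self._qmul = quality_field((h, w), seed=self.seed + 10_000_019)

        # weather -> per-day drivers; one synthetic year per simulated year
        rng = np.random.default_rng(self.seed)
        if weather is None:
            weather = [synthetic_weather(weather_profile,
                                         seed=int(rng.integers(2 ** 31)))
                       for _ in range(years)]
        self.weather = weather
        growth_ok = np.zeros(self.n_days, dtype=np.uint8)
        conceive_ok = np.zeros(self.n_days, dtype=np.uint8)
        self.windows = []
        for yidx in range(years):
            wx = weather[yidx % len(weather)]
            t_year = wx.temp_c[:365]
            growth_ok[yidx * 365:(yidx + 1) * 365] = t_year >= p.grass_growth_temp
            win = breeding_window(wx, p)
            self.windows.append(win)
            if win.start_day is not None:
                a = yidx * 365 + win.start_day - 1
                b = yidx * 365 + win.end_day - 1
                conceive_ok[a:b] = 1
        self._growth_ok = growth_ok
        self._conceive_ok = conceive_ok

        # vegetation
        self._veg_ring = np.zeros((npatch, K.NEW_GREEN_AGE))
        self._veg_total = np.zeros(npatch)
        self._veg_head = np.zeros(1, dtype=np.int64)
        self._digest = np.full(npatch, 0.7)

        # agents
        habitat_ha = float(np.count_nonzero(self._baseq_p[grid.patch_ids] > 0)) / 1e4
        self.habitat_ha = habitat_ha
        N = int(max(4000, habitat_ha * 600))
        self.capacity = N
        self._alive = np.zeros(N, dtype=np.uint8)
        self._sex = np.zeros(N, dtype=np.uint8)
        self._age = np.zeros(N, dtype=np.int32)
        self._x = np.zeros(N, dtype=np.int32)
        self._y = np.zeros(N, dtype=np.int32)
        self._natal_x = np.zeros(N, dtype=np.int32)
        self._natal_y = np.zeros(N, dtype=np.int32)
        self._lifespan = np.zeros(N, dtype=np.int32)
        self._tx = np.zeros(N, dtype=np.int32)
        self._ty = np.zeros(N, dtype=np.int32)
        self._tr = np.zeros(N, dtype=np.int32)
        self._uid = np.zeros(N, dtype=np.int64)
        self._preg_due = np.full(N, -1, dtype=np.int32)
        self._nursing = np.full(N, -1, dtype=np.int32)
        self._heading = np.zeros(N, dtype=np.float64)
        self._disp_left = np.zeros(N, dtype=np.int32)
        self._uid_counter = np.zeros(1, dtype=np.int64)

        NL = max(1024, N // 8)
        self._l_alive = np.zeros(NL, dtype=np.uint8)
        self._l_mother = np.full(NL, -1, dtype=np.int32)
        self._l_x = np.zeros(NL, dtype=np.int32)
        self._l_y = np.zeros(NL, dtype=np.int32)
        self._l_born = np.zeros(NL, dtype=np.int32)
        self._l_size = np.zeros(NL, dtype=np.int16)

        self._occ = np.zeros((h, w), dtype=np.int32)
        self._occ_af = np.zeros((h, w), dtype=np.int32)

        # predators
        NP = int(predators.max_predators) if predators else 1
        self._pd_alive = np.zeros(NP, dtype=np.uint8)
        self._pd_x = np.zeros(NP, dtype=np.int32)
        self._pd_y = np.zeros(NP, dtype=np.int32)
        self._pd_unsucc = np.zeros(NP, dtype=np.int32)
        self._pd_repro_year = np.full(NP, -1, dtype=np.int32)
        self._PP = (predators.to_array() if predators
                    else np.zeros(K.NQ_PARAMS))
        hab_mask = self._baseq_p[grid.patch_ids] > 0
        hys, hxs = np.nonzero(hab_mask)
        self._hab_xs = hxs.astype(np.int32)
        self._hab_ys = hys.astype(np.int32)

        # traps
        if traps is None:
            self._traps = None
            self._trap_map = np.full((h, w), -1, dtype=np.int32)
            self._capture_start = -1
        else:
            from .trapping import trap_cell_map
            self._traps = np.asarray(traps, dtype=float)
            self._trap_map = trap_cell_map(self._traps, (h, w))
            start_year = capture_start_year if capture_start_year is not None else 0
            self._capture_start = start_year * 365
        ncap = 2_000_000 if self._capture_start >= 0 else 1
        self._cap_day = np.zeros(ncap, dtype=np.int32)
        self._cap_trap = np.zeros(ncap, dtype=np.int32)
        self._cap_uid = np.zeros(ncap, dtype=np.int64)
        self._cap_age = np.zeros(ncap, dtype=np.int32)
        self._cap_sex = np.zeros(ncap, dtype=np.int8)
        self._cap_nx = np.zeros(ncap, dtype=np.int32)
        self._cap_ny = np.zeros(ncap, dtype=np.int32)
        self._cap_x = np.zeros(ncap, dtype=np.int32)
        self._cap_y = np.zeros(ncap, dtype=np.int32)
        self._cap_count = np.zeros(1, dtype=np.int64)

        # outputs
        self._out_counts = np.zeros((self.n_days, 5), dtype=np.int32)
        self._record_patch = 1 if record_patch else 0
        self._out_patch_n = (np.zeros((self.n_days, npatch), dtype=np.int32)
                             if record_patch else np.zeros((1, 1), dtype=np.int32))
        self._deaths = np.zeros(K.ND_CAUSES * 2, dtype=np.int64)
        self._overflow = np.zeros(3, dtype=np.int64)  # [overflow, born_f, born_m]

        snapshot_days = snapshot_days or []
        self._snap_days = list(snapshot_days)
        self._snap_idx = np.full(self.n_days, -1, dtype=np.int32)
        for i, d in enumerate(snapshot_days):
            self._snap_idx[d] = i
        S = max(1, len(snapshot_days))
        self._snap_age = np.full((S, N), -1, dtype=np.int16)
        self._snap_sex = np.zeros((S, N), dtype=np.int8)

        # spatial-hash scratch
        bx_n = (w + K.HASH_BS - 1) // K.HASH_BS
        by_n = (h + K.HASH_BS - 1) // K.HASH_BS
        self._th_heads = np.full(bx_n * by_n, -1, dtype=np.int32)
        self._th_next = np.full(N, -1, dtype=np.int32)
        self._ah_heads = np.full(bx_n * by_n, -1, dtype=np.int32)
        self._ah_next = np.full(N, -1, dtype=np.int32)

        self._P = self._param_array(p)
        K.seed_rng(self.seed % (2 ** 31))
        self._init_population(rng, init_density)
        if predators:
            self._init_predators(rng)

    @staticmethod
    def _param_array(p: VoleParams) -> np.ndarray:
        P = np.zeros(K.NP_PARAMS)
        P[K.P_MALE_MIN_AGE] = p.male_min_repro_age
        P[K.P_FEMALE_MIN_AGE] = p.female_min_repro_age
        P[K.P_QUALITY_MULT] = p.quality_multiplier
        P[K.P_F_MIN_R] = p.female_min_radius
        P[K.P_F_MAX_R] = p.female_max_radius
        P[K.P_M_MIN_R] = p.male_min_radius
        P[K.P_M_MAX_R] = p.male_max_radius
        P[K.P_EVICT_GAP] = p.eviction_age_gap
        P[K.P_DISP_MORT] = p.dispersal_mortality
        P[K.P_DAILY_MORT] = p.daily_mortality
        P[K.P_MALE_MOVE] = p.male_move_prob_no_females
        P[K.P_DENS_THRESH] = p.density_threshold
        P[K.P_V17] = p.infanticide_prob
        P[K.P_WEAN_AGE] = p.weaning_age
        P[K.P_LIFE_MEAN_D] = p.lifespan_mean_months * MONTH_DAYS
        P[K.P_LIFE_SD_D] = p.lifespan_sd_months * MONTH_DAYS
        P[K.P_GESTATION] = p.gestation_days
        P[K.P_LITTER_MEAN] = p.litter_size_mean
        P[K.P_DISP_STEP] = p.dispersal_step
        P[K.P_INF_RADIUS] = p.infanticide_radius
        P[K.P_MALE_NEEDS_F] = 1.0 if p.male_needs_female_to_settle else 0.0
        P[K.P_BIOMASS_DECAY] = 0.01
        P[K.P_MALE_EXC_PROB] = p.male_excursion_prob
        P[K.P_MALE_EXC_RADIUS] = p.male_excursion_radius
        P[K.P_P_FAR] = p.disperser_fraction
        P[K.P_DISP_MIN_D] = p.disperser_min_days
        P[K.P_DISP_MAX_D] = p.disperser_max_days
        P[K.P_MALE_RANGE_R] = p.male_range_radius
        P[K.P_DISP_MALE_X] = p.disperser_male_factor
        P[K.P_OBLIGATE_STEP] = p.obligate_step
        P[K.P_THRESH_MODE] = p.density_boundary_mode
        P[K.P_EXC_OFFSEASON] = p.offseason_excursion_scale
        P[K.P_DD_GATE] = p.disperser_gate_frac
        return P

    def _init_population(self, rng: np.random.Generator, density: float) -> None:
        n0 = int(round(self.habitat_ha * density))
        n0 = min(n0, self.capacity)
        quality_ok = self._baseq_p[self.grid.patch_ids] > 0
        ys, xs = np.nonzero(quality_ok)
        if len(ys) == 0 or n0 == 0:
            return
        pick = rng.integers(0, len(ys), size=n0)
        p = self.params
        for i in range(n0):
            self._alive[i] = 1
            self._sex[i] = i % 2
            self._age[i] = int(rng.integers(30, 200))
            self._x[i] = xs[pick[i]]
            self._y[i] = ys[pick[i]]
            self._natal_x[i] = self._x[i]
            self._natal_y[i] = self._y[i]
            ls = rng.normal(p.lifespan_mean_months * MONTH_DAYS,
                            p.lifespan_sd_months * MONTH_DAYS)
            self._lifespan[i] = max(self._age[i] + 1, int(round(ls)))
            self._preg_due[i] = -1
            self._nursing[i] = -1
            self._uid[i] = i
            self._occ[self._y[i], self._x[i]] += 1
            if self._sex[i] == 0 and self._age[i] >= p.female_min_repro_age:
                self._occ_af[self._y[i], self._x[i]] += 1
        self._uid_counter[0] = n0

    def _init_predators(self, rng: np.random.Generator) -> None:
        pp = self.predators
        quality_ok = self._baseq_p[self.grid.patch_ids] > 0
        ys, xs = np.nonzero(quality_ok)
        n0 = min(pp.initial_predators, len(self._pd_alive))
        pick = rng.integers(0, len(ys), size=n0)
        for i in range(n0):
            self._pd_alive[i] = 1
            self._pd_x[i] = xs[pick[i]]
            self._pd_y[i] = ys[pick[i]]

    # ------------------------------------------------------------------

    def run(self, days: int | None = None) -> SimResult:
        t1 = self.n_days if days is None else min(self.n_days, self.t + days)
        if t1 > self.t:
            K.run_days(
                self.t, t1,
                self._patch, self._baseq_p, self._growth_p, self._qmul,
                self._barrier,
                self._veg_ring, self._veg_total, self._veg_head, self._digest,
                self._growth_ok, self._conceive_ok, self.vole_immigration,
                self._alive, self._sex, self._age, self._x, self._y,
                self._natal_x, self._natal_y, self._lifespan,
                self._tx, self._ty, self._tr, self._uid,
                self._preg_due, self._nursing, self._heading,
                self._disp_left, self._uid_counter,
                self._l_alive, self._l_mother, self._l_x, self._l_y,
                self._l_born, self._l_size,
                self._occ, self._occ_af,
                1 if self.predators else 0,
                self.predator_start_year * 365,
                self._pd_alive, self._pd_x, self._pd_y,
                self._pd_unsucc, self._pd_repro_year, self._PP,
                self._hab_xs, self._hab_ys,
                self._trap_map, self._capture_start,
                self._cap_day, self._cap_trap, self._cap_uid, self._cap_age,
                self._cap_sex, self._cap_nx, self._cap_ny,
                self._cap_x, self._cap_y, self._cap_count,
                self._out_counts, self._out_patch_n, self._record_patch,
                self._deaths, self._overflow,
                self._snap_idx, self._snap_age, self._snap_sex,
                self._th_heads, self._th_next, self._ah_heads, self._ah_next,
                self._P, K.RING_DY, K.RING_DX, K.RING_PTR,
            )
            self.t = t1
        return self.result()

    def step_day(self) -> SimResult:
        """Advance exactly one day."""
        return self.run(days=1)

    @property
    def n_alive(self) -> int:
        return int(self._alive.sum())

    def result(self) -> SimResult:
        counts = pd.DataFrame(
            self._out_counts[:self.t],
            columns=["males", "females", "adult_m", "adult_f", "predators"])
        d = self._deaths
        deaths = {name: int(d[2 * c] + d[2 * c + 1])
                  for name, c in (("lifespan", K.D_LIFESPAN),
                                  ("background", K.D_BACKGROUND),
                                  ("dispersal", K.D_DISPERSAL),
                                  ("predation", K.D_PREDATION),
                                  ("infanticide", K.D_INFANTICIDE))}
        deaths["by_sex"] = {name: (int(d[2 * c]), int(d[2 * c + 1]))
                            for name, c in (("lifespan", K.D_LIFESPAN),
                                            ("background", K.D_BACKGROUND),
                                            ("dispersal", K.D_DISPERSAL),
                                            ("predation", K.D_PREDATION))}
        captures = None
        if self._capture_start >= 0:
            n = int(self._cap_count[0])
            tid = self._cap_trap[:n]
            captures = pd.DataFrame({
                "trap_x": self._traps[tid, 0] if n else np.array([]),
                "trap_y": self._traps[tid, 1] if n else np.array([]),
                "natal_x": self._cap_nx[:n],
                "natal_y": self._cap_ny[:n],
                "day": self._cap_day[:n],
                "vole_id": self._cap_uid[:n],
                "age_days": self._cap_age[:n],
                "sex": np.where(self._cap_sex[:n] == 0, "F", "M"),
                "trap_id": self._cap_trap[:n],
            })
        snapshots = []
        for i, d in enumerate(self._snap_days):
            mask = self._snap_age[i] >= 0
            snapshots.append((d, self._snap_age[i][mask].copy(),
                              self._snap_sex[i][mask].copy()))
        return SimResult(
            counts=counts, deaths=deaths, captures=captures,
            snapshots=snapshots,
            patch_counts=self._out_patch_n if self._record_patch else None,
            grid=self.grid, params=self.params,
            overflow=int(self._overflow[0]),
            born=(int(self._overflow[1]), int(self._overflow[2])))


def run_scenario(grid: HabitatGrid, params: VoleParams | None = None,
                 years: int = 10, seed: int = 0, **kwargs) -> SimResult:
    """Build a :class:`Simulation` and run it to completion."""
    sim = Simulation(grid, params, years=years, seed=seed, **kwargs)
    return sim.run()
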