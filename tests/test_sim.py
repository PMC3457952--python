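import numpy as np
from scipy import stats as sstats

from volepom import VoleParams, generate_landscape
from volepom.sim import Simulation


def _cold_profile_sim(grid, params, years=1, seed=0, **kw):
    """Simulation under constant sub-growth temperature: no breeding."""
    from volepom.landscape import WeatherSeries
    weather = [WeatherSeries(np.zeros(365), np.zeros(365))]
    return Simulation(grid, params, years=years, seed=seed, weather=weather,
                      **kw)


class TestDeterminism:
    def test_same_seed_bit_identical(self, small_block):
        a = Simulation(small_block, VoleParams(), years=2, seed=11).run()
        b = Simulation(small_block, VoleParams(), years=2, seed=11).run()
        assert a.counts.equals(b.counts)
        assert a.deaths == b.deaths

    def test_different_seeds_differ(self, small_block):
        a = Simulation(small_block, VoleParams(), years=2, seed=1).run()
        b = Simulation(small_block, VoleParams(), years=2, seed=2).run()
        assert not a.counts.equals(b.counts)

    def test_step_day_chunking_equivalent(self, small_block):
        whole = Simulation(small_block, VoleParams(), years=1, seed=5)
        whole.run(days=30)
        stepped = Simulation(small_block, VoleParams(), years=1, seed=5)
        for _ in range(30):
            stepped.step_day()
        assert whole.result().counts.iloc[:30].equals(
            stepped.result().counts.iloc[:30])


class TestPopulationAccounting:
    def test_empty_world_stays_empty(self, small_block):
        sim = Simulation(small_block, VoleParams(), years=1, seed=0,
                         init_density=0.0)
        r = sim.run(days=100)
        assert sim.t == 100
        assert r.counts.iloc[:100].to_numpy().sum() == 0

    def test_counts_never_negative_and_consistent(self, small_block):
        r = Simulation(small_block, VoleParams(), years=2, seed=3).run()
        c = r.counts
        assert (c.to_numpy() >= 0).all()
        assert (c.adult_m <= c.males).all()
        assert (c.adult_f <= c.females).all()

    def test_no_overflow_in_standard_run(self, small_block):
        r = Simulation(small_block, VoleParams(), years=2, seed=3).run()
        assert r.overflow == 0

    def test_lone_female_never_conceives(self, small_block):
        sim = Simulation(small_block, VoleParams(), years=1, seed=2,
                         init_density=0.0)
        h, w = small_block.codes.shape
        sim._alive[0] = 1
        sim._sex[0] = 0
        sim._age[0] = 100
        sim._x[0] = sim._y[0] = h // 2
        sim._lifespan[0] = 5000
        sim._occ[h // 2, h // 2] += 1
        sim._occ_af[h // 2, h // 2] += 1
        r = sim.run()
        assert r.born == (0, 0)


class TestDemographicProperties:
    def test_survival_under_background_hazard_only(self):
        """With V9 = 0 and no breeding, survival follows (1 - V10)^t."""
        grid = generate_landscape("homogeneous_block", dims=650)
        p = VoleParams(dispersal_mortality=0.0, lifespan_mean_months=200,
                       lifespan_sd_months=0.1)
        sim = _cold_profile_sim(grid, p, init_density=480.0)
        n0 = sim.n_alive
        assert n0 > 15_000
        sim.run(days=365)
        expected = (1 - p.daily_mortality) ** 365
        se = np.sqrt(expected * (1 - expected) / n0)
        assert abs(sim.n_alive / n0 - expected) < 3 * se

    def test_only_lifespan_deaths_without_hazards(self, small_block):
        p = VoleParams(dispersal_mortality=0.0, daily_mortality=0.0)
        sim = _cold_profile_sim(small_block, p, init_density=30.0)
        r = sim.run(days=365)
        assert r.deaths["background"] == 0
        assert r.deaths["dispersal"] == 0
        assert r.deaths["predation"] == 0

    def test_weaned_sex_ratio_is_binomial(self, ):
        grid = generate_landscape("homogeneous_block", dims=200)
        r = Simulation(grid, VoleParams(), years=7, seed=9).run()
        f, m = r.born
        assert f + m > 10_000
        assert sstats.binomtest(m, m + f, 0.5).pvalue > 0.01

    def test_no_weaned_young_before_gestation_plus_weaning(self):
        grid = generate_landscape("homogeneous_block", dims=120)
        sim = Simulation(grid, VoleParams(), years=3, seed=4)
        r = sim.run()
        c = r.counts
        juveniles = (c.males + c.females - c.adult_m - c.adult_f).to_numpy()
        p = sim.params
        for year, win in enumerate(sim.windows):
            if win.start_day is None:
                continue
            earliest = (year * 365 + win.start_day - 1
                        + p.gestation_days + p.weaning_age)
            seg = juveniles[year * 365:earliest]
            assert (seg == 0).all(), f"juveniles before weaning in year {year}"

    def test_weanlings_enter_at_age_fourteen(self, small_block):
        """Offspring become independent agents exactly at weaning age."""
        sim = Simulation(small_block, VoleParams(), years=1, seed=6,
                         init_density=0.0)
        h = small_block.codes.shape[0]
        cx = h // 2
        # one pregnant, territorial female due to give birth tomorrow
        sim._alive[0] = 1
        sim._sex[0] = 0
        sim._age[0] = 100
        sim._x[0] = sim._y[0] = cx
        sim._tx[0] = sim._ty[0] = cx
        sim._tr[0] = 8
        sim._lifespan[0] = 5000
        sim._preg_due[0] = 1
        sim._occ[cx, cx] += 1
        sim._occ_af[cx, cx] += 1
        sim.run(days=2 + sim.params.weaning_age)
        new = (sim._alive == 1) & (np.arange(sim.capacity) != 0)
        assert new.sum() >= 1
        assert (sim._age[new] == sim.params.weaning_age).all()


class TestDispersalContracts:
    def test_dispersal_only_world_never_settles(self):
        """A vole in pure dispersal-only habitat keeps moving forever and
        can die only through the hazards (here disabled)."""
        from volepom.landscape import HabitatClass, HabitatGrid
        codes = np.full((120, 120), int(HabitatClass.DISPERSAL_ONLY),
                        dtype=np.int8)
        grid = HabitatGrid(codes)
        p = VoleParams(dispersal_mortality=0.0, daily_mortality=0.0)
        sim = _cold_profile_sim(grid, p, init_density=0.0)
        sim._alive[0] = 1
        sim._sex[0] = 1
        sim._age[0] = 100
        sim._x[0] = sim._y[0] = 60
        sim._lifespan[0] = 5000
        sim._occ[60, 60] += 1
        sim.run(days=200)
        assert sim.n_alive == 1          # only hazards can kill it
        assert sim._tr[0] == 0           # never acquired a territory
        assert (sim._x[0], sim._y[0]) != (60, 60)  # kept moving
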