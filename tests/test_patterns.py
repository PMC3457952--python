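import numpy as np
import pandas as pd
import pytest

from volepom.patterns import (age_structure_fit, cycle_metrics,
                              evaluate_pattern_set, female_density,
                              habitat_density_fit, mid_month_days, sex_ratio)


def _counts(males, females, days=365):
    m = np.full(days, males, dtype=int)
    f = np.full(days, females, dtype=int)
    return pd.DataFrame({"males": m, "females": f,
                         "adult_m": m, "adult_f": f,
                         "predators": np.zeros(days, int)})


class TestSexRatio:
    def test_balanced_population(self):
        assert sex_ratio(_counts(50, 50), 90) == pytest.approx(1.0)

    def test_female_biased_population(self):
        assert sex_ratio(_counts(40, 78), 200) == pytest.approx(1.95)

    def test_varying_counts_match_brute_force(self):
        days = 365
        m = np.arange(1, days + 1)
        f = 2 * m + 10
        counts = pd.DataFrame({"males": m, "females": f, "adult_m": m,
                               "adult_f": f, "predators": 0 * m})
        got = sex_ratio(counts, 200, window_days=15)
        expected = np.mean([f[d] / m[d] for d in range(184, 215)])
        assert got == pytest.approx(expected)

    def test_ratio_of_sums_variant(self):
        got = sex_ratio(_counts(40, 78), 200, method="ratio_of_sums")
        assert got == pytest.approx(1.95)

    def test_no_males_raises(self):
        with pytest.raises(ZeroDivisionError):
            sex_ratio(_counts(0, 50), 90)


class TestFemaleDensity:
    def test_constant_counts(self):
        assert female_density(_counts(0, 300), 4.0) == pytest.approx(75.0)

    def test_zero_females(self):
        assert female_density(_counts(10, 0), 4.0) == 0.0

    def test_window_mean_matches_hand_computation(self):
        f = np.arange(365, dtype=float)
        counts = pd.DataFrame({"males": f, "females": f, "adult_m": f,
                               "adult_f": f, "predators": 0 * f})
        got = female_density(counts, 2.0, day=200, window_days=15)
        assert got == pytest.approx(f[184:215].mean() / 2.0)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            female_density(_counts(1, 1), 0.0)


class TestAgeStructureFit:
    def test_identical_proportions_fit_zero(self):
        props = np.array([[0.5, 0.3, 0.2]] * 5)
        assert age_structure_fit(props, props) == 0.0

    def test_hand_computed_single_month_deviation(self):
        target = np.array([[0.5, 0.5]] * 5)
        model = target.copy()
        model[0] = [0.6, 0.4]
        assert age_structure_fit(model, target) == pytest.approx(0.004)

    def test_positive_whenever_different(self):
        target = np.full((5, 4), 0.25)
        rng = np.random.default_rng(0)
        for _ in range(20):
            noise = rng.dirichlet(np.ones(4), size=5)
            if not np.allclose(noise, target):
                assert age_structure_fit(noise, target) > 0

    def test_empty_month_excluded_with_warning(self):
        target = np.array([[0.5, 0.5]] * 5)
        model = target.copy().astype(float)
        model[2] = np.nan
        with pytest.warns(UserWarning, match="no animals"):
            fit = age_structure_fit(model, target)
        assert fit == 0.0

    def test_monotone_in_perturbation(self):
        """The fit degrades smoothly as proportions drift from the target."""
        target = np.array([[0.4, 0.3, 0.2, 0.1]] * 5)
        fits = []
        for eps in (0.0, 0.05, 0.1, 0.2):
            model = target + np.array([eps, -eps, 0, 0])
            fits.append(age_structure_fit(model, target))
        assert fits == sorted(fits)
        assert fits[0] == 0.0 and fits[1] > 0


def _tables(n=22, density=50.0):
    combos = [(f"hab{i}", s) for i in range(6)
              for s in ("spring", "summer", "autumn", "winter")][:n]
    habs = [h for h, _ in combos]
    seasons = [s for _, s in combos]
    target = pd.DataFrame({"habitat": habs, "season": seasons,
                           "density": [density] * n,
                           "lumped": [False] * n})
    model = target.drop(columns="lumped").copy()
    return model, target


class TestHabitatDensityFit:
    def test_perfect_match_passes(self):
        model, target = _tables()
        table, total, passed = habitat_density_fit(model, target)
        assert total == 0.0 and passed

    def test_single_factor_e_deviation(self):
        model, target = _tables()
        model.loc[0, "density"] *= np.e
        _, total, passed = habitat_density_fit(model, target)
        assert total == pytest.approx(1.0) and passed

    def test_all_observations_off_by_half_log_unit_fails(self):
        model, target = _tables(n=22)
        model["density"] *= np.exp(0.5)
        _, total, passed = habitat_density_fit(model, target)
        assert total == pytest.approx(11.0)
        assert not passed  # 11.0 > the 10.0 pass mark

    def test_lumped_category_zero_inside(self):
        model, target = _tables(n=4)
        target["lumped"] = True
        model["density"] = [5.0, 8.9, 9.0, 18.0]
        table, total, _ = habitat_density_fit(model, target)
        devs = table["ln_deviation"].to_numpy()
        assert devs[0] == 0.0 and devs[1] == 0.0
        assert devs[2] == pytest.approx(0.0)  # ln(9/9)
        assert devs[3] == pytest.approx(np.log(2.0))

    def test_missing_observation_reported(self):
        model, target = _tables()
        with pytest.raises(KeyError, match="hab0"):
            habitat_density_fit(model.iloc[1:], target)

    def test_common_scaling_invariance(self):
        model, target = _tables()
        rng = np.random.default_rng(1)
        model["density"] *= np.exp(rng.normal(0, 0.2, len(model)))
        _, t1, _ = habitat_density_fit(model, target)
        model2 = model.copy()
        target2 = target.copy()
        model2["density"] *= 3.7
        target2["density"] *= 3.7
        _, t2, _ = habitat_density_fit(model2, target2)
        assert t1 == pytest.approx(t2)


class TestCycleMetrics:
    def test_amplitude_formula(self):
        series = np.array([100, 500, 2008.6, 700, 150, 400, 1200, 300])
        m = cycle_metrics(series)
        assert m.amplitude == pytest.approx(np.log(2008.6 / 100), abs=1e-6)

    def test_constant_series_is_regime_three(self):
        m = cycle_metrics(np.full(20, 500.0))
        assert m.amplitude == 0.0
        assert np.isnan(m.period_years)
        assert m.regime == 3

    def test_sawtooth_period(self):
        base = np.array([100, 300, 900, 2000, 500])
        series = np.tile(base, 5)
        m = cycle_metrics(series)
        assert m.period_years == pytest.approx(5.0)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(50, 5000, 30)
        a = cycle_metrics(s)
        b = cycle_metrics(s * 13.7)
        assert a.amplitude == pytest.approx(b.amplitude)
        assert a.regime == b.regime

    def test_zero_minimum_clamped_and_flagged(self):
        m = cycle_metrics(np.array([0.0, 10, 400, 30, 0, 20, 500, 10]))
        assert m.min_clamped
        assert np.isfinite(m.amplitude)


class TestEvaluatePatternSet:
    def test_marginal_sex_ratio_flagged(self):
        rep = evaluate_pattern_set(
            {"sex_ratio_day90": 1.021, "sex_ratio_day200": 1.95,
             "female_density": 75.0}, 1)
        row = rep.to_frame().set_index("pattern").loc["sex_ratio_day90"]
        assert not row.passed       # 2.1% is outside the 2% criterion
        assert row.marginal         # but flagged as borderline
        assert rep.to_frame().set_index("pattern").loc["female_density"].passed

    def test_habitat_density_pass_mark(self):
        rep = evaluate_pattern_set({"total_ln_dev": 11.0}, 2)
        assert not rep.all_passed
        rep2 = evaluate_pattern_set({"total_ln_dev": 9.0}, 2)
        assert rep2.all_passed

    def test_philopatry_criterion(self):
        from volepom.trapping import DispersalStats
        ds = DispersalStats(
            philopatry_pct={"M": 1.0, "F": 0.3},
            mean_successive_dist={"M": 10.2, "F": 9.0},
            mean_max_dist={"M": 28.6, "F": 22.4},
            natal_far_pct=13.8, natal_near_pct=60.0)
        rep = evaluate_pattern_set(ds, 3)
        frame = rep.to_frame().set_index("pattern")
        assert frame.loc["philopatry_M"].passed
        assert frame.loc["philopatry_F"].passed
        assert rep.all_passed


def test_mid_month_days_land_on_the_fifteenth():
    days = mid_month_days([5], years=1)
    # May 15 in a 365-day year: 31+28+31+30+15 = 135 -> index 134
    assert days == [134]
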