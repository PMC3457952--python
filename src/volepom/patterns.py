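"""Pattern statistics and pass/fail evaluation for the four pattern sets.

Set 1: population sex ratios, female density and age structure in a
homogeneous high-quality block.  Set 2: seasonal density across habitat
classes on a mixed landscape, scored as total absolute natural-log
deviation.  Set 3: dispersal statistics from the virtual trapping grids
(computed in :mod:`volepom.trapping`).  Set 4: multi-annual cycle metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PatternTargets", "CycleMetrics", "PatternFitReport",
    "sex_ratio", "female_density", "age_structure_props",
    "age_structure_fit", "habitat_density_fit", "cycle_metrics",
    "evaluate_pattern_set", "mid_month_days", "SEASONS",
]

#: Month -> season (meteorological seasons).
SEASONS = {3: "spring", 4: "spring", 5: "spring",
           6: "summer", 7: "summer", 8: "summer",
           9: "autumn", 10: "autumn", 11: "autumn",
           12: "winter", 1: "winter", 2: "winter"}

#: First day-of-year of each month (365-day calendar).
_MONTH_START = [1, 32, 60, 91, 121, 152, 182, 213, 244, 274, 305, 335]


def mid_month_days(months, years, burn_in_years: int = 0) -> list[int]:
    """Absolute day indices of the 15th of each month for analysis years."""
    days = []
    for y in range(burn_in_years, years):
        for m in months:
            days.append(y * 365 + _MONTH_START[m - 1] + 14 - 1)
    return days


@dataclass
class PatternTargets:
    """Printed fitting targets and tolerances."""

    sex_ratio_day90: float = 1.0        # females per male
    sex_ratio_day200: float = 1.95
    female_density_per_ha: float = 75.0
    relative_tolerance: float = 0.02    # +/- 2% criterion
    pass_mark_total_ln_dev: float = 10.0
    low_density_lump: float = 9.0       # voles/ha
    census_window_days: int = 15
    age_class_edges: tuple = (14, 30, 60, 90)  # days; final class open-ended
    age_structure_months: tuple = (5, 6, 7, 8, 9)
    philopatry_limit_pct: float = 2.0


@dataclass
class CycleMetrics:
    amplitude: float
    period_years: float
    low_phase_years: float
    regime: int
    min_clamped: bool = False


@dataclass
class PatternFitReport:
    """Per-pattern statistics against targets with recomputable pass flags."""

    rows: list = field(default_factory=list)

    def add(self, pattern: str, statistic: float, target: float,
            tolerance: float, passed: bool, marginal: bool = False) -> None:
        dev = statistic - target
        self.rows.append(dict(pattern=pattern, statistic=statistic,
                              target=target, deviation=dev,
                              tolerance=tolerance, passed=passed,
                              marginal=marginal))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    @property
    def all_passed(self) -> bool:
        return all(r["passed"] for r in self.rows)


def _window_days(day: int, window: int, years: int, burn_in: int) -> list[int]:
    days = []
    for y in range(burn_in, years):
        for d in range(day - window, day + window + 1):
            t = y * 365 + d - 1
            if 0 <= t:
                days.append(t)
    return days


def sex_ratio(counts: pd.DataFrame, day: int, window_days: int = 15,
              burn_in_years: int = 0, method: str = "mean_of_ratios") -> float:
    """Females-per-male around a census day, averaged across years.

    ``method='mean_of_ratios'`` averages the daily females/males ratio over
    qualifying days (days with zero males are skipped); ``'ratio_of_sums'``
    divides window-summed counts instead.
    """
    years = len(counts) // 365
    days = [t for t in _window_days(day, window_days, years, burn_in_years)
            if t < len(counts)]
    if not days:
        raise ValueError("series does not cover the census window")
    m = counts["males"].to_numpy()[days].astype(float)
    f = counts["females"].to_numpy()[days].astype(float)
    if method == "ratio_of_sums":
        if m.sum() == 0:
            raise ZeroDivisionError("no males in any census window")
        return float(f.sum() / m.sum())
    ok = m > 0
    if not ok.any():
        raise ZeroDivisionError("no males in any census window")
    return float((f[ok] / m[ok]).mean())


def female_density(counts: pd.DataFrame, area_ha: float, day: int = 200,
                   window_days: int = 15, burn_in_years: int = 0) -> float:
    """Mean female count over the census window per hectare of habitat."""
    if area_ha <= 0:
        raise ValueError("habitat area must be positive")
    years = len(counts) // 365
    days = [t for t in _window_days(day, window_days, years, burn_in_years)
            if t < len(counts)]
    f = counts["females"].to_numpy()[days].astype(float)
    return float(f.mean() / area_ha)


def age_structure_props(snapshots, sex: str, edges,
                        months, years_per_month: int | None = None) -> np.ndarray:
    """Proportion-by-age-class matrix from mid-month population snapshots.

    ``snapshots`` is the list of (day, ages, sexes) triples recorded at the
    mid-month days of the analysis months, cycling May..Sep per year; counts
    are pooled across years per calendar month, then converted to
    proportions.  Age classes are [edges[0], edges[1]), ...,
    [edges[-1], inf).
    """
    sex_code = 0 if sex == "F" else 1
    n_m = len(months)
    n_c = len(edges)
    pooled = np.zeros((n_m, n_c))
    for i, (day, ages, sexes) in enumerate(snapshots):
        mi = i % n_m
        a = ages[sexes == sex_code]
        for ci in range(n_c):
            lo = edges[ci]
            hi = edges[ci + 1] if ci + 1 < n_c else np.inf
            pooled[mi, ci] += np.count_nonzero((a >= lo) & (a < hi))
    totals = pooled.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        props = pooled / totals
    return props


def age_structure_fit(model_props: np.ndarray,
                      target_props: np.ndarray) -> float:
    """Mean over months of the summed squared proportion differences.

    Months whose model proportions are undefined (no animals) are excluded
    with a warning; the mean divisor stays the full number of target months
    so an empty month cannot improve the fit.
    """
    model_props = np.asarray(model_props, dtype=float)
    target_props = np.asarray(target_props, dtype=float)
    if model_props.shape != target_props.shape:
        raise ValueError("model/target shape mismatch")
    n_months = model_props.shape[0]
    total = 0.0
    for mi in range(n_months):
        row = model_props[mi]
        if np.isnan(row).any():
            warnings.warn(f"month index {mi}: no animals, excluded from fit")
            continue
        total += float(((row - target_props[mi]) ** 2).sum())
    return total / n_months


def habitat_density_fit(model_table: pd.DataFrame, target_table: pd.DataFrame,
                        lump: float = 9.0, pass_mark: float = 10.0):
    """Total absolute ln-scale deviation across (habitat, season) cells.

    Both tables carry columns ``habitat, season, density``; the target may
    mark rows ``lumped`` (the "<9 voles/ha" category), for which the
    deviation is 0 when the model is inside the category and ln(model/9)
    beyond it.  Returns (per-observation table, total, passed).
    """
    t = target_table.set_index(["habitat", "season"]).sort_index()
    m = model_table.set_index(["habitat", "season"]).sort_index()
    if t.index.duplicated().any() or m.index.duplicated().any():
        raise ValueError("duplicate (habitat, season) observations")
    missing = [ix for ix in t.index if ix not in m.index]
    if missing:
        raise KeyError(f"model table lacks observations for: {missing}")
    rows = []
    for (hab, season), trow in t.iterrows():
        model_d = float(m.loc[(hab, season), "density"])
        lumped = bool(trow.get("lumped", False))
        if lumped:
            dev = 0.0 if model_d < lump else float(np.log(model_d / lump))
        else:
            target_d = float(trow["density"])
            if model_d <= 0 or target_d <= 0:
                dev = np.inf
            else:
                dev = abs(float(np.log(model_d) - np.log(target_d)))
        rows.append(dict(habitat=hab, season=season, model=model_d,
                         lumped=lumped, ln_deviation=dev))
    table = pd.DataFrame(rows)
    total = float(table["ln_deviation"].sum())
    return table, total, total < pass_mark


def seasonal_patch_densities(patch_counts: np.ndarray, grid,
                             burn_in_years: int = 0) -> pd.DataFrame:
    """Model-side (habitat, season, density) table from daily patch counts.

    Seasonal mean density (voles/ha) per qualifying patch (the patch-table
    area rules), averaged over occupied patches of each habitat class.
    ``patch_counts`` is the (days, n_patches) recording of a run.
    """
    from .landscape import patch_table

    qualifying = patch_table(grid)
    n_days = patch_counts.shape[0]
    doy = np.arange(n_days) % 365 + 1
    year = np.arange(n_days) // 365
    month = np.searchsorted(_MONTH_START, doy, side="right")
    season = np.array([SEASONS[m] for m in month])
    keep = year >= burn_in_years
    areas = grid.patch_areas()
    rows = []
    for season_name in ("spring", "summer", "autumn", "winter"):
        sel = keep & (season == season_name)
        if not sel.any():
            continue
        mean_counts = patch_counts[sel].mean(axis=0)
        for hab, sub in qualifying.groupby("habitat"):
            dens = []
            for pid in sub["patch_id"]:
                d = mean_counts[pid] / (areas[pid] / 1e4)
                if d > 0:
                    dens.append(d)
            if dens:
                rows.append(dict(habitat=hab, season=season_name,
                                 density=float(np.mean(dens))))
    return pd.DataFrame(rows)


def cycle_metrics(annual_peaks: np.ndarray) -> CycleMetrics:
    """Cycle amplitude, period and low phase from annual peak abundances.

    Amplitude is ln(max/min) over the window (min clamped to one animal,
    flagged).  Period is the mean spacing of local maxima; the low phase is
    the mean run length of years below the series' geometric mean between
    peaks.  Regimes: deep regular cycles (amplitude >= 2.5) are regime 1,
    intermediate (>= 1.5) regime 2, weak fluctuations regime 3.
    """
    s = np.asarray(annual_peaks, dtype=float)
    if len(s) < 3:
        raise ValueError("need at least 3 years of peaks")
    clamped = False
    smin = s.min()
    if smin < 1.0:
        smin = 1.0
        clamped = True
    amplitude = float(np.log(s.max() / smin))

    # local maxima (strictly above the previous, at least equal to the next)
    peaks = [i for i in range(1, len(s) - 1)
             if s[i] > s[i - 1] and s[i] >= s[i + 1]]
    period = float(np.mean(np.diff(peaks))) if len(peaks) >= 2 else float("nan")

    gmean = float(np.exp(np.mean(np.log(np.maximum(s, 1.0)))))
    runs = []
    run = 0
    for v in s:
        if v < gmean:
            run += 1
        elif run:
            runs.append(run)
            run = 0
    if run:
        runs.append(run)
    low_phase = float(np.mean(runs)) if runs else 0.0

    if amplitude >= 2.5:
        regime = 1
    elif amplitude >= 1.5:
        regime = 2
    else:
        regime = 3
    return CycleMetrics(amplitude, period, low_phase, regime, clamped)


def evaluate_pattern_set(stats: dict, set_id: int,
                         targets: PatternTargets | None = None) -> PatternFitReport:
    """Apply the printed fitting criteria to computed statistics.

    ``stats`` keys by set: 1 -> sex_ratio_day90, sex_ratio_day200,
    female_density (optional age_structure_fit_m/f); 2 -> total_ln_dev;
    3 -> a :class:`~volepom.trapping.DispersalStats`; 4 -> list of
    (landscape label, CycleMetrics) expected to span the three regimes.
    """
    targets = targets or PatternTargets()
    rep = PatternFitReport()
    tol = targets.relative_tolerance
    if set_id == 1:
        for name, stat, tgt in [
                ("sex_ratio_day90", stats["sex_ratio_day90"],
                 targets.sex_ratio_day90),
                ("sex_ratio_day200", stats["sex_ratio_day200"],
                 targets.sex_ratio_day200),
                ("female_density", stats["female_density"],
                 targets.female_density_per_ha)]:
            rel = abs(stat - tgt) / tgt
            rep.add(name, stat, tgt, tol, rel <= tol,
                    marginal=tol < rel <= tol + 0.005)
        for key in ("age_structure_fit_m", "age_structure_fit_f"):
            if key in stats:
                rep.add(key, stats[key], 0.0, np.inf, True)
    elif set_id == 2:
        total = stats["total_ln_dev"]
        rep.add("habitat_density_total_ln_dev", total,
                0.0, targets.pass_mark_total_ln_dev,
                total < targets.pass_mark_total_ln_dev)
    elif set_id == 3:
        from .trapping import DispersalCriteria

        ds = stats
        crit = DispersalCriteria()
        for sex_label in ("M", "F"):
            p = ds.philopatry_pct[sex_label]
            rep.add(f"philopatry_{sex_label}", p, 0.0,
                    targets.philopatry_limit_pct,
                    bool(p < targets.philopatry_limit_pct))
        for sex_label, succ_band, max_band in (
                ("M", crit.succ_dist_male, crit.max_dist_male),
                ("F", crit.succ_dist_female, crit.max_dist_female)):
            s_val = ds.mean_successive_dist[sex_label]
            rep.add(f"succ_dist_{sex_label}", s_val, succ_band[0],
                    succ_band[1], bool(abs(s_val - succ_band[0]) <= succ_band[1]))
            m_val = ds.mean_max_dist[sex_label]
            rep.add(f"max_dist_{sex_label}", m_val, max_band[0],
                    max_band[1], bool(abs(m_val - max_band[0]) <= max_band[1]))
        rep.add("natal_far_pct", ds.natal_far_pct,
                crit.natal_far_target_pct, crit.natal_far_tol_pct,
                bool(abs(ds.natal_far_pct - crit.natal_far_target_pct)
                     <= crit.natal_far_tol_pct))
        rep.add("natal_near_pct", ds.natal_near_pct,
                crit.natal_near_target_pct, crit.natal_near_tol_pct,
                bool(abs(ds.natal_near_pct - crit.natal_near_target_pct)
                     <= crit.natal_near_tol_pct))
    elif set_id == 4:
        regimes = {m.regime for _, m in stats}
        for label, m in stats:
            rep.add(f"cycle_regime_{label}", m.regime, m.regime, 0.0, True)
        rep.add("all_three_regimes", float(len(regimes)), 3.0, 0.0,
                regimes == {1, 2, 3})
    else:
        raise ValueError(f"unknown pattern set {set_id}")
    return rep
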