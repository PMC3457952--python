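import numpy as np
import pandas as pd
import pytest

from volepom.trapping import (DispersalCriteria, TrapGridSpec,
                              build_trap_grids, dispersal_stats,
                              record_captures, trap_cell_map)


class TestTrapGrids:
    def test_trap_count(self):
        assert len(build_trap_grids()) == 3 * 14 * 7 == 294

    def test_within_grid_spacing(self):
        traps = build_trap_grids()
        first = traps[:98]
        d = np.hypot(first[:, None, 0] - first[None, :, 0],
                     first[:, None, 1] - first[None, :, 1])
        np.fill_diagonal(d, np.inf)
        assert d.min() == pytest.approx(7.0)

    def test_inter_grid_gap(self):
        traps = build_trap_grids()
        g1, g2 = traps[:98], traps[98:196]
        d = np.hypot(g1[:, None, 0] - g2[None, :, 0],
                     g1[:, None, 1] - g2[None, :, 1])
        assert d.min() == pytest.approx(30.0)

    def test_centered_spec_fits_map(self):
        spec = TrapGridSpec().centered(500, 400)
        traps = build_trap_grids(spec)
        assert traps[:, 0].min() > 0 and traps[:, 0].max() < 500
        assert traps[:, 1].min() > 0 and traps[:, 1].max() < 400


def _positions(rows):
    return pd.DataFrame(rows, columns=["x", "y", "vole_id", "natal_x",
                                       "natal_y", "day", "age_days", "sex"])


class TestRecordCaptures:
    traps = np.array([[10.0, 10.0], [17.0, 10.0]])

    def test_vole_within_radius_recorded(self):
        pos = _positions([(10.5, 10.0, 1, 0, 0, 5, 40, "F")])
        rec = record_captures(pos, self.traps)
        assert len(rec) == 1
        assert (rec.trap_x.iloc[0], rec.trap_y.iloc[0]) == (10.0, 10.0)

    def test_vole_outside_radius_ignored(self):
        pos = _positions([(13.5, 10.0, 1, 0, 0, 5, 40, "F")])
        assert len(record_captures(pos, self.traps)) == 0

    def test_equidistant_vole_yields_one_record(self):
        # halfway between traps is out of reach; use overlapping traps
        traps = np.array([[10.0, 10.0], [11.0, 10.0]])
        pos = _positions([(10.5, 10.0, 1, 0, 0, 5, 40, "F")])
        rec = record_captures(pos, traps)
        assert len(rec) == 1
        assert rec.trap_x.iloc[0] == 10.0  # lowest-index tie-break


class TestTrapCellMap:
    def test_cells_within_one_meter(self):
        traps = np.array([[5.0, 5.0]])
        m = trap_cell_map(traps, (11, 11))
        assert m[5, 5] == 0
        assert m[5, 6] == 0 and m[6, 5] == 0  # orthogonal, distance 1
        assert m[6, 6] == -1                  # diagonal, sqrt(2) > 1

    def test_nearest_trap_wins(self):
        traps = np.array([[5.0, 5.0], [7.0, 5.0]])
        m = trap_cell_map(traps, (11, 11))
        assert m[5, 6] == 0 and m[5, 7] == 1


def _brute_force_stats(records, criteria):
    """Independent recomputation over all capture pairs."""
    out = {}
    bx0, bx1 = records.trap_x.min(), records.trap_x.max()
    by0, by1 = records.trap_y.min(), records.trap_y.max()
    natal_pool = []
    for sex in ("M", "F"):
        hr = criteria.diameter(sex)
        cut = criteria.adult_age(sex)
        sub = records[records.sex == sex]
        succ, far, moves, maxima = [], 0, 0, []
        natal = []
        for vid in sorted(sub.vole_id.unique()):
            df = sub[sub.vole_id == vid].sort_values("day")
            pts = df[["trap_x", "trap_y"]].to_numpy(float)
            if len(pts) >= 2:
                dd = [float(np.hypot(*(pts[i + 1] - pts[i])))
                      for i in range(len(pts) - 1)]
                succ += dd
                best = 0.0
                for i in range(len(pts)):
                    for j in range(len(pts)):
                        best = max(best, float(np.hypot(*(pts[i] - pts[j]))))
                maxima.append(best)
            adult = df[df.age_days >= cut]
            if len(adult) >= 2:
                apts = adult[["trap_x", "trap_y"]].to_numpy(float)
                for i in range(len(apts) - 1):
                    d = float(np.hypot(*(apts[i + 1] - apts[i])))
                    moves += 1
                    far += d > 2 * hr
            if len(adult) >= 1:
                f0 = adult.iloc[0]
                if (bx0 - hr <= f0.natal_x <= bx1 + hr
                        and by0 - hr <= f0.natal_y <= by1 + hr):
                    natal.append(float(np.hypot(f0.trap_x - f0.natal_x,
                                                f0.trap_y - f0.natal_y)))
        out[sex] = dict(
            phil=100.0 * far / moves if moves else np.nan,
            succ=float(np.mean(succ)) if succ else np.nan,
            mx=float(np.mean(maxima)) if maxima else np.nan,
            natal=natal, hr=hr)
        natal_pool += [(d, hr) for d in natal]
    out["far"] = (100.0 * np.mean([d > 2 * hr for d, hr in natal_pool])
                  if natal_pool else np.nan)
    out["near"] = (100.0 * np.mean([d <= hr for d, hr in natal_pool])
                   if natal_pool else np.nan)
    return out


def _random_records(rng, n_voles=10, n_caps=50):
    traps = build_trap_grids()
    rows = []
    day = 0
    for vid in range(n_voles):
        sex = "M" if rng.random() < 0.5 else "F"
        nx, ny = rng.uniform(-50, 250), rng.uniform(-50, 150)
        for _ in range(int(rng.integers(1, 1 + n_caps // n_voles))):
            t = traps[rng.integers(len(traps))]
            day += int(rng.integers(1, 5))
            rows.append((t[0], t[1], nx, ny, day, vid,
                         int(rng.integers(10, 200)), sex))
    return pd.DataFrame(rows, columns=["trap_x", "trap_y", "natal_x",
                                       "natal_y", "day", "vole_id",
                                       "age_days", "sex"])


class TestDispersalStats:
    def test_two_captures_simple_distances(self):
        rec = pd.DataFrame([
            (0.0, 0.0, 0.0, 0.0, 1, 1, 60, "F"),
            (7.0, 0.0, 0.0, 0.0, 2, 1, 61, "F"),
        ], columns=["trap_x", "trap_y", "natal_x", "natal_y", "day",
                    "vole_id", "age_days", "sex"])
        ds = dispersal_stats(rec)
        assert ds.mean_successive_dist["F"] == pytest.approx(7.0)
        assert ds.mean_max_dist["F"] == pytest.approx(7.0)

    def test_empty_records_explicit_empty_result(self):
        ds = dispersal_stats(pd.DataFrame(
            columns=["trap_x", "trap_y", "natal_x", "natal_y", "day",
                     "vole_id", "age_days", "sex"]))
        assert ds.n_records == 0
        assert np.isnan(ds.natal_far_pct)

    def test_single_capture_contributes_to_natal_only(self):
        rec = pd.DataFrame([
            (10.0, 10.0, 5.0, 10.0, 1, 1, 60, "F"),
        ], columns=["trap_x", "trap_y", "natal_x", "natal_y", "day",
                    "vole_id", "age_days", "sex"])
        ds = dispersal_stats(rec)
        assert np.isnan(ds.mean_successive_dist["F"])
        assert ds.natal_mean_dist["F"] == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rec = _random_records(rng)
        crit = DispersalCriteria()
        ds = dispersal_stats(rec, crit)
        bf = _brute_force_stats(rec, crit)
        for sex in ("M", "F"):
            np.testing.assert_allclose(ds.philopatry_pct[sex],
                                       bf[sex]["phil"], equal_nan=True)
            np.testing.assert_allclose(ds.mean_successive_dist[sex],
                                       bf[sex]["succ"], equal_nan=True)
            np.testing.assert_allclose(ds.mean_max_dist[sex],
                                       bf[sex]["mx"], equal_nan=True)
        np.testing.assert_allclose(ds.natal_far_pct, bf["far"], equal_nan=True)
        np.testing.assert_allclose(ds.natal_near_pct, bf["near"],
                                   equal_nan=True)

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        rec = _random_records(rng)
        moved = rec.copy()
        for col in ("trap_x", "natal_x"):
            moved[col] += 1000.0
        for col in ("trap_y", "natal_y"):
            moved[col] -= 500.0
        a = dispersal_stats(rec)
        b = dispersal_stats(moved)
        assert a.mean_successive_dist == b.mean_successive_dist
        assert a.natal_far_pct == pytest.approx(b.natal_far_pct, nan_ok=True)

    def test_larger_trap_influence_shrinks_max_distances(self):
        """With a wide area of trap influence it becomes almost impossible
        for a vole not to be caught, so sedentary animals flood the sample
        and the mean per-individual maximum movement distance falls."""
        rng = np.random.default_rng(3)
        traps = build_trap_grids()
        rows = []
        # sedentary voles sit between traps, out of reach of a 1 m radius
        for vid in range(30):
            t = traps[rng.integers(len(traps))]
            x, y = t[0] + 3.5, t[1]
            for day in range(60):
                rows.append((x + rng.normal(0, 0.2), y + rng.normal(0, 0.2),
                             vid, 0.0, 0.0, day, 100, "F"))
        # mobile voles run the trap lines and are caught at any radius,
        # so their recorded movements are already fully observed at 1 m
        for vid in range(30, 45):
            for day in range(60):
                t = traps[rng.integers(len(traps))]
                rows.append((t[0] + rng.normal(0, 0.3),
                             t[1] + rng.normal(0, 0.3),
                             vid, 0.0, 0.0, day, 100, "F"))
        pos = pd.DataFrame(rows, columns=["x", "y", "vole_id", "natal_x",
                                          "natal_y", "day", "age_days", "sex"])
        means = []
        for radius in (1.0, 4.0, 6.0):
            spec = TrapGridSpec(capture_radius=radius)
            rec = record_captures(pos, traps, spec)
            ds = dispersal_stats(rec)
            means.append(ds.mean_max_dist["F"])
        assert means[0] >= means[1] >= means[2]
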