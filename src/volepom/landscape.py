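"""Raster world: habitat classes, patches, vegetation quality, breeding window.

The world is a 1 m^2-resolution raster of integer habitat codes.  Vegetation
grows per patch when daily mean temperature reaches the growth threshold
(V14); forage quality ("digestibility") depends on the share of biomass
younger than 14 days.  The onset of grass growth, sustained for seven
consecutive days, opens the annual breeding window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import ndimage

from .params import VoleParams

__all__ = [
    "HabitatClass", "HabitatGrid", "VegetationState", "WeatherSeries",
    "BreedingWindow", "digestibility", "update_vegetation", "breeding_window",
    "generate_landscape", "patch_table", "BASE_QUALITY", "GROWTH_INCREMENT",
]


class HabitatClass(IntEnum):
    """Habitat classes; codes are the raster cell values."""

    NON_HABITAT = 0          # impassable (buildings, water)
    GRASSLAND_UNMANAGED = 1
    PASTURE_TUSSOCKY = 2
    PASTURE_LOW_YIELD = 3
    SET_ASIDE = 4
    LINEAR_FEATURE = 5
    FIELD_CROP = 6
    WOODLAND = 7
    FOREST_PLANTATION = 8
    DISPERSAL_ONLY = 9       # passable, zero forage value


#: Per-class base quality multiplied by patch digestibility to give cell
#: quality.  Ranked by the habitat preference order of the density-pattern
#: literature (unmanaged grassland best; woodland and arable worst).
BASE_QUALITY = {
    HabitatClass.NON_HABITAT: 0.00,
    HabitatClass.GRASSLAND_UNMANAGED: 0.68,
    HabitatClass.PASTURE_TUSSOCKY: 0.74,
    HabitatClass.PASTURE_LOW_YIELD: 0.60,
    HabitatClass.SET_ASIDE: 0.70,
    HabitatClass.LINEAR_FEATURE: 0.72,
    HabitatClass.FIELD_CROP: 0.30,
    HabitatClass.WOODLAND: 0.25,
    HabitatClass.FOREST_PLANTATION: 0.35,
    HabitatClass.DISPERSAL_ONLY: 0.00,
}

#: Daily biomass growth increment per class (arbitrary biomass units/day) on
#: days warm enough for grass growth.
GROWTH_INCREMENT = {c: (1.0 if BASE_QUALITY[c] > 0 else 0.0) for c in HabitatClass}

#: Daily fractional biomass loss (senescence); sets the equilibrium
#: new-green fraction during sustained growth to ~14*decay/(1-(1-decay)^inf).
BIOMASS_DECAY = 0.01

#: Within-class spatial quality heterogeneity: cell quality is multiplied by
#: a smoothed random field with this standard deviation (correlation length
#: QUALITY_NOISE_SCALE_M).  Poorer swards fall below the territory-quality
#: threshold when forage digestibility is at its winter floor, so the
#: population contracts to the better areas outside the growing season.
QUALITY_NOISE_SD = 0.12
QUALITY_NOISE_SCALE_M = 10.0


def quality_field(shape: tuple[int, int], seed: int,
                  sd: float = QUALITY_NOISE_SD,
                  scale_m: float = QUALITY_NOISE_SCALE_M) -> np.ndarray:
    """Smoothed multiplicative quality field, mean 1, clipped to [0.3, 1.7]."""
    rng = np.random.default_rng(seed)
    field = rng.normal(0.0, 1.0, size=shape)
    field = ndimage.gaussian_filter(field, sigma=scale_m, mode="reflect")
    s = field.std()
    if s > 0:
        field /= s
    return np.clip(1.0 + sd * field, 0.3, 1.7)

#: Age (days) below which biomass counts as "new green".
NEW_GREEN_AGE = 14

#: Cells are 1 m^2.
CELL_AREA_M2 = 1.0

_BARRIER = {HabitatClass.NON_HABITAT}


@dataclass
class HabitatGrid:
    """Raster of habitat codes with connected-component patch labels.

    Origin convention: 0-based, row-major (``codes[y, x]``); a cell's
    position is its center; distances are Euclidean in meters.
    """

    codes: np.ndarray                    # int8 (H, W)
    patch_ids: np.ndarray = field(default=None, repr=False)  # int32 (H, W)
    patch_class: np.ndarray = field(default=None, repr=False)  # int8 (P,)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        valid = {int(c) for c in HabitatClass}
        bad = set(np.unique(self.codes).tolist()) - valid
        if bad:
            raise ValueError(f"unknown habitat codes: {sorted(bad)}")
        if self.patch_ids is None:
            self._label_patches()

    def _label_patches(self) -> None:
        """Label connected (4-neighbour) same-class regions 0..P-1."""
        h, w = self.codes.shape
        self.patch_ids = np.zeros((h, w), dtype=np.int32)
        classes = []
        next_id = 0
        for c in np.unique(self.codes):
            mask = self.codes == c
            lab, n = ndimage.label(mask)
            self.patch_ids[mask] = lab[mask] + next_id - 1
            classes.extend([int(c)] * n)
            next_id += n
        self.patch_class = np.array(classes, dtype=np.int8)

    @property
    def height_m(self) -> int:
        return self.codes.shape[0]

    @property
    def width_m(self) -> int:
        return self.codes.shape[1]

    @property
    def n_patches(self) -> int:
        return len(self.patch_class)

    def patch_areas(self) -> np.ndarray:
        """Patch area in m^2 (= cell count; cells are 1 m^2)."""
        return np.bincount(self.patch_ids.ravel(),
                           minlength=self.n_patches).astype(np.int64)

    def base_quality_map(self) -> np.ndarray:
        lut = np.zeros(max(HabitatClass) + 1)
        for c, q in BASE_QUALITY.items():
            lut[int(c)] = q
        return lut[self.codes.astype(np.intp)]

    def barrier_mask(self) -> np.ndarray:
        mask = np.zeros_like(self.codes, dtype=bool)
        for c in _BARRIER:
            mask |= self.codes == int(c)
        return mask

    def area_ha(self, habitat_class: HabitatClass) -> float:
        return float(np.count_nonzero(self.codes == int(habitat_class))) / 1e4


def digestibility(new_green_fraction: float) -> float:
    """Forage quality from the share of biomass younger than 14 days.

    quality = min(1.0, 0.7 + sqrt(new_green_fraction)); a sward with no new
    growth scores the 0.7 floor, fully fresh growth saturates at 1.0.
    """
    f = float(new_green_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"new_green_fraction={f} outside [0, 1]")
    return min(1.0, 0.7 + math.sqrt(f))


@dataclass
class VegetationState:
    """Per-patch daily biomass cohort ledger.

    ``ring[p, k]`` holds the biomass grown k days ago (k < 14) on patch p;
    ``total[p]`` is all standing biomass including older cohorts.
    """

    ring: np.ndarray      # (P, NEW_GREEN_AGE) float64
    total: np.ndarray     # (P,) float64
    head: int = 0         # ring index of "today"

    @classmethod
    def zeros(cls, n_patches: int) -> "VegetationState":
        return cls(ring=np.zeros((n_patches, NEW_GREEN_AGE)),
                   total=np.zeros(n_patches))

    @property
    def new_green_fraction(self) -> np.ndarray:
        new = self.ring.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(self.total > 0, new / self.total, 0.0)
        return np.clip(f, 0.0, 1.0)

    @property
    def digestibility(self) -> np.ndarray:
        return np.minimum(1.0, 0.7 + np.sqrt(self.new_green_fraction))


def update_vegetation(state: VegetationState, temp: float,
                      growth: np.ndarray, params: VoleParams,
                      decay: float = BIOMASS_DECAY) -> VegetationState:
    """Advance the cohort ledger one day.

    On days with ``temp >= V14`` each patch gains its per-class growth
    increment as an age-0 cohort; all cohorts age one day, dropping out of
    the new-green pool at 14 days; standing biomass senesces at ``decay``
    per day.  Mutates and returns ``state``.
    """
    state.head = (state.head - 1) % NEW_GREEN_AGE
    grown = growth if temp >= params.grass_growth_temp else 0.0
    state.total *= (1.0 - decay)
    state.ring *= (1.0 - decay)
    inc = np.broadcast_to(np.asarray(grown, dtype=float), state.total.shape)
    state.ring[:, state.head] = inc
    state.total += inc
    return state


@dataclass
class WeatherSeries:
    """Daily weather, day-of-year indexed from 1."""

    temp_c: np.ndarray
    precip_mm: np.ndarray

    def __post_init__(self):
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        self.precip_mm = np.asarray(self.precip_mm, dtype=float)
        if self.temp_c.shape != self.precip_mm.shape:
            raise ValueError("temperature/precipitation length mismatch")
        if not 365 <= len(self.temp_c) <= 366:
            raise ValueError("weather series must cover one year")

    def __len__(self) -> int:
        return len(self.temp_c)


@dataclass
class BreedingWindow:
    """Annual conception window [start_day, end_day), day-of-year."""

    start_day: int | None
    end_day: int
    trigger_day: int | None = None  # 7th consecutive growth day, pre-V15 floor

    def is_open(self, day_of_year: int) -> bool:
        return (self.start_day is not None
                and self.start_day <= day_of_year < self.end_day)


def breeding_window(weather: WeatherSeries, params: VoleParams) -> BreedingWindow:
    """Derive the annual breeding window from daily temperature.

    Breeding can start on the first day D such that days D-6..D all reach the
    grass-growth temperature V14, floored at the earliest calendar date V15;
    conception stops at V11.  Returns an empty window when no 7-day warm run
    exists.
    """
    warm = weather.temp_c >= params.grass_growth_temp
    trigger = None
    run = 0
    for i, w in enumerate(warm):
        run = run + 1 if w else 0
        if run >= 7:
            trigger = i + 1  # day-of-year
            break
    if trigger is None:
        return BreedingWindow(None, params.repro_stop_day, None)
    start = max(params.earliest_breed_day, trigger)
    if start >= params.repro_stop_day:
        return BreedingWindow(None, params.repro_stop_day, trigger)
    return BreedingWindow(start, params.repro_stop_day, trigger)


# ---------------------------------------------------------------------------
# scenario landscape generators
# ---------------------------------------------------------------------------

def generate_landscape(kind: str, dims: tuple[int, int] | int = None,
                       n_patches: int = 1, seed: int = 0,
                       patch_frac: float = 0.25,
                       class_shares: dict | None = None) -> HabitatGrid:
    """Deterministic scenario landscapes.

    Kinds
    -----
    ``homogeneous_block``
        Square block of unmanaged grassland surrounded by an equally large
        area of dispersal-only habitat.  ``dims`` is the block side (m).
    ``trap_meadow``
        Exactly 500 x 400 m of grassland bounded by forest plantation
        (the live-trapping scenario).  ``dims`` optionally overrides the
        meadow (w, h).
    ``patches``
        ``n_patches`` in {1, 3, 16} disjoint equal-area grassland squares in
        a dispersal-only matrix covering ``patch_frac`` of the landscape.
    ``mosaic``
        Seeded random rectangles of mixed classes with Dirichlet-distributed
        shares over a low-quality arable matrix.
    """
    rng = np.random.default_rng(seed)
    G, D = int(HabitatClass.GRASSLAND_UNMANAGED), int(HabitatClass.DISPERSAL_ONLY)

    if kind == "homogeneous_block":
        side = int(dims if dims is not None else 200)
        # surround area equals block area: total side = side * sqrt(2)
        total = int(math.ceil(side * math.sqrt(2.0)))
        codes = np.full((total, total), D, dtype=np.int8)
        off = (total - side) // 2
        codes[off:off + side, off:off + side] = G
        return HabitatGrid(codes)

    if kind == "trap_meadow":
        w, h = (500, 400) if dims is None else dims
        border = 50
        codes = np.full((h + 2 * border, w + 2 * border),
                        int(HabitatClass.FOREST_PLANTATION), dtype=np.int8)
        codes[border:border + h, border:border + w] = G
        return HabitatGrid(codes)

    if kind == "patches":
        if dims is None:
            dims = (1000, 1000)
        w, h = (dims, dims) if isinstance(dims, int) else dims
        if n_patches not in (1, 3, 16):
            raise ValueError("n_patches must be 1, 3 or 16")
        codes = np.full((h, w), D, dtype=np.int8)
        total_area = patch_frac * w * h
        side = int(math.sqrt(total_area / n_patches))
        ncol = int(math.ceil(math.sqrt(n_patches)))
        nrow = int(math.ceil(n_patches / ncol))
        placed = 0
        for r in range(nrow):
            for c in range(ncol):
                if placed >= n_patches:
                    break
                cy = int((r + 0.5) * h / nrow)
                cx = int((c + 0.5) * w / ncol)
                y0, x0 = max(0, cy - side // 2), max(0, cx - side // 2)
                codes[y0:y0 + side, x0:x0 + side] = G
                placed += 1
        return HabitatGrid(codes)

    if kind == "mosaic":
        if dims is None:
            dims = (1000, 1000)
        w, h = (dims, dims) if isinstance(dims, int) else dims
        pool = [HabitatClass.GRASSLAND_UNMANAGED, HabitatClass.PASTURE_TUSSOCKY,
                HabitatClass.PASTURE_LOW_YIELD, HabitatClass.SET_ASIDE,
                HabitatClass.LINEAR_FEATURE, HabitatClass.WOODLAND,
                HabitatClass.FOREST_PLANTATION]
        if class_shares is None:
            shares = rng.dirichlet(np.full(len(pool), 2.0)) * 0.5
            class_shares = dict(zip(pool, shares))
        codes = np.full((h, w), int(HabitatClass.FIELD_CROP), dtype=np.int8)
        for cls, share in class_shares.items():
            target = share * w * h
            area = 0.0
            while area < target:
                if cls == HabitatClass.LINEAR_FEATURE:
                    pw, ph = int(rng.integers(40, 200)), int(rng.integers(3, 8))
                    if rng.random() < 0.5:
                        pw, ph = ph, pw
                else:
                    pw = int(rng.integers(30, max(31, w // 5)))
                    ph = int(rng.integers(30, max(31, h // 5)))
                x0 = int(rng.integers(0, max(1, w - pw)))
                y0 = int(rng.integers(0, max(1, h - ph)))
                codes[y0:y0 + ph, x0:x0 + pw] = int(cls)
                area += pw * ph
        return HabitatGrid(codes)

    raise ValueError(f"unsupported landscape kind: {kind!r}")


#: Patch-table inclusion rules: minimum patch area (m^2) by class; classes
#: rarely exceeding 1 ha (unmanaged grassland, linear features) use 1000 m^2.
_MIN_AREA_DEFAULT = 10_000.0
_MIN_AREA_SMALL = 1_000.0
_SMALL_RULE_CLASSES = {HabitatClass.GRASSLAND_UNMANAGED, HabitatClass.LINEAR_FEATURE}


def patch_table(grid: HabitatGrid, min_area_rules: dict | None = None):
    """Patches qualifying for density evaluation: (patch id, class, area m^2).

    Only patches > 1 ha are considered, except unmanaged grassland and linear
    features where the lower limit is 1000 m^2 (these are rarely > 1 ha);
    this keeps single-vole occupancy of tiny patches from biasing densities.
    Matrix classes (dispersal-only, non-habitat) are never included.
    """
    import pandas as pd

    areas = grid.patch_areas()
    rows = []
    for pid in range(grid.n_patches):
        cls = HabitatClass(int(grid.patch_class[pid]))
        if BASE_QUALITY[cls] <= 0:
            continue
        small = cls in _SMALL_RULE_CLASSES
        if min_area_rules is not None:
            min_area = min_area_rules.get(cls, _MIN_AREA_DEFAULT)
        else:
            min_area = _MIN_AREA_SMALL if small else _MIN_AREA_DEFAULT
        # ">1 ha" is strict; the 1000 m^2 small-feature limit is inclusive
        if (areas[pid] >= min_area) if small else (areas[pid] > min_area):
            rows.append((pid, cls.name.lower(), int(areas[pid])))
    return pd.DataFrame(rows, columns=["patch_id", "habitat", "area_m2"])
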