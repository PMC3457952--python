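"""Vole life-history parameter registry.

The seventeen calibration parameters V1--V17 form the calibration surface of
the model; their defaults are the post-calibration configuration.  Auxiliary
life-history constants (gestation, litter size, weaning age, lifespan) are
not part of that surface but are needed to close the life cycle; their
defaults are documented in ``docs/methods.md``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

__all__ = ["VoleParams", "MONTH_DAYS"]

#: Days per month used to convert the 15 +/- 3 month physiological lifespan.
MONTH_DAYS = 30.44


@dataclass
class VoleParams:
    """Registry of the V1--V17 parameters plus auxiliary constants.

    All probabilities are daily unless stated otherwise; days are day-of-year
    for the calendar parameters (V11, V15) and ages in days elsewhere.
    """

    # --- calibration surface -------------------------------------------------
    male_min_repro_age: int = 30          #: V1, days
    female_min_repro_age: int = 23        #: V2, days
    quality_multiplier: float = 2.1       #: V3, area -> quality score scaling
    female_min_radius: int = 8            #: V4, m
    female_max_radius: int = 8            #: V5, m
    male_min_radius: int = 9              #: V6, m
    male_max_radius: int = 23             #: V7, m
    eviction_age_gap: int = 30            #: V8, days
    dispersal_mortality: float = 0.055    #: V9, per dispersal-day probability
    daily_mortality: float = 0.0025       #: V10, daily probability
    repro_stop_day: int = 230             #: V11, day-of-year
    male_move_prob_no_females: float = 0.0505  #: V12, daily probability
    density_threshold: float = 4.0        #: V13, voles within a minimum territory
    grass_growth_temp: float = 3.552      #: V14, deg C
    earliest_breed_day: int = 80          #: V15, day-of-year
    starvation_days: float = math.inf     #: V16, disabled (infinite)
    infanticide_prob: float = 1.0         #: V17, per-encounter probability

    # --- auxiliary life-history constants ------------------------------------
    weaning_age: int = 14                 #: days; age at independence
    lifespan_mean_months: float = 15.0
    lifespan_sd_months: float = 3.0
    gestation_days: int = 21
    litter_size_mean: float = 5.4         #: truncated-Poisson mean, min 1

    # --- movement / behaviour constants (not in the calibration table) -------
    dispersal_step: float = 14.0          #: m, daily step budget while dispersing
    infanticide_radius: float = 2.0       #: m, nest-encounter radius for roaming males
    male_needs_female_to_settle: bool = True  #: breeding-season settlement rule
    male_excursion_prob: float = 0.63     #: daily prob of a breeding-season excursion
    male_excursion_radius: float = 30.0   #: m, excursion reach beyond the territory
    disperser_fraction: float = 0.7       #: share of weanlings with an obligate
                                          #: long-dispersal phase before settling
    disperser_min_days: int = 5           #: obligate dispersal duration bounds
    disperser_max_days: int = 10
    male_range_radius: float = 18.0       #: m, daily ranging radius of males
    disperser_male_factor: float = 1.0    #: male obligate-dispersal duration scale
    obligate_step: float = 30.0           #: m/day travel during the obligate phase
    density_boundary_mode: int = 2        #: male scaled-V13 rounding: 0 settle-floor,
                                          #: 1 none, 2 both-floor, 3 owner-floor
    offseason_excursion_scale: float = 0.135  #: male excursion rate multiplier
                                             #: outside the breeding window
    disperser_gate_frac: float = 0.35      #: natal crowding (fraction of V13)
                                          #: required to express dispersal

    _V_NAMES = {
        "V1": "male_min_repro_age", "V2": "female_min_repro_age",
        "V3": "quality_multiplier", "V4": "female_min_radius",
        "V5": "female_max_radius", "V6": "male_min_radius",
        "V7": "male_max_radius", "V8": "eviction_age_gap",
        "V9": "dispersal_mortality", "V10": "daily_mortality",
        "V11": "repro_stop_day", "V12": "male_move_prob_no_females",
        "V13": "density_threshold", "V14": "grass_growth_temp",
        "V15": "earliest_breed_day", "V16": "starvation_days",
        "V17": "infanticide_prob",
    }

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("dispersal_mortality", "daily_mortality",
                     "male_move_prob_no_females", "infanticide_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} is not a probability")
        if self.female_min_radius > self.female_max_radius:
            raise ValueError("female radius bounds inverted")
        if self.male_min_radius > self.male_max_radius:
            raise ValueError("male radius bounds inverted")
        if not self.earliest_breed_day < self.repro_stop_day:
            raise ValueError("V15 must precede V11")

    # -- V-name access ---------------------------------------------------------

    def get_v(self, vname: str) -> float:
        return getattr(self, self._V_NAMES[vname])

    def with_v(self, vname: str, value: float) -> "VoleParams":
        """Return a copy with one V-parameter replaced (integers re-rounded)."""
        attr = self._V_NAMES[vname]
        cur = getattr(self, attr)
        if isinstance(cur, int):
            value = int(round(value))
        return replace(self, **{attr: value})

    def min_radius(self, sex: str) -> int:
        return self.female_min_radius if sex == "F" else self.male_min_radius

    def max_radius(self, sex: str) -> int:
        return self.female_max_radius if sex == "F" else self.male_max_radius

    def scaled_density_threshold(self, sex: str) -> float:
        """V13 scaled by sex-specific minimum territory area (area ratio).

        The scaled value is floored: a threshold *number of voles* is an
        integer count, and flooring keeps the per-area binding density
        nearly sex-neutral.
        """
        r = self.min_radius(sex)
        return float(math.floor(
            self.density_threshold * (r / self.female_min_radius) ** 2))

    # -- flat key=value config file -------------------------------------------

    def save(self, path: str | Path) -> None:
        lines = []
        for vname, attr in self._V_NAMES.items():
            lines.append(f"{vname} = {getattr(self, attr)}")
        for f in fields(self):
            if f.name in self._V_NAMES.values():
                continue
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "VoleParams":
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            attr = cls._V_NAMES.get(key, key)
            if attr not in known:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            f = known[attr]
            if f.type in ("int", int):
                kwargs[attr] = int(round(float(val)))
            elif f.type in ("bool", bool):
                kwargs[attr] = val.lower() in ("1", "true", "yes")
            else:
                kwargs[attr] = float(val)
        return cls(**kwargs)
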