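"""Readers and writers: ESRI ASCII habitat rasters, weather CSV, run manifests."""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .landscape import HabitatClass, HabitatGrid, WeatherSeries

__all__ = [
    "read_habitat_raster", "write_habitat_raster",
    "read_weather_csv", "write_weather_csv", "synthetic_weather",
    "RunConfig", "write_manifest",
]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_habitat_raster(path: str | Path) -> HabitatGrid:
    """Read an ESRI ASCII grid of integer habitat codes (cellsize 1 m)."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ValueError(f"malformed ESRI ASCII header, missing {missing}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if header["cellsize"] != 1:
        raise ValueError("cellsize must be 1 (cells are 1 m^2)")
    rows = []
    for lineno, line in enumerate(lines[i:], i + 1):
        if not line.strip():
            continue
        vals = line.split()
        if len(vals) != ncols:
            raise ValueError(f"line {lineno}: expected {ncols} values, got {len(vals)}")
        rows.append([int(v) for v in vals])
    if len(rows) != nrows:
        raise ValueError(f"expected {nrows} rows, got {len(rows)}")
    # ESRI rows run north->south; internal convention is row 0 = y 0 (south)
    codes = np.array(rows, dtype=np.int8)[::-1]
    nodata = int(header.get("nodata_value", -9999))
    codes[codes == nodata] = int(HabitatClass.NON_HABITAT)
    valid = {int(c) for c in HabitatClass}
    bad = sorted(set(np.unique(codes).tolist()) - valid)
    if bad:
        ys, xs = np.where(np.isin(codes, bad))
        raise ValueError(
            f"unknown habitat codes {bad} (first at cell x={xs[0]}, y={ys[0]})")
    return HabitatGrid(codes)


def write_habitat_raster(grid: HabitatGrid, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.width_m}\n")
        fh.write(f"nrows {grid.height_m}\n")
        fh.write("xllcorner 0\nyllcorner 0\ncellsize 1\nNODATA_value -9999\n")
        for row in grid.codes[::-1]:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_weather_csv(path: str | Path) -> WeatherSeries:
    """Read daily weather with header ``date,temp_c,precip_mm`` (ISO dates)."""
    df = pd.read_csv(path)
    expected = ["date", "temp_c", "precip_mm"]
    if list(df.columns) != expected:
        raise ValueError(f"weather header must be {expected}, got {list(df.columns)}")
    dates = pd.to_datetime(df["date"], format="%Y-%m-%d")
    deltas = dates.diff().dropna().dt.days
    if (deltas != 1).any():
        gap = dates[deltas[deltas != 1].index[0]]
        raise ValueError(f"weather series has a gap around {gap.date()}")
    return WeatherSeries(df["temp_c"].to_numpy(), df["precip_mm"].to_numpy())


def write_weather_csv(weather: WeatherSeries, path: str | Path,
                      year: int = 2001) -> None:
    start = _dt.date(year, 1, 1)
    dates = [start + _dt.timedelta(days=i) for i in range(len(weather))]
    pd.DataFrame({
        "date": [d.isoformat() for d in dates],
        "temp_c": weather.temp_c,
        "precip_mm": weather.precip_mm,
    }).to_csv(path, index=False)


#: Annual temperature profiles: (mean deg C, seasonal amplitude, noise sd).
#: ``finland_like`` crosses the grass-growth threshold later in spring than
#: ``denmark_like``.
_PROFILES = {
    "finland_like": (6.0, 11.5, 1.5),
    "denmark_like": (8.5, 8.5, 1.5),
    "constant": (10.0, 0.0, 0.0),
}


def synthetic_weather(profile: str = "finland_like", seed: int = 0,
                      days: int = 365) -> WeatherSeries:
    """Sinusoidal annual temperature with seeded day-to-day noise."""
    if profile not in _PROFILES:
        raise ValueError(f"unknown weather profile {profile!r}")
    mean, amp, sd = _PROFILES[profile]
    rng = np.random.default_rng(seed)
    doy = np.arange(1, days + 1)
    # coldest around late January (day 25), warmest late July
    temp = mean - amp * np.cos(2 * np.pi * (doy - 25) / 365.0)
    temp = temp + rng.normal(0.0, sd, size=days)
    precip = np.maximum(0.0, rng.normal(1.8, 2.5, size=days))
    return WeatherSeries(temp, precip)


@dataclasses.dataclass
class RunConfig:
    """Reproducibility envelope for a run; serialized into the manifest."""

    scenario: str
    seed: int
    n_replicates: int = 10
    years: int = 10
    burn_in: int = 5
    scale_factor: float = 1.0
    weather_profile: str = "finland_like"
    param_file: str | None = None
    out_dir: str = "runs"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(config: RunConfig, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = dict(config.to_dict(), config_hash=config.hash())
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
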