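"""Plain-text (CSV/JSON) read/write contracts for every pipeline stage.

The synthetic writers double as the read contracts for real data: any
provider that produces these schemas can be run through the same pipeline.
Daily weather uses (year, doy) indexing on a fixed 365-day calendar, so
real-data exporters must drop Feb 29.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calendar import DAYS_PER_YEAR
from .synthetic import SyntheticDataset, WeatherCube

HIST_LABEL = "historical"


# ---------------------------------------------------------------------------
# daily weather


def weather_frame(cube: WeatherCube, scenario: str = HIST_LABEL, gcm: int = -1) -> pd.DataFrame:
    n_cells, n_years = cube.n_cells, cube.n_years
    cell = np.repeat(np.arange(n_cells), n_years * DAYS_PER_YEAR)
    year = np.tile(np.repeat(np.arange(n_years), DAYS_PER_YEAR), n_cells)
    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), n_cells * n_years)
    return pd.DataFrame(
        {
            "cell_id": cell,
            "scenario": scenario,
            "gcm": gcm,
            "year": year,
            "doy": doy,
            "tmax_c": cube.tmax.ravel(),
            "tmin_c": cube.tmin.ravel(),
            "prcp_mm": cube.prcp.ravel(),
        }
    )


def frame_to_cube(df: pd.DataFrame) -> WeatherCube:
    df = df.sort_values(["cell_id", "year", "doy"], kind="stable")
    n_cells = df["cell_id"].nunique()
    n_years = df["year"].nunique()
    shape = (n_cells, n_years, DAYS_PER_YEAR)
    if len(df) != np.prod(shape):
        raise ValueError("incomplete daily weather table")
    return WeatherCube(
        df["tmax_c"].to_numpy().reshape(shape),
        df["tmin_c"].to_numpy().reshape(shape),
        df["prcp_mm"].to_numpy().reshape(shape),
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write a synthetic dataset as the pipeline's canonical CSV inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    weather_frame(dataset.historical).to_csv(out / "weather_historical.csv", index=False)
    parts = [
        weather_frame(cube, scenario=s, gcm=g)
        for (s, g), cube in sorted(dataset.future.items())
    ]
    pd.concat(parts, ignore_index=True).to_csv(out / "weather_future.csv", index=False)
    dataset.county_map.to_csv(out / "county_map.csv", index=False)
    pd.DataFrame(
        {"cell_id": np.arange(len(dataset.landuse)), "ag_fraction": dataset.landuse}
    ).to_csv(out / "landuse.csv", index=False)
    dataset.crop_census.to_csv(out / "census.csv", index=False)
    meta = {
        "scenarios": list(dataset.config.scenarios),
        "n_gcms": dataset.config.n_gcms,
        "planted_pairs": [list(p) for p in dataset.planted_pairs],
    }
    (out / "dataset_meta.json").write_text(json.dumps(meta, indent=2))


def read_weather(path: str | Path) -> dict[tuple[str, int], WeatherCube]:
    """Read a weather CSV into cubes keyed by (scenario, gcm)."""
    df = pd.read_csv(path)
    out = {}
    for (s, g), grp in df.groupby(["scenario", "gcm"]):
        out[(str(s), int(g))] = frame_to_cube(grp)
    return out


def read_county_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_landuse(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path).sort_values("cell_id")
    return df["ag_fraction"].to_numpy()


def read_census(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# county-year variable table (long form)


def county_year_frame(
    county_years: dict[int, np.ndarray],
    variable_names: tuple[str, ...],
    scenario: str = HIST_LABEL,
    gcm: int = -1,
    first_year: int = 0,
) -> pd.DataFrame:
    rows = []
    for cid in sorted(county_years):
        arr = county_years[cid]
        for yi in range(arr.shape[0]):
            for vi, name in enumerate(variable_names):
                rows.append((cid, scenario, gcm, first_year + yi, name, arr[yi, vi]))
    return pd.DataFrame(
        rows, columns=["county_id", "scenario", "gcm", "year", "variable", "value"]
    )


def frame_to_county_years(
    df: pd.DataFrame, variable_names: tuple[str, ...]
) -> dict[int, np.ndarray]:
    out = {}
    for cid, grp in df.groupby("county_id"):
        piv = grp.pivot_table(index="year", columns="variable", values="value")
        out[int(cid)] = piv[list(variable_names)].to_numpy()
    return out


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
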