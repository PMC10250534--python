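"""Seeded synthetic inputs for offline testing of the analog pipeline.

Generates gridded daily weather with a sinusoidal annual cycle and a
north-south (row-index) gradient, a future pseudo-GCM ensemble obtained by
shifting the historical climatology by per-model warming offsets, a land-use
(agricultural fraction) layer, a cell->county partition with coarse regions,
and a county crop census with heavy-tailed acreage. Known target->analog
ground truths can be planted so recovery by the full pipeline is testable.

Everything is a pure function of the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calendar import DAYS_PER_YEAR, MONTH_LENGTHS, MONTH_STARTS

SPECIALTY_GROUPS = ("vegetable", "fruit", "tree nut", "berry")

CROP_CATALOG: dict[str, tuple[str, ...]] = {
    "vegetable": (
        "tomatoes", "sweet corn", "onions", "peppers",
        "carrots", "squash", "leafy greens",
    ),
    "fruit": ("apples", "peaches", "cherries", "grapes", "pears"),
    "tree nut": ("almonds", "walnuts", "pecans", "hazelnuts"),
    "berry": ("blueberries", "strawberries", "raspberries", "cranberries"),
    "non-specialty": ("wheat", "field corn", "soybeans", "alfalfa", "barley", "oats"),
}

# Monthly precipitation climatology (mm/year split across months).
ANNUAL_PRECIP_MM = 600.0
WINTER_WET_SHARE = 0.75  # Oct-Mar share of the annual total
WINTER_MONTHS = (9, 10, 11, 0, 1, 2)  # Oct..Dec, Jan..Mar (0-based)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the synthetic dataset; the seed determines everything."""

    seed: int
    grid_shape: tuple[int, int] = (8, 8)
    n_counties: int = 8
    n_years_hist: int = 30
    n_gcms: int = 6
    scenarios: tuple[str, ...] = ("rcp45-like", "rcp85-like")
    scenario_warming: Mapping[str, float] | None = None
    warming_offsets: Mapping[tuple[str, int], float] | None = None
    gcm_spread: float = 0.5
    temp_base: float = 16.0
    temp_amplitude: float = 11.0
    temp_row_gradient: float = 0.3
    diurnal_range: float = 10.0
    temp_day_sd: float = 1.2
    temp_year_sd: float = 0.5
    precip_day_sd: float = 0.8
    precip_year_sd: float = 0.2
    precip_regime_split: float = 0.5
    ag_fraction_range: tuple[float, float] = (0.05, 0.95)
    specialty_fraction: float = 0.85
    suppressed_fraction: float = 0.1
    n_regions: int = 4
    planted_pairs: tuple[tuple[int, int], ...] = ()
    plant_identical_crops: bool = True

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.n_counties > rows * cols:
            raise ValueError("more counties than grid cells")
        if self.n_counties < 1:
            raise ValueError("need at least one county")
        if self.n_years_hist < 3:
            raise ValueError("n_years_hist must be >= 3")
        if self.n_gcms < 1:
            raise ValueError("need at least one pseudo-GCM")
        for t, a in self.planted_pairs:
            if t == a:
                raise ValueError(f"planted pair maps county {t} to itself")
        offs = self.resolved_warming_offsets()
        if not all(np.isfinite(v) for v in offs.values()):
            raise ValueError("warming offsets must be finite")

    @property
    def n_cells(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def resolved_warming_offsets(self) -> dict[tuple[str, int], float]:
        """Per-(scenario, gcm) mean warming (°C), defaulting to a spread
        around scenario-level central values."""
        if self.warming_offsets is not None:
            return {
                (s, g): float(self.warming_offsets[(s, g)])
                for s in self.scenarios
                for g in range(self.n_gcms)
            }
        base = self.scenario_warming
        if base is None:
            defaults = {"rcp45-like": 2.0, "rcp85-like": 3.5}
            base = {s: defaults.get(s, 2.5) for s in self.scenarios}
        half = (self.n_gcms - 1) / 2.0
        out = {}
        for s in self.scenarios:
            for g in range(self.n_gcms):
                rel = 0.0 if half == 0 else (g - half) / half
                out[(s, g)] = float(base[s] + self.gcm_spread * rel)
        return out


@dataclass
class WeatherCube:
    """Daily weather for every cell and year: arrays (n_cells, n_years, 365)."""

    tmax: np.ndarray
    tmin: np.ndarray
    prcp: np.ndarray

    def __post_init__(self) -> None:
        if not (self.tmax.shape == self.tmin.shape == self.prcp.shape):
            raise ValueError("tmax/tmin/prcp shapes differ")
        if self.tmax.shape[-1] != DAYS_PER_YEAR:
            raise ValueError("trailing axis must hold 365 days")

    @property
    def n_cells(self) -> int:
        return self.tmax.shape[0]

    @property
    def n_years(self) -> int:
        return self.tmax.shape[1]

    def copy(self) -> "WeatherCube":
        return WeatherCube(self.tmax.copy(), self.tmin.copy(), self.prcp.copy())


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    historical: WeatherCube
    future: dict[tuple[str, int], WeatherCube]
    landuse: np.ndarray  # (n_cells,) agricultural fraction in [0, 1]
    county_map: pd.DataFrame  # cell_id, county_id, region
    crop_census: pd.DataFrame  # county_id, crop, group, acres, complete
    planted_pairs: tuple[tuple[int, int], ...] = ()

    @property
    def county_ids(self) -> np.ndarray:
        return np.unique(self.county_map["county_id"].to_numpy())


# ---------------------------------------------------------------------------
# climatology


def _cell_rows(config: SyntheticConfig) -> np.ndarray:
    return np.arange(config.n_cells) // config.grid_shape[1]


def _cell_cols(config: SyntheticConfig) -> np.ndarray:
    return np.arange(config.n_cells) % config.grid_shape[1]


def temperature_climatology(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic daily (tmax, tmin) climatology, shape (n_cells, 365).

    Midpoint temperature follows a cosine annual cycle (coldest mid-January,
    warmest mid-July) with a linear decrease along the row index.
    """
    doy = np.arange(DAYS_PER_YEAR)
    cycle = -config.temp_amplitude * np.cos(2.0 * np.pi * (doy - 15) / DAYS_PER_YEAR)
    rows = _cell_rows(config)
    tmid = (config.temp_base - config.temp_row_gradient * rows)[:, None] + cycle[None, :]
    half = config.diurnal_range / 2.0
    return tmid + half, tmid - half


def monthly_precip_climatology(config: SyntheticConfig) -> np.ndarray:
    """Per-cell monthly precipitation totals (n_cells, 12).

    Columns below ``precip_regime_split`` of the grid width get a winter-wet
    regime (>= WINTER_WET_SHARE of the annual total in Oct-Mar); the rest get
    a uniform regime (every month equal to the annual mean).
    """
    cols = _cell_cols(config)
    n_wet_cols = int(round(config.precip_regime_split * config.grid_shape[1]))
    winter_wet = cols < n_wet_cols

    uniform = np.full(12, ANNUAL_PRECIP_MM / 12.0)
    wet = np.full(12, ANNUAL_PRECIP_MM * (1.0 - WINTER_WET_SHARE) / 6.0)
    wet[list(WINTER_MONTHS)] = ANNUAL_PRECIP_MM * WINTER_WET_SHARE / 6.0

    out = np.where(winter_wet[:, None], wet[None, :], uniform[None, :])
    return out


def daily_precip_climatology(config: SyntheticConfig) -> np.ndarray:
    """Deterministic per-cell daily precipitation (n_cells, 365)."""
    monthly = monthly_precip_climatology(config)
    daily = np.empty((config.n_cells, DAYS_PER_YEAR))
    for m in range(12):
        start = MONTH_STARTS[m]
        daily[:, start:start + MONTH_LENGTHS[m]] = (
            monthly[:, m][:, None] / MONTH_LENGTHS[m]
        )
    return daily


def _simulate_cube(
    config: SyntheticConfig,
    rng: np.random.Generator,
    warming: float = 0.0,
) -> WeatherCube:
    """One realization of the weather process around the shared climatology."""
    n_cells, n_years = config.n_cells, config.n_years_hist
    tmax_c, tmin_c = temperature_climatology(config)
    prcp_c = daily_precip_climatology(config)

    shape_year = (n_cells, n_years, 1)
    shape_day = (n_cells, n_years, DAYS_PER_YEAR)

    year_tmax = rng.normal(0.0, config.temp_year_sd, shape_year)
    year_tmin = rng.normal(0.0, config.temp_year_sd, shape_year)
    year_prcp = rng.normal(0.0, config.precip_year_sd, shape_year)
    day_tmax = rng.normal(0.0, config.temp_day_sd, shape_day)
    day_tmin = rng.normal(0.0, config.temp_day_sd, shape_day)
    day_prcp = rng.normal(0.0, config.precip_day_sd, shape_day)

    tmax = tmax_c[:, None, :] + warming + year_tmax + day_tmax
    tmin = tmin_c[:, None, :] + warming + year_tmin + day_tmin
    # physical-order guard; inactive in the zero-noise limit
    tmin = np.minimum(tmin, tmax - 0.1)
    prcp = np.maximum(0.0, prcp_c[:, None, :] + year_prcp + day_prcp)
    return WeatherCube(tmax, tmin, prcp)


# ---------------------------------------------------------------------------
# partition, land use, census


def build_county_map(config: SyntheticConfig) -> pd.DataFrame:
    """Partition cells into contiguous (row-major) counties and band the
    counties into regions by mean row index."""
    chunks = np.array_split(np.arange(config.n_cells), config.n_counties)
    county_of_cell = np.empty(config.n_cells, dtype=np.int64)
    for cid, cells in enumerate(chunks):
        if len(cells) == 0:
            raise ValueError("county with zero cells; reduce n_counties")
        county_of_cell[cells] = cid

    rows = _cell_rows(config)
    mean_row = np.array([rows[county_of_cell == c].mean() for c in range(config.n_counties)])
    n_regions = min(config.n_regions, config.n_counties)
    # quantile banding keeps regions near-equal in county count
    edges = np.quantile(mean_row, np.linspace(0, 1, n_regions + 1)[1:-1]) if n_regions > 1 else []
    region_of_county = np.searchsorted(edges, mean_row, side="right")
    region_labels = np.array([f"region-{r + 1}" for r in region_of_county])

    return pd.DataFrame(
        {
            "cell_id": np.arange(config.n_cells),
            "county_id": county_of_cell,
            "region": region_labels[county_of_cell],
        }
    )


def generate_landuse(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.ag_fraction_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("ag_fraction_range must be within [0, 1]")
    return rng.uniform(lo, hi, config.n_cells)


def generate_crop_census(
    config: SyntheticConfig,
    county_map: pd.DataFrame,
    rng: np.random.Generator,
    catalog: Mapping[str, Sequence[str]] = CROP_CATALOG,
    forced_specialty: frozenset[int] = frozenset(),
) -> pd.DataFrame:
    """Heavy-tailed county crop census.

    Specialty acreage per county is lognormal with a large sigma so a small
    subset of counties dominates the national total; a configurable fraction
    of counties are non-specialty, and another fraction have their crop list
    flagged incomplete to emulate disclosure suppression. Counties listed in
    ``forced_specialty`` (planted targets) are always specialty and complete.
    """
    if not catalog or not any(len(v) for v in catalog.values()):
        raise ValueError("empty crop catalog")
    county_ids = np.unique(county_map["county_id"].to_numpy())
    records: list[dict] = []
    for cid in county_ids:
        is_specialty = rng.random() < config.specialty_fraction
        complete = rng.random() >= config.suppressed_fraction
        if cid in forced_specialty:
            is_specialty, complete = True, True

        n_nonspec = rng.integers(2, 5)
        nonspec = rng.choice(catalog["non-specialty"], size=min(n_nonspec, len(catalog["non-specialty"])), replace=False)
        for crop in nonspec:
            records.append(
                dict(county_id=int(cid), crop=str(crop), group="non-specialty",
                     acres=float(rng.lognormal(6.0, 1.0)), complete=bool(complete))
            )
        if is_specialty:
            scale = rng.lognormal(4.0, 2.0)  # heavy tail across counties
            spec_pool = [(g, c) for g in SPECIALTY_GROUPS for c in catalog.get(g, ())]
            k = int(rng.integers(2, min(7, len(spec_pool) + 1)))
            idx = rng.choice(len(spec_pool), size=k, replace=False)
            for i in idx:
                g, crop = spec_pool[i]
                records.append(
                    dict(county_id=int(cid), crop=str(crop), group=g,
                         acres=float(scale * rng.lognormal(0.0, 1.0)), complete=bool(complete))
                )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# planting ground truths


def plant_known_analog(
    dataset: SyntheticDataset,
    target: int,
    analog: int,
    rng: np.random.Generator | None = None,
) -> SyntheticDataset:
    """Overwrite the target county's future weather with the analog county's
    historical weather, in every scenario/GCM member.

    Each member receives an independent random cyclic shift of the analog's
    historical years, so members differ from one another while every
    member's future normals match the analog's historical normals (a year
    rotation leaves the multi-year mean unchanged). Additive daily-space
    noise is deliberately avoided: threshold-type indices (heat degree
    hours, chill) respond asymmetrically to it wherever the analog's own
    interannual variability is near zero, which would break the planted
    guarantee. Mutates and returns ``dataset``.
    """
    if target == analog:
        raise ValueError("target and analog must differ")
    cmap = dataset.county_map
    cells_by_county = cmap.groupby("county_id")["cell_id"].apply(list).to_dict()
    if target not in cells_by_county:
        raise KeyError(f"unknown county id {target}")
    if analog not in cells_by_county:
        raise KeyError(f"unknown county id {analog}")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([dataset.config.seed, 0x9A17, target, analog]))

    t_cells = np.asarray(cells_by_county[target])
    a_cells = np.asarray(cells_by_county[analog])
    # cycle analog cells over the target's cells; exact when counts divide
    src = a_cells[np.arange(len(t_cells)) % len(a_cells)]

    cfg = dataset.config
    hist = dataset.historical
    for cube in dataset.future.values():
        shift = int(rng.integers(cfg.n_years_hist))
        years = (np.arange(cfg.n_years_hist) + shift) % cfg.n_years_hist
        cube.tmax[t_cells] = hist.tmax[src][:, years, :]
        cube.tmin[t_cells] = hist.tmin[src][:, years, :]
        cube.prcp[t_cells] = hist.prcp[src][:, years, :]
    return dataset


def boost_specialty_acreage(census: pd.DataFrame, county_id: int) -> pd.DataFrame:
    """Scale a county's specialty acreage so it tops the national ranking.

    Planted targets must survive the 99%-coverage target selection; making
    them the largest producers guarantees that without touching crop sets.
    """
    spec = census["group"].isin(SPECIALTY_GROUPS)
    totals = census[spec].groupby("county_id")["acres"].sum()
    own = float(totals.get(county_id, 0.0))
    if own <= 0:
        raise ValueError(f"county {county_id} has no specialty acreage to boost")
    factor = 1.1 * float(totals.max()) / own
    if factor > 1.0:
        sel = spec & (census["county_id"] == county_id)
        census = census.copy()
        census.loc[sel, "acres"] *= factor
    return census


def plant_identical_crop_mix(census: pd.DataFrame, target: int, analog: int) -> pd.DataFrame:
    """Give the analog county a copy of the target's crop records (both become
    complete), so the pair's specialty crop match fraction is exactly 1."""
    for cid in (target, analog):
        if cid not in set(census["county_id"]):
            raise KeyError(f"unknown county id {cid}")
    keep = census[census["county_id"] != analog]
    donor = census[census["county_id"] == target].copy()
    donor["county_id"] = analog
    out = pd.concat([keep, donor], ignore_index=True)
    out.loc[out["county_id"].isin([target, analog]), "complete"] = True
    return out.sort_values(["county_id", "crop"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# top-level generator


def generate_climate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset from the configuration seed."""
    root = np.random.SeedSequence(config.seed)
    n_streams = 4 + len(config.scenarios) * config.n_gcms
    children = root.spawn(n_streams)
    rng_hist = np.random.default_rng(children[0])
    rng_land = np.random.default_rng(children[1])
    rng_census = np.random.default_rng(children[2])
    rng_plant = np.random.default_rng(children[3])

    historical = _simulate_cube(config, rng_hist)

    offsets = config.resolved_warming_offsets()
    future: dict[tuple[str, int], WeatherCube] = {}
    i = 4
    for s in config.scenarios:
        for g in range(config.n_gcms):
            rng_member = np.random.default_rng(children[i])
            i += 1
            future[(s, g)] = _simulate_cube(config, rng_member, warming=offsets[(s, g)])

    county_map = build_county_map(config)
    landuse = generate_landuse(config, rng_land)
    forced = frozenset(t for t, _ in config.planted_pairs)
    census = generate_crop_census(config, county_map, rng_census, forced_specialty=forced)

    dataset = SyntheticDataset(
        config=config,
        historical=historical,
        future=future,
        landuse=landuse,
        county_map=county_map,
        crop_census=census,
        planted_pairs=tuple(config.planted_pairs),
    )
    for target, analog in config.planted_pairs:
        plant_known_analog(dataset, target, analog, rng_plant)
        dataset.crop_census = boost_specialty_acreage(dataset.crop_census, target)
        if config.plant_identical_crops:
            dataset.crop_census = plant_identical_crop_mix(dataset.crop_census, target, analog)
    return dataset
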