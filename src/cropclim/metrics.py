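"""Agro-climatic indices derived from daily Tmax/Tmin/precipitation.

Two families of per-location, per-year summary variables are produced:

* the context-specific vector (5 values): annual growing degree days,
  frost-free season length, summer heat degree hours, dormancy-season chill
  hours, and the wettest-minus-driest-month precipitation range;
* the generic vector (8 values): mean temperature and total precipitation
  for each of the four 3-month season blocks (JFM/AMJ/JAS/OND).

All functions accept numpy arrays with days on the trailing axis and
broadcast over any leading axes, so the same code serves a single day, one
station-year, or a whole gridded cube.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .calendar import (
    CHILL_SEASON_DAYS,
    DAYS_PER_YEAR,
    MAR31_END,
    OCT1_DOY,
    SEASON_NAMES,
    SEASON_SLICES,
    monthly_totals,
)

CONTEXT_VARIABLES = ("gdd", "season_length", "hdh", "chill", "precip_range")
GENERIC_VARIABLES = tuple(f"tmean_{s}" for s in SEASON_NAMES) + tuple(
    f"prcp_{s}" for s in SEASON_NAMES
)


@dataclass(frozen=True)
class MetricThresholds:
    """Temperature thresholds (°C) for the derived agro-climatic indices."""

    gdd_base: float = 0.0
    gdd_upper: float = 29.44
    heat_threshold: float = 32.0
    chill_low: float = 0.0
    chill_high: float = 7.22
    frost_threshold: float = 0.0
    heat_season: str = "JAS"

    def __post_init__(self) -> None:
        vals = (
            self.gdd_base,
            self.gdd_upper,
            self.heat_threshold,
            self.chill_low,
            self.chill_high,
            self.frost_threshold,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("thresholds must be finite")
        if not self.gdd_base < self.gdd_upper:
            raise ValueError("gdd_base must be < gdd_upper")
        if not self.chill_low < self.chill_high:
            raise ValueError("chill_low must be < chill_high")
        if self.heat_season not in SEASON_SLICES:
            raise ValueError(f"unknown heat season {self.heat_season!r}")


DEFAULT_THRESHOLDS = MetricThresholds()


def _check_order(tmax, tmin) -> None:
    if np.any(np.asarray(tmax) < np.asarray(tmin)):
        raise ValueError("tmax < tmin")


def daily_gdd(tmax, tmin, thresholds: MetricThresholds = DEFAULT_THRESHOLDS):
    """Daily growing degree days by the clipped-average method.

    Both temperatures are clipped into [base, upper] before averaging, and
    the base is subtracted; the result is never negative.
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    _check_order(tmax, tmin)
    hi = np.clip(tmax, thresholds.gdd_base, thresholds.gdd_upper)
    lo = np.clip(tmin, thresholds.gdd_base, thresholds.gdd_upper)
    return np.maximum(0.0, (hi + lo) / 2.0 - thresholds.gdd_base)


def annual_gdd(tmax, tmin, thresholds: MetricThresholds = DEFAULT_THRESHOLDS):
    """Sum of daily GDD over a (..., 365) calendar year."""
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if tmax.shape[-1] != DAYS_PER_YEAR:
        raise ValueError("full calendar year required")
    return daily_gdd(tmax, tmin, thresholds).sum(axis=-1)


def longest_true_run(mask: np.ndarray) -> np.ndarray:
    """Length of the longest run of True along the trailing axis."""
    mask = np.asarray(mask, dtype=bool)
    run = np.zeros(mask.shape[:-1], dtype=np.int64)
    best = np.zeros(mask.shape[:-1], dtype=np.int64)
    for t in range(mask.shape[-1]):
        run = np.where(mask[..., t], run + 1, 0)
        best = np.maximum(best, run)
    return best


def frost_free_season_length(
    tmin, thresholds: MetricThresholds = DEFAULT_THRESHOLDS
):
    """Longest run of consecutive days with tmin strictly above freezing.

    The run is confined to the calendar year (no wraparound).
    """
    tmin = np.asarray(tmin, dtype=float)
    if tmin.shape[-1] != DAYS_PER_YEAR:
        raise ValueError("full calendar year required")
    return longest_true_run(tmin > thresholds.frost_threshold)


def disaggregate_hourly(tmax, tmin) -> np.ndarray:
    """Estimate 24 hourly temperatures from daily extremes with a sine curve.

    T(h) = mean + amplitude * sin(2*pi*(h - 9)/24), giving the daily maximum
    at 15:00 and the minimum at 03:00; the hourly mean equals
    (tmax + tmin)/2 exactly. Output gains a trailing axis of length 24.
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    _check_order(tmax, tmin)
    hours = np.arange(24)
    phase = np.sin(2.0 * np.pi * (hours - 9) / 24.0)
    mid = (tmax + tmin) / 2.0
    amp = (tmax - tmin) / 2.0
    return mid[..., np.newaxis] + amp[..., np.newaxis] * phase


def heat_degree_hours_days(
    tmax, tmin, thresholds: MetricThresholds = DEFAULT_THRESHOLDS
):
    """Heat degree hours accumulated over an arbitrary set of days.

    One unit is one hour spent 1 °C above the heat threshold; hourly
    temperatures come from :func:`disaggregate_hourly`. Days occupy the
    trailing axis. Days whose tmax never reaches the threshold contribute
    nothing and skip the hourly disaggregation.
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    _check_order(tmax, tmin)
    flat_max = tmax.reshape(-1)
    flat_min = tmin.reshape(-1)
    per_day = np.zeros(flat_max.shape)
    hot = flat_max > thresholds.heat_threshold
    if hot.any():
        hourly = disaggregate_hourly(flat_max[hot], flat_min[hot])
        per_day[hot] = np.maximum(0.0, hourly - thresholds.heat_threshold).sum(axis=-1)
    return per_day.reshape(tmax.shape).sum(axis=-1)


def heat_degree_hours(
    tmax, tmin, thresholds: MetricThresholds = DEFAULT_THRESHOLDS
):
    """Heat degree hours over the heat season (JAS block) of a (..., 365) year."""
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if tmax.shape[-1] != DAYS_PER_YEAR:
        raise ValueError("full calendar year required")
    sl = SEASON_SLICES[thresholds.heat_season]
    return heat_degree_hours_days(tmax[..., sl], tmin[..., sl], thresholds)


def chill_hours_days(
    tmax, tmin, thresholds: MetricThresholds = DEFAULT_THRESHOLDS
):
    """Count hours within [chill_low, chill_high] (both bounds inclusive).

    Hourly values from the sine disaggregation always lie in [tmin, tmax],
    so days entirely inside the band contribute 24 hours and days entirely
    outside contribute 0 without computing the hourly curve.
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    _check_order(tmax, tmin)
    flat_max = tmax.reshape(-1)
    flat_min = tmin.reshape(-1)
    per_day = np.zeros(flat_max.shape, dtype=np.int64)
    inside = (flat_min >= thresholds.chill_low) & (flat_max <= thresholds.chill_high)
    outside = (flat_max < thresholds.chill_low) | (flat_min > thresholds.chill_high)
    per_day[inside] = 24
    partial = ~(inside | outside)
    if partial.any():
        hourly = disaggregate_hourly(flat_max[partial], flat_min[partial])
        in_band = (hourly >= thresholds.chill_low) & (hourly <= thresholds.chill_high)
        per_day[partial] = in_band.sum(axis=-1)
    return per_day.reshape(tmax.shape).sum(axis=-1)


def chill_season_slice(
    tmax_years: np.ndarray, tmin_years: np.ndarray, year_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the 182-day dormancy season ending in ``year_index``.

    The season runs from Oct 1 of ``year_index - 1`` through Mar 31 of
    ``year_index``; ``*_years`` arrays are shaped (..., n_years, 365).
    """
    if year_index < 1:
        raise ValueError(
            "chill season needs the prior year's Oct-Dec; the first year of "
            "a series has no dormancy season"
        )
    tmax_prev = tmax_years[..., year_index - 1, OCT1_DOY:]
    tmin_prev = tmin_years[..., year_index - 1, OCT1_DOY:]
    tmax_cur = tmax_years[..., year_index, :MAR31_END]
    tmin_cur = tmin_years[..., year_index, :MAR31_END]
    tmax = np.concatenate([tmax_prev, tmax_cur], axis=-1)
    tmin = np.concatenate([tmin_prev, tmin_cur], axis=-1)
    assert tmax.shape[-1] == CHILL_SEASON_DAYS
    return tmax, tmin


def chill_hours(
    tmax_years: np.ndarray,
    tmin_years: np.ndarray,
    year_index: int,
    thresholds: MetricThresholds = DEFAULT_THRESHOLDS,
):
    """Chill hours over the dormancy season ending in ``year_index``."""
    tmax, tmin = chill_season_slice(tmax_years, tmin_years, year_index)
    return chill_hours_days(tmax, tmin, thresholds)


def precipitation_uniformity(prcp):
    """Wettest-month total minus driest-month total (mm) for a (..., 365) year."""
    prcp = np.asarray(prcp, dtype=float)
    if prcp.shape[-1] != DAYS_PER_YEAR:
        raise ValueError("full calendar year required")
    months = monthly_totals(prcp)
    return months.max(axis=-1) - months.min(axis=-1)


def generic_vector(tmax, tmin, prcp) -> np.ndarray:
    """Seasonal mean temperature and total precipitation, 8 values.

    Order follows :data:`GENERIC_VARIABLES`: four seasonal means of
    (tmax + tmin)/2 then four seasonal precipitation totals.
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    prcp = np.asarray(prcp, dtype=float)
    if tmax.shape[-1] != DAYS_PER_YEAR:
        raise ValueError("full calendar year required")
    tmean = (tmax + tmin) / 2.0
    cols = [tmean[..., SEASON_SLICES[s]].mean(axis=-1) for s in SEASON_NAMES]
    cols += [prcp[..., SEASON_SLICES[s]].sum(axis=-1) for s in SEASON_NAMES]
    return np.stack(cols, axis=-1)


def context_vector(
    tmax_years: np.ndarray,
    tmin_years: np.ndarray,
    prcp_years: np.ndarray,
    year_index: int,
    thresholds: MetricThresholds = DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """The 5-value context-specific vector for one year of a series.

    Requires ``year_index >= 1`` because chill accumulation uses the prior
    year's Oct-Dec days.
    """
    tmax = np.asarray(tmax_years, dtype=float)
    tmin = np.asarray(tmin_years, dtype=float)
    prcp = np.asarray(prcp_years, dtype=float)
    ty = tmax[..., year_index, :]
    ny = tmin[..., year_index, :]
    py = prcp[..., year_index, :]
    return np.stack(
        [
            annual_gdd(ty, ny, thresholds),
            frost_free_season_length(ny, thresholds).astype(float),
            heat_degree_hours(ty, ny, thresholds),
            chill_hours(tmax, tmin, year_index, thresholds).astype(float),
            precipitation_uniformity(py),
        ],
        axis=-1,
    )


def context_vectors(
    tmax_years: np.ndarray,
    tmin_years: np.ndarray,
    prcp_years: np.ndarray,
    thresholds: MetricThresholds = DEFAULT_THRESHOLDS,
    warn_first_year: bool = False,
) -> np.ndarray:
    """Context vectors for every usable year of a (..., n_years, 365) series.

    The first year has no dormancy season and is dropped; the result is
    shaped (..., n_years - 1, 5) and aligns with years[1:].
    """
    n_years = np.asarray(tmax_years).shape[-2]
    if n_years < 2:
        raise ValueError("need at least 2 years (chill uses the prior year)")
    if warn_first_year:
        warnings.warn(
            "first year dropped: no prior Oct-Dec for chill accumulation",
            stacklevel=2,
        )
    out = [
        context_vector(tmax_years, tmin_years, prcp_years, y, thresholds)
        for y in range(1, n_years)
    ]
    return np.stack(out, axis=-2)


def generic_vectors(
    tmax_years: np.ndarray, tmin_years: np.ndarray, prcp_years: np.ndarray
) -> np.ndarray:
    """Generic vectors for every year: (..., n_years, 8)."""
    return generic_vector(tmax_years, tmin_years, prcp_years)
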