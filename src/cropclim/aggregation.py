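"""Agricultural-cell masking and county-level climate aggregation.

Derived yearly climate vectors are computed per grid cell, averaged
(unweighted) over each county's agricultural cells, and summarized into a
30-year normal plus an interannual-variability (ICV) covariance of linearly
detrended yearly values. Future-scenario series contribute only normals —
no future ICV is ever computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from . import metrics
from .synthetic import WeatherCube

logger = logging.getLogger(__name__)

AG_FRACTION_THRESHOLD = 1.0 / 8.0

RIDGE_SCALE = 1e-8
CONDITION_LIMIT = 1e10


def regrid_linear(fine: np.ndarray, factor: int) -> np.ndarray:
    """Bilinear downsampling of a fine 2-D field to a coarse grid.

    The fine grid must be an integer ``factor`` refinement of the coarse
    grid; coarse values are bilinear interpolations of the fine field at the
    coarse cell centers, so constant fields are preserved exactly.
    """
    fine = np.asarray(fine, dtype=float)
    if fine.ndim != 2:
        raise ValueError("expected a 2-D field")
    if factor < 1 or fine.shape[0] % factor or fine.shape[1] % factor:
        raise ValueError(
            f"fine grid {fine.shape} is not an integer x{factor} refinement"
        )
    rows = np.arange(fine.shape[0], dtype=float)
    cols = np.arange(fine.shape[1], dtype=float)
    interp = RegularGridInterpolator((rows, cols), fine, method="linear")
    cr = np.arange(fine.shape[0] // factor) * factor + (factor - 1) / 2.0
    cc = np.arange(fine.shape[1] // factor) * factor + (factor - 1) / 2.0
    pts = np.stack(np.meshgrid(cr, cc, indexing="ij"), axis=-1)
    return interp(pts)


def build_ag_mask(ag_fraction: np.ndarray, threshold: float = AG_FRACTION_THRESHOLD) -> np.ndarray:
    """Flag cells whose agricultural fraction meets the threshold (inclusive)."""
    frac = np.asarray(ag_fraction, dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("agricultural fractions must lie in [0, 1]")
    return frac >= threshold


def county_yearly_vector(
    cell_vectors: np.ndarray, cell_is_county_ag: np.ndarray
) -> np.ndarray:
    """Unweighted mean of yearly vectors over a county's agricultural cells.

    ``cell_vectors`` is (n_cells, ..., k); ``cell_is_county_ag`` a boolean
    selector over cells.
    """
    sel = np.asarray(cell_is_county_ag, dtype=bool)
    if sel.sum() == 0:
        raise ValueError("county has no agricultural cells")
    return np.asarray(cell_vectors)[sel].mean(axis=0)


@dataclass
class CountyClimateProfile:
    """A county's climate normal and interannual-variability covariance."""

    county_id: int
    variable_names: tuple[str, ...]
    normal: np.ndarray            # (k,) mean over years of yearly vectors
    icv_series: np.ndarray        # (n_years, k) yearly values (pre-detrend)
    icv_cov: np.ndarray           # (k, k) covariance of detrended series
    n_years: int
    ridged: bool = False


def _detrend(series: np.ndarray) -> np.ndarray:
    """Remove a per-column OLS linear trend in the year index."""
    n = series.shape[0]
    t = np.arange(n, dtype=float)
    design = np.stack([np.ones(n), t], axis=1)
    coef, *_ = np.linalg.lstsq(design, series, rcond=None)
    return series - design @ coef


def build_profile(
    yearly_vectors: np.ndarray,
    county_id: int = -1,
    variable_names: tuple[str, ...] | None = None,
) -> CountyClimateProfile:
    """Summarize a (n_years, k) series into a normal + ICV covariance.

    The normal is the raw column mean. The ICV covariance is the sample
    covariance of the linearly detrended series; a small ridge is added when
    the matrix is ill-conditioned (or degenerate) so that a Mahalanobis
    factorization always exists.
    """
    series = np.asarray(yearly_vectors, dtype=float)
    if series.ndim != 2:
        raise ValueError("expected a (n_years, k) matrix")
    n_years, k = series.shape
    if n_years < 3:
        raise ValueError("need at least 3 years to estimate variability")
    if variable_names is None:
        variable_names = tuple(f"v{i}" for i in range(k))

    normal = series.mean(axis=0)
    resid = _detrend(series)
    cov = np.cov(resid, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)

    ridged = False
    mean_diag = float(np.mean(np.diag(cov)))
    # variance this small relative to the normals is numerical residue
    # (e.g. a noise-free trend), not real interannual variability
    scale = float(np.mean(normal**2)) + 1.0
    degenerate = mean_diag <= 1e-18 * scale
    eps = RIDGE_SCALE * (mean_diag if mean_diag > 0 and not degenerate else 1.0)
    cond = np.linalg.cond(cov)
    while degenerate or not np.isfinite(cond) or cond > CONDITION_LIMIT:
        if not ridged:
            logger.warning(
                "county %s: degenerate ICV covariance (cond=%.3g); adding ridge",
                county_id, cond,
            )
        cov = cov + eps * np.eye(k)
        ridged = True
        degenerate = False
        cond = np.linalg.cond(cov)
        eps *= 10.0

    return CountyClimateProfile(
        county_id=county_id,
        variable_names=tuple(variable_names),
        normal=normal,
        icv_series=series,
        icv_cov=cov,
        n_years=n_years,
        ridged=ridged,
    )


# ---------------------------------------------------------------------------
# cube -> county tables


def cell_yearly_vectors(cube: WeatherCube, mode: str,
                        thresholds: metrics.MetricThresholds = metrics.DEFAULT_THRESHOLDS) -> np.ndarray:
    """Per-cell yearly climate vectors for a weather cube.

    ``mode`` is "context" (5 variables, first year dropped for chill) or
    "generic" (8 variables, all years).
    """
    if mode == "context":
        return metrics.context_vectors(cube.tmax, cube.tmin, cube.prcp, thresholds)
    if mode == "generic":
        return metrics.generic_vectors(cube.tmax, cube.tmin, cube.prcp)
    raise ValueError(f"unknown variable mode {mode!r}")


def variable_names(mode: str) -> tuple[str, ...]:
    if mode == "context":
        return metrics.CONTEXT_VARIABLES
    if mode == "generic":
        return metrics.GENERIC_VARIABLES
    raise ValueError(f"unknown variable mode {mode!r}")


def county_cells(county_map, ag_mask: np.ndarray) -> dict[int, np.ndarray]:
    """Map county_id -> array of agricultural cell ids; counties without
    agricultural cells are excluded (and logged)."""
    out: dict[int, np.ndarray] = {}
    for cid, grp in county_map.groupby("county_id"):
        cells = grp["cell_id"].to_numpy()
        ag = cells[ag_mask[cells]]
        if len(ag) == 0:
            logger.warning("county %s has no agricultural cells; excluded", cid)
            continue
        out[int(cid)] = ag
    return out


def county_yearly_table(
    cube: WeatherCube,
    county_ag_cells: dict[int, np.ndarray],
    mode: str,
    thresholds: metrics.MetricThresholds = metrics.DEFAULT_THRESHOLDS,
) -> dict[int, np.ndarray]:
    """county_id -> (n_usable_years, k) yearly vectors averaged over the
    county's agricultural cells."""
    cell_vecs = cell_yearly_vectors(cube, mode, thresholds)
    return {
        cid: cell_vecs[cells].mean(axis=0)
        for cid, cells in county_ag_cells.items()
    }


def build_profiles(
    county_years: dict[int, np.ndarray], mode: str
) -> dict[int, CountyClimateProfile]:
    names = variable_names(mode)
    return {
        cid: build_profile(years, county_id=cid, variable_names=names)
        for cid, years in county_years.items()
    }


def future_normals(
    cube: WeatherCube,
    county_ag_cells: dict[int, np.ndarray],
    mode: str,
    thresholds: metrics.MetricThresholds = metrics.DEFAULT_THRESHOLDS,
) -> dict[int, np.ndarray]:
    """county_id -> (k,) future climate normal (mean over future years).

    Only the normal is retained for future scenarios.
    """
    table = county_yearly_table(cube, county_ag_cells, mode, thresholds)
    return {cid: years.mean(axis=0) for cid, years in table.items()}
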