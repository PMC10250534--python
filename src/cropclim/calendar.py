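"""365-day (leap-free) calendar helpers shared across the pipeline.

All daily series in this package use a fixed 365-day year; real-data readers
must drop Feb 29 before ingestion so that day-of-year indexing is stable.
"""

from __future__ import annotations

import numpy as np

DAYS_PER_YEAR = 365
HOURS_PER_DAY = 24

MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
MONTH_STARTS = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)[:-1]])
MONTH_ENDS = np.cumsum(MONTH_LENGTHS)  # exclusive

#: Day-of-year index (0-based) of each day's month, shape (365,).
DAY_MONTH = np.repeat(np.arange(12), MONTH_LENGTHS)

#: Three-month season blocks starting from January, as (start, stop) slices
#: into a 365-day year.
SEASON_NAMES = ("JFM", "AMJ", "JAS", "OND")
SEASON_SLICES = {
    "JFM": slice(int(MONTH_STARTS[0]), int(MONTH_ENDS[2])),   # 90 days
    "AMJ": slice(int(MONTH_STARTS[3]), int(MONTH_ENDS[5])),   # 91 days
    "JAS": slice(int(MONTH_STARTS[6]), int(MONTH_ENDS[8])),   # 92 days
    "OND": slice(int(MONTH_STARTS[9]), int(MONTH_ENDS[11])),  # 92 days
}

#: Oct 1 as a 0-based day-of-year index (day 274 of the year).
OCT1_DOY = int(MONTH_STARTS[9])
#: Mar 31 (exclusive end) as a 0-based day-of-year index.
MAR31_END = int(MONTH_ENDS[2])
#: Length of the dormancy (chill) season: prior Oct 1 .. current Mar 31.
CHILL_SEASON_DAYS = (DAYS_PER_YEAR - OCT1_DOY) + MAR31_END  # 92 + 90 = 182


def monthly_totals(daily: np.ndarray) -> np.ndarray:
    """Sum a (..., 365) daily array into (..., 12) monthly totals."""
    daily = np.asarray(daily)
    if daily.shape[-1] != DAYS_PER_YEAR:
        raise ValueError(f"expected {DAYS_PER_YEAR} days, got {daily.shape[-1]}")
    out = np.empty(daily.shape[:-1] + (12,), dtype=float)
    for m in range(12):
        out[..., m] = daily[..., MONTH_STARTS[m]:MONTH_ENDS[m]].sum(axis=-1)
    return out
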