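"""Specialty-crop coding, target selection, and crop-mix similarity.

Counties are coded specialty when any vegetable / fruit / tree-nut / berry
acreage is reported. Targets are the top specialty counties covering 99% of
specialty acreage. Target-analog crop-mix similarity is the Jaccard
fraction of shared specialty crops; pairs with a disclosure-suppressed
(incomplete) crop list are excluded from match statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analogs import ConsensusSet
from .synthetic import SPECIALTY_GROUPS

VALID_GROUPS = set(SPECIALTY_GROUPS) | {"non-specialty"}

CATEGORY_SPECIALTY_ANALOG = "has-specialty-analog"
CATEGORY_NONSPECIALTY_ONLY = "only-nonspecialty-analog"
CATEGORY_NO_ANALOG = "no-analog"


@dataclass
class CropMix:
    county_id: int
    crops: frozenset[str]
    specialty_crops: frozenset[str]
    specialty_acres: float
    complete: bool = True

    @property
    def is_specialty(self) -> bool:
        return self.specialty_acres > 0


def code_specialty(census: pd.DataFrame) -> dict[int, CropMix]:
    """Build a CropMix per county from long-form census records.

    Expects columns county_id, crop, group, acres and an optional boolean
    ``complete`` column (county-level disclosure flag).
    """
    bad = set(census["group"]) - VALID_GROUPS
    if bad:
        raise ValueError(f"unknown crop group label(s): {sorted(bad)}")
    if np.any(census["acres"].to_numpy() < 0):
        raise ValueError("negative acreage")
    out: dict[int, CropMix] = {}
    for cid, grp in census.groupby("county_id"):
        spec = grp[grp["group"].isin(SPECIALTY_GROUPS)]
        complete = bool(grp["complete"].all()) if "complete" in grp else True
        out[int(cid)] = CropMix(
            county_id=int(cid),
            crops=frozenset(grp["crop"]),
            specialty_crops=frozenset(spec["crop"]),
            specialty_acres=float(spec["acres"].sum()),
            complete=complete,
        )
    return out


def select_targets(
    crop_mixes: dict[int, CropMix], coverage: float = 0.99
) -> list[int]:
    """Shortest prefix of specialty counties (by descending specialty acreage,
    county_id tie-break) whose cumulative acreage share reaches ``coverage``."""
    specialty = [m for m in crop_mixes.values() if m.is_specialty]
    if not specialty:
        raise ValueError("no specialty counties in census")
    total = sum(m.specialty_acres for m in specialty)
    if total <= 0:
        raise ValueError("zero total specialty acreage")
    ranked = sorted(specialty, key=lambda m: (-m.specialty_acres, m.county_id))
    out, cum = [], 0.0
    for m in ranked:
        out.append(m.county_id)
        cum += m.specialty_acres
        if cum / total >= coverage:
            break
    return out


def crop_match_fraction(target: CropMix, analog: CropMix) -> float:
    """Jaccard similarity of specialty crop sets; 0 when the union is empty.

    Both crop lists must be complete — suppressed lists cannot be compared.
    """
    if not (target.complete and analog.complete):
        raise ValueError("crop match requires complete crop lists")
    union = target.specialty_crops | analog.specialty_crops
    if not union:
        return 0.0
    return len(target.specialty_crops & analog.specialty_crops) / len(union)


@dataclass
class MatchResult:
    target_id: int
    category: str
    match_fractions: dict[int, float] = field(default_factory=dict)
    max_match_fraction: float | None = None
    best_analog_id: int | None = None
    n_excluded_incomplete: int = 0


def max_match(
    target_id: int,
    consensus_set: ConsensusSet,
    crop_mixes: dict[int, CropMix],
) -> MatchResult:
    """Best specialty-crop match over a target's consensus analog set.

    The three-way existence category is: at least one acceptable analog in
    *another* specialty county (self-pairs do not count); acceptable analogs
    only in non-specialty counties; or no acceptable analogs at all.
    Analogs with incomplete crop lists stay in the analog set but are left
    out of the match statistics, as is the target itself when incomplete.
    """
    analogs = set(consensus_set.analog_ids)
    if not analogs:
        return MatchResult(target_id=target_id, category=CATEGORY_NO_ANALOG)

    others = analogs - {target_id}
    has_specialty = any(crop_mixes[a].is_specialty for a in others)
    category = CATEGORY_SPECIALTY_ANALOG if has_specialty else CATEGORY_NONSPECIALTY_ONLY

    target_mix = crop_mixes[target_id]
    fractions: dict[int, float] = {}
    excluded = 0
    for a in sorted(analogs):
        mix = crop_mixes[a]
        if not (target_mix.complete and mix.complete):
            excluded += 1
            continue
        fractions[a] = crop_match_fraction(target_mix, mix)

    best_id, best = None, None
    for a, f in fractions.items():
        if best is None or f > best:
            best_id, best = a, f
    return MatchResult(
        target_id=target_id,
        category=category,
        match_fractions=fractions,
        max_match_fraction=best,
        best_analog_id=best_id,
        n_excluded_incomplete=excluded,
    )
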