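"""Sigma-dissimilarity climate analog identification.

A target county's projected future climate normal is compared with every
candidate county's historical normal using a Mahalanobis distance scaled by
the candidate's interannual-variability covariance. Distances are
re-expressed on the sigma scale: the chi(k) percentile of the distance is
mapped back through the chi(1) quantile, so thresholds read like
one-dimensional standard deviations (2-sigma = 95th percentile, 4-sigma =
99.994th percentile). Candidates within 2-sigma are acceptable analogs;
targets beyond 4-sigma of everything are novel climates. Acceptable sets
from the GCM ensemble are merged by an at-least-m-models consensus rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi

from .aggregation import CountyClimateProfile

SIGMA_ACCEPT = 2.0
SIGMA_NOVEL = 4.0
SIGMA_CAP = 10.0

CATEGORY_ACCEPTABLE = "acceptable"
CATEGORY_INTERMEDIATE = "intermediate"
CATEGORY_NOVEL = "novel-range"


def mahalanobis(
    target_future_normal: np.ndarray,
    candidate_hist_normal: np.ndarray,
    candidate_icv_cov: np.ndarray,
) -> float:
    """sqrt(d' C^-1 d) with d the normal difference, via Cholesky solve."""
    d = np.asarray(target_future_normal, float) - np.asarray(candidate_hist_normal, float)
    cov = np.asarray(candidate_icv_cov, float)
    if d.ndim != 1 or cov.shape != (d.size, d.size):
        raise ValueError("dimension mismatch between vectors and covariance")
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(cov))):
        raise ValueError("non-finite inputs")
    factor = cho_factor(cov, lower=True)
    return float(np.sqrt(d @ cho_solve(factor, d)))


def sigma_dissimilarity(
    distance, dof: int, cap: float = SIGMA_CAP
) -> tuple[np.ndarray, np.ndarray]:
    """Map Mahalanobis distances to the sigma scale.

    p = chi(dof).cdf(distance); sigma = chi(1).ppf(p). The far tail is
    evaluated through survival functions so precision survives p -> 1, and
    the result is capped at ``cap`` with a saturation flag (ordering above
    the classification thresholds is all that matters there).

    Returns (sigma, saturated) with scalar inputs giving 0-d arrays.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if dof < 1:
        raise ValueError("dof must be >= 1")
    p = chi.cdf(d, dof)
    with np.errstate(over="ignore", divide="ignore"):
        low = chi.ppf(p, 1)
        high = chi.isf(chi.sf(d, dof), 1)
    sigma = np.where(p < 0.5, low, high)
    saturated = ~np.isfinite(sigma) | (sigma > cap)
    sigma = np.where(saturated, cap, sigma)
    return sigma, saturated


def sigma_percentile(sigma) -> np.ndarray:
    """Chi-distribution percentile equivalent to a sigma level.

    The sigma scale is anchored to the chi distribution with 1 degree of
    freedom, so 2-sigma sits at its 95th percentile and 4-sigma at its
    99.994th.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    return 100.0 * chi.cdf(sigma, 1)


def classify_sigma(sigma, accept: float = SIGMA_ACCEPT, novel: float = SIGMA_NOVEL):
    """Three-way partition with inclusive thresholds (<= accept; >= novel)."""
    sigma = np.asarray(sigma)
    out = np.full(sigma.shape, CATEGORY_INTERMEDIATE, dtype=object)
    out[sigma <= accept] = CATEGORY_ACCEPTABLE
    out[sigma >= novel] = CATEGORY_NOVEL
    return out


def compute_distances(
    future_normals: dict[tuple[str, int], dict[int, np.ndarray]],
    profiles: dict[int, CountyClimateProfile],
    target_ids,
    sigma_accept: float = SIGMA_ACCEPT,
    sigma_novel: float = SIGMA_NOVEL,
) -> pd.DataFrame:
    """All target x candidate x scenario x GCM distance records.

    ``future_normals`` maps (scenario, gcm) -> {county -> future normal};
    ``profiles`` holds every candidate's historical normal and ICV
    covariance. Produces exactly T*G*S*C rows.
    """
    target_ids = [int(t) for t in target_ids]
    cand_ids = sorted(profiles)
    k = len(profiles[cand_ids[0]].variable_names)
    cand_normals = np.stack([profiles[c].normal for c in cand_ids])
    factors = [cho_factor(profiles[c].icv_cov, lower=True) for c in cand_ids]

    rows = []
    for (scenario, gcm), normals in future_normals.items():
        for t in target_ids:
            diff = normals[t][None, :] - cand_normals  # (C, k)
            d2 = np.array(
                [diff[i] @ cho_solve(factors[i], diff[i]) for i in range(len(cand_ids))]
            )
            dist = np.sqrt(np.maximum(0.0, d2))
            sigma, saturated = sigma_dissimilarity(dist, k)
            cat = classify_sigma(sigma, sigma_accept, sigma_novel)
            rows.append(
                pd.DataFrame(
                    {
                        "target_id": t,
                        "candidate_id": cand_ids,
                        "scenario": scenario,
                        "gcm": gcm,
                        "mahalanobis": dist,
                        "dof": k,
                        "sigma": sigma,
                        "saturated": saturated,
                        "category": cat,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


@dataclass
class ConsensusSet:
    """Acceptable analogs supported by at least ``m`` ensemble members."""

    target_id: int
    scenario: str
    analog_ids: frozenset[int]
    m: int
    support: dict[int, int] = field(default_factory=dict)
    no_analog: bool = False
    novel: bool = False  # empty set AND >= 4-sigma from everything in all GCMs


def default_consensus_threshold(n_gcms: int) -> int:
    """Smallest member count exceeding a quarter of the ensemble.

    floor(n/4) + 1; equals the 5-of-19 rule at the full ensemble size.
    """
    if n_gcms < 1:
        raise ValueError("need at least one GCM")
    return n_gcms // 4 + 1


def consensus_fraction_pct(m: int, n_gcms: int) -> float:
    """Ensemble share (percent) represented by an m-of-n consensus rule."""
    return 100.0 * m / n_gcms


def consensus(
    distances: pd.DataFrame,
    target_id: int,
    scenario: str,
    m: int,
    sigma_accept: float = SIGMA_ACCEPT,
    sigma_novel: float = SIGMA_NOVEL,
) -> ConsensusSet:
    """Merge per-GCM acceptable-analog sets with an at-least-m rule."""
    sub = distances[
        (distances["target_id"] == target_id) & (distances["scenario"] == scenario)
    ]
    n_gcms = sub["gcm"].nunique()
    if n_gcms == 0:
        raise ValueError(f"no records for target {target_id} / {scenario}")
    if m < 1 or m > n_gcms:
        raise ValueError(f"consensus threshold m={m} outside [1, {n_gcms}]")
    acc = sub[sub["sigma"] <= sigma_accept]
    support = acc.groupby("candidate_id")["gcm"].nunique()
    kept = support[support >= m]
    analog_ids = frozenset(int(c) for c in kept.index)
    no_analog = len(analog_ids) == 0
    novel = bool(no_analog and (sub.groupby("gcm")["sigma"].min() >= sigma_novel).all())
    return ConsensusSet(
        target_id=int(target_id),
        scenario=scenario,
        analog_ids=analog_ids,
        m=m,
        support={int(c): int(v) for c, v in support.items()},
        no_analog=no_analog,
        novel=novel,
    )


def consensus_all(
    distances: pd.DataFrame, m: int, **kw
) -> dict[tuple[int, str], ConsensusSet]:
    out = {}
    for (t, s), _ in distances.groupby(["target_id", "scenario"]):
        out[(int(t), s)] = consensus(distances, int(t), s, m, **kw)
    return out


def analogset_overlap(set_a, set_b) -> tuple[float, bool]:
    """Jaccard overlap of two analog sets.

    Two empty sets agree ("no analogs" both ways) and score 1.0; the second
    return value flags that degenerate case so reports can exclude it.
    """
    a, b = set(set_a), set(set_b)
    if not a and not b:
        return 1.0, True
    return len(a & b) / len(a | b), False


def expected_comparisons(n_targets: int, n_gcms: int, n_scenarios: int, n_candidates: int) -> int:
    """Closed-form audit count of distance computations in a full run."""
    return n_targets * n_gcms * n_scenarios * n_candidates
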