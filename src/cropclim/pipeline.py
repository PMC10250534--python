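"""End-to-end orchestration: synthesize -> metrics -> aggregate -> analogs
-> consensus -> crop match -> report.

All stages are deterministic functions of the configuration seed. A run
produces plain CSV outputs plus a JSON summary and manifest so that two runs
with the same config can be diffed file-by-file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, aggregation, analogs, cropmix, io
from .analogs import ConsensusSet
from .cropmix import (
    CATEGORY_NO_ANALOG,
    CATEGORY_NONSPECIALTY_ONLY,
    CATEGORY_SPECIALTY_ANALOG,
    CropMix,
    MatchResult,
)
from .synthetic import SyntheticConfig, SyntheticDataset, generate_climate

logger = logging.getLogger(__name__)

VARIABLE_MODES = ("context", "generic", "both")
SENSITIVITY_THRESHOLDS = (3, 5, 7, 10)
MATCH_BINS = (0.2, 0.4, 0.6)

STAGES = (
    "synthesize", "metrics", "aggregate", "analogs",
    "consensus", "cropmatch", "report",
)


class PipelineError(RuntimeError):
    """A stage failed; carries the failing stage's name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig
    variable_mode: str = "context"
    sigma_accept: float = analogs.SIGMA_ACCEPT
    sigma_novel: float = analogs.SIGMA_NOVEL
    consensus_m: int | None = None
    coverage: float = 0.99
    sensitivity: bool = False

    def __post_init__(self) -> None:
        if self.variable_mode not in VARIABLE_MODES:
            raise ValueError(f"variable_mode must be one of {VARIABLE_MODES}")
        if not (0 < self.sigma_accept < self.sigma_novel):
            raise ValueError("need 0 < sigma_accept < sigma_novel")
        if self.consensus_m is not None and self.consensus_m < 1:
            raise ValueError("consensus_m must be >= 1")

    @property
    def modes(self) -> tuple[str, ...]:
        return ("context", "generic") if self.variable_mode == "both" else (self.variable_mode,)

    @property
    def primary_mode(self) -> str:
        return "context" if "context" in self.modes else "generic"

    def resolved_consensus_m(self) -> int:
        if self.consensus_m is not None:
            return self.consensus_m
        return analogs.default_consensus_threshold(self.synthetic.n_gcms)


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: SyntheticDataset
    targets: list[int]
    candidates: list[int]
    crop_mixes: dict[int, CropMix]
    distances: dict[str, pd.DataFrame]
    consensus: dict[str, dict[tuple[int, str], ConsensusSet]]
    matches: dict[str, dict[int, MatchResult]]  # scenario -> target -> result
    overlap: pd.DataFrame | None
    summary: dict
    sensitivity: dict | None = None


def _county_regions(county_map: pd.DataFrame) -> dict[int, str]:
    return {
        int(c): str(r)
        for c, r in county_map.groupby("county_id")["region"].first().items()
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run everything from the synthetic generator onward."""
    try:
        dataset = generate_climate(config.synthetic)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("synthesize", e) from e
    return run_on_dataset(dataset, config)


def run_on_dataset(dataset: SyntheticDataset, config: PipelineConfig) -> PipelineResult:
    """Run the pipeline on an already-generated (possibly modified) dataset."""
    stage = "aggregate"
    try:
        mask = aggregation.build_ag_mask(dataset.landuse)
        county_ag = aggregation.county_cells(dataset.county_map, mask)
        candidates = sorted(county_ag)

        stage = "cropmatch"
        crop_mixes = cropmix.code_specialty(dataset.crop_census)
        ranked = cropmix.select_targets(crop_mixes, coverage=config.coverage)
        targets = [t for t in ranked if t in county_ag]
        dropped = [t for t in ranked if t not in county_ag]
        if dropped:
            logger.warning("targets without agricultural cells excluded: %s", dropped)
        if not targets:
            raise ValueError("no target county has agricultural cells")

        distances: dict[str, pd.DataFrame] = {}
        consensus: dict[str, dict[tuple[int, str], ConsensusSet]] = {}
        m = config.resolved_consensus_m()
        for mode in config.modes:
            stage = "metrics"
            hist_years = aggregation.county_yearly_table(
                dataset.historical, county_ag, mode
            )
            stage = "aggregate"
            profiles = aggregation.build_profiles(hist_years, mode)
            # future climate is only needed for the targets, not the pool
            target_ag = {t: county_ag[t] for t in targets}
            futures = {
                key: aggregation.future_normals(cube, target_ag, mode)
                for key, cube in sorted(dataset.future.items())
            }
            stage = "analogs"
            distances[mode] = analogs.compute_distances(
                futures, profiles, targets,
                sigma_accept=config.sigma_accept, sigma_novel=config.sigma_novel,
            )
            expected = analogs.expected_comparisons(
                len(targets), dataset.config.n_gcms,
                len(dataset.config.scenarios), len(candidates),
            )
            if len(distances[mode]) != expected:
                raise AssertionError(
                    f"audit failure ({mode}): {len(distances[mode])} records, "
                    f"expected {expected}"
                )
            stage = "consensus"
            consensus[mode] = analogs.consensus_all(
                distances[mode], m,
                sigma_accept=config.sigma_accept, sigma_novel=config.sigma_novel,
            )

        stage = "cropmatch"
        primary = config.primary_mode
        matches: dict[str, dict[int, MatchResult]] = {}
        for scenario in dataset.config.scenarios:
            matches[scenario] = {
                t: cropmix.max_match(t, consensus[primary][(t, scenario)], crop_mixes)
                for t in targets
            }

        overlap = None
        if config.variable_mode == "both":
            rows = []
            for scenario in dataset.config.scenarios:
                for t in targets:
                    frac, both_empty = analogs.analogset_overlap(
                        consensus["context"][(t, scenario)].analog_ids,
                        consensus["generic"][(t, scenario)].analog_ids,
                    )
                    rows.append((t, scenario, frac, both_empty))
            overlap = pd.DataFrame(
                rows, columns=["target_id", "scenario", "overlap", "both_empty"]
            )

        sens = None
        if config.sensitivity:
            sens = sensitivity_analysis(distances[primary], dataset.config.n_gcms)

        stage = "report"
        summary = summarize(
            _county_regions(dataset.county_map), targets, candidates,
            dataset.config, matches, overlap, m,
        )
        if sens is not None:
            summary["sensitivity"] = sens
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    return PipelineResult(
        config=config, dataset=dataset, targets=targets, candidates=candidates,
        crop_mixes=crop_mixes, distances=distances, consensus=consensus,
        matches=matches, overlap=overlap, summary=summary, sensitivity=sens,
    )


def sensitivity_analysis(
    distance_table: pd.DataFrame,
    n_gcms: int,
    thresholds: tuple[int, ...] = SENSITIVITY_THRESHOLDS,
) -> dict:
    """Consensus-set sizes re-computed for a ladder of m thresholds."""
    out: dict[str, dict] = {}
    for m in thresholds:
        if m > n_gcms:
            continue
        sets = analogs.consensus_all(distance_table, m)
        out[str(m)] = {
            f"{t}/{s}": len(cs.analog_ids) for (t, s), cs in sorted(sets.items())
        }
    return out


def summarize(
    regions: dict[int, str],
    targets: list[int],
    candidates: list[int],
    syn: SyntheticConfig,
    matches: dict[str, dict[int, MatchResult]],
    overlap: pd.DataFrame | None,
    consensus_m: int,
) -> dict:
    """Region-level analog-existence percentages and match-fraction bins."""
    audit = analogs.expected_comparisons(
        len(targets), syn.n_gcms, len(syn.scenarios), len(candidates)
    )
    summary: dict = {
        "n_targets": len(targets),
        "n_candidates": len(candidates),
        "n_gcms": syn.n_gcms,
        "scenarios": list(syn.scenarios),
        "consensus_m": consensus_m,
        "comparisons_per_mode": audit,
        "by_scenario": {},
    }
    cats = (CATEGORY_SPECIALTY_ANALOG, CATEGORY_NONSPECIALTY_ONLY, CATEGORY_NO_ANALOG)
    for scenario, per_target in matches.items():
        region_of = lambda t: regions[t]  # noqa: E731
        region_names = sorted({region_of(t) for t in targets})
        by_region = {}
        for rn in ["all"] + region_names:
            members = [t for t in targets if rn == "all" or region_of(t) == rn]
            if not members:
                logger.warning("region %s has no targets; omitted", rn)
                continue
            counts = {c: 0 for c in cats}
            for t in members:
                counts[per_target[t].category] += 1
            by_region[rn] = {
                "n_targets": len(members),
                **{f"pct_{c}": 100.0 * counts[c] / len(members) for c in cats},
            }
        max_fracs = [
            r.max_match_fraction
            for r in per_target.values()
            if r.max_match_fraction is not None
        ]
        bins = {
            f"pct_max_match_ge_{b}": (
                100.0 * float(np.mean([f >= b for f in max_fracs])) if max_fracs else 0.0
            )
            for b in MATCH_BINS
        }
        entry = {"regions": by_region, "n_with_match": len(max_fracs), **bins}
        if overlap is not None:
            sub = overlap[overlap["scenario"] == scenario]
            informative = sub[~sub["both_empty"]]
            entry["overlap_mean"] = (
                float(informative["overlap"].mean()) if len(informative) else None
            )
            entry["pct_zero_overlap"] = (
                100.0 * float((informative["overlap"] == 0).mean())
                if len(informative)
                else None
            )
        summary["by_scenario"][scenario] = entry
    return summary


# ---------------------------------------------------------------------------
# file outputs


def consensus_frame(sets: dict[tuple[int, str], ConsensusSet]) -> pd.DataFrame:
    rows = []
    for (t, s), cs in sorted(sets.items()):
        if cs.analog_ids:
            for a in sorted(cs.analog_ids):
                rows.append((t, s, a, cs.support[a], False, False))
        else:
            rows.append((t, s, pd.NA, 0, True, cs.novel))
    return pd.DataFrame(
        rows,
        columns=["target_id", "scenario", "analog_id",
                 "n_gcms_supporting", "no_analog", "novel"],
    ).astype({"analog_id": "Int64"})


def matches_frame(matches: dict[str, dict[int, MatchResult]]) -> pd.DataFrame:
    rows = []
    for scenario, per_target in matches.items():
        for t, r in sorted(per_target.items()):
            if r.match_fractions:
                for a, f in sorted(r.match_fractions.items()):
                    rows.append((t, scenario, a, f, a == r.best_analog_id, r.category))
            else:
                rows.append((t, scenario, pd.NA, np.nan, False, r.category))
    return pd.DataFrame(
        rows,
        columns=["target_id", "scenario", "analog_id",
                 "match_fraction", "max_flag", "category"],
    ).astype({"analog_id": "Int64"})


def write_outputs(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write CSV/JSON outputs; on failure, remove partial files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        for mode, df in result.distances.items():
            p = out / f"distances_{mode}.csv"
            df.to_csv(p, index=False)
            written.append(p)
            p = out / f"consensus_{mode}.csv"
            consensus_frame(result.consensus[mode]).to_csv(p, index=False)
            written.append(p)
        p = out / "matches.csv"
        matches_frame(result.matches).to_csv(p, index=False)
        written.append(p)
        if result.overlap is not None:
            p = out / "overlap.csv"
            result.overlap.to_csv(p, index=False)
            written.append(p)
        p = out / "summary.json"
        io.write_json(result.summary, p)
        written.append(p)
        p = out / "manifest.json"
        io.write_json(_manifest(result), p)
        written.append(p)
    except Exception as e:  # noqa: BLE001
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError("report", e) from e
    return written


def _manifest(result: PipelineResult) -> dict:
    import pandas
    import scipy

    syn = result.config.synthetic
    return {
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pandas.__version__,
            "scipy": scipy.__version__,
        },
        "config": {
            "seed": syn.seed,
            "grid_shape": list(syn.grid_shape),
            "n_counties": syn.n_counties,
            "n_years_hist": syn.n_years_hist,
            "n_gcms": syn.n_gcms,
            "scenarios": list(syn.scenarios),
            "variable_mode": result.config.variable_mode,
            "sigma_accept": result.config.sigma_accept,
            "sigma_novel": result.config.sigma_novel,
            "consensus_m": result.config.resolved_consensus_m(),
            "coverage": result.config.coverage,
        },
        "counts": {
            "n_targets": len(result.targets),
            "n_candidates": len(result.candidates),
            "distance_records": {
                mode: int(len(df)) for mode, df in result.distances.items()
            },
        },
    }
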