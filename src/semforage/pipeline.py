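"""End-to-end orchestration: read -> code -> exclude -> MVT -> nulls -> stats."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import coding, fluency_io, foraging, nulls, preprocess, stats

log = logging.getLogger("semforage")

__all__ = ["RunConfig", "run_pipeline", "load_and_prepare", "mvt_tables"]


@dataclass
class RunConfig:
    fluency_path: Path
    lexicon_path: Path
    out_dir: Path
    dialect: dict | None = None
    timing_policy: str = "fold"
    hold_policy: str = "hold"
    t_max: float | None = None
    n_perms: int = 1000
    seed: int = 0
    permutation_scope: str = "group"
    run_nulls: bool = True
    run_individual_test: bool = False
    ages: dict[str, float] | None = None


def load_and_prepare(
    config: RunConfig,
) -> tuple[coding.CodedDataset, preprocess.ExclusionReport, fluency_io.ReadReport]:
    """Read, code, and apply exclusions; returns the retained dataset + audits."""
    lists, read_report = fluency_io.read_fluency_table(
        config.fluency_path, config.dialect
    )
    lexicon = fluency_io.read_lexicon(config.lexicon_path)
    coded = coding.code_dataset(lists, lexicon)
    retained, excl_report = preprocess.apply_exclusions(coded)
    log.info(
        "read %d rows -> %d lists; retained %d lists from %d participants",
        read_report.rows_read, read_report.lists_formed,
        excl_report.n_lists_retained, excl_report.n_participants_retained,
    )
    return retained, excl_report, read_report


def mvt_tables(dataset: coding.CodedDataset, config: RunConfig) -> dict[str, pd.DataFrame]:
    """Group, per-participant, and per-trial MVT result tables plus the curve."""
    tables: dict[str, pd.DataFrame] = {}
    for scope in ("group", "participant", "trial"):
        results = foraging.mvt_analysis(
            dataset, scope=scope, timing_policy=config.timing_policy,
            hold_policy=config.hold_policy, t_max=config.t_max,
        )
        tables[f"mvt_{scope}"] = pd.DataFrame(
            [
                {
                    "scope": r.scope, "label": r.label,
                    "switch_time_mean_ms": r.switch_time_mean_ms,
                    "empirical_leave_mean_ms": r.empirical_leave_mean_ms,
                    "optimal_leave_ms": r.optimal_leave_ms,
                    "abs_deviance_ms": r.abs_deviance_ms,
                    "rel_deviance": r.relative_deviance,
                    "max_rate_per_ms": r.max_rate_per_ms,
                    "n_clusters": r.n_clusters,
                    "n_switch_times": r.n_switch_times,
                }
                for r in results
            ]
        )
    clusters = foraging.dataset_clusters(dataset, config.timing_policy)
    curve = foraging.average_retrieval_curve(
        clusters, hold_policy=config.hold_policy, t_max=config.t_max
    )
    tables["retrieval_curve"] = pd.DataFrame(
        {"jump_time_ms": curve.jump_times_ms, "g": curve.values}
    )
    return tables


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the full analysis and write all tables under ``config.out_dir``."""
    retained, excl_report, read_report = load_and_prepare(config)
    tables = mvt_tables(retained, config)
    tables["exclusions"] = excl_report.to_frame()

    if config.run_nulls:
        null = nulls.null_distribution(
            retained, scope=config.permutation_scope, n_perms=config.n_perms,
            seed=config.seed, timing_policy=config.timing_policy,
            hold_policy=config.hold_policy, t_max=config.t_max,
        )
        tables["null_distribution"] = null.to_frame()
        tables["null_summary"] = pd.DataFrame(
            [{
                "scope": null.scope, "n_perms": null.n_perms, "seed": null.seed,
                "empirical_deviance_ms": null.empirical_deviance_ms,
                "null_mean_ms": null.mean_ms, "null_min_ms": null.min_ms,
                "exceedance": null.exceedance,
            }]
        )
    if config.run_individual_test:
        table, summary = nulls.individual_optimality_test(
            retained, n_perms=config.n_perms, seed=config.seed,
            timing_policy=config.timing_policy, hold_policy=config.hold_policy,
        )
        tables["individual_test"] = table
        tables["individual_summary"] = pd.DataFrame([summary])

    if config.ages is not None:
        tables["participant_metrics"] = stats.participant_table(
            retained, ages=config.ages, timing_policy=config.timing_policy,
            hold_policy=config.hold_policy,
        )

    fluency_io.write_results(tables, config.out_dir, config=config, seed=config.seed)
    return tables
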