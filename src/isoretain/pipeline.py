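"""End-to-end scenario runner: simulate, analyse, and write reports.

Three self-contained scenarios cover the pipeline's stages:

* ``retention``  — gene models → stressed/control reads → counts →
  retention rates → fold changes → ranked list → set enrichment,
* ``bimodality`` — dose grid → per-well flow samples → trough-depth map
  and the pooled depth-vs-median curve,
* ``survival``   — CFU decay → Delta statistic and Poisson bootstrap.

Outputs are deterministic given the config (the run log carries the only
timestamps); ``summary.json`` collects the headline numbers of each stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import io as iso_io
from .bimodality import grid_bimodality_map
from .config import AnalysisConfig, write_config
from .counting import build_counts_table
from .resampling import delta_statistic, poisson_bootstrap_p, survival_curve
from .retention import enrichment_table, fold_changes, rank_by_fold, retention_table
from .synthetic import (
    FlowSimParams,
    SurvivalSimParams,
    gen_gene_models,
    make_grid,
    sim_flow_grid,
    sim_reads,
    sim_survival,
)
from .validation import _condition_truth

logger = logging.getLogger(__name__)

SCENARIOS = ("retention", "bimodality", "survival", "all")


def _run_retention(config: AnalysisConfig, out: Path) -> dict:
    rng = np.random.default_rng(config.seed)
    models = gen_gene_models(
        n_genes=120, frac_rp=0.2, frac_utr_intron=0.4, seed=config.seed,
        frac_cds_intron=0.6,
    )
    control_truth = _condition_truth(models, rng, stressed=False)
    treated_truth = _condition_truth(models, rng, stressed=True)
    control_reads = sim_reads(models, control_truth, depth=400.0,
                              read_length=config.read_length, seed=config.seed + 1)
    treated_reads = sim_reads(models, treated_truth, depth=400.0,
                              read_length=config.read_length, seed=config.seed + 2)
    iso_io.write_saf(models, out / "annotation.saf")
    iso_io.write_reads_bed(treated_reads, out / "reads_treated.bed")
    iso_io.write_reads_bed(control_reads, out / "reads_control.bed")
    control_counts = build_counts_table(control_reads, models, config.read_length)
    treated_counts = build_counts_table(treated_reads, models, config.read_length)
    iso_io.write_counts_tsv(treated_counts, out / "counts_treated.tsv")
    iso_io.write_counts_tsv(control_counts, out / "counts_control.tsv")
    treated_recs, undefined = retention_table(treated_counts, method="density")
    control_recs, _ = retention_table(control_counts, method="density")
    folds = fold_changes(treated_recs, control_recs)
    iso_io.write_retention_tsv(folds, out / "retention.tsv")
    ranked = rank_by_fold(folds)
    rp_set = {m.gene_id for m in models if "RP" in m.labels} & set(ranked)
    sets = {"RP": rp_set}
    rng_sets = np.random.default_rng(config.seed + 3)
    for d in range(5):
        sets[f"decoy{d}"] = set(
            rng_sets.choice(ranked, size=min(len(rp_set), len(ranked)),
                            replace=False).tolist()
        )
    iso_io.write_gene_sets(sets, out / "gene_sets.tsv")
    top_n = max(1, int(len(ranked) * config.top_n_fraction))
    results = enrichment_table(ranked, sets, top_n=top_n)
    iso_io.write_enrichment_tsv(results, out / "enrichment.tsv")
    best = min(results, key=lambda r: (r.p_adj, r.set_name))
    return {
        "n_genes": len(models),
        "n_ranked": len(ranked),
        "n_undefined": len(undefined),
        "top_gene": ranked[0] if ranked else None,
        "best_set": best.set_name,
        "best_p_adj": best.p_adj,
    }


def _run_bimodality(config: AnalysisConfig, out: Path) -> dict:
    grid = make_grid(n_rows=8, n_cols=8)
    params = FlowSimParams(n_cells=1000)
    wells = sim_flow_grid(grid, params, seed=config.seed)
    iso_io.write_cells_csv(wells, out / "cells.csv")
    iso_io.write_flow_truth_csv(wells, out / "flow_truth.csv")
    observed = [w.observed() for w in wells]
    per_well, curve, m_peak = grid_bimodality_map(
        observed,
        smooth_window=config.smooth_window,
        running_window=config.running_window,
        n_bins=config.hist_bins,
        lo=config.hist_lo,
        hi=config.hist_hi,
    )
    per_well.to_csv(out / "well_scores.tsv", sep="\t", index=False)
    curve.to_csv(out / "pooled_curve.tsv", sep="\t", index=False)
    return {
        "n_wells": len(per_well),
        "max_depth": float(per_well["d"].max()),
        "m_peak": m_peak,
    }


def _run_survival(config: AnalysisConfig, out: Path) -> dict:
    params = SurvivalSimParams()
    table = sim_survival(params, seed=config.seed)
    iso_io.write_survival_csv(table, out / "cfu.csv")
    curve = survival_curve(table)
    curve.to_csv(out / "survival_curve.tsv", sep="\t", index=False)
    res = poisson_bootstrap_p(
        table, n_surrogates=config.n_surrogates, seed=config.seed + 1
    )
    return {
        "delta_obs": res.delta_obs,
        "p_two_sided": res.p_two_sided,
        "p_one_sided": res.p_one_sided,
        "n_surrogates": res.n_surrogates,
    }


def run_scenario(
    config: AnalysisConfig, scenario: str, out_dir: str | Path
) -> dict:
    """Run one scenario (or all) into ``out_dir``; returns the summary dict."""
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_config(config, out / "config.toml")
    log_path = out / "run.log"
    with open(log_path, "w") as log:
        log.write(f"started {datetime.now(timezone.utc).isoformat()}\n")
        log.write(f"scenario {scenario} seed {config.seed}\n")
        summary: dict = {"scenario": scenario, "seed": config.seed}
        stages = (
            ["retention", "bimodality", "survival"] if scenario == "all" else [scenario]
        )
        for stage in stages:
            stage_dir = out / stage
            stage_dir.mkdir(exist_ok=True)
            runner = {
                "retention": _run_retention,
                "bimodality": _run_bimodality,
                "survival": _run_survival,
            }[stage]
            summary[stage] = runner(config, stage_dir)
            log.write(f"finished stage {stage}\n")
        log.write(f"done {datetime.now(timezone.utc).isoformat()}\n")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def config_digest(config: AnalysisConfig) -> str:
    import hashlib

    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()
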