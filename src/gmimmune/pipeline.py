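"""Configuration-driven end-to-end runs with a single JSON report.

A run executes: simulate (or load) Ct data -> relative expression ->
summaries -> gated hypothesis tests -> cross-/within-treatment correlation
-> clustering, plus optional health scoring and alignment-consensus
stages.  Every output is a plain CSV/JSON/newick file; re-running with the
same config and seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import correlation, health, qpcr, stats
from .consensus import (alignment_metrics, derive_consensus,
                        load_residue_classes, read_aligned_pair,
                        write_column_table, write_consensus_fasta)
from .design import EffectProfileSet, ExperimentDesign
from .errors import GmimmuneError
from .simulate import (generate_ct_table, generate_health_observations,
                       healthy_profile)


@dataclass
class PipelineConfig:
    """Everything a run needs; thresholds default to the screen's values."""

    seed: int = 0
    ct_csv: Optional[str] = None          # load instead of simulating
    noise_sd: float = 0.25
    alpha: float = 0.05
    fc_edges: Tuple[float, float] = (0.5, 2.0)
    rho_edges: Tuple[float, float, float] = (0.3, 0.5, 0.7)
    linkage: str = "average"
    class_map: Optional[str] = None       # YAML residue-class override
    alignments: List[str] = field(default_factory=list)
    health_csv: Optional[str] = None
    simulate_health: bool = True
    design: ExperimentDesign = field(default_factory=ExperimentDesign)

    def __post_init__(self):
        self.fc_edges = tuple(self.fc_edges)
        self.rho_edges = tuple(self.rho_edges)
        if not (self.fc_edges[0] < 1 < self.fc_edges[1]):
            raise GmimmuneError("fc_edges must straddle 1")
        if list(self.rho_edges) != sorted(self.rho_edges):
            raise GmimmuneError("rho_edges must be strictly ordered")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        design_kwargs = raw.pop("design", None)
        config = cls(**raw)
        if design_kwargs:
            config.design = ExperimentDesign(**design_kwargs)
        return config


def run_pipeline(config: PipelineConfig, outdir) -> Dict:
    """Execute all stages, write outputs under ``outdir``, return the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = config.design
    report: Dict = {"seed": config.seed, "alpha": config.alpha,
                    "outputs": {}, "stages": {}}

    def save(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        report["outputs"][name.split(".")[0]] = name

    # --- stage: Ct data -----------------------------------------------------
    if config.ct_csv:
        ct = pd.read_csv(config.ct_csv)
    else:
        # default trajectories where the design matches the screen's genes;
        # unit fold change for any other cell
        from .reference import default_trajectories
        known = default_trajectories()
        fc = {cell: known.get(cell, 1.0) for cell in design.cells()}
        profiles = EffectProfileSet(fc=fc, noise_sd=config.noise_sd)
        ct = generate_ct_table(design, profiles, seed=config.seed)
    save(ct, "ct_table.csv")

    # --- stage: expression --------------------------------------------------
    expr = qpcr.compute_relative_expression(
        ct, housekeeping=design.housekeeping_gene,
        control_label=design.control_label)
    save(expr, "expression.csv")
    summary = qpcr.summarize_expression(expr, edges=config.fc_edges)
    save(summary, "expression_summary.csv")
    report["stages"]["expression"] = {
        "n_cells": len(summary),
        "bands": summary["band"].value_counts().to_dict(),
    }

    # --- stage: hypothesis tests -------------------------------------------
    comparisons = stats.build_comparison_set(design)
    results = stats.test_group_differences(expr, comparisons, alpha=config.alpha)
    tests_df = stats.results_to_frame(results)
    save(tests_df, "tests.csv")
    report["stages"]["tests"] = {
        "n_comparisons": len(tests_df),
        "n_significant": int((tests_df["p"] < config.alpha).sum()),
    }

    # --- stage: correlation + clustering -------------------------------------
    if len(design.treatments) >= 2:
        tr_a, tr_b = design.treatments[:2]
        cross = [correlation.cross_treatment_correlation(expr, g, tr_a, tr_b,
                                                         alpha=config.alpha)
                 for g in design.target_genes]
        cross_df = pd.DataFrame([vars(c) for c in cross])
        cross_df["category"] = [
            correlation.classify_correlation_strength(c.rho, c.p, config.alpha,
                                                      config.rho_edges)
            for c in cross]
        save(cross_df, "cross_treatment.csv")

    trees = {}
    for treatment in design.treatments:
        mat = correlation.within_treatment_matrix(expr, treatment,
                                                  alpha=config.alpha)
        save(correlation.matrix_to_long(mat, config.rho_edges),
             f"correlation_{treatment}.csv")
        tree = correlation.cluster_correlation_matrix(mat, linkage=config.linkage)
        newick_path = outdir / f"tree_{treatment}.newick"
        newick_path.write_text(tree.to_newick() + "\n")
        report["outputs"][f"tree_{treatment}"] = newick_path.name
        trees[treatment] = tree.cut(2)
    report["stages"]["clustering"] = {t: c for t, c in trees.items()}

    # --- stage: health -------------------------------------------------------
    obs = None
    if config.health_csv:
        obs = pd.read_csv(config.health_csv)
    elif config.simulate_health:
        groups = list(design.all_groups)
        obs = generate_health_observations(
            groups, {g: healthy_profile() for g in groups},
            seed=config.seed)
    if obs is not None:
        save(health.score_table(obs), "health_observations.csv")
        agg = health.aggregate_health(obs)
        save(agg, "health_summary.csv")
        surv = health.survival_fraction(obs)
        save(surv, "survival.csv")
        report["stages"]["health"] = {
            "mean_score": float(agg["mean_score"].mean()),
            "min_survival_fraction": float(surv["survival_fraction"].min()),
        }

    # --- stage: consensus ----------------------------------------------------
    classes = load_residue_classes(config.class_map) if config.class_map else None
    consensus_entries = []
    for fasta in config.alignments:
        pair = read_aligned_pair(fasta)
        cons = derive_consensus(pair, classes)
        stem = Path(fasta).stem
        write_consensus_fasta(cons, outdir / f"consensus_{stem}.fasta")
        write_column_table(pair, cons, outdir / f"columns_{stem}.tsv")
        metrics = alignment_metrics(pair)
        consensus_entries.append({
            "input": str(fasta), "query": pair.query_id,
            "subject": pair.subject_id, **metrics,
            "n_x": cons.sequence.count("X"),
        })
        report["outputs"][f"consensus_{stem}"] = f"consensus_{stem}.fasta"
    if consensus_entries:
        report["stages"]["consensus"] = consensus_entries

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
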