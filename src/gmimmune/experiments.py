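"""Simulation experiments validating the pipeline's statistical behaviour.

These are first-class, seeded experiments run by the test suite and the
acceptance script: fold-change recovery under Ct noise, empirical type-I
error of the gated testing branch, and recovery of injected co-expression
modules by clustering.
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .correlation import (cluster_correlation_matrix, module_accuracy,
                          within_treatment_matrix)
from .design import EffectProfileSet, ExperimentDesign
from .qpcr import compute_relative_expression
from .simulate import generate_ct_table
from .stats import ANOVA_TUKEY, choose_branch

DEFAULT_FC_SET = (0.25, 0.5, 1.0, 2.0, 4.0, 39.5)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def _fc_design(fc_values: Sequence[float], n_bio: int, n_tech: int) -> ExperimentDesign:
    return ExperimentDesign(
        target_genes=tuple(f"g{i}" for i in range(len(fc_values))),
        housekeeping_gene="hk", treatments=("T",), control_label="C",
        times_h=(3.0,), n_bio=n_bio, n_tech=n_tech)


def recover_fold_change(fc_values: Sequence[float] = DEFAULT_FC_SET,
                        noise_sd: float = 0.1, n_bio: int = 3, n_tech: int = 2,
                        n_seeds: int = 200, seed: int = 0) -> pd.DataFrame:
    """Mean recovered 2^-ddCt per injected fold change over many seeds.

    One gene per fold-change value, one treatment against control, Ct noise
    at ``noise_sd``.  Returns per-value injected truth, Monte-Carlo mean of
    the per-seed cell means, and the relative error in percent.
    """
    design = _fc_design(fc_values, n_bio, n_tech)
    profiles_fc = {(f"g{i}", "T", 3.0): float(v) for i, v in enumerate(fc_values)}
    recovered = np.zeros((n_seeds, len(fc_values)))
    for row, s in enumerate(_child_seeds(seed, n_seeds)):
        profiles = EffectProfileSet(fc=dict(profiles_fc), noise_sd=noise_sd)
        ct = generate_ct_table(design, profiles, seed=int(s))
        expr = compute_relative_expression(ct, housekeeping="hk", control_label="C")
        means = expr[expr["treatment"] == "T"].groupby("gene")["rel_expr"].mean()
        recovered[row] = [means[f"g{i}"] for i in range(len(fc_values))]
    mean_rec = recovered.mean(axis=0)
    return pd.DataFrame({
        "injected_fc": list(fc_values),
        "mean_recovered_fc": mean_rec,
        "rel_error_pct": 100.0 * (mean_rec - np.asarray(fc_values)) / np.asarray(fc_values),
    })


def estimate_type1_error(n_datasets: int = 2000, n_groups: int = 5,
                         n_per_group: int = 3, alpha: float = 0.05,
                         seed: int = 0) -> Dict[str, float]:
    """Empirical size of the gated branch on null Gaussian families.

    Each dataset is one comparison family of ``n_groups`` identical Gaussian
    groups; a rejection is an omnibus p < alpha after the Shapiro/Levene
    gate chooses the branch.  Also reports how often the parametric branch
    was taken.
    """
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    rejections = 0
    parametric = 0
    for _ in range(n_datasets):
        groups = [rng.normal(0.0, 1.0, n_per_group) for _ in range(n_groups)]
        # gate + omnibus only; the post hoc stage does not affect the
        # omnibus rejection rate
        branch = choose_branch(groups, gate_alpha=alpha)
        if branch == ANOVA_TUKEY:
            parametric += 1
            omnibus_p = sps.f_oneway(*groups).pvalue
        else:
            omnibus_p = sps.kruskal(*groups).pvalue
        rejections += omnibus_p < alpha
    return {
        "type1_error": float(rejections / n_datasets),
        "parametric_fraction": float(parametric / n_datasets),
        "n_datasets": n_datasets,
    }


def _module_profiles(design: ExperimentDesign,
                     membership: Dict[str, int],
                     noise_sd: float) -> EffectProfileSet:
    # two injected trajectories with opposite temporal shapes
    trajectories = {
        1: {3.0: 1.0, 6.0: 4.0, 12.0: 8.0, 18.0: 2.0, 24.0: 0.5},
        2: {3.0: 4.0, 6.0: 1.0, 12.0: 0.25, 18.0: 1.0, 24.0: 4.0},
    }
    fc = {}
    for gene, module in membership.items():
        for t in design.times_h:
            fc[(gene, "T", t)] = trajectories[module][t]
    return EffectProfileSet(fc=fc, noise_sd=noise_sd)


def module_recovery(n_seeds: int = 100, noise_sd: float = 0.2,
                    n_genes: int = 10, seed: int = 0) -> Dict[str, float]:
    """Accuracy of a 2-cluster cut at recovering two injected co-expression
    modules (shared trajectories + Ct noise), averaged over seeds."""
    genes = tuple(f"g{i:02d}" for i in range(n_genes))
    membership = {g: 1 if i < n_genes // 2 else 2 for i, g in enumerate(genes)}
    design = ExperimentDesign(target_genes=genes, housekeeping_gene="hk",
                              treatments=("T",), control_label="C",
                              times_h=(3.0, 6.0, 12.0, 18.0, 24.0),
                              n_bio=3, n_tech=2)
    accuracies = []
    for s in _child_seeds(seed, n_seeds):
        profiles = _module_profiles(design, membership, noise_sd)
        ct = generate_ct_table(design, profiles, seed=int(s))
        expr = compute_relative_expression(ct, housekeeping="hk", control_label="C")
        mat = within_treatment_matrix(expr[expr["treatment"] == "T"], "T")
        tree = cluster_correlation_matrix(mat)
        accuracies.append(module_accuracy(tree.cut(2), membership))
    return {"mean_accuracy": float(np.mean(accuracies)),
            "min_accuracy": float(np.min(accuracies)),
            "n_seeds": n_seeds}
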