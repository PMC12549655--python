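"""Normality-gated hypothesis testing over the screen's comparison set.

Comparisons are reported only between consecutive time points within a
treatment and between treatments at the same time point.  Each comparison
belongs to a family — the groups entering one omnibus test: all time points
of one gene x treatment (consecutive kind) or all treatments of one gene x
time (between kind).  A family whose groups all pass Shapiro–Wilk
(p >= 0.05) and Levene (p >= 0.05) is tested parametrically (one-way ANOVA
with Tukey HSD pairwise p); otherwise non-parametrically (Kruskal–Wallis
with Dunn's post hoc, Bonferroni-adjusted over the family's pairs).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import ExperimentDesign

CONSECUTIVE = "consecutive_within_treatment"
BETWEEN = "between_treatments_same_time"

ANOVA_TUKEY = "anova_tukey"
KRUSKAL_DUNN = "kruskal_dunn_bonferroni"

GroupKey = Tuple[str, float]  # (treatment, time_h)


@dataclass(frozen=True)
class Comparison:
    kind: str
    gene: str
    group_a: GroupKey
    group_b: GroupKey


@dataclass
class TestResult:
    comparison: Comparison
    branch: str
    statistic: float  # omnibus statistic of the comparison's family
    omnibus_p: float
    p: float          # adjusted pairwise p for this comparison
    stars: str


def significance_stars(p: float) -> str:
    """Star label: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value outside [0, 1]: {p!r}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def build_comparison_set(design: ExperimentDesign) -> List[Comparison]:
    """All reported comparisons: per gene, (T−1) consecutive time pairs per
    non-control treatment plus one between-treatment pair per time."""
    comparisons: List[Comparison] = []
    for gene in design.target_genes:
        for treatment in design.treatments:
            for t_a, t_b in zip(design.times_h, design.times_h[1:]):
                comparisons.append(Comparison(CONSECUTIVE, gene,
                                              (treatment, t_a), (treatment, t_b)))
        for time_h in design.times_h:
            for tr_a, tr_b in itertools.combinations(design.treatments, 2):
                comparisons.append(Comparison(BETWEEN, gene,
                                              (tr_a, time_h), (tr_b, time_h)))
    return comparisons


def dunn_pairwise(groups: Sequence[np.ndarray]) -> np.ndarray:
    """Unadjusted p-values of Dunn's rank-sum post hoc test.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)) with the
    standard tie correction T = Σ(t³−t)/(12(N−1)); two-sided normal p.
    """
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[a:b].mean() for a, b in zip(bounds, bounds[1:])]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum() / (12 * (n_total - 1))
                if n_total > 1 else 0.0)
    variance = n_total * (n_total + 1) / 12.0 - tie_term

    k = len(groups)
    p = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(variance * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p[i, j] = p[j, i] = 2 * sps.norm.sf(abs(z))
    return p


def choose_branch(groups: Sequence[np.ndarray], gate_alpha: float = 0.05) -> str:
    """Gate a family: parametric only if every group passes Shapiro–Wilk and
    the family passes Levene; groups of n<3 force the non-parametric branch."""
    if any(len(g) < 3 for g in groups):
        warnings.warn("group with n < 3: forcing non-parametric branch",
                      stacklevel=2)
        return KRUSKAL_DUNN
    for g in groups:
        if np.ptp(g) == 0:  # Shapiro undefined on constant data
            return KRUSKAL_DUNN
        if sps.shapiro(g).pvalue < gate_alpha:
            return KRUSKAL_DUNN
    if sps.levene(*groups).pvalue < gate_alpha:
        return KRUSKAL_DUNN
    return ANOVA_TUKEY


def test_family(groups: Sequence[np.ndarray],
                gate_alpha: float = 0.05) -> Tuple[str, float, float, np.ndarray]:
    """Run the gated branch on one family.

    Returns (branch, omnibus statistic, omnibus p, pairwise adjusted p
    matrix).  Tukey p-values are family-wise by construction; Dunn p-values
    are Bonferroni-multiplied by the family's pair count.
    """
    branch = choose_branch(groups, gate_alpha)
    k = len(groups)
    if branch == ANOVA_TUKEY:
        omnibus = sps.f_oneway(*groups)
        if k > 1:
            tk = sps.tukey_hsd(*groups)
            pairwise = np.asarray(tk.pvalue)
        else:
            pairwise = np.ones((1, 1))
        return branch, float(omnibus.statistic), float(omnibus.pvalue), pairwise
    omnibus = sps.kruskal(*groups)
    pairwise = dunn_pairwise(groups)
    m = k * (k - 1) // 2
    pairwise = np.minimum(pairwise * max(m, 1), 1.0)
    np.fill_diagonal(pairwise, 1.0)
    return branch, float(omnibus.statistic), float(omnibus.pvalue), pairwise


def test_group_differences(expr: pd.DataFrame,
                           comparisons: Sequence[Comparison],
                           alpha: float = 0.05,
                           gate_alpha: float = 0.05) -> List[TestResult]:
    """Run the gated testing branch for every requested comparison.

    ``alpha`` only drives the star labels; ``gate_alpha`` is the threshold
    of the Shapiro–Wilk/Levene gate.
    """
    values: Dict[Tuple[str, str, float], np.ndarray] = {
        (g, tr, t): cell["rel_expr"].to_numpy()
        for (g, tr, t), cell in expr.groupby(["gene", "treatment", "time_h"])
    }

    # family key -> ordered group keys
    families: Dict[tuple, List[GroupKey]] = {}
    for comp in comparisons:
        if comp.kind == CONSECUTIVE:
            key = (CONSECUTIVE, comp.gene, comp.group_a[0])
        else:
            key = (BETWEEN, comp.gene, comp.group_a[1])
        members = families.setdefault(key, [])
        for gk in (comp.group_a, comp.group_b):
            if gk not in members:
                members.append(gk)

    cache: Dict[tuple, Tuple[str, float, float, np.ndarray, List[GroupKey]]] = {}
    results: List[TestResult] = []
    for comp in comparisons:
        key = ((CONSECUTIVE, comp.gene, comp.group_a[0])
               if comp.kind == CONSECUTIVE
               else (BETWEEN, comp.gene, comp.group_a[1]))
        if key not in cache:
            members = families[key]
            groups = []
            for tr, t in members:
                try:
                    groups.append(values[(comp.gene, tr, t)])
                except KeyError:
                    raise ValueError(
                        f"no expression values for gene={comp.gene!r}, "
                        f"treatment={tr!r}, time_h={t!r}") from None
            branch, stat, om_p, pairwise = test_family(groups, gate_alpha)
            cache[key] = (branch, stat, om_p, pairwise, members)
        branch, stat, om_p, pairwise, members = cache[key]
        i, j = members.index(comp.group_a), members.index(comp.group_b)
        p = float(pairwise[i, j])
        results.append(TestResult(comp, branch, stat, om_p, p,
                                  significance_stars(p)))
    return results


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "kind": r.comparison.kind, "gene": r.comparison.gene,
            "treatment_a": r.comparison.group_a[0], "time_a": r.comparison.group_a[1],
            "treatment_b": r.comparison.group_b[0], "time_b": r.comparison.group_b[1],
            "branch": r.branch, "statistic": r.statistic,
            "omnibus_p": r.omnibus_p, "p": r.p, "stars": r.stars,
        })
    return pd.DataFrame(rows)
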