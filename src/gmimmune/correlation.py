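"""Spearman co-expression analysis: cross-treatment similarity, within-
treatment gene x gene matrices with significance masking, and hierarchical
clustering of the matrices.

Paired observations are replicate-level expression values ordered by
(time_h, bio_rep) — five time points x three biological replicates = 15
pairs in the default design, enough rank resolution for the p < 0.001
coefficients the screen reports.  Correlation strength is banded on |rho|
at 0.3 / 0.5 / 0.7 (none / weak / moderate / strong), with non-significant
coefficients reported as "none" regardless of magnitude.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .errors import PairingError

STRENGTH_EDGES = (0.3, 0.5, 0.7)

#: Below this sample size the two-sided p-value is computed by exhaustive
#: permutation of one rank vector; at or above it by the t-approximation.
EXACT_P_MAX_N = 10


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Returns NaN when either vector is constant (undefined ranks variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def _exact_p(rx: np.ndarray, ry: np.ndarray, observed: float) -> float:
    """Two-sided exact permutation p over all orderings of one rank vector."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    permuted = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = permuted - permuted.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c @ rx_c) * (ry_c ** 2).sum(axis=1))
    rhos = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(observed) - 1e-12))


def spearman_test(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """(rho, two-sided p).  Exact permutation p for n < 10, t-approximation
    (t = rho sqrt((n−2)/(1−rho²)), df = n−2) otherwise."""
    rho = spearman_rho(x, y)
    n = len(x)
    if math.isnan(rho) or n < 3:
        return rho, float("nan")
    if abs(rho) == 1.0:
        p_t = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1 - rho * rho))
        p_t = 2 * sps.t.sf(abs(t), df=n - 2)
    if n < EXACT_P_MAX_N:
        return rho, _exact_p(sps.rankdata(x), sps.rankdata(y), rho)
    return rho, float(p_t)


def classify_correlation_strength(rho: float, p: float,
                                  alpha: float = 0.05,
                                  edges: Tuple[float, float, float] = STRENGTH_EDGES) -> str:
    """Band |rho| into none/weak/moderate/strong; non-significant -> none."""
    if math.isnan(rho):
        return "none"
    if not math.isnan(p) and p >= alpha:
        return "none"
    low, mid, high = edges
    magnitude = abs(rho)
    if magnitude >= high:
        return "strong"
    if magnitude >= mid:
        return "moderate"
    if magnitude >= low:
        return "weak"
    return "none"


@dataclass
class CorrelationResult:
    subject: str
    rho: float
    p: float
    category: str
    n: int


@dataclass
class CorrelationMatrix:
    treatment: str
    genes: List[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    mask: pd.DataFrame  # True where significant at alpha (off-diagonal)
    alpha: float = 0.05


def _paired_series(expr: pd.DataFrame, gene: str, treatment: str) -> pd.Series:
    sub = expr[(expr["gene"] == gene) & (expr["treatment"] == treatment)]
    return sub.set_index(["time_h", "bio_rep"])["rel_expr"].sort_index()


def cross_treatment_correlation(expr: pd.DataFrame, gene: str,
                                treat_a: str, treat_b: str,
                                alpha: float = 0.05) -> CorrelationResult:
    """Similarity of one gene's temporal profile between two treatments.

    Observations are paired by (time_h, bio_rep); an incomplete match
    raises :class:`PairingError` listing the unmatched cells.
    """
    a = _paired_series(expr, gene, treat_a)
    b = _paired_series(expr, gene, treat_b)
    unmatched = sorted(set(a.index).symmetric_difference(b.index))
    if unmatched:
        raise PairingError(unmatched)
    rho, p = spearman_test(a.to_numpy(), b.loc[a.index].to_numpy())
    return CorrelationResult(subject=gene, rho=rho, p=p,
                             category=classify_correlation_strength(rho, p, alpha),
                             n=len(a))


def within_treatment_matrix(expr: pd.DataFrame, treatment: str,
                            alpha: float = 0.05) -> CorrelationMatrix:
    """All pairwise gene correlations within one treatment.

    Constant gene vectors yield undefined rho, recorded as missing (NaN),
    never as zero.  The mask marks off-diagonal cells with p < alpha.
    """
    genes = sorted(expr.loc[expr["treatment"] == treatment, "gene"].unique())
    if len(genes) < 2:
        raise ValueError(f"need >= 2 genes for treatment {treatment!r}")
    series = {g: _paired_series(expr, g, treatment) for g in genes}
    index = series[genes[0]].index
    for g in genes[1:]:
        if not series[g].index.equals(index):
            raise PairingError(sorted(set(series[g].index)
                                      .symmetric_difference(index)))
    k = len(genes)
    rho = np.eye(k)
    p = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        r, pv = spearman_test(series[genes[i]].to_numpy(),
                              series[genes[j]].to_numpy())
        rho[i, j] = rho[j, i] = r
        p[i, j] = p[j, i] = pv
    rho_df = pd.DataFrame(rho, index=genes, columns=genes)
    p_df = pd.DataFrame(p, index=genes, columns=genes)
    mask = (p_df < alpha) & ~np.eye(k, dtype=bool)
    return CorrelationMatrix(treatment=treatment, genes=genes,
                             rho=rho_df, p=p_df, mask=mask, alpha=alpha)


def matrix_to_long(mat: CorrelationMatrix,
                   edges: Tuple[float, float, float] = STRENGTH_EDGES) -> pd.DataFrame:
    """Long-format upper-triangle listing: pair, rho, p, category, masked flag."""
    rows = []
    for i, j in itertools.combinations(range(len(mat.genes)), 2):
        gi, gj = mat.genes[i], mat.genes[j]
        rho, p = mat.rho.iloc[i, j], mat.p.iloc[i, j]
        rows.append({
            "treatment": mat.treatment, "gene_a": gi, "gene_b": gj,
            "rho": rho, "p": p,
            "category": classify_correlation_strength(rho, p, mat.alpha, edges),
            "significant": bool(mat.mask.iloc[i, j]),
        })
    return pd.DataFrame(rows)


@dataclass
class ClusterTree:
    """Agglomerative clustering of a correlation matrix on d = 1 − rho."""

    labels: List[str]          # lexicographically sorted leaf labels
    linkage_matrix: np.ndarray
    method: str

    @property
    def leaf_order(self) -> List[str]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.labels[i] for i in order]

    def cut(self, k: int) -> Dict[str, int]:
        """Leaf -> cluster id (1..k) from a maxclust cut."""
        assignment = hierarchy.fcluster(self.linkage_matrix, k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in assignment)))

    def to_newick(self) -> str:
        root = hierarchy.to_tree(self.linkage_matrix)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.left), walk(node.right)
            return (f"({left}:{node.dist - node.left.dist:.6g},"
                    f"{right}:{node.dist - node.right.dist:.6g})")

        return walk(root) + ";"


def cluster_correlation_matrix(mat: CorrelationMatrix,
                               linkage: str = "average",
                               distance: str = "signed") -> ClusterTree:
    """Cluster genes on correlation distance.

    ``distance="signed"`` uses d = 1 − rho (anti-correlated genes are far
    apart); ``"absolute"`` uses d = 1 − |rho|.  Missing coefficients are
    imputed as 0 with a warning.  Genes are sorted lexicographically before
    linkage, making the tree invariant to input order with deterministic
    tie-breaking.
    """
    if len(mat.genes) < 2:
        raise ValueError("clustering requires >= 2 genes")
    order = sorted(mat.genes)
    rho = mat.rho.loc[order, order].to_numpy(dtype=float)
    if np.isnan(rho).any():
        warnings.warn("missing correlations imputed as 0 for clustering",
                      stacklevel=2)
        rho = np.nan_to_num(rho, nan=0.0)
    dist = 1.0 - (np.abs(rho) if distance == "absolute" else rho)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = dist[np.triu_indices(len(order), k=1)]
    z = hierarchy.linkage(condensed, method=linkage)
    return ClusterTree(labels=order, linkage_matrix=z, method=linkage)


def module_accuracy(assignment: Dict[str, int],
                    truth: Dict[str, int]) -> float:
    """Fraction of genes assigned to the right module, maximised over the
    two possible label pairings (two-module case)."""
    genes = sorted(truth)
    a = np.array([assignment[g] for g in genes])
    t = np.array([truth[g] for g in genes])
    direct = np.mean((a == a.min()) == (t == t.min()))
    return float(max(direct, 1 - direct))
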