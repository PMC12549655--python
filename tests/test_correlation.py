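"""Spearman correlation, strength bands, matrices, and clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gmimmune.correlation import (classify_correlation_strength,
                                  cluster_correlation_matrix,
                                  cross_treatment_correlation, module_accuracy,
                                  spearman_rho, spearman_test,
                                  within_treatment_matrix)
from gmimmune.errors import PairingError
from gmimmune.reference import CROSS_TREATMENT_RHO

from conftest import spearman_oracle


def expr_frame(cells):
    rows = []
    for (gene, treatment, time_h), values in cells.items():
        for i, v in enumerate(values, 1):
            rows.append((gene, treatment, time_h, i, v))
    return pd.DataFrame(rows, columns=["gene", "treatment", "time_h",
                                       "bio_rep", "rel_expr"])


class TestSpearmanRho:
    @pytest.mark.parametrize("x,y,expected", [
        ((1, 2, 3, 4, 5), (2, 4, 6, 8, 10), 1.0),     # identical ranks
        ((1, 2, 3, 4, 5), (5, 4, 3, 2, 1), -1.0),     # reversed ranks
        ((1, 2, 3, 4, 5), (1, 3, 2, 5, 4), 0.8),      # d^2 sum 4 -> 1-24/120
    ])
    def test_known_values(self, x, y, expected):
        assert spearman_rho(np.array(x, float), np.array(y, float)) == \
            pytest.approx(expected)

    def test_matches_brute_force_oracle_small_n(self):
        """1,000 random vectors of n <= 6 against the counting-rank oracle."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(3, 7)
            x = rng.integers(0, 5, n).astype(float)  # integer draws force ties
            y = rng.normal(size=n)
            ours = spearman_rho(x, y)
            oracle = spearman_oracle(x, y)
            if np.isnan(oracle):
                assert np.isnan(ours)
            else:
                assert ours == pytest.approx(oracle, abs=1e-12)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.integers(0, 4, 15).astype(float)
            y = rng.integers(0, 4, 15).astype(float)
            expected = sps.spearmanr(x, y).statistic
            ours = spearman_rho(x, y)
            if np.isnan(expected):
                assert np.isnan(ours)
            else:
                assert ours == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_is_nan(self):
        assert np.isnan(spearman_rho(np.ones(5), np.arange(5.0)))

    def test_exact_p_matches_enumeration_logic(self):
        """For n >= 10 the t-approximation is used and agrees with scipy;
        for small n the exact permutation p bounds it sensibly."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        rho, p = spearman_test(x, y)
        sp = sps.spearmanr(x, y)
        assert rho == pytest.approx(sp.statistic)
        assert p == pytest.approx(sp.pvalue, rel=1e-6)

        x5, y5 = np.arange(5.0), np.array([1.0, 3, 2, 5, 4])
        _, p_exact = spearman_test(x5, y5)
        # enumeration over all 120 orderings: rho = 1 - S/20 with S the
        # squared rank-difference sum; |rho| >= 0.8 needs S <= 4 (8 ways)
        # or S >= 36 (8 ways by reversal symmetry) -> 16/120
        assert p_exact == pytest.approx(16 / 120)


class TestStrengthBands:
    @pytest.mark.parametrize("gene,rho,p_label,category", CROSS_TREATMENT_RHO)
    def test_reference_table_reproduced(self, gene, rho, p_label, category):
        p = 0.0005 if p_label == "<0.001" else 0.5
        assert classify_correlation_strength(rho, p) == category

    @pytest.mark.parametrize("rho,category", [
        (0.7, "strong"), (0.5, "moderate"), (0.3, "weak"), (0.299, "none"),
        (-0.75, "strong"),  # banding is on magnitude
    ])
    def test_edges(self, rho, category):
        assert classify_correlation_strength(rho, p=0.001) == category

    def test_nonsignificant_is_none_regardless_of_rho(self):
        assert classify_correlation_strength(0.95, p=0.2) == "none"


class TestCrossTreatment:
    def test_identical_profiles_rho_one(self):
        cells = {}
        for t in (3.0, 6.0, 12.0):
            values = [t, t + 0.5, t + 1.0]
            cells[("g", "LP", t)] = values
            cells[("g", "LK", t)] = values
        res = cross_treatment_correlation(expr_frame(cells), "g", "LP", "LK")
        assert res.rho == pytest.approx(1.0)
        assert res.n == 9

    def test_reversed_ranks_rho_minus_one(self):
        up = {("g", "LP", t): [t + i for i in range(3)] for t in (3.0, 6.0, 12.0)}
        down = {("g", "LK", t): [-(t + i) for i in range(3)] for t in (3.0, 6.0, 12.0)}
        res = cross_treatment_correlation(expr_frame(up | down), "g", "LP", "LK")
        assert res.rho == pytest.approx(-1.0)

    def test_unmatched_pairing_raises(self):
        cells = {("g", "LP", 3.0): [1.0, 2.0, 3.0],
                 ("g", "LK", 3.0): [1.0, 2.0]}
        with pytest.raises(PairingError) as err:
            cross_treatment_correlation(expr_frame(cells), "g", "LP", "LK")
        assert (3.0, 3) in err.value.unmatched


class TestWithinTreatmentMatrix:
    def three_gene_expr(self):
        rng = np.random.default_rng(3)
        cells = {}
        for gene, base in (("a", 1.0), ("b", 2.0), ("c", 0.5)):
            for t in (3.0, 6.0, 12.0):
                cells[(gene, "LP", t)] = list(base * t + rng.normal(0, 0.3, 3))
        return expr_frame(cells)

    def test_matrix_matches_pairwise_oracle(self):
        expr = self.three_gene_expr()
        mat = within_treatment_matrix(expr, "LP")
        for gi in mat.genes:
            for gj in mat.genes:
                x = expr[expr.gene == gi].sort_values(["time_h", "bio_rep"])["rel_expr"]
                y = expr[expr.gene == gj].sort_values(["time_h", "bio_rep"])["rel_expr"]
                expected = 1.0 if gi == gj else spearman_oracle(x, y)
                assert mat.rho.loc[gi, gj] == pytest.approx(expected, abs=1e-12)

    def test_symmetry_diagonal_and_mask(self):
        mat = within_treatment_matrix(self.three_gene_expr(), "LP")
        assert np.allclose(mat.rho, mat.rho.T)
        assert np.allclose(np.diag(mat.rho), 1.0)
        off = ~np.eye(len(mat.genes), dtype=bool)
        assert ((mat.mask.to_numpy() == (mat.p.to_numpy() < 0.05)) | ~off).all()
        assert not mat.mask.to_numpy()[~off].any()

    def test_constant_gene_recorded_missing(self):
        cells = {("flat", "LP", t): [1.0, 1.0, 1.0] for t in (3.0, 6.0, 12.0)}
        cells |= {("var", "LP", t): [t, t + 1, t + 2] for t in (3.0, 6.0, 12.0)}
        mat = within_treatment_matrix(expr_frame(cells), "LP")
        assert np.isnan(mat.rho.loc["flat", "var"])
        assert not mat.mask.loc["flat", "var"]


class TestClustering:
    def matrix_from_rho(self, genes, rho):
        rho_df = pd.DataFrame(rho, index=genes, columns=genes)
        p = pd.DataFrame(np.full_like(rho, 0.01), index=genes, columns=genes)
        from gmimmune.correlation import CorrelationMatrix
        return CorrelationMatrix("LP", list(genes), rho_df, p,
                                 (p < 0.05) & ~np.eye(len(genes), dtype=bool))

    def test_perfectly_correlated_merge_at_zero(self):
        mat = self.matrix_from_rho(["a", "b"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        tree = cluster_correlation_matrix(mat)
        assert tree.linkage_matrix[0, 2] == pytest.approx(0.0)

    def test_distance_ordering_forces_first_merge(self):
        """A,B at rho 0.9 and C at rho 0 to both: (A,B) merge first."""
        rho = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 1.0]])
        tree = cluster_correlation_matrix(self.matrix_from_rho(["A", "B", "C"], rho))
        first = sorted(tree.labels[int(i)] for i in tree.linkage_matrix[0, :2])
        assert first == ["A", "B"]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        genes = ["g1", "g2", "g3", "g4", "g5"]
        base = rng.uniform(-1, 1, (5, 5))
        rho = (base + base.T) / 2
        np.fill_diagonal(rho, 1.0)
        tree = cluster_correlation_matrix(self.matrix_from_rho(genes, rho))
        perm = [3, 0, 4, 1, 2]
        shuffled = self.matrix_from_rho([genes[i] for i in perm],
                                        rho[np.ix_(perm, perm)])
        tree2 = cluster_correlation_matrix(shuffled)
        assert tree.to_newick() == tree2.to_newick()
        assert tree.leaf_order == tree2.leaf_order

    def test_missing_imputed_with_warning(self):
        rho = np.array([[1.0, np.nan], [np.nan, 1.0]])
        with pytest.warns(UserWarning, match="imputed"):
            cluster_correlation_matrix(self.matrix_from_rho(["a", "b"], rho))

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            cluster_correlation_matrix(
                self.matrix_from_rho(["a"], np.array([[1.0]])))

    def test_module_accuracy_label_invariance(self):
        truth = {"a": 1, "b": 1, "c": 2, "d": 2}
        assert module_accuracy({"a": 2, "b": 2, "c": 1, "d": 1}, truth) == 1.0
        assert module_accuracy({"a": 1, "b": 2, "c": 1, "d": 2}, truth) == 0.5
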