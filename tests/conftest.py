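import numpy as np
import pytest

from gmimmune.design import EffectProfileSet, ExperimentDesign
from gmimmune.qpcr import compute_relative_expression
from gmimmune.simulate import generate_ct_table


@pytest.fixture
def small_design():
    """Two genes, one treatment vs control, three times, 3x2 replicates."""
    return ExperimentDesign(
        target_genes=("geneA", "geneB"), housekeeping_gene="hk",
        treatments=("LP",), control_label="PBS",
        times_h=(3.0, 6.0, 12.0), n_bio=3, n_tech=2)


@pytest.fixture
def default_design():
    return ExperimentDesign()


def noiseless_expression(design, fc_map):
    """Expression table from a noiseless simulation with injected FC."""
    profiles = EffectProfileSet(fc=fc_map, noise_sd=0.0)
    ct = generate_ct_table(design, profiles, seed=0)
    return compute_relative_expression(ct, housekeeping=design.housekeeping_gene,
                                       control_label=design.control_label)


def spearman_oracle(x, y):
    """Brute-force rank-formula Spearman: ranks by pairwise counting, rho by
    explicit Pearson sums.  Independent of the package implementation."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)

    def ranks(v):
        return [1 + sum(1 for u in v if u < w) + (sum(1 for u in v if u == w) - 1) / 2
                for w in v]

    rx, ry = ranks(x), ranks(y)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = sum((a - mx) ** 2 for a in rx)
    dy = sum((b - my) ** 2 for b in ry)
    if dx == 0 or dy == 0:
        return float("nan")
    return num / (dx * dy) ** 0.5
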