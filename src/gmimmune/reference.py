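"""Reference values from the probiotic immunomodulation screen.

Two kinds of reference data live here:

* the reported cross-treatment Spearman coefficients for the ten immune
  genes (LP vs LK temporal profiles), with their printed significance labels
  and strength categories — used to validate the strength-banding rules;

* default fold-change trajectories for the synthetic-data generator.  Cells
  the screen reports numerically carry those means; the remaining cells are
  smooth interpolations consistent with the described time courses (early
  AMP induction peaking at 6–12 h, transient NF-kB regulator activation,
  sustained oxidase response, biphasic receptor expression).
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .design import FCKey

#: (gene, rho, significance label, strength category).  "ns" marks p >= 0.05.
CROSS_TREATMENT_RHO: List[Tuple[str, float, str, str]] = [
    ("Dorsal", 0.9693, "<0.001", "strong"),
    ("Rel", 0.8888, "<0.001", "strong"),
    ("cad", 0.9240, "<0.001", "strong"),
    ("18w", 0.6917, "<0.001", "moderate"),
    ("spz4", 0.8115, "<0.001", "strong"),
    ("gallerimycin", 0.4633, "<0.001", "weak"),
    ("gloverin", 0.8976, "<0.001", "strong"),
    ("NADPH_oxidase_4", 0.2010, "ns", "none"),
    ("Hem", 0.8798, "<0.001", "strong"),
    ("IMPI", 0.0880, "ns", "none"),
]

# gene -> treatment -> fold change at (3, 6, 12, 18, 24) h.
_TRAJECTORIES: Dict[str, Dict[str, Tuple[float, ...]]] = {
    "Dorsal": {
        "LP": (0.532, 1.738, 3.775, 1.20, 0.80),
        "LK": (0.390, 1.127, 2.320, 0.90, 0.60),
    },
    "Rel": {
        "LP": (1.20, 2.00, 6.677, 0.297, 0.50),
        "LK": (0.90, 1.50, 4.512, 0.113, 0.40),
    },
    "cad": {
        "LP": (1.00, 2.305, 1.80, 0.638, 0.70),
        "LK": (0.867, 1.362, 1.30, 0.475, 0.60),
    },
    "18w": {
        "LP": (0.390, 0.048, 0.720, 0.40, 0.20),
        "LK": (0.145, 0.060, 0.127, 0.08, 0.06),
    },
    "spz4": {
        "LP": (0.90, 1.455, 0.370, 0.30, 0.30),
        "LK": (0.70, 0.990, 0.225, 0.20, 0.20),
    },
    "gallerimycin": {
        "LP": (2.00, 10.0, 39.515, 30.345, 13.087),
        "LK": (1.50, 8.00, 29.622, 20.00, 10.00),
    },
    "gloverin": {
        "LP": (3.00, 19.220, 8.00, 3.00, 1.50),
        "LK": (2.00, 12.885, 6.00, 2.50, 1.20),
    },
    "NADPH_oxidase_4": {
        "LP": (1.148, 2.522, 3.00, 3.700, 3.20),
        "LK": (2.350, 3.962, 3.365, 1.848, 2.60),
    },
    "Hem": {
        "LP": (1.50, 2.427, 0.570, 0.80, 0.90),
        "LK": (2.605, 2.20, 1.50, 1.10, 0.90),
    },
    "IMPI": {
        "LP": (0.883, 0.70, 0.773, 0.065, 0.07),
        "LK": (0.80, 1.722, 0.257, 1.013, 0.092),
    },
}

_TIMES = (3.0, 6.0, 12.0, 18.0, 24.0)


def default_trajectories() -> Dict[FCKey, float]:
    """Flatten the default trajectories to a (gene, treatment, time) map."""
    table: Dict[FCKey, float] = {}
    for gene, per_treatment in _TRAJECTORIES.items():
        for treatment, values in per_treatment.items():
            for t, fc in zip(_TIMES, values):
                table[(gene, treatment, t)] = fc
    return table
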