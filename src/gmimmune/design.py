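"""Experimental design and injected-effect containers for the screen.

The default design mirrors a qRT-PCR probiotic immunomodulation screen in
*Galleria mellonella*: ten immune-related target genes plus the *eEF1alpha1*
housekeeping gene, two live-bacteria treatments (LP = *Lactiplantibacillus
plantarum*, LK = *Lentilactobacillus kefiri*) against a PBS-injected control,
sampled at 3, 6, 12, 18 and 24 h with three biological replicates each
measured in technical duplicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Optional, Tuple

from .errors import MissingProfileCellError

#: Target genes of the default screen (Toll/IMD regulators, AMP effectors,
#: oxidative and tissue-remodelling markers).
DEFAULT_TARGET_GENES = (
    "Dorsal",
    "Rel",
    "cad",
    "18w",
    "spz4",
    "gallerimycin",
    "gloverin",
    "NADPH_oxidase_4",
    "Hem",
    "IMPI",
)

DEFAULT_HOUSEKEEPING = "eEF1alpha1"
DEFAULT_TREATMENTS = ("LP", "LK")
DEFAULT_CONTROL = "PBS"
DEFAULT_TIMES_H = (3.0, 6.0, 12.0, 18.0, 24.0)

FCKey = Tuple[str, str, float]  # (gene, treatment, time_h)


@dataclass(frozen=True)
class ExperimentDesign:
    """Dimensions of one qRT-PCR time-course experiment."""

    target_genes: Tuple[str, ...] = DEFAULT_TARGET_GENES
    housekeeping_gene: str = DEFAULT_HOUSEKEEPING
    treatments: Tuple[str, ...] = DEFAULT_TREATMENTS
    control_label: str = DEFAULT_CONTROL
    times_h: Tuple[float, ...] = DEFAULT_TIMES_H
    n_bio: int = 3
    n_tech: int = 2

    def __post_init__(self):
        object.__setattr__(self, "target_genes", tuple(self.target_genes))
        object.__setattr__(self, "treatments", tuple(self.treatments))
        object.__setattr__(self, "times_h", tuple(float(t) for t in self.times_h))
        if self.housekeeping_gene in self.target_genes:
            raise ValueError("housekeeping gene must not be a target gene")
        if len(set(self.target_genes)) != len(self.target_genes):
            raise ValueError("duplicate target genes")
        if any(b >= a for a, b in zip(self.times_h[1:], self.times_h)):
            raise ValueError("times_h must be strictly increasing")
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("n_bio and n_tech must be >= 1")
        if self.control_label in self.treatments:
            raise ValueError("control_label must be distinct from treatments")

    @property
    def all_groups(self) -> Tuple[str, ...]:
        """Treatments plus the control label."""
        return self.treatments + (self.control_label,)

    def cells(self) -> Iterator[FCKey]:
        """All (gene, non-control treatment, time) cells a profile must cover."""
        for gene in self.target_genes:
            for treatment in self.treatments:
                for t in self.times_h:
                    yield gene, treatment, t


@dataclass
class EffectProfileSet:
    """Injected ground truth for the Ct generator.

    ``fc`` maps (gene, treatment, time_h) to the target fold change relative
    to the time-matched control; the control group is implicitly at fold
    change 1 (entries for the control label, if present, must equal 1).
    Noise is placed on the Ct scale: biological replicates draw an additive
    Gaussian offset with sd ``noise_sd`` (shared by both technical wells of
    that sample), technical wells an independent offset with sd
    ``tech_noise_sd`` (default half the biological sd).
    """

    fc: Dict[FCKey, float] = field(default_factory=dict)
    baseline_ct: Dict[str, float] = field(default_factory=dict)
    default_baseline_ct: float = 24.0
    hk_ct: float = 18.0
    noise_sd: float = 0.25
    tech_noise_sd: Optional[float] = None

    def __post_init__(self):
        self.fc = {(g, tr, float(t)): float(v) for (g, tr, t), v in self.fc.items()}
        for key, value in self.fc.items():
            if not value > 0:
                raise ValueError(f"fold change must be positive, got {value} at {key}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.tech_noise_sd is None:
            self.tech_noise_sd = 0.5 * self.noise_sd
        if self.tech_noise_sd < 0:
            raise ValueError("tech_noise_sd must be >= 0")

    @classmethod
    def flat(cls, design: ExperimentDesign, fc: float = 1.0, **kwargs) -> "EffectProfileSet":
        """A profile with the same fold change in every treatment cell."""
        table = {cell: fc for cell in design.cells()}
        return cls(fc=table, **kwargs)

    def fold_change(self, gene: str, treatment: str, time_h: float,
                    control_label: str) -> float:
        if treatment == control_label:
            value = self.fc.get((gene, treatment, float(time_h)), 1.0)
            if value != 1.0:
                raise ValueError("control fold change must be 1")
            return 1.0
        try:
            return self.fc[(gene, treatment, float(time_h))]
        except KeyError:
            raise MissingProfileCellError(gene, treatment, time_h) from None

    def baseline(self, gene: str) -> float:
        return self.baseline_ct.get(gene, self.default_baseline_ct)

    def require_coverage(self, design: ExperimentDesign) -> None:
        for cell in design.cells():
            if cell not in self.fc:
                raise MissingProfileCellError(*cell)
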