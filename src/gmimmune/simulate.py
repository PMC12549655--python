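"""Synthetic-data generators for the three pipeline inputs.

All three generators are deterministic given a seed.  Ct noise is additive
Gaussian on the cycle-threshold scale (qPCR error is approximately
log-scale, and the ddCt algebra is linear in Ct), with a biological
component shared by the technical wells of a sample and a smaller
independent technical component per well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import EffectProfileSet, ExperimentDesign
from .errors import GmimmuneError, InvalidCategoryError
from .reference import default_trajectories

#: Rubric levels for the four health categories (activity, cocoon
#: formation, melanisation extent, survival).  Scores sum to at most 10.
CATEGORY_LEVELS: Dict[str, Tuple[float, ...]] = {
    "activity": (0, 1, 2, 3),
    "cocoon": (0, 0.5, 1),
    "melanisation": (0, 1, 2, 3, 4),
    "survival": (0, 2),
}

CT_COLUMNS = ["gene", "treatment", "time_h", "bio_rep", "tech_rep", "ct"]
HEALTH_COLUMNS = ["larva_id", "group", "time_h", "observer_id",
                  "activity", "cocoon", "melanisation", "survival"]


def default_profiles(**kwargs) -> EffectProfileSet:
    """Effect profiles carrying the screen's default fold-change trajectories."""
    return EffectProfileSet(fc=default_trajectories(), **kwargs)


def generate_ct_table(design: ExperimentDesign, profiles: EffectProfileSet,
                      seed: int) -> pd.DataFrame:
    """Simulate a long-format raw Ct table for the whole design.

    Target Ct = baseline_ct[gene] - log2(fc) + biological + technical noise;
    housekeeping Ct = hk_ct + biological + technical noise.  One row per
    gene x group x time x biological x technical replicate, housekeeping
    included for every sample.
    """
    profiles.require_coverage(design)
    rng = np.random.default_rng(seed)
    genes = list(design.target_genes) + [design.housekeeping_gene]
    rows = []
    for treatment in design.all_groups:
        for time_h in design.times_h:
            for bio in range(1, design.n_bio + 1):
                for gene in genes:
                    if gene == design.housekeeping_gene:
                        base = profiles.hk_ct
                    else:
                        fc = profiles.fold_change(gene, treatment, time_h,
                                                  design.control_label)
                        base = profiles.baseline(gene) - np.log2(fc)
                    bio_noise = rng.normal(0.0, profiles.noise_sd) if profiles.noise_sd else 0.0
                    for tech in range(1, design.n_tech + 1):
                        tech_noise = (rng.normal(0.0, profiles.tech_noise_sd)
                                      if profiles.tech_noise_sd else 0.0)
                        rows.append((gene, treatment, time_h, bio, tech,
                                     base + bio_noise + tech_noise))
    return pd.DataFrame(rows, columns=CT_COLUMNS)


# ---------------------------------------------------------------------------
# Health observations
# ---------------------------------------------------------------------------

HealthProfile = Mapping[str, Mapping[float, float]]


def healthy_profile() -> Dict[str, Dict[float, float]]:
    """Every larva fully active, cocooned, unmelanised, alive (score 10)."""
    return {"activity": {3: 1.0}, "cocoon": {1: 1.0},
            "melanisation": {4: 1.0}, "survival": {2: 1.0}}


def dead_profile() -> Dict[str, Dict[float, float]]:
    """Rubric minimum: no activity, no cocoon, full melanisation, dead."""
    return {"activity": {0: 1.0}, "cocoon": {0: 1.0},
            "melanisation": {0: 1.0}, "survival": {0: 1.0}}


def _validate_profile(profile: HealthProfile) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    parsed = {}
    for category, levels in CATEGORY_LEVELS.items():
        dist = profile.get(category)
        if dist is None:
            raise InvalidCategoryError(category, None)
        vals, probs = [], []
        for level, p in dist.items():
            if float(level) not in [float(x) for x in levels]:
                raise InvalidCategoryError(category, level)
            vals.append(float(level))
            probs.append(float(p))
        probs = np.asarray(probs)
        if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise GmimmuneError(f"probabilities for {category!r} must be a distribution")
        parsed[category] = (np.asarray(vals), probs / probs.sum())
    return parsed


def generate_health_observations(groups: Sequence[str],
                                 profiles: Mapping[str, HealthProfile],
                                 n_larvae: int = 10,
                                 times_h: Sequence[float] = (24, 48, 72),
                                 n_observers: int = 2,
                                 seed: int = 0) -> pd.DataFrame:
    """Simulate scored health observations, one row per larva x time x observer.

    Survival is objective and shared by observers; it is made monotone per
    larva (a dead larva stays dead).  Subjective categories are drawn
    independently per observer from the group's distributions.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in groups:
        parsed = _validate_profile(profiles[group])
        for larva in range(1, n_larvae + 1):
            larva_id = f"{group}-{larva:02d}"
            surv_vals, surv_p = parsed["survival"]
            survival = rng.choice(surv_vals, size=len(times_h), p=surv_p)
            survival = np.minimum.accumulate(survival)  # no resurrection
            for ti, time_h in enumerate(times_h):
                for obs in range(1, n_observers + 1):
                    record = {"larva_id": larva_id, "group": group,
                              "time_h": float(time_h), "observer_id": obs,
                              "survival": survival[ti]}
                    for category in ("activity", "cocoon", "melanisation"):
                        vals, p = parsed[category]
                        record[category] = rng.choice(vals, p=p)
                    rows.append(record)
    return pd.DataFrame(rows, columns=HEALTH_COLUMNS)


# ---------------------------------------------------------------------------
# Alignment pairs
# ---------------------------------------------------------------------------

@dataclass
class _ColumnSampler:
    rng: np.random.Generator
    classes: Mapping[str, str]

    def __post_init__(self):
        by_class: Dict[str, list] = {}
        for residue, cls in self.classes.items():
            by_class.setdefault(cls, []).append(residue)
        self.by_class = {c: sorted(rs) for c, rs in by_class.items()}
        self.residues = sorted(self.classes)
        self.multi_classes = sorted(c for c, rs in self.by_class.items() if len(rs) >= 2)

    def identical(self):
        r = self.rng.choice(self.residues)
        return r, r

    def conservative(self):
        cls = self.rng.choice(self.multi_classes)
        q, s = self.rng.choice(self.by_class[cls], size=2, replace=False)
        return q, s

    def nonconservative(self):
        cq, cs = self.rng.choice(sorted(self.by_class), size=2, replace=False)
        return self.rng.choice(self.by_class[cq]), self.rng.choice(self.by_class[cs])

    def single_gap(self):
        r = self.rng.choice(self.residues)
        if self.rng.random() < 0.5:
            return "-", r
        return r, "-"


def generate_alignment_pair(length: int, p_identity: float,
                            p_conservative: float = 0.0, p_gap: float = 0.0,
                            seed: int = 0, p_double_gap: float = 0.0,
                            query_id: str = "query",
                            subject_id: str = "subject"):
    """Simulate a gapped pairwise protein alignment with known column mix.

    Column categories (identical / conservative / single-gap / double-gap /
    non-conservative remainder) are drawn i.i.d. at the stated rates;
    residues are drawn uniformly within the constraint of each category
    using the default physicochemical class map.
    """
    from .consensus import DEFAULT_RESIDUE_CLASSES, AlignedPair

    probs = np.array([p_identity, p_conservative, p_gap, p_double_gap], dtype=float)
    if probs.min() < 0 or probs.sum() > 1 + 1e-12:
        raise ValueError("category probabilities must be >= 0 and sum to <= 1")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    sampler = _ColumnSampler(rng, DEFAULT_RESIDUE_CLASSES)
    p_full = np.append(probs, max(0.0, 1.0 - probs.sum()))
    categories = rng.choice(5, size=length, p=p_full / p_full.sum())
    q_chars, s_chars = [], []
    for cat in categories:
        if cat == 0:
            q, s = sampler.identical()
        elif cat == 1:
            q, s = sampler.conservative()
        elif cat == 2:
            q, s = sampler.single_gap()
        elif cat == 3:
            q, s = "-", "-"
        else:
            q, s = sampler.nonconservative()
        q_chars.append(q)
        s_chars.append(s)
    return AlignedPair(query_id=query_id, subject_id=subject_id,
                       query_seq="".join(q_chars), subject_seq="".join(s_chars))
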