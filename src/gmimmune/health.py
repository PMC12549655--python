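"""Larval health-index scoring, observer aggregation, and survival summaries.

The health index sums four observable categories — activity (0–3), cocoon
formation (0/0.5/1), melanisation (0–4, higher = less melanised) and
survival (0 dead / 2 alive) — giving 10 for a fully healthy larva and 0 at
the rubric minimum.  Scoring is performed independently by blinded
observers; aggregation reports the arithmetic mean across observers with a
per-cell inter-observer concordance measure.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Mapping

import pandas as pd

from .errors import InvalidCategoryError
from .simulate import CATEGORY_LEVELS

#: Observer disagreements larger than this (in score points, per larva) are
#: flagged in the aggregate output.
DISCORDANCE_FLAG = 2.0

MAX_SCORE = sum(max(levels) for levels in CATEGORY_LEVELS.values())


def score_observation(obs: Mapping[str, float]) -> float:
    """Score one observation: the sum of its four category levels.

    Raises :class:`InvalidCategoryError` naming the offending field for any
    value outside the rubric.  Dead larvae keep their observed category
    values — the rubric does not couple categories.
    """
    total = 0.0
    for category, levels in CATEGORY_LEVELS.items():
        try:
            value = float(obs[category])
        except (KeyError, TypeError, ValueError):
            raise InvalidCategoryError(category, obs.get(category) if hasattr(obs, "get") else None)
        if value not in [float(x) for x in levels]:
            raise InvalidCategoryError(category, value)
        total += value
    return total


def score_table(observations: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the observation table with a ``score`` column."""
    out = observations.copy()
    out["score"] = [score_observation(row) for row in out.to_dict("records")]
    return out


def aggregate_health(observations: pd.DataFrame) -> pd.DataFrame:
    """Per group x time: mean score, SD, and inter-observer concordance.

    Concordance is the mean absolute difference between observers' scores of
    the same larva (mean over observer pairs when there are more than two);
    ``n_discordant`` counts larvae whose observers disagree by more than
    :data:`DISCORDANCE_FLAG` points.
    """
    scored = score_table(observations)
    records = []
    for (group, time_h), cell in scored.groupby(["group", "time_h"], sort=True):
        per_larva = cell.pivot_table(index="larva_id", columns="observer_id",
                                     values="score")
        diffs = []
        n_discordant = 0
        for _, row in per_larva.iterrows():
            vals = row.dropna().to_list()
            if len(vals) < 2:
                continue
            pair_diffs = [abs(a - b) for a, b in itertools.combinations(vals, 2)]
            larva_diff = sum(pair_diffs) / len(pair_diffs)
            diffs.append(larva_diff)
            if larva_diff > DISCORDANCE_FLAG:
                n_discordant += 1
        records.append({
            "group": group,
            "time_h": time_h,
            "n_obs": len(cell),
            "mean_score": cell["score"].mean(),
            "sd_score": cell["score"].std(ddof=1) if len(cell) > 1 else 0.0,
            "observer_mad": sum(diffs) / len(diffs) if diffs else float("nan"),
            "n_discordant": n_discordant,
        })
    return pd.DataFrame(records)


def survival_fraction(observations: pd.DataFrame) -> pd.DataFrame:
    """Per group x time proportion of larvae alive (survival level 2).

    Survival is objective, so observers should agree; on disagreement a
    warning is raised and the larva is counted as dead.  A larva recorded
    dead and later alive triggers a resurrection warning but is reported as
    observed.
    """
    per_larva = (observations.groupby(["group", "time_h", "larva_id"])["survival"]
                 .agg(["min", "max"]).reset_index())
    disagree = per_larva["min"] != per_larva["max"]
    if disagree.any():
        warnings.warn(f"observers disagree on survival for "
                      f"{sorted(per_larva.loc[disagree, 'larva_id'])}; "
                      "treating as dead", stacklevel=2)
    per_larva["alive"] = per_larva["min"] == 2

    for larva_id, track in per_larva.sort_values("time_h").groupby("larva_id"):
        alive = track["alive"].to_numpy()
        if any(~alive[:-1] & alive[1:]):
            warnings.warn(f"larva {larva_id!r} recorded dead then alive",
                          stacklevel=2)

    out = (per_larva.groupby(["group", "time_h"])["alive"]
           .mean().rename("survival_fraction").reset_index())
    return out
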