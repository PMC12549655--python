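"""Relative expression by the 2^-ddCt method with fold-change banding.

For every biological sample, dCt = Ct_target − Ct_housekeeping; ddCt is
taken against the mean control-group dCt of the same gene at the same time
point, and relative expression is 2^−ddCt.  Expression is computed per
biological replicate and summarised afterwards (mean, sample SD, median),
with the mean classified into the screen's fold-change bands.
"""

from __future__ import annotations

import logging
import warnings
from typing import Tuple

import numpy as np
import pandas as pd

from .errors import MissingControlError, MissingHousekeepingError

logger = logging.getLogger(__name__)

#: Fold-change band labels, ordered from strongest repression to strongest
#: induction.  Edges: <0.5 strong down, [0.5, 1) mild down, exactly 1 no
#: change, (1, 2] mild up, >2 strong up.
BANDS = ("strong_down", "mild_down", "no_change", "mild_up", "strong_up")

SAMPLE_KEYS = ["treatment", "time_h", "bio_rep"]


def collapse_technical_replicates(table: pd.DataFrame,
                                  warn_threshold: float = 1.0) -> pd.DataFrame:
    """Average technical wells into one Ct per biological sample.

    Technical duplicates spreading more than ``warn_threshold`` cycles
    (default one cycle) trigger a warning naming the sample — wide spread
    usually indicates a pipetting or amplification problem.
    """
    keys = ["gene"] + SAMPLE_KEYS
    spread = table.groupby(keys)["ct"].agg(lambda x: x.max() - x.min())
    wide = spread[spread > warn_threshold]
    if len(wide):
        warnings.warn(
            f"{len(wide)} samples with technical-replicate spread > "
            f"{warn_threshold} cycles: {list(wide.index[:5])}", stacklevel=2)
    out = table.groupby(keys, sort=False, as_index=False)["ct"].mean()
    return out


def compute_relative_expression(table: pd.DataFrame,
                                housekeeping: str = "eEF1alpha1",
                                control_label: str = "PBS") -> pd.DataFrame:
    """Per-biological-replicate 2^-ddCt, normalised to housekeeping and the
    time-matched control mean.

    Accepts raw tables (technical replicates are collapsed first when a
    ``tech_rep`` column is present).  Control-group rows are retained in the
    output — their geometric mean is 1 by construction.
    """
    if "tech_rep" in table.columns:
        table = collapse_technical_replicates(table)

    hk = table[table["gene"] == housekeeping].set_index(SAMPLE_KEYS)["ct"]
    targets = table[table["gene"] != housekeeping].copy()
    if targets.empty:
        raise ValueError("no target-gene rows in Ct table")

    sample_index = pd.MultiIndex.from_frame(targets[SAMPLE_KEYS])
    missing_hk = ~sample_index.isin(hk.index)
    if missing_hk.any():
        tr, t, b = sample_index[missing_hk.argmax()]
        raise MissingHousekeepingError(tr, t, b)
    targets["dct"] = targets["ct"].to_numpy() - hk.loc[sample_index].to_numpy()

    control = targets[targets["treatment"] == control_label]
    control_mean = control.groupby(["gene", "time_h"])["dct"].mean()
    cell_index = pd.MultiIndex.from_frame(targets[["gene", "time_h"]])
    missing_ctl = ~cell_index.isin(control_mean.index)
    if missing_ctl.any():
        gene, t = cell_index[missing_ctl.argmax()]
        raise MissingControlError(gene, t)

    targets["ddct"] = targets["dct"].to_numpy() - control_mean.loc[cell_index].to_numpy()
    targets["rel_expr"] = 2.0 ** (-targets["ddct"])
    return targets[["gene", "treatment", "time_h", "bio_rep", "rel_expr"]].reset_index(drop=True)


def classify_fold_change(fc: float,
                         edges: Tuple[float, float] = (0.5, 2.0)) -> str:
    """Band a fold change: strong/mild down, no change (exactly 1), mild/strong up."""
    low, high = edges
    if not np.isfinite(fc) or fc <= 0:
        raise ValueError(f"fold change must be finite and positive, got {fc!r}")
    if fc > high:
        return "strong_up"
    if fc > 1:
        return "mild_up"
    if fc == 1:
        return "no_change"
    if fc >= low:
        return "mild_down"
    return "strong_down"


def summarize_expression(expr: pd.DataFrame,
                         edges: Tuple[float, float] = (0.5, 2.0)) -> pd.DataFrame:
    """Per gene x treatment x time: mean, sample SD (n−1), median, band.

    Cells with a single replicate get a missing SD; empty cells are simply
    absent and logged.
    """
    records = []
    for (gene, treatment, time_h), cell in expr.groupby(
            ["gene", "treatment", "time_h"], sort=True):
        values = cell["rel_expr"].dropna()
        if values.empty:
            logger.info("empty expression cell %s/%s/%s omitted",
                        gene, treatment, time_h)
            continue
        mean = values.mean()
        records.append({
            "gene": gene, "treatment": treatment, "time_h": time_h,
            "n": len(values),
            "mean": mean,
            "sd": values.std(ddof=1) if len(values) > 1 else np.nan,
            "median": values.median(),
            "band": classify_fold_change(mean, edges),
        })
    return pd.DataFrame(records)
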