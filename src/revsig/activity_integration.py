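"""Compound-activity aggregation, activity classification, and the
correlation between reversal potency (sRGES) and measured activity.

Activity arrives as per-record IC50 (uM) or AUC values across cell lines;
records are median-aggregated per compound and IC50 medians are classified
against the conventional 10 uM screening threshold (active strictly below,
inactive at or above).
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ACTIVITY_THRESHOLD_UM = 10.0


class PotencyCorrelation(NamedTuple):
    rho: float
    p_value: float
    n: int


def aggregate_activity(records: pd.DataFrame) -> pd.Series:
    """Median activity per compound across cell lines and replicates.

    ``records`` needs columns compound / measure / value with a single
    measure type per call (IC50 and AUC are never mixed in one
    aggregation).  Even record counts use the mean-of-middle-pair median.
    """
    required = {"compound", "measure", "value"}
    if not required <= set(records.columns):
        raise ValueError(f"activity records need columns {sorted(required)}")
    if len(records) == 0:
        raise ValueError("no activity records")
    measures = records["measure"].unique()
    if len(measures) > 1:
        raise ValueError(f"mixed measures in one aggregation: "
                         f"{sorted(measures)}")
    if measures[0] == "IC50" and (records["value"] <= 0).any():
        raise ValueError("IC50 values must be positive")
    return records.groupby("compound", sort=True)["value"].median()


def classify_activity(median_ic50: float,
                      threshold: float = ACTIVITY_THRESHOLD_UM) -> str:
    """'active' iff the median IC50 is strictly below the threshold."""
    if not np.isfinite(median_ic50) or median_ic50 <= 0:
        raise ValueError(f"median IC50 must be positive, got {median_ic50}")
    return "active" if median_ic50 < threshold else "inactive"


def classify_activity_table(
    medians: pd.Series, threshold: float = ACTIVITY_THRESHOLD_UM,
) -> pd.DataFrame:
    """Per-compound table of median IC50 and active/inactive label."""
    labels = [classify_activity(v, threshold) for v in medians]
    return pd.DataFrame({"median_value": medians, "label": labels},
                        index=medians.index)


def evaluate_reversal_potency(srges: pd.Series,
                              activity: pd.Series) -> PotencyCorrelation:
    """Spearman correlation of sRGES with median activity per compound.

    A positive rho means stronger reversers (lower sRGES) are also the more
    potent compounds (lower IC50 / AUC).
    """
    shared = srges.index.intersection(activity.index)
    if len(shared) < 3:
        raise ValueError("need >=3 compounds shared between sRGES and "
                         "activity tables")
    x = srges.loc[shared].to_numpy(dtype=float)
    y = activity.loc[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    res = stats.spearmanr(x, y)
    return PotencyCorrelation(rho=float(res.statistic),
                              p_value=float(res.pvalue), n=len(shared))


def expression_similarity(tumor_matrix: pd.DataFrame,
                          cellline_matrix: pd.DataFrame,
                          top_k: int = 5000) -> pd.DataFrame:
    """Spearman similarity of tumor samples to cell lines.

    Genes are intersected, ranked by interquartile range computed across
    the cell lines, and the top ``top_k`` retained (clipped, with a
    warning, when fewer genes are available) before per-pair Spearman
    correlation.  Rows are tumor samples, columns cell lines.
    """
    shared = tumor_matrix.index.intersection(cellline_matrix.index)
    if len(shared) == 0:
        raise ValueError("no genes shared between tumor and cell-line "
                         "matrices")
    if top_k > len(shared):
        logger.warning("expression_similarity: top_k=%d exceeds %d shared "
                       "genes; clipping", top_k, len(shared))
        top_k = len(shared)
    cl = cellline_matrix.loc[shared]
    q75, q25 = np.percentile(cl.to_numpy(), [75, 25], axis=1)
    iqr = pd.Series(q75 - q25, index=shared)
    top = iqr.sort_values(ascending=False, kind="mergesort").index[:top_k]

    t = tumor_matrix.loc[top].to_numpy(dtype=float)
    c = cl.loc[top].to_numpy(dtype=float)
    tr = stats.rankdata(t, axis=0)
    cr = stats.rankdata(c, axis=0)
    tr = (tr - tr.mean(axis=0)) / tr.std(axis=0)
    cr = (cr - cr.mean(axis=0)) / cr.std(axis=0)
    rho = tr.T @ cr / top_k
    return pd.DataFrame(rho, index=tumor_matrix.columns,
                        columns=cellline_matrix.columns)
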