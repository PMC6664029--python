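"""Reversal-gene discovery with leave-one-compound-out validation.

For each compound, its gold profiles are collapsed to a single ranking
(per-gene median differential value, then rank with 1 = most
up-regulated) and each signature gene gets a normalized position
rank/n in (0, 1].  A disease-up gene is "reversed" when active compounds
place it lower in their rankings (larger positions) than inactive
compounds do; a disease-down gene when active compounds place it higher.
The shift is tested with a one-sided rank-sum test, BH-adjusted across
genes within each leave-one-compound-out trial, and a gene is called only
if it clears the threshold in every trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_Q_THRESHOLD = 0.25


@dataclass
class RankPositionTable:
    """Normalized rank positions of signature genes across compounds.

    ``positions``: genes x compounds, entries in (0, 1];
    ``directions``: gene -> 'up' | 'down' (disease direction);
    ``n_genes``: size of the ranked universe.
    """

    positions: pd.DataFrame
    directions: pd.Series
    n_genes: int

    def __post_init__(self) -> None:
        v = self.positions.to_numpy()
        if ((v <= 0) | (v > 1)).any():
            raise ValueError("normalized positions must lie in (0, 1]")
        if not set(self.positions.index) <= set(self.directions.index):
            raise ValueError("every gene in the table needs a direction")


def normalized_rank_positions(profiles, signature) -> RankPositionTable:
    """Build the per-(gene, compound) normalized position table.

    Per compound, gold profiles are reduced to one vector by the per-gene
    median differential value, ranked descending (ties broken by gene id
    ascending), and signature-gene positions are rank/n.
    """
    gold = [p for p in profiles if p.is_gold]
    if not gold:
        raise ValueError("no gold profiles")
    genes = gold[0].values.sort_index().index
    n = len(genes)
    sig_genes = list(signature.up_genes) + list(signature.down_genes)
    missing = set(sig_genes) - set(genes)
    if missing:
        raise ValueError(f"signature genes missing from the landmark "
                         f"universe: {sorted(missing)[:5]}")

    by_compound: dict[str, list[np.ndarray]] = {}
    for p in gold:
        p.validate()
        v = p.values
        if not v.index.equals(genes):
            v = v.sort_index()
        by_compound.setdefault(p.compound, []).append(v.to_numpy())

    compounds = sorted(by_compound)
    medians = np.vstack([np.median(np.vstack(by_compound[c]), axis=0)
                         for c in compounds])
    order = np.argsort(-medians, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(len(compounds))[:, None]
    ranks[rows, order] = np.arange(1, n + 1)

    gene_pos = {g: i for i, g in enumerate(genes)}
    idx = [gene_pos[g] for g in sig_genes]
    positions = pd.DataFrame(ranks[:, idx].T / n, index=sig_genes,
                             columns=compounds)
    directions = pd.Series(
        ["up"] * len(signature.up_genes) + ["down"] * len(signature.down_genes),
        index=sig_genes)
    return RankPositionTable(positions=positions, directions=directions,
                             n_genes=n)


def test_reversal(positions_active, positions_inactive,
                  direction: str) -> float:
    """One-sided rank-sum p-value for a reversal-direction shift.

    Up-genes are reversed when active compounds rank them lower (larger
    normalized positions); down-genes when active compounds rank them
    higher (smaller positions).  Exact for small untied samples, normal
    approximation otherwise.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got "
                         f"{direction!r}")
    a = np.asarray(positions_active, dtype=float)
    b = np.asarray(positions_inactive, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >=2 compounds per activity group")
    alternative = "greater" if direction == "up" else "less"
    return float(stats.mannwhitneyu(a, b, alternative=alternative,
                                    method="auto").pvalue)


def _ranksum_p_vectorized(positions: np.ndarray, active: np.ndarray,
                          up: np.ndarray) -> np.ndarray:
    """Row-wise one-sided rank-sum p (normal approximation).

    ``positions``: genes x compounds; ``active``: boolean column mask;
    ``up``: boolean per-gene mask selecting the 'greater' alternative.
    Tie-corrected with continuity correction, matching scipy's asymptotic
    Mann-Whitney implementation.
    """
    n1 = int(active.sum())
    n2 = positions.shape[1] - n1
    ranks = stats.rankdata(positions, axis=1)
    u1 = ranks[:, active].sum(axis=1) - n1 * (n1 + 1) / 2.0
    mean = n1 * n2 / 2.0
    n = n1 + n2
    # tie correction per row
    tie_term = np.zeros(positions.shape[0])
    for i in range(positions.shape[0]):
        _, counts = np.unique(positions[i], return_counts=True)
        tie_term[i] = (counts ** 3 - counts).sum()
    sd = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))))
    sd = np.where(sd == 0, np.nan, sd)
    z_greater = (u1 - mean - 0.5) / sd
    z_less = (u1 - mean + 0.5) / sd
    p = np.where(up, stats.norm.sf(z_greater), stats.norm.cdf(z_less))
    return np.where(np.isnan(p), 1.0, p)


def loco_reversal_genes(
    table: RankPositionTable,
    classes: pd.Series,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-compound-out screen for reversal genes.

    For every held-out compound, per-gene one-sided rank-sum p-values are
    recomputed on the remaining compounds and BH-adjusted across genes
    within the trial.  A gene is reversed iff its adjusted p stays below
    ``q_threshold`` in every trial (and the observed shift points in the
    reversal direction in every trial).  Returns (results, per-trial q
    matrix); results columns: direction, worst_q, reversed.
    """
    from .meta_signature import bh_adjust

    compounds = list(table.positions.columns)
    labels = classes.loc[compounds]
    if set(labels.unique()) - {"active", "inactive"}:
        raise ValueError("activity labels must be 'active'/'inactive'")
    n_active = int((labels == "active").sum())
    n_inactive = int((labels == "inactive").sum())
    if n_active < 3 or n_inactive < 3:
        raise ValueError(f"need >=3 compounds per class, got {n_active} "
                         f"active / {n_inactive} inactive")

    pos = table.positions.to_numpy()
    active_mask = (labels == "active").to_numpy()
    up_mask = (table.directions.loc[table.positions.index] == "up"
               ).to_numpy()
    genes = table.positions.index

    trial_q = np.empty((len(genes), len(compounds)))
    shift_ok = np.ones(len(genes), dtype=bool)
    for k in range(len(compounds)):
        keep = np.ones(len(compounds), dtype=bool)
        keep[k] = False
        sub = pos[:, keep]
        sub_active = active_mask[keep]
        p = _ranksum_p_vectorized(sub, sub_active, up_mask)
        trial_q[:, k] = bh_adjust(p)
        diff = (sub[:, sub_active].mean(axis=1)
                - sub[:, ~sub_active].mean(axis=1))
        shift_ok &= np.where(up_mask, diff > 0, diff < 0)

    worst_q = trial_q.max(axis=1)
    reversed_flag = (trial_q < q_threshold).all(axis=1) & shift_ok
    results = pd.DataFrame(
        {"direction": table.directions.loc[genes].to_numpy(),
         "worst_q": worst_q, "reversed": reversed_flag}, index=genes)
    q_frame = pd.DataFrame(trial_q, index=genes,
                           columns=[f"minus_{c}" for c in compounds])
    return results, q_frame


def heatmap_order(table: RankPositionTable,
                  median_ic50: pd.Series) -> pd.DataFrame:
    """Position table with compound columns ordered by median IC50
    ascending (most potent first), for heatmap rendering."""
    order = (median_ic50.loc[median_ic50.index.intersection(
        table.positions.columns)].sort_values(kind="mergesort").index)
    return table.positions[list(order)]
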