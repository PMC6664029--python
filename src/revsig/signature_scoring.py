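"""Reverse gene expression scoring (RGES / sRGES).

A drug profile is ranked by differential expression (rank 1 = most
up-regulated).  For the disease up- and down-gene sets the Connectivity-Map
style KS enrichment statistic is computed from the sets' positions in that
ranking; RGES = ES_up - ES_down when the two enrichments have opposite
signs and 0 otherwise, so a strongly negative RGES means the compound
pushes disease-up genes to the bottom and disease-down genes to the top of
its ranking.  Per-compound summarization (sRGES) averages profile scores
after an additive adjustment of non-reference conditions to the 10 uM /
24 h reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REFERENCE_DOSE_UM = 10.0
REFERENCE_DURATION_H = 24.0


@dataclass
class DrugProfile:
    """One compound treatment's landmark differential-expression vector."""

    profile_id: str
    compound: str
    cell_line: str
    dose_um: float
    duration_h: float
    is_gold: bool
    values: pd.Series

    def validate(self) -> None:
        if self.dose_um <= 0 or self.duration_h <= 0:
            raise ValueError(f"profile {self.profile_id!r}: dose and "
                             "duration must be positive")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError(
                f"profile {self.profile_id!r} has non-finite values")


@dataclass
class RankedProfile:
    """A full ordering of the landmark universe, most up-regulated first."""

    genes: np.ndarray              # ordered gene ids, index 0 = rank 1
    position: pd.Series            # gene id -> 1-based rank

    @property
    def n(self) -> int:
        return len(self.genes)

    def positions_of(self, gene_set: Iterable[str]) -> np.ndarray:
        return np.sort(self.position.loc[list(gene_set)].to_numpy())


class RgesRecord(NamedTuple):
    profile_id: str
    compound: str
    cell_line: str
    dose_um: float
    duration_h: float
    is_gold: bool
    es_up: float
    es_down: float
    rges: float


class SimilarityResult(NamedTuple):
    spearman: float
    pearson: float
    cosine: float


class ContrastResult(NamedTuple):
    statistic: float
    p_value: float
    n_low: int
    n_high: int


def rank_profile(profile: DrugProfile) -> RankedProfile:
    """Order genes by differential expression, descending; ties broken by
    gene id ascending.  Only gold profiles may be ranked."""
    if not profile.is_gold:
        raise ValueError(f"profile {profile.profile_id!r} is not gold; "
                         "filter non-gold profiles before scoring")
    profile.validate()
    values = profile.values.sort_index()
    order = np.argsort(-values.to_numpy(), kind="stable")
    genes = values.index.to_numpy()[order]
    position = pd.Series(np.arange(1, len(genes) + 1), index=genes)
    return RankedProfile(genes=genes, position=position)


def enrichment_score(ranked: RankedProfile,
                     gene_set: Iterable[str]) -> float:
    """KS enrichment of a gene set in a ranked profile.

    With the set's 1-based positions p(1) <= ... <= p(t) in a list of n
    genes:  a = max_j (j/t - p(j)/n),  b = max_j (p(j)/n - (j-1)/t),
    ES = a if a > b else -b.  Positive ES: the set sits near the top.
    The saturated set (t = n) scores 0 by convention.
    """
    genes = set(gene_set)
    if not genes:
        raise ValueError("gene set is empty")
    unknown = genes - set(ranked.position.index)
    if unknown:
        raise ValueError(f"genes outside the ranked universe: "
                         f"{sorted(unknown)[:5]}")
    n = ranked.n
    t = len(genes)
    if t == n:
        return 0.0
    p = ranked.positions_of(genes)
    j = np.arange(1, t + 1)
    a = float((j / t - p / n).max())
    b = float((p / n - (j - 1) / t).max())
    return a if a > b else -b


def compute_rges(ranked: RankedProfile, signature,
                 profile: DrugProfile | None = None) -> RgesRecord:
    """RGES of one ranked profile against a disease signature.

    ES is evaluated for the signature's up and down sets restricted to the
    ranked universe; RGES = ES_up - ES_down when the two signs differ,
    else 0 (a profile that shifts both sets the same way carries no
    reversal information).
    """
    universe = set(ranked.position.index)
    up = [g for g in signature.up_genes if g in universe]
    down = [g for g in signature.down_genes if g in universe]
    if not up:
        raise ValueError("signature up set is empty after restriction to "
                         "the landmark universe")
    if not down:
        raise ValueError("signature down set is empty after restriction to "
                         "the landmark universe")
    es_up = enrichment_score(ranked, up)
    es_down = enrichment_score(ranked, down)
    rges = es_up - es_down if np.sign(es_up) != np.sign(es_down) else 0.0
    meta = profile or DrugProfile("", "", "", np.nan, np.nan, True,
                                  pd.Series(dtype=float))
    return RgesRecord(profile_id=meta.profile_id, compound=meta.compound,
                      cell_line=meta.cell_line, dose_um=meta.dose_um,
                      duration_h=meta.duration_h, is_gold=meta.is_gold,
                      es_up=es_up, es_down=es_down, rges=rges)


def score_profiles(profiles: Sequence[DrugProfile],
                   signature) -> pd.DataFrame:
    """RGES for every gold profile, vectorized over profiles.

    Equivalent to ``compute_rges(rank_profile(p), signature, p)`` per gold
    profile; non-gold profiles are skipped.  Raises if no gold profile is
    present.
    """
    gold = [p for p in profiles if p.is_gold]
    if not gold:
        raise ValueError("no gold profiles to score")
    genes = gold[0].values.sort_index().index
    n = len(genes)
    values = np.empty((len(gold), n))
    for i, p in enumerate(gold):
        p.validate()
        v = p.values
        if not v.index.equals(genes):
            v = v.sort_index()
            if not v.index.equals(genes):
                raise ValueError("profiles do not share a gene universe")
        values[i] = v.to_numpy()

    # stable argsort of -values over gene-id-sorted columns = descending
    # value with gene-id-ascending tie-break; ranks are its inverse
    order = np.argsort(-values, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(len(gold))[:, None]
    ranks[rows, order] = np.arange(1, n + 1)

    gene_pos = {g: i for i, g in enumerate(genes)}
    universe = set(genes)
    records = []
    es = {}
    for label, gene_list in (("up", signature.up_genes),
                             ("down", signature.down_genes)):
        members = [g for g in gene_list if g in universe]
        if not members:
            raise ValueError(f"signature {label} set is empty after "
                             "restriction to the landmark universe")
        idx = [gene_pos[g] for g in members]
        p = np.sort(ranks[:, idx], axis=1)
        t = len(idx)
        j = np.arange(1, t + 1)
        a = (j / t - p / n).max(axis=1)
        b = (p / n - (j - 1) / t).max(axis=1)
        es[label] = np.where(a > b, a, -b)
    rges = np.where(np.sign(es["up"]) != np.sign(es["down"]),
                    es["up"] - es["down"], 0.0)
    for i, p in enumerate(gold):
        records.append(RgesRecord(
            profile_id=p.profile_id, compound=p.compound,
            cell_line=p.cell_line, dose_um=p.dose_um,
            duration_h=p.duration_h, is_gold=True,
            es_up=float(es["up"][i]), es_down=float(es["down"][i]),
            rges=float(rges[i])))
    return pd.DataFrame(records)


def estimate_condition_offsets(
    records: pd.DataFrame,
    ref_dose: float = REFERENCE_DOSE_UM,
    ref_duration: float = REFERENCE_DURATION_H,
) -> tuple[float, float]:
    """Global additive offsets of non-reference conditions.

    For each factor, the offset is mean(rges | below reference) minus
    mean(rges | at/above reference) computed within compounds that carry
    both conditions, then averaged across those compounds; 0 when no
    compound is informative.
    """
    def _offset(level: pd.Series) -> float:
        deltas = []
        for _, grp in records.groupby("compound"):
            lo = grp.loc[level.loc[grp.index], "rges"]
            hi = grp.loc[~level.loc[grp.index], "rges"]
            if len(lo) and len(hi):
                deltas.append(lo.mean() - hi.mean())
        return float(np.mean(deltas)) if deltas else 0.0

    return (_offset(records["dose_um"] < ref_dose),
            _offset(records["duration_h"] < ref_duration))


def summarize_rges(
    records: pd.DataFrame,
    ref_dose: float = REFERENCE_DOSE_UM,
    ref_duration: float = REFERENCE_DURATION_H,
) -> pd.DataFrame:
    """Summarize profile-level RGES into one sRGES per compound.

    Non-reference records (dose below 10 uM, duration below 24 h) are
    shifted by the applicable global condition offsets before equal-weight
    averaging over the compound's gold profiles.  Compounds with no gold
    profile are excluded with a warning.  Result is sorted ascending by
    sRGES (strongest reversers first).
    """
    if len(records) == 0:
        raise ValueError("no profile scores to summarize")
    records = records[records["is_gold"]]
    if len(records) == 0:
        raise ValueError("no gold profile scores to summarize")
    d_dose, d_time = estimate_condition_offsets(records, ref_dose,
                                                ref_duration)
    adj = records["rges"].to_numpy().astype(float).copy()
    adj -= d_dose * (records["dose_um"] < ref_dose).to_numpy()
    adj -= d_time * (records["duration_h"] < ref_duration).to_numpy()
    work = records.assign(adjusted=adj)
    rows = []
    for compound, grp in work.groupby("compound", sort=True):
        at_ref = ((grp["dose_um"] >= ref_dose)
                  & (grp["duration_h"] >= ref_duration)).sum()
        rows.append({
            "compound": compound,
            "srges": float(grp["adjusted"].mean()),
            "n_profiles": int(len(grp)),
            "conditions_used": f"{int(at_ref)}/{len(grp)} at reference",
        })
    return (pd.DataFrame(rows)
            .sort_values("srges", kind="mergesort")
            .reset_index(drop=True))


def similarity_metrics(signature_fc: pd.Series,
                       profile_values: pd.Series) -> SimilarityResult:
    """Spearman/Pearson/cosine similarity over the shared gene index.

    Correlations are reported as NaN (with a warning) for constant vectors;
    cosine is still returned.
    """
    shared = signature_fc.index.intersection(profile_values.index)
    if len(shared) < 3:
        raise ValueError("need >=3 shared genes for similarity metrics")
    x = signature_fc.loc[shared].to_numpy(dtype=float)
    y = profile_values.loc[shared].to_numpy(dtype=float)
    constant = np.ptp(x) == 0 or np.ptp(y) == 0
    if constant:
        logger.warning("similarity_metrics: constant vector, correlations "
                       "undefined")
        spearman = pearson = np.nan
    else:
        spearman = float(stats.spearmanr(x, y).statistic)
        pearson = float(stats.pearsonr(x, y).statistic)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    cosine = float(x @ y / (nx * ny)) if nx > 0 and ny > 0 else np.nan
    return SimilarityResult(spearman=spearman, pearson=pearson,
                            cosine=cosine)


def condition_contrast(records: pd.DataFrame, factor: str) -> ContrastResult:
    """Rank-test contrast of RGES across experimental conditions.

    ``factor`` is one of:

    * ``"dose"``: profiles below vs at/above the 10 uM reference dose;
    * ``"duration"``: below vs at/above 24 h;
    * ``"cell_line_sd"``: per-compound standard deviation of RGES across
      cell lines (at matched dose/duration) vs across replicates within a
      cell line.

    Both sides are compared with a two-sided Mann-Whitney rank test.
    """
    if factor == "dose":
        low = records.loc[records["dose_um"] < REFERENCE_DOSE_UM, "rges"]
        high = records.loc[records["dose_um"] >= REFERENCE_DOSE_UM, "rges"]
    elif factor == "duration":
        low = records.loc[records["duration_h"] < REFERENCE_DURATION_H,
                          "rges"]
        high = records.loc[records["duration_h"] >= REFERENCE_DURATION_H,
                           "rges"]
    elif factor == "cell_line_sd":
        across, within = [], []
        for (_, _, _), grp in records.groupby(
                ["compound", "dose_um", "duration_h"]):
            per_line = grp.groupby("cell_line")["rges"]
            if per_line.ngroups >= 2:
                across.append(float(per_line.mean().std(ddof=1)))
            rep_sds = per_line.std(ddof=1).dropna()
            within.extend(float(s) for s in rep_sds)
        low, high = pd.Series(within), pd.Series(across)
    else:
        raise ValueError(f"unknown factor {factor!r}")
    if len(low) < 2 or len(high) < 2:
        raise ValueError(f"factor {factor!r}: both levels need >=2 "
                         "observations")
    res = stats.mannwhitneyu(low, high, alternative="two-sided",
                             method="auto")
    return ContrastResult(statistic=float(res.statistic),
                          p_value=float(res.pvalue),
                          n_low=int(len(low)), n_high=int(len(high)))
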