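"""Target-inhibition synergy prediction (TIMMA-style max/min averaging).

Given a binary drug-target matrix and a per-drug sensitivity y in [0, 1],
the sensitivity of inhibiting an arbitrary target set T is predicted as

* the mean observed y of drugs whose target set equals T exactly, if any;
* otherwise the midpoint of a lower bound L(T) (the largest y among drugs
  whose target sets are contained in T; 0 with no such drug - inhibiting
  more targets can only help) and an upper bound U(T) (the smallest y
  among drugs whose target sets contain T; 1 with no such drug).

Synergy of a drug pair is scored per target pair (i from drug 1, j from
drug 2) by comparing the predicted pair sensitivity y(i,j) against an
additive, multiplicative or highest-single-agent reference built from the
predicted single-target sensitivities, averaged over all target pairs.
The predicted combination sensitivity adds the average synergy to the
expectation, taken as the prediction for the union target set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple

import numpy as np
import pandas as pd

ScoreKind = Literal["additive", "multiplicative", "highest-agent"]
ExpectationKind = Literal["timma", "additive-null"]


class SynergyScores(NamedTuple):
    s_a: float
    s_m: float
    s_l: float


@dataclass
class SynergyResult:
    drug_1: str
    drug_2: str
    pair_scores: pd.DataFrame       # target_1, target_2, y_i, y_j, y_ij, s
    average_synergy: float
    expectation: float
    predicted_sensitivity: float
    score_kind: str


def validate_drug_target_matrix(matrix: pd.DataFrame) -> None:
    v = matrix.to_numpy()
    if not np.isin(v, (0, 1)).all():
        raise ValueError("drug-target matrix entries must be 0/1")
    empty = matrix.index[v.sum(axis=1) == 0]
    if len(empty):
        raise ValueError(f"drugs without any target: {list(empty)[:5]}")


def validate_sensitivity(y: pd.Series) -> None:
    v = y.to_numpy(dtype=float)
    if ((v < 0) | (v > 1) | ~np.isfinite(v)).any():
        raise ValueError("sensitivities must lie in [0, 1]")


def rges_to_sensitivity(srges: pd.Series) -> pd.Series:
    """Min-max map of sRGES onto [0, 1], strongest reverser -> 1."""
    v = srges.to_numpy(dtype=float)
    if len(v) < 2 or np.ptp(v) == 0:
        raise ValueError("need >=2 distinct sRGES values to rescale")
    return pd.Series((v.max() - v) / np.ptp(v), index=srges.index)


class _Instance:
    """Bitmask-encoded drug-target instance for fast set queries."""

    def __init__(self, matrix: pd.DataFrame, y: pd.Series):
        validate_drug_target_matrix(matrix)
        y = y.loc[matrix.index]
        validate_sensitivity(y)
        self.targets = list(matrix.columns)
        self.bit = {t: 1 << i for i, t in enumerate(self.targets)}
        m = matrix.to_numpy()
        self.drug_masks = np.array(
            [int(sum(self.bit[t] for t, hit in zip(self.targets, row)
                     if hit)) for row in m], dtype=object)
        self.y = y.to_numpy(dtype=float)
        self.drugs = list(matrix.index)

    def mask_of(self, target_set: Iterable[str]) -> int:
        mask = 0
        for t in set(target_set):
            if t not in self.bit:
                raise ValueError(f"unknown target id {t!r}")
            mask |= self.bit[t]
        return mask

    def predict_mask(self, mask: int) -> float:
        exact = [y for dm, y in zip(self.drug_masks, self.y) if dm == mask]
        if exact:
            return float(np.mean(exact))
        lower = [y for dm, y in zip(self.drug_masks, self.y)
                 if dm | mask == mask]          # drug set subset of query
        upper = [y for dm, y in zip(self.drug_masks, self.y)
                 if dm & mask == mask]          # drug set superset of query
        lo = max(lower) if lower else 0.0
        up = min(upper) if upper else 1.0
        return (lo + up) / 2.0

    def bounds_mask(self, mask: int) -> tuple[float, float]:
        lower = [y for dm, y in zip(self.drug_masks, self.y)
                 if dm | mask == mask]
        upper = [y for dm, y in zip(self.drug_masks, self.y)
                 if dm & mask == mask]
        return (max(lower) if lower else 0.0,
                min(upper) if upper else 1.0)


def timma_predict(target_set: Iterable[str], matrix: pd.DataFrame,
                  y: pd.Series) -> float:
    """Predicted sensitivity of inhibiting ``target_set``; see module doc."""
    inst = _Instance(matrix, y)
    return inst.predict_mask(inst.mask_of(target_set))


def timma_bounds(target_set: Iterable[str], matrix: pd.DataFrame,
                 y: pd.Series) -> tuple[float, float]:
    """(L, U) subset/superset bounds for ``target_set``."""
    inst = _Instance(matrix, y)
    return inst.bounds_mask(inst.mask_of(target_set))


def synergy_scores(y_i: float, y_j: float, y_ij: float) -> SynergyScores:
    """Additive, multiplicative and highest-single-agent synergy scores:
    S_a = y(i,j) - (y(i) + y(j)); S_m = y(i,j) - y(i)*y(j);
    S_l = y(i,j) - max(y(i), y(j))."""
    for name, v in (("y_i", y_i), ("y_j", y_j), ("y_ij", y_ij)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return SynergyScores(s_a=y_ij - (y_i + y_j),
                         s_m=y_ij - y_i * y_j,
                         s_l=y_ij - max(y_i, y_j))


def _pair_table(inst: _Instance, d1: str, d2: str,
                score_kind: ScoreKind) -> pd.DataFrame:
    i1, i2 = inst.drugs.index(d1), inst.drugs.index(d2)
    t1 = [t for t in inst.targets if inst.drug_masks[i1] & inst.bit[t]]
    t2 = [t for t in inst.targets if inst.drug_masks[i2] & inst.bit[t]]
    rows = []
    single = {t: inst.predict_mask(inst.bit[t]) for t in set(t1) | set(t2)}
    for ti in t1:
        for tj in t2:
            if ti == tj:
                continue
            y_ij = inst.predict_mask(inst.bit[ti] | inst.bit[tj])
            s = synergy_scores(single[ti], single[tj], y_ij)
            score = {"additive": s.s_a, "multiplicative": s.s_m,
                     "highest-agent": s.s_l}[score_kind]
            rows.append((ti, tj, single[ti], single[tj], y_ij, score))
    if not rows:
        raise ValueError(f"no valid target pairs for ({d1}, {d2}): "
                         "identical single-target drugs")
    return pd.DataFrame(rows, columns=["target_1", "target_2", "y_i",
                                       "y_j", "y_ij", "s"])


def average_synergy(d1: str, d2: str, matrix: pd.DataFrame, y: pd.Series,
                    score_kind: ScoreKind = "additive") -> float:
    """Mean synergy score over all (i in targets(d1), j in targets(d2))
    target pairs, skipping shared targets (i = j)."""
    _check_drugs(matrix, d1, d2)
    inst = _Instance(matrix, y)
    return float(_pair_table(inst, d1, d2, score_kind)["s"].mean())


def combination_sensitivity(
    d1: str, d2: str, matrix: pd.DataFrame, y: pd.Series,
    score_kind: ScoreKind = "additive",
    expectation_kind: ExpectationKind = "timma",
) -> SynergyResult:
    """Predicted combination sensitivity = clip(expectation + synergy, 0, 1).

    The expectation is the prediction for the union target set
    (``"timma"``), or the Bliss-style additive null
    1 - (1 - y(d1)) * (1 - y(d2)) on the observed drug sensitivities
    (``"additive-null"``).
    """
    _check_drugs(matrix, d1, d2)
    inst = _Instance(matrix, y)
    pairs = _pair_table(inst, d1, d2, score_kind)
    syn = float(pairs["s"].mean())
    i1, i2 = inst.drugs.index(d1), inst.drugs.index(d2)
    if expectation_kind == "timma":
        expectation = inst.predict_mask(inst.drug_masks[i1]
                                        | inst.drug_masks[i2])
    elif expectation_kind == "additive-null":
        expectation = 1.0 - (1.0 - inst.y[i1]) * (1.0 - inst.y[i2])
    else:
        raise ValueError(f"unknown expectation kind {expectation_kind!r}")
    predicted = float(np.clip(expectation + syn, 0.0, 1.0))
    return SynergyResult(drug_1=d1, drug_2=d2, pair_scores=pairs,
                         average_synergy=syn, expectation=float(expectation),
                         predicted_sensitivity=predicted,
                         score_kind=score_kind)


def rank_combinations(
    matrix: pd.DataFrame, y: pd.Series,
    score_kind: ScoreKind = "additive",
    expectation_kind: ExpectationKind = "timma",
) -> pd.DataFrame:
    """Score every unordered drug pair; sorted descending by predicted
    sensitivity.  Pairs with no valid target pair (identical single-target
    drugs) are skipped."""
    inst = _Instance(matrix, y)
    single = {t: inst.predict_mask(inst.bit[t]) for t in inst.targets}
    pair_pred = {}

    def pair_sens(ti: str, tj: str) -> float:
        key = (ti, tj) if ti < tj else (tj, ti)
        if key not in pair_pred:
            pair_pred[key] = inst.predict_mask(inst.bit[ti] | inst.bit[tj])
        return pair_pred[key]

    drug_targets = {d: [t for t in inst.targets
                        if inst.drug_masks[k] & inst.bit[t]]
                    for k, d in enumerate(inst.drugs)}
    rows = []
    for a in range(len(inst.drugs)):
        for b in range(a + 1, len(inst.drugs)):
            d1, d2 = inst.drugs[a], inst.drugs[b]
            scores = []
            for ti in drug_targets[d1]:
                for tj in drug_targets[d2]:
                    if ti == tj:
                        continue
                    s = synergy_scores(single[ti], single[tj],
                                       pair_sens(ti, tj))
                    scores.append({"additive": s.s_a,
                                   "multiplicative": s.s_m,
                                   "highest-agent": s.s_l}[score_kind])
            if not scores:
                continue
            syn = float(np.mean(scores))
            if expectation_kind == "timma":
                expectation = inst.predict_mask(inst.drug_masks[a]
                                                | inst.drug_masks[b])
            else:
                expectation = 1.0 - (1.0 - inst.y[a]) * (1.0 - inst.y[b])
            rows.append((d1, d2, syn, float(expectation),
                         float(np.clip(expectation + syn, 0.0, 1.0))))
    out = pd.DataFrame(rows, columns=["drug_1", "drug_2", "average_synergy",
                                      "expectation",
                                      "predicted_sensitivity"])
    return (out.sort_values("predicted_sensitivity", ascending=False,
                            kind="mergesort")
            .reset_index(drop=True))


def synergy_matrix(ranked: pd.DataFrame) -> pd.DataFrame:
    """Square predicted-sensitivity matrix for heatmap rendering."""
    drugs = sorted(set(ranked["drug_1"]) | set(ranked["drug_2"]))
    m = pd.DataFrame(np.nan, index=drugs, columns=drugs)
    for _, r in ranked.iterrows():
        m.loc[r["drug_1"], r["drug_2"]] = r["predicted_sensitivity"]
        m.loc[r["drug_2"], r["drug_1"]] = r["predicted_sensitivity"]
    return m


def _check_drugs(matrix: pd.DataFrame, *drugs: str) -> None:
    missing = [d for d in drugs if d not in matrix.index]
    if missing:
        raise ValueError(f"drugs not in matrix: {missing}")
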