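"""Disease-signature derivation: probe collapsing, moderated t-statistics,
fixed-effect meta-analysis, BH adjustment and DEG selection.

The per-study test is a two-sample t with empirical-Bayes variance
shrinkage: per-gene residual variances s2_g (d_g df each) are modelled as
scaled inverse chi-square draws around a prior (d0, s0^2) estimated by
method of moments on log s2_g, and the moderated statistic uses the
posterior variance  s~2 = (d0*s0^2 + d_g*s2_g) / (d0 + d_g)  with d_g + d0
degrees of freedom.  Study effects (log2 fold changes) are then pooled with
an inverse-variance-weighted fixed-effect model, BH-adjusted, and
thresholded on both the adjusted p-value and the combined fold change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

_MAX_DF = 1e6  # stand-in for an infinite prior df in t tail evaluation


@dataclass
class ExpressionStudy:
    """One study: log2 expression (probes or genes x samples) with labels."""

    matrix: pd.DataFrame
    labels: pd.Series
    platform_id: str
    probe_map: pd.Series | None = None

    def validate(self) -> None:
        if self.matrix.empty:
            raise ValueError("expression matrix is empty")
        if not np.isfinite(self.matrix.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        missing = set(self.matrix.columns) - set(self.labels.index)
        if missing:
            raise ValueError(f"samples without labels: {sorted(missing)[:5]}")
        counts = self.labels.loc[self.matrix.columns].value_counts()
        for group in ("tumor", "normal"):
            if counts.get(group, 0) < 2:
                raise ValueError(
                    f"study {self.platform_id!r} needs >=2 {group} samples")

    def group_columns(self, group: str) -> list[str]:
        lab = self.labels.loc[self.matrix.columns]
        return list(lab.index[lab == group])


@dataclass
class DiseaseSignature:
    """Up- and down-regulated DEG tables (index gene_id; combined_log2fc, q),
    each sorted by |combined_log2fc| descending."""

    up: pd.DataFrame
    down: pd.DataFrame

    def __post_init__(self) -> None:
        overlap = set(self.up.index) & set(self.down.index)
        if overlap:
            raise ValueError(f"up/down gene sets overlap: "
                             f"{sorted(overlap)[:5]}")

    @property
    def up_genes(self) -> list[str]:
        return list(self.up.index)

    @property
    def down_genes(self) -> list[str]:
        return list(self.down.index)


def collapse_probes(matrix: pd.DataFrame,
                    probe_map: pd.Series) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level.

    For genes measured by multiple probes the probe with the largest
    interquartile range across samples is retained; exact IQR ties are broken
    by the lexicographically smallest probe id.  Probes absent from the map
    are dropped (count logged).
    """
    if matrix.empty:
        raise ValueError("cannot collapse an empty matrix")
    probe_map = pd.Series(probe_map)
    mapped = matrix.index.intersection(probe_map.index)
    n_dropped = len(matrix.index) - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropping %d unmapped probes", n_dropped)
    if len(mapped) == 0:
        raise ValueError("no probes could be mapped to genes")
    sub = matrix.loc[mapped]
    q75, q25 = np.percentile(sub.to_numpy(), [75, 25], axis=1)
    choice = (pd.DataFrame({"gene": probe_map.loc[mapped].to_numpy(),
                            "iqr": q75 - q25,
                            "probe": mapped})
              .sort_values(["gene", "iqr", "probe"],
                           ascending=[True, False, True])
              .drop_duplicates("gene"))
    out = sub.loc[choice["probe"]]
    out.index = choice["gene"].to_numpy()
    return out.sort_index()


def intersect_genes(matrices: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Restrict gene-level matrices to their common, sorted gene index."""
    if not matrices:
        raise ValueError("need at least one study")
    common = matrices[0].index
    for m in matrices[1:]:
        common = common.intersection(m.index)
    if len(common) == 0:
        raise ValueError("gene intersection across studies is empty")
    common = common.sort_values()
    return [m.loc[common] for m in matrices]


def _trigamma_inverse(y: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) / x < 1e-10):
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the (d0, s0^2) variance prior.

    Matches the first two moments of log s2_g to those implied by a scaled
    F distribution: with e_g = log s2_g - digamma(df/2) + log(df/2),
    mean(e) identifies s0^2 and the excess variance of e over
    trigamma(df/2) identifies d0 through the trigamma function.  Returns
    (inf, exp(mean e)) when the observed spread is at or below the
    chi-square-only expectation.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all per-gene variances are zero; degenerate input")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = e.size
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = float(((e - emean) ** 2).sum() / (n - 1))
    excess = evar - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * float(_trigamma_inverse(excess))
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def moderated_t(study: ExpressionStudy,
                prior_df: float | None = None) -> pd.DataFrame:
    """Per-gene moderated t-statistics for one (gene-level) study.

    Returns a frame indexed by gene with columns ``log2fc`` (tumor minus
    normal), ``s2`` (pooled residual variance), ``s2_post`` (shrunken),
    ``t_mod``, ``df_total``, ``p`` (two-sided) and ``v`` (sampling variance
    of the effect).  ``prior_df`` overrides the estimated d0: 0 recovers the
    ordinary pooled t, ``np.inf`` shrinks every variance to the prior.
    """
    study.validate()
    tumor = study.matrix[study.group_columns("tumor")].to_numpy()
    normal = study.matrix[study.group_columns("normal")].to_numpy()
    n1, n2 = tumor.shape[1], normal.shape[1]
    df = n1 + n2 - 2

    fc = tumor.mean(axis=1) - normal.mean(axis=1)
    ss = (((tumor - tumor.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
          + ((normal - normal.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))
    s2 = ss / df

    d0, s02 = estimate_variance_prior(s2, df)
    if prior_df is not None:
        d0 = float(prior_df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    elif d0 == 0.0:
        s2_post = s2
        df_total = float(df)
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = df + d0

    scale = 1.0 / n1 + 1.0 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = fc / np.sqrt(s2_post * scale)
    p = 2.0 * stats.t.sf(np.abs(t_mod), min(df_total, _MAX_DF))
    v = s2_post * scale
    out = pd.DataFrame(
        {"log2fc": fc, "s2": s2, "s2_post": s2_post, "t_mod": t_mod,
         "df_total": df_total, "p": p, "v": v},
        index=study.matrix.index)
    out.attrs["d0"] = d0
    out.attrs["s02"] = s02
    return out


def fixed_effect_meta(stats_per_study: list[pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance-weighted fixed-effect pooling of study effects.

    Requires every study frame to share the gene index and have strictly
    positive sampling variances ``v``.  Returns combined_log2fc, combined_v,
    z, p_meta and BH-adjusted q per gene.
    """
    if not stats_per_study:
        raise ValueError("need at least one study")
    index = stats_per_study[0].index
    for s in stats_per_study[1:]:
        if not s.index.equals(index):
            raise ValueError("studies do not share a gene index; run "
                             "intersect_genes first")
    v = np.column_stack([s["v"].to_numpy() for s in stats_per_study])
    if (v <= 0).any():
        raise ValueError("non-positive sampling variance in meta input")
    fc = np.column_stack([s["log2fc"].to_numpy() for s in stats_per_study])
    w = 1.0 / v
    combined_v = 1.0 / w.sum(axis=1)
    combined_fc = (w * fc).sum(axis=1) * combined_v
    z = combined_fc / np.sqrt(combined_v)
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = bh_adjust(p)
    return pd.DataFrame(
        {"combined_log2fc": combined_fc, "combined_v": combined_v,
         "z": z, "p_meta": p, "q": q}, index=index)


def bh_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_degs(meta: pd.DataFrame, q_threshold: float = 0.001,
                fc_threshold: float = 1.5) -> DiseaseSignature:
    """Threshold the meta table into an up/down disease signature.

    Up: q < q_threshold and combined_log2fc > fc_threshold; down symmetric
    with the negated cut.  Both tables are sorted by |combined_log2fc|
    descending.
    """
    if q_threshold <= 0 or fc_threshold <= 0:
        raise ValueError("thresholds must be positive")
    sig = meta[meta["q"] < q_threshold]
    up = sig[sig["combined_log2fc"] > fc_threshold]
    down = sig[sig["combined_log2fc"] < -fc_threshold]

    def _order(df: pd.DataFrame) -> pd.DataFrame:
        out = df[["combined_log2fc", "q"]].copy()
        return out.reindex(
            out["combined_log2fc"].abs().sort_values(ascending=False).index)

    return DiseaseSignature(up=_order(up), down=_order(down))


def meta_signature_from_studies(
    studies: list[ExpressionStudy],
    q_threshold: float = 0.001,
    fc_threshold: float = 1.5,
    prior_df: float | None = None,
) -> tuple[pd.DataFrame, DiseaseSignature]:
    """Full per-study-to-signature path used by the pipeline.

    Collapses probes where a probe map is present, intersects gene indices,
    computes per-study moderated t tables, pools them and selects DEGs.
    Returns (meta table, signature).
    """
    gene_level = []
    for study in studies:
        m = study.matrix
        if study.probe_map is not None:
            m = collapse_probes(m, study.probe_map)
        gene_level.append((study, m))
    matrices = intersect_genes([m for _, m in gene_level])
    stats_tables = []
    for (study, _), m in zip(gene_level, matrices):
        stats_tables.append(moderated_t(
            ExpressionStudy(matrix=m, labels=study.labels,
                            platform_id=study.platform_id),
            prior_df=prior_df))
    meta = fixed_effect_meta(stats_tables)
    return meta, select_degs(meta, q_threshold, fc_threshold)
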