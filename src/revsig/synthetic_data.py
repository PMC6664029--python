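"""Synthetic cohort, drug-profile, activity and target-matrix generators.

Every input the real analysis would download (multi-platform tumor/normal
expression studies, landmark-gene drug perturbation profiles, IC50/AUC
activity tables, a binary drug-target matrix) is generated here with planted
structure, so each downstream stage has a known ground truth to recover:

* a fixed set of up- and down-regulated disease genes shifted by a common
  log2 fold change in tumors, consistently across studies;
* a subset of "reverser" compounds whose profiles push the planted up-genes
  toward the bottom of the ranking and the down-genes toward the top;
* IC50s whose log10 values increase with the planted reversal score, so
  strong reversers are the active compounds;
* a drug-target matrix with a combination-sensitivity truth that is monotone
  in the union target set, matching the assumption of the target-inhibition
  synergy model.

All randomness flows from ``SimulationConfig.seed`` through fixed, named
substreams, so equal seeds give byte-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .meta_signature import DiseaseSignature, ExpressionStudy
from .signature_scoring import DrugProfile

CELL_LINES = ("PC3", "VCAP", "DU145")

# substream tags: one per generator so they can be called independently
_STREAM_TRUTH = 11
_STREAM_STUDIES = 12
_STREAM_PROFILES = 13
_STREAM_ACTIVITY = 14
_STREAM_TARGETS = 15

# intercept/slope of the log10(IC50) ~ planted-RGES link.  The intercept puts
# non-reversers near 20 uM (inactive side of the 10 uM threshold) and the unit
# slope drags default-strength reversers to ~1-5 uM, so both activity classes
# are populated.
IC50_LOG10_INTERCEPT = 1.3
IC50_LOG10_SLOPE = 1.0

# value-shift (in residual-sd units) applied to planted genes of a
# full-strength reverser at the reference condition; large enough that the
# planted sets land at the extremes of the 978-gene ranking.
PROFILE_SHIFT_SCALE = 6.0


def gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def compound_ids(n: int) -> list[str]:
    return [f"cmpd{i:03d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the scale of the real cohort: a 978-gene landmark
    universe, 4 studies totalling 64 tumors and 114 normal/benign samples,
    53 planted up- and 42 planted down-regulated genes, and 172 profiled
    compounds of which a fraction reverse the disease signature.
    """

    n_genes: int = 978
    n_studies: int = 4
    samples_per_study: tuple[tuple[int, int], ...] = (
        (16, 29),
        (16, 29),
        (16, 28),
        (16, 28),
    )
    n_deg_up: int = 53
    n_deg_down: int = 42
    deg_log2fc: float = 2.0
    n_compounds: int = 172
    frac_reversers: float = 0.3
    reversal_strength: float = 0.6
    ic50_noise_sd: float = 0.4
    doses: tuple[float, ...] = (0.37, 1.11, 3.33, 10.0)
    durations: tuple[float, ...] = (6.0, 24.0)
    n_targets: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_studies", "n_deg_up", "n_deg_down",
                     "n_compounds", "n_targets"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive count, got "
                                 f"{getattr(self, name)}")
        if len(self.samples_per_study) != self.n_studies:
            raise ValueError("samples_per_study must list one (n_tumor, "
                             "n_normal) pair per study")
        for nt, nn in self.samples_per_study:
            if nt < 2 or nn < 2:
                raise ValueError("samples_per_study requires >=2 samples per "
                                 "group in every study")
        if not 0.0 <= self.frac_reversers <= 1.0:
            raise ValueError(f"frac_reversers must lie in [0, 1], got "
                             f"{self.frac_reversers}")
        if not 0.0 <= self.reversal_strength <= 1.0:
            raise ValueError(f"reversal_strength must lie in [0, 1], got "
                             f"{self.reversal_strength}")
        if self.ic50_noise_sd < 0:
            raise ValueError("ic50_noise_sd must be non-negative")
        if 10.0 not in self.doses:
            raise ValueError("doses must include the 10 uM reference dose")
        if 24.0 not in self.durations:
            raise ValueError("durations must include the 24 h reference "
                             "duration")
        if self.n_deg_up + self.n_deg_down >= self.n_genes:
            raise ValueError("n_deg_up + n_deg_down must be smaller than "
                             "n_genes")


@dataclass
class GroundTruth:
    """Planted structure shared by all generators for one seed."""

    planted_up_genes: tuple[str, ...]
    planted_down_genes: tuple[str, ...]
    reverser_compounds: frozenset[str]
    compounds: tuple[str, ...]
    reversal_level: pd.Series          # compound -> latent strength in [0,1]
    planted_rges: pd.Series            # compound -> noise-free reversal score
    true_ic50: pd.Series               # compound -> noise-free IC50 (uM)
    n_genes: int
    drug_targets: pd.DataFrame | None = None
    target_weights: pd.Series | None = None
    true_combination_sensitivity: dict[tuple[str, str], float] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        if not self.reverser_compounds <= set(self.compounds):
            raise ValueError("reverser_compounds must be a subset of the "
                             "compound universe")
        if set(self.planted_up_genes) & set(self.planted_down_genes):
            raise ValueError("planted up/down gene sets must be disjoint")

    def sensitivity(self, target_set: Sequence[str]) -> float:
        """Monotone truth: normalized weight mass of the inhibited set."""
        if self.target_weights is None:
            raise ValueError("ground truth has no drug-target component")
        w = self.target_weights
        # summation order can push the full-set ratio a ulp above 1
        return float(min(1.0, w.loc[list(set(target_set))].sum() / w.sum()))


def generate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the planted gene sets, reverser set, latent scores and targets."""
    rng = np.random.default_rng([config.seed, _STREAM_TRUTH])
    genes = gene_ids(config.n_genes)
    perm = rng.permutation(config.n_genes)
    up = tuple(sorted(genes[i] for i in perm[: config.n_deg_up]))
    down = tuple(sorted(
        genes[i] for i in perm[config.n_deg_up: config.n_deg_up
                               + config.n_deg_down]))

    compounds = tuple(compound_ids(config.n_compounds))
    n_rev = int(round(config.frac_reversers * config.n_compounds))
    rev_idx = rng.permutation(config.n_compounds)[:n_rev]
    reversers = frozenset(compounds[i] for i in rev_idx)

    level = pd.Series(0.0, index=list(compounds))
    if n_rev:
        level.iloc[sorted(rev_idx)] = (
            config.reversal_strength * rng.uniform(0.5, 1.0, n_rev))
    # small continuous jitter keeps the planted score tie-free so a noiseless
    # monotone IC50 link yields a Spearman rho of exactly 1
    jitter = rng.uniform(-0.05, 0.05, config.n_compounds)
    planted_rges = pd.Series(-2.0 * level.to_numpy() + jitter,
                             index=list(compounds))
    true_ic50 = pd.Series(
        10.0 ** (IC50_LOG10_INTERCEPT
                 + IC50_LOG10_SLOPE * planted_rges.to_numpy()),
        index=list(compounds))

    truth = GroundTruth(
        planted_up_genes=up,
        planted_down_genes=down,
        reverser_compounds=reversers,
        compounds=compounds,
        reversal_level=level,
        planted_rges=planted_rges,
        true_ic50=true_ic50,
        n_genes=config.n_genes,
    )
    generate_drug_target_matrix(config, truth)
    return truth


def generate_disease_studies(
    config: SimulationConfig,
) -> tuple[list[ExpressionStudy], GroundTruth]:
    """Simulate the tumor/normal expression studies.

    Background expression is Normal(7, 1) on the log2 scale with per-gene
    mean offsets shared across studies; planted genes are shifted by
    ``deg_log2fc`` in tumor samples, in a consistent direction across
    studies.  Each study gets its own platform id and probe map in which
    ~15% of genes carry a second, attenuated probe.
    """
    truth = generate_ground_truth(config)
    rng = np.random.default_rng([config.seed, _STREAM_STUDIES])
    genes = np.array(gene_ids(config.n_genes))
    up_idx = np.flatnonzero(np.isin(genes, truth.planted_up_genes))
    down_idx = np.flatnonzero(np.isin(genes, truth.planted_down_genes))
    base_mean = 7.0 + rng.normal(0.0, 1.0, config.n_genes)

    studies: list[ExpressionStudy] = []
    for s, (n_tumor, n_normal) in enumerate(config.samples_per_study):
        platform = f"GPL{9000 + s}"
        n = n_tumor + n_normal
        vals = base_mean[:, None] + rng.normal(0.0, 1.0, (config.n_genes, n))
        vals[np.ix_(up_idx, np.arange(n_tumor))] += config.deg_log2fc
        vals[np.ix_(down_idx, np.arange(n_tumor))] -= config.deg_log2fc

        sample_ids = ([f"{platform}_T{j:02d}" for j in range(n_tumor)]
                      + [f"{platform}_N{j:02d}" for j in range(n_normal)])
        labels = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal,
                           index=sample_ids)

        # probe expansion: every gene has a primary probe; a 15% subset gets a
        # second probe with attenuated dynamic range (lower IQR), so probe
        # collapsing has real work to do
        n_multi = max(1, int(round(0.15 * config.n_genes)))
        multi = np.sort(rng.permutation(config.n_genes)[:n_multi])
        probe_rows = [vals]
        probe_names = [f"{platform}:{g}:a" for g in genes]
        second = (7.0 + 0.4 * (vals[multi] - 7.0)
                  + rng.normal(0.0, 0.5, (n_multi, n)))
        probe_rows.append(second)
        probe_names += [f"{platform}:{genes[i]}:b" for i in multi]

        matrix = pd.DataFrame(np.vstack(probe_rows), index=probe_names,
                              columns=sample_ids)
        probe_map = pd.Series(
            list(genes) + [genes[i] for i in multi], index=probe_names)
        studies.append(ExpressionStudy(matrix=matrix, labels=labels,
                                       platform_id=platform,
                                       probe_map=probe_map))
    return studies, truth


def generate_compound_profiles(
    config: SimulationConfig, truth: GroundTruth,
) -> list[DrugProfile]:
    """Simulate landmark-gene differential-expression profiles.

    Every compound gets one gold profile at the reference condition
    (10 uM, 24 h, PC3) plus 1-3 profiles at random conditions, a minority of
    which are flagged non-gold.  For reverser compounds the planted up-genes
    are pushed down and the down-genes up by an amount proportional to the
    compound's latent reversal level, attenuated at sub-reference dose or
    duration.
    """
    if truth.n_genes != config.n_genes:
        raise ValueError("config/truth n_genes mismatch: "
                         f"{config.n_genes} vs {truth.n_genes}")
    rng = np.random.default_rng([config.seed, _STREAM_PROFILES])
    genes = gene_ids(config.n_genes)
    gene_arr = np.array(genes)
    up_idx = np.flatnonzero(np.isin(gene_arr, truth.planted_up_genes))
    down_idx = np.flatnonzero(np.isin(gene_arr, truth.planted_down_genes))

    profiles: list[DrugProfile] = []
    counter = itertools.count(1)
    for compound in truth.compounds:
        level = float(truth.reversal_level.loc[compound])
        n_extra = int(rng.integers(1, 4))
        conditions = [("PC3", 10.0, 24.0, True)]
        for _ in range(n_extra):
            cell = CELL_LINES[int(rng.integers(0, len(CELL_LINES)))]
            dose = float(config.doses[int(rng.integers(0, len(config.doses)))])
            dur = float(
                config.durations[int(rng.integers(0, len(config.durations)))])
            gold = bool(rng.random() < 0.85)
            conditions.append((cell, dose, dur, gold))
        for cell, dose, dur, gold in conditions:
            vals = rng.normal(0.0, 1.0, config.n_genes)
            if level > 0:
                mult = ((1.0 if dose >= 10.0 else 0.5)
                        * (1.0 if dur >= 24.0 else 0.5))
                shift = PROFILE_SHIFT_SCALE * level * mult
                vals[up_idx] -= shift
                vals[down_idx] += shift
            profiles.append(DrugProfile(
                profile_id=f"prof{next(counter):05d}",
                compound=compound,
                cell_line=cell,
                dose_um=dose,
                duration_h=dur,
                is_gold=gold,
                values=pd.Series(vals, index=genes),
            ))
    return profiles


def generate_activity_data(
    config: SimulationConfig, truth: GroundTruth,
) -> pd.DataFrame:
    """Simulate IC50 and AUC activity records.

    ``log10(IC50)`` equals the noise-free link value plus Gaussian noise of
    sd ``ic50_noise_sd`` per record; records are spread over >=2 cell lines
    per compound.  AUC records follow the same monotone ordering on a [0, 1]
    scale.  All IC50s are positive by construction (clipped on the log
    scale).
    """
    rng = np.random.default_rng([config.seed, _STREAM_ACTIVITY])
    pr = truth.planted_rges
    lo, hi = float(pr.min()), float(pr.max())
    span = (hi - lo) or 1.0
    rows: list[tuple[str, str, str, float]] = []
    for compound in truth.compounds:
        base = float(np.log10(truth.true_ic50.loc[compound]))
        cells = [CELL_LINES[i] for i in
                 np.sort(rng.permutation(len(CELL_LINES))[:2])]
        for cell in cells:
            for _ in range(int(rng.integers(1, 3))):
                log10_ic50 = np.clip(
                    base + rng.normal(0.0, config.ic50_noise_sd), -4.0, 4.0)
                rows.append((compound, cell, "IC50",
                             float(10.0 ** log10_ic50)))
            auc = np.clip(0.55 + 0.3 * (pr.loc[compound] - lo) / span
                          + rng.normal(0.0, 0.05), 0.0, 1.0)
            rows.append((compound, cell, "AUC", float(auc)))
    return pd.DataFrame(rows,
                        columns=["compound", "cell_line", "measure", "value"])


def generate_drug_target_matrix(
    config: SimulationConfig, truth: GroundTruth,
) -> GroundTruth:
    """Fill the drug-target matrix and monotone combination truth in place.

    Each compound hits each target independently (expected ~4 targets per
    drug), with at least one target guaranteed.  The true sensitivity of any
    inhibited target set is the normalized weight mass of the set, which is
    monotone under set inclusion, so supersets are never less sensitive.
    """
    if config.n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    rng = np.random.default_rng([config.seed, _STREAM_TARGETS])
    targets = [f"T{i:02d}" for i in range(1, config.n_targets + 1)]
    p_hit = min(1.0, 4.0 / config.n_targets)
    mat = (rng.random((len(truth.compounds), config.n_targets))
           < p_hit).astype(int)
    for i in range(mat.shape[0]):          # every drug needs >=1 target
        if mat[i].sum() == 0:
            mat[i, int(rng.integers(0, config.n_targets))] = 1
    truth.drug_targets = pd.DataFrame(mat, index=list(truth.compounds),
                                      columns=targets)
    w = rng.uniform(0.2, 1.0, config.n_targets)
    truth.target_weights = pd.Series(w, index=targets)
    # pairwise union weight = w(T1) + w(T2) - w(T1 & T2), vectorized
    per_drug = mat @ w
    inter = (mat * w) @ mat.T
    union = per_drug[:, None] + per_drug[None, :] - inter
    total = w.sum()
    sens: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(range(len(truth.compounds)), 2):
        sens[(truth.compounds[i], truth.compounds[j])] = float(
            min(1.0, union[i, j] / total))
    truth.true_combination_sensitivity = sens
    return truth


# ---------------------------------------------------------------------------
# benchmark instances for the synergy model and reversal-gene screen
# ---------------------------------------------------------------------------

def generate_timma_instance(
    n_drugs: int, n_targets: int, rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series, Callable[[Sequence[str]], float]]:
    """Random drug-target matrix with sensitivities from a monotone truth.

    Per-drug sensitivity is the truth evaluated at the drug's own target
    set (``y_d = f(targets(d))``), i.e. an instance of the model the
    target-inhibition predictor assumes, which makes its interval bounds and
    monotonicity exact properties rather than approximations.
    """
    targets = [f"T{i:02d}" for i in range(1, n_targets + 1)]
    drugs = [f"D{i:02d}" for i in range(1, n_drugs + 1)]
    mat = (rng.random((n_drugs, n_targets)) < 0.35).astype(int)
    for i in range(n_drugs):
        if mat[i].sum() == 0:
            mat[i, int(rng.integers(0, n_targets))] = 1
    weights = pd.Series(rng.uniform(0.1, 1.0, n_targets), index=targets)

    def truth_fn(target_set: Sequence[str]) -> float:
        return float(min(1.0, weights.loc[list(set(target_set))].sum()
                         / weights.sum()))

    matrix = pd.DataFrame(mat, index=drugs, columns=targets)
    y = pd.Series(
        [truth_fn(matrix.columns[matrix.loc[d] == 1]) for d in drugs],
        index=drugs)
    return matrix, y, truth_fn


def generate_reversal_benchmark(
    seed: int,
    n_genes: int = 978,
    n_sig_up: int = 53,
    n_sig_down: int = 42,
    n_planted_up: int = 2,
    n_planted_down: int = 2,
    n_active: int = 50,
    n_inactive: int = 48,
    shift: float = 0.3,
    permute_labels: bool = False,
) -> tuple[list[DrugProfile], DiseaseSignature, pd.Series, set[str]]:
    """Benchmark for the reversal-gene screen with exact planted rank shifts.

    Each compound gets one gold profile whose ranking realizes per-gene
    normalized positions drawn uniformly on (0, 1], except that in active
    compounds the planted up-genes are displaced toward the bottom by
    ``shift`` (``u -> min(u + shift, 1)``) and the planted down-genes
    toward the top (``u -> max(u - shift, 0)``), i.e. ``shift`` is the
    displacement of the active group's normalized rank.  Returns profiles,
    a disease signature containing the planted genes, active/inactive
    labels, and the planted gene set.

    With ``permute_labels`` the position shifts are still planted but the
    activity labels are assigned independently of them, giving a null screen
    for false-call calibration.
    """
    rng = np.random.default_rng([seed, 21])
    genes = gene_ids(n_genes)
    perm = rng.permutation(n_genes)
    up_genes = sorted(genes[i] for i in perm[:n_sig_up])
    down_genes = sorted(
        genes[i] for i in perm[n_sig_up:n_sig_up + n_sig_down])
    planted = set(up_genes[:n_planted_up]) | set(down_genes[:n_planted_down])
    up_planted_idx = [genes.index(g) for g in up_genes[:n_planted_up]]
    down_planted_idx = [genes.index(g) for g in down_genes[:n_planted_down]]

    n_cmpd = n_active + n_inactive
    compounds = compound_ids(n_cmpd)
    active = set(compounds[:n_active])
    labels = pd.Series(
        ["active" if c in active else "inactive" for c in compounds],
        index=compounds)
    shifted = set(compounds[:n_active])
    if permute_labels:
        # decouple the planted shift from the labels
        shuffled = rng.permutation(n_cmpd)
        labels = pd.Series(labels.to_numpy()[shuffled], index=compounds)

    profiles = []
    for k, compound in enumerate(compounds):
        pos = rng.uniform(0.0, 1.0, n_genes)
        if compound in shifted:
            pos[up_planted_idx] = np.minimum(pos[up_planted_idx] + shift,
                                             1.0)
            pos[down_planted_idx] = np.maximum(pos[down_planted_idx]
                                               - shift, 0.0)
        # ranking by value descending reproduces the planted positions;
        # tiny jitter de-duplicates positions clipped to the boundary
        values = -pos + rng.uniform(0.0, 1e-9, n_genes)
        profiles.append(DrugProfile(
            profile_id=f"prof{k + 1:05d}", compound=compound,
            cell_line="PC3", dose_um=10.0, duration_h=24.0, is_gold=True,
            values=pd.Series(values, index=genes)))

    sig_up = pd.DataFrame({"combined_log2fc": 2.0, "q": 1e-6},
                          index=pd.Index(up_genes, name="gene_id"))
    sig_down = pd.DataFrame({"combined_log2fc": -2.0, "q": 1e-6},
                            index=pd.Index(down_genes, name="gene_id"))
    signature = DiseaseSignature(up=sig_up, down=sig_down)
    return profiles, signature, labels, planted
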