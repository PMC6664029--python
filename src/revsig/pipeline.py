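"""End-to-end orchestration: simulate -> disease signature -> RGES ->
sRGES -> activity -> reversal genes -> synergy.

One config drives all stages; in synthetic mode every input is generated
(and written as TSV) from the root seed, in user mode the inputs are read
from the configured paths.  Each stage writes its outputs under the run
directory, the run report records summary counts and the full parameter
echo, and a fixed seed reproduces every output file byte for byte.  A
stage failure writes a ``FAILED_<stage>`` marker (partial outputs are
retained) and aborts with the stage name and cause.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .activity_integration import (aggregate_activity,
                                   classify_activity_table,
                                   evaluate_reversal_potency)
from .meta_signature import meta_signature_from_studies
from .reversal_genes import (heatmap_order, loco_reversal_genes,
                             normalized_rank_positions)
from .signature_scoring import score_profiles, summarize_rges
from .synergy_timma import (rank_combinations, rges_to_sensitivity,
                            synergy_matrix)
from .synthetic_data import (SimulationConfig, generate_activity_data,
                             generate_compound_profiles,
                             generate_disease_studies)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "meta_signature", "rges", "srges", "activity",
          "reversal_genes", "synergy")


@dataclass
class PipelineConfig:
    outdir: Path = Path("revsig_run")
    seed: int = 0
    synthetic: bool = True
    # user-mode input paths (ignored in synthetic mode)
    studies_dir: Path | None = None
    profiles_dir: Path | None = None
    activity_path: Path | None = None
    drug_targets_path: Path | None = None
    # thresholds
    q_deg: float = 0.001
    lfc: float = 1.5
    ic50_threshold_um: float = 10.0
    q_reversal: float = 0.25
    ref_dose_um: float = 10.0
    ref_duration_h: float = 24.0
    score_kind: str = "additive"
    n_synergy_drugs: int = 98
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        for name in ("q_deg", "lfc", "ic50_threshold_um", "q_reversal",
                     "ref_dose_um", "ref_duration_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.outdir = Path(self.outdir)
        object.__setattr__(self, "simulation",
                           _reseed(self.simulation, self.seed))

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)


def _reseed(sim: SimulationConfig, seed: int) -> SimulationConfig:
    if sim.seed == seed:
        return sim
    kw = asdict(sim)
    kw["seed"] = seed
    return SimulationConfig(**kw)


@dataclass
class RunReport:
    parameters: dict
    stages_completed: list[str]
    counts: dict
    outputs: dict


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    outputs: dict = {}
    completed: list[str] = []
    stage = "simulate"
    try:
        # ------------------------------------------------------- simulate
        if config.synthetic:
            studies, truth = generate_disease_studies(config.simulation)
            profiles = generate_compound_profiles(config.simulation, truth)
            activity = generate_activity_data(config.simulation, truth)
            targets = truth.drug_targets
            inputs = out / "inputs"
            io.write_studies(inputs, studies)
            io.write_profiles(inputs, profiles)
            io.write_activity(inputs / "activity.tsv", activity)
            io.write_drug_targets(inputs / "drug_targets.tsv", targets)
            outputs["inputs"] = str(inputs)
        else:
            studies = io.read_studies(config.studies_dir)
            profiles = io.read_profiles(config.profiles_dir)
            truth = None
        counts["studies"] = len(studies)
        counts["samples"] = int(sum(s.matrix.shape[1] for s in studies))
        counts["profiles"] = len(profiles)
        _done(completed, stage)

        # ------------------------------------------------- meta signature
        stage = "meta_signature"
        meta, signature = meta_signature_from_studies(
            studies, q_threshold=config.q_deg, fc_threshold=config.lfc)
        io.write_frame(out / "meta_stats.tsv", meta, index_label="gene_id")
        io.write_signature(out / "signature.tsv", signature)
        counts["degs_up"] = len(signature.up_genes)
        counts["degs_down"] = len(signature.down_genes)
        _done(completed, stage)

        # ------------------------------------------------------------ rges
        stage = "rges"
        rges = score_profiles(profiles, signature)
        rges.to_csv(out / "rges.tsv", sep="\t", index=False,
                    float_format="%.10g")
        counts["profiles_scored"] = len(rges)
        _done(completed, stage)

        # ----------------------------------------------------------- srges
        stage = "srges"
        srges = summarize_rges(rges, ref_dose=config.ref_dose_um,
                               ref_duration=config.ref_duration_h)
        srges.to_csv(out / "srges.tsv", sep="\t", index=False,
                     float_format="%.10g")
        counts["compounds_scored"] = len(srges)
        _done(completed, stage)

        # -------------------------------------------------------- activity
        stage = "activity"
        if config.synthetic:
            activity_df = activity
        else:
            activity_df = io.read_activity(config.activity_path)
        ic50 = aggregate_activity(
            activity_df[activity_df["measure"] == "IC50"])
        classes = classify_activity_table(ic50, config.ic50_threshold_um)
        io.write_frame(out / "activity_class.tsv", classes,
                       index_label="compound")
        srges_s = srges.set_index("compound")["srges"]
        evals = []
        for measure in sorted(activity_df["measure"].unique()):
            med = aggregate_activity(
                activity_df[activity_df["measure"] == measure])
            pc = evaluate_reversal_potency(srges_s, med)
            evals.append((measure, pc.rho, pc.p_value, pc.n))
        potency = pd.DataFrame(evals, columns=["measure", "rho", "p", "n"])
        potency.to_csv(out / "potency_eval.tsv", sep="\t", index=False,
                       float_format="%.10g")
        counts["active_compounds"] = int((classes["label"] == "active").sum())
        counts["inactive_compounds"] = int(
            (classes["label"] == "inactive").sum())
        counts["srges_ic50_spearman_rho"] = float(
            potency.loc[potency["measure"] == "IC50", "rho"].iloc[0])
        _done(completed, stage)

        # -------------------------------------------------- reversal genes
        stage = "reversal_genes"
        table = normalized_rank_positions(profiles, signature)
        table.positions = table.positions[
            [c for c in table.positions.columns if c in classes.index]]
        results, trial_q = loco_reversal_genes(
            table, classes["label"], q_threshold=config.q_reversal)
        io.write_frame(out / "reversal_genes.tsv", results,
                       index_label="gene_id")
        io.write_frame(out / "reversal_trial_q.tsv", trial_q,
                       index_label="gene_id")
        io.write_frame(out / "reversal_heatmap.tsv",
                       heatmap_order(table, ic50), index_label="gene_id")
        counts["reversal_genes"] = int(results["reversed"].sum())
        _done(completed, stage)

        # --------------------------------------------------------- synergy
        stage = "synergy"
        if config.synthetic:
            targets_df = targets
        else:
            targets_df = io.read_drug_targets(config.drug_targets_path)
        candidates = [c for c in srges["compound"] if c in targets_df.index]
        candidates = candidates[: config.n_synergy_drugs]
        y = rges_to_sensitivity(
            srges.set_index("compound")["srges"].loc[candidates])
        ranked = rank_combinations(targets_df.loc[candidates], y,
                                   score_kind=config.score_kind)
        ranked.to_csv(out / "synergy.tsv", sep="\t", index=False,
                      float_format="%.10g")
        io.write_frame(out / "synergy_matrix.tsv", synergy_matrix(ranked),
                       index_label="drug")
        counts["synergy_pairs"] = len(ranked)
        counts["top_pair"] = (f"{ranked.iloc[0]['drug_1']}+"
                              f"{ranked.iloc[0]['drug_2']}"
                              if len(ranked) else "")
        counts["top_pair_predicted_sensitivity"] = (
            float(ranked.iloc[0]["predicted_sensitivity"])
            if len(ranked) else float("nan"))
        _done(completed, stage)
    except Exception as exc:
        marker = out / f"FAILED_{stage}"
        marker.write_text(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    params = {
        "seed": config.seed, "q_deg": config.q_deg, "lfc": config.lfc,
        "ic50_threshold_um": config.ic50_threshold_um,
        "q_reversal": config.q_reversal,
        "ref_dose_um": config.ref_dose_um,
        "ref_duration_h": config.ref_duration_h,
        "score_kind": config.score_kind,
        "n_synergy_drugs": config.n_synergy_drugs,
        "synthetic": config.synthetic,
        "simulation": asdict(config.simulation) if config.synthetic else None,
    }
    for key in ("synergy.tsv", "srges.tsv", "rges.tsv", "signature.tsv",
                "meta_stats.tsv", "activity_class.tsv", "potency_eval.tsv",
                "reversal_genes.tsv"):
        outputs[key] = str(out / key)
    report = RunReport(parameters=params, stages_completed=completed,
                       counts=counts, outputs=outputs)
    (out / "report.json").write_text(
        json.dumps({"parameters": params, "stages_completed": completed,
                    "counts": counts, "outputs": sorted(outputs)},
                   indent=2, sort_keys=True, default=str) + "\n")
    manifest = sorted(str(p.relative_to(out)) for p in out.rglob("*")
                      if p.is_file())
    (out / "manifest.txt").write_text("\n".join(manifest) + "\n")
    return report


def _done(completed: list[str], stage: str) -> None:
    completed.append(stage)
    logger.info("stage %s complete", stage)
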