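"""TSV readers/writers for every pipeline artifact.

All files are plain tab-separated text.  Layout of a simulated input
directory::

    study01_GPL9000_expression.tsv   probe_id + one column per sample
    study01_GPL9000_labels.tsv       sample_id, group (tumor | normal)
    study01_GPL9000_probe_map.tsv    probe_id, gene_id
    ...
    profiles.tsv                     gene_id + one column per profile
    profile_meta.tsv                 profile_id, compound, cell_line,
                                     dose_um, duration_h, is_gold
    activity.tsv                     compound, cell_line, measure, value
    drug_targets.tsv                 drug x target 0/1 matrix
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .meta_signature import DiseaseSignature, ExpressionStudy
from .signature_scoring import DrugProfile

_FLOAT = "%.10g"


def write_frame(path: Path, frame: pd.DataFrame, index_label=None) -> None:
    frame.to_csv(path, sep="\t", float_format=_FLOAT,
                 index_label=index_label)


def write_studies(directory: Path,
                  studies: Sequence[ExpressionStudy]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(studies, start=1):
        stem = f"study{i:02d}_{s.platform_id}"
        write_frame(directory / f"{stem}_expression.tsv", s.matrix,
                    index_label="probe_id")
        s.labels.rename("group").to_frame().to_csv(
            directory / f"{stem}_labels.tsv", sep="\t",
            index_label="sample_id")
        if s.probe_map is not None:
            s.probe_map.rename("gene_id").to_frame().to_csv(
                directory / f"{stem}_probe_map.tsv", sep="\t",
                index_label="probe_id")


def read_studies(directory: Path) -> list[ExpressionStudy]:
    directory = Path(directory)
    studies = []
    for expr in sorted(directory.glob("study*_expression.tsv")):
        stem = expr.name[: -len("_expression.tsv")]
        platform = stem.split("_", 1)[1]
        matrix = pd.read_csv(expr, sep="\t", index_col=0)
        labels = pd.read_csv(directory / f"{stem}_labels.tsv", sep="\t",
                             index_col=0)["group"]
        pm_path = directory / f"{stem}_probe_map.tsv"
        probe_map = (pd.read_csv(pm_path, sep="\t", index_col=0)["gene_id"]
                     if pm_path.exists() else None)
        studies.append(ExpressionStudy(matrix=matrix, labels=labels,
                                       platform_id=platform,
                                       probe_map=probe_map))
    if not studies:
        raise FileNotFoundError(f"no study*_expression.tsv under "
                                f"{directory}")
    return studies


def write_profiles(directory: Path,
                   profiles: Sequence[DrugProfile]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    values = pd.DataFrame({p.profile_id: p.values for p in profiles})
    write_frame(directory / "profiles.tsv", values, index_label="gene_id")
    meta = pd.DataFrame(
        [(p.profile_id, p.compound, p.cell_line, p.dose_um, p.duration_h,
          int(p.is_gold)) for p in profiles],
        columns=["profile_id", "compound", "cell_line", "dose_um",
                 "duration_h", "is_gold"])
    meta.to_csv(directory / "profile_meta.tsv", sep="\t", index=False,
                float_format=_FLOAT)


def read_profiles(directory: Path) -> list[DrugProfile]:
    directory = Path(directory)
    values = pd.read_csv(directory / "profiles.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(directory / "profile_meta.tsv", sep="\t")
    profiles = []
    for _, r in meta.iterrows():
        profiles.append(DrugProfile(
            profile_id=r["profile_id"], compound=r["compound"],
            cell_line=r["cell_line"], dose_um=float(r["dose_um"]),
            duration_h=float(r["duration_h"]), is_gold=bool(r["is_gold"]),
            values=values[r["profile_id"]]))
    return profiles


def write_activity(path: Path, records: pd.DataFrame) -> None:
    records.to_csv(path, sep="\t", index=False, float_format=_FLOAT)


def read_activity(path: Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"activity table not found: {path}")
    return pd.read_csv(path, sep="\t")


def write_drug_targets(path: Path, matrix: pd.DataFrame) -> None:
    write_frame(Path(path), matrix, index_label="drug")


def read_drug_targets(path: Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"drug-target matrix not found: {path}")
    return pd.read_csv(path, sep="\t", index_col=0)


def write_signature(path: Path, signature: DiseaseSignature) -> None:
    rows = []
    for direction, table in (("up", signature.up), ("down", signature.down)):
        for gene, r in table.iterrows():
            rows.append((gene, direction, r["combined_log2fc"], r["q"]))
    pd.DataFrame(rows, columns=["gene_id", "direction", "combined_log2fc",
                                "q"]).to_csv(path, sep="\t", index=False,
                                             float_format=_FLOAT)


def read_signature(path: Path) -> DiseaseSignature:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signature table not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DiseaseSignature(
        up=df[df["direction"] == "up"][["combined_log2fc", "q"]],
        down=df[df["direction"] == "down"][["combined_log2fc", "q"]])
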