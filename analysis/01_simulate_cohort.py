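"""Simulate the full synthetic study: multi-platform tumor/normal
expression cohorts, landmark drug perturbation profiles, IC50/AUC activity
tables and the drug-target matrix, all with planted ground truth.

Writes the input TSVs under results/inputs/ and the planted truth summary
under results/ground_truth.tsv.
"""

from pathlib import Path

import pandas as pd

from revsig import io
from revsig.synthetic_data import (SimulationConfig, generate_activity_data,
                                   generate_compound_profiles,
                                   generate_disease_studies)

SEED = 2019
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    config = SimulationConfig(seed=SEED)
    studies, truth = generate_disease_studies(config)
    profiles = generate_compound_profiles(config, truth)
    activity = generate_activity_data(config, truth)

    inputs = RESULTS / "inputs"
    io.write_studies(inputs, studies)
    io.write_profiles(inputs, profiles)
    io.write_activity(inputs / "activity.tsv", activity)
    io.write_drug_targets(inputs / "drug_targets.tsv", truth.drug_targets)

    pd.DataFrame({
        "compound": list(truth.compounds),
        "is_reverser": [c in truth.reverser_compounds
                        for c in truth.compounds],
        "planted_rges": truth.planted_rges.to_numpy(),
        "true_ic50_um": truth.true_ic50.to_numpy(),
    }).to_csv(RESULTS / "ground_truth.tsv", sep="\t", index=False,
              float_format="%.10g")

    n_samples = sum(s.matrix.shape[1] for s in studies)
    print(f"simulated {len(studies)} studies, {n_samples} samples, "
          f"{config.n_genes} landmark genes")
    print(f"planted {len(truth.planted_up_genes)} up / "
          f"{len(truth.planted_down_genes)} down disease genes")
    print(f"{len(profiles)} drug profiles for {config.n_compounds} "
          f"compounds ({len(truth.reverser_compounds)} reversers)")
    print(f"inputs written to {inputs}")


if __name__ == "__main__":
    main()
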