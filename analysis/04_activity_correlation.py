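"""Aggregate compound activity (median IC50 across cell lines), classify
compounds against the 10 uM threshold, and correlate reversal potency
(sRGES) with measured activity for both IC50 and AUC.

Reads results/inputs/activity.tsv and results/srges.tsv; writes
results/activity_class.tsv and results/potency_eval.tsv.
"""

from pathlib import Path

import pandas as pd

from revsig import io
from revsig.activity_integration import (aggregate_activity,
                                         classify_activity_table,
                                         evaluate_reversal_potency)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = io.read_activity(RESULTS / "inputs" / "activity.tsv")
    srges = pd.read_csv(RESULTS / "srges.tsv", sep="\t").set_index(
        "compound")["srges"]

    ic50 = aggregate_activity(records[records["measure"] == "IC50"])
    classes = classify_activity_table(ic50)
    io.write_frame(RESULTS / "activity_class.tsv", classes,
                   index_label="compound")
    n_active = int((classes["label"] == "active").sum())
    print(f"{n_active} active / {len(classes) - n_active} inactive "
          "compounds (median IC50 vs 10 uM)")

    rows = []
    for measure in sorted(records["measure"].unique()):
        med = aggregate_activity(records[records["measure"] == measure])
        res = evaluate_reversal_potency(srges, med)
        rows.append((measure, res.rho, res.p_value, res.n))
        print(f"Spearman rho(sRGES, median {measure}) = {res.rho:.3f} "
              f"(p = {res.p_value:.3g}, n = {res.n})")
    pd.DataFrame(rows, columns=["measure", "rho", "p", "n"]).to_csv(
        RESULTS / "potency_eval.tsv", sep="\t", index=False,
        float_format="%.10g")


if __name__ == "__main__":
    main()
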