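"""Screen the disease signature for reversal genes: genes whose position
in compound-induced rankings shifts in the reversing direction between
active and inactive compounds, surviving a leave-one-compound-out screen
at adjusted P < 0.25 in every trial.

Reads results/inputs/, results/signature.tsv and
results/activity_class.tsv; writes results/reversal_genes.tsv, the
per-trial q matrix and the IC50-ordered heatmap table.
"""

from pathlib import Path

import pandas as pd

from revsig import io
from revsig.reversal_genes import (heatmap_order, loco_reversal_genes,
                                   normalized_rank_positions)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    signature = io.read_signature(RESULTS / "signature.tsv")
    profiles = io.read_profiles(RESULTS / "inputs")
    classes = pd.read_csv(RESULTS / "activity_class.tsv", sep="\t",
                          index_col=0)

    table = normalized_rank_positions(profiles, signature)
    table.positions = table.positions[
        [c for c in table.positions.columns if c in classes.index]]
    results, trial_q = loco_reversal_genes(table, classes["label"])
    io.write_frame(RESULTS / "reversal_genes.tsv", results,
                   index_label="gene_id")
    io.write_frame(RESULTS / "reversal_trial_q.tsv", trial_q,
                   index_label="gene_id")
    io.write_frame(RESULTS / "reversal_heatmap.tsv",
                   heatmap_order(table, classes["median_value"]),
                   index_label="gene_id")

    called = results[results["reversed"]]
    print(f"{len(called)}/{len(results)} signature genes reversed in all "
          f"{trial_q.shape[1]} leave-one-compound-out trials")
    worst = called.sort_values("worst_q").head(5)
    for gene, r in worst.iterrows():
        print(f"  {gene} ({r['direction']}): worst adjusted p = "
              f"{r['worst_q']:.3g}")


if __name__ == "__main__":
    main()
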