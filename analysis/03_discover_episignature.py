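"""Discover the episignature: matching, moderated statistics, selection.

Selects 4:1 matched controls for the discovery cases, fits the
cell-adjusted linear model per probe, shrinks variances by empirical
Bayes, adjusts with Benjamini-Hochberg, sweeps significance cutoffs and
keeps the probe set with the best case/control silhouette.  Compares the
selected set against the planted truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from episig import discovery, io
from episig.preprocess import CellProportions

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "analysis" / "cohort"
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main() -> None:
    filtered = io.read_beta_matrix(SCRATCH / "beta_filtered.tsv")
    sheet = io.read_sample_sheet(COHORT / "samples.csv")
    cell = CellProportions(io.read_table(SCRATCH / "cell_proportions.tsv"))
    truth = io.read_table(COHORT / "truth_planted.tsv")

    match = discovery.match_controls(
        sheet.where(group_label="case", cohort_role="discovery"),
        sheet.where(group_label="control"), ratio=4,
    )
    ids = match.case_ids + match.control_ids
    dmp = discovery.differential_methylation(
        filtered.select_samples(ids), sheet.subset(ids),
        CellProportions(cell.fractions.loc[ids]),
    )
    labels = np.array([r.group_label for r in sheet.subset(ids).records])
    probe_set = discovery.select_episignature(dmp, filtered.select_samples(ids), labels)

    io.write_table(dmp, SCRATCH / "dmp_table.tsv")
    match_df = pd.DataFrame(
        [(c, ctrl) for c, ctrls in sorted(match.matches.items()) for ctrl in ctrls],
        columns=["case_id", "control_id"],
    ).set_index("case_id")
    io.write_table(match_df, SCRATCH / "matches.tsv")

    RESULTS.mkdir(exist_ok=True)
    io.write_table(probe_set.selection_log.set_index("cutoff"),
                   RESULTS / "03_selection_log.tsv")
    sel = dmp.loc[probe_set.probes, ["delta_beta", "t", "adj_p", "direction"]].copy()
    sel["auc"] = probe_set.auc
    io.write_table(sel, RESULTS / "03_episignature_probes.tsv")

    planted = set(truth[truth["cohort"] == "case"].index) & set(filtered.probe_ids)
    chosen = set(probe_set.probes)
    recall = len(planted & chosen) / len(planted)
    precision = len(planted & chosen) / len(chosen)
    n_sig = int((dmp["adj_p"] < 0.05).sum())
    summary = pd.DataFrame(
        {"value": [n_sig, len(chosen), probe_set.cutoff, probe_set.score,
                   recall, precision]},
        index=pd.Index(["n_significant_fdr05", "n_selected", "chosen_cutoff",
                        "silhouette", "recall_vs_truth", "precision_vs_truth"],
                       name="metric"),
    )
    io.write_table(summary, RESULTS / "03_discovery_summary.tsv")
    hypo = (sel["direction"] == "hypo").mean()
    print(f"{n_sig} probes significant at FDR < 0.05")
    print(f"selected {len(chosen)} probes at cutoff {probe_set.cutoff:g} "
          f"(silhouette {probe_set.score:.3f}); {hypo:.1%} hypomethylated")
    print(f"vs planted truth: recall {recall:.3f}, precision {precision:.3f}")


if __name__ == "__main__":
    main()
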