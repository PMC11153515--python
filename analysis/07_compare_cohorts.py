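"""Cross-cohort comparison of the case signature against the
other-disorder cohorts.

Builds a signature (top-n DMPs, n = min(#significant, 500), plus a median
case-minus-control difference profile) for each cohort against its own
matched controls, computes the pairwise DMP overlap percentages, and
clusters the cohorts into a relatedness tree.
"""

from pathlib import Path

from episig import comparison, io
from episig.preprocess import CellProportions

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "analysis" / "cohort"
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main() -> None:
    filtered = io.read_beta_matrix(SCRATCH / "beta_filtered.tsv")
    sheet = io.read_sample_sheet(COHORT / "samples.csv")
    cell = CellProportions(io.read_table(SCRATCH / "cell_proportions.tsv"))

    cohorts = ["case"] + sorted(
        {r.group_label for r in sheet.records} - {"case", "control"}
    )
    sigs = [
        comparison.build_cohort_signature(name, filtered, sheet, cell)
        for name in cohorts
    ]
    for s in sigs:
        comparison.save_signature(s, SCRATCH / "signatures")

    mat = comparison.overlap_matrix(sigs)
    mat.index.name = "cohort"
    tree = comparison.cohort_tree(sigs)
    RESULTS.mkdir(exist_ok=True)
    io.write_table(mat, RESULTS / "07_overlap_matrix.tsv")
    io.write_table(comparison.shared_probe_pairs(sigs),
                   RESULTS / "07_shared_probes.tsv", index=False)
    (RESULTS / "07_cohort_tree.nwk").write_text(tree.newick + "\n")
    io.write_table(tree.attributes, RESULTS / "07_cohort_attributes.tsv")

    print("signature sizes: "
          + ", ".join(f"{s.cohort_id}={s.n_dmps}" for s in sigs))
    print("pairwise overlap (% of row cohort's probes found in column cohort):")
    print(mat.round(2).to_string())
    print(f"cohort tree: {tree.newick}")


if __name__ == "__main__":
    main()
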