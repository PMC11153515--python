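"""Genomic context of the episignature probes, and a DMR scan.

Annotates the selected probes against CpG islands (island / shore / shelf
/ open sea) and gene models (promoter, promoter+, UTRs, CDS, intron,
intergenic), alongside the background distribution of all filtered
probes, then scans for DMRs (>= 5 consecutive significant probes within
1 kb).
"""

from pathlib import Path

import pandas as pd

from episig import annotation as ann
from episig import io

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "analysis" / "cohort"
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main() -> None:
    manifest = io.read_manifest(COHORT / "manifest.tsv")
    cgis = io.read_bed(COHORT / "cgi.bed")
    genes = io.read_bed12(COHORT / "genes.bed12")
    dmp = io.read_table(SCRATCH / "dmp_table.tsv")
    probes = list(io.read_table(RESULTS / "03_episignature_probes.tsv").index)

    selected = manifest.subset(probes)
    background = manifest.subset(list(dmp.index))

    rows = []
    for name, sub in (("episignature", selected), ("background", background)):
        cgi_pct = ann.annotate_cgi_context(sub, cgis).summary_percent()
        gene_pct = ann.annotate_gene_context(sub, genes).summary_percent()
        for cat, pct in pd.concat([cgi_pct, gene_pct]).items():
            kind = "cgi" if cat in ann.CGI_CATEGORIES else "gene"
            rows.append((name, kind, cat, pct))
    summary = pd.DataFrame(rows, columns=["probe_set", "kind", "category", "percent"])
    RESULTS.mkdir(exist_ok=True)
    io.write_table(summary, RESULTS / "06_annotation_summary.tsv", index=False)

    dmrs = ann.detect_dmrs(dmp, background)
    sig_pct = summary[(summary.probe_set == "episignature") & (summary.kind == "cgi")]
    print("episignature CGI context (%):")
    for _, r in sig_pct.iterrows():
        print(f"  {r['category']}: {r['percent']:.1f}")
    print(f"DMRs (>=5 consecutive significant probes within 1 kb): {len(dmrs)}")


if __name__ == "__main__":
    main()
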