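"""CGI-context and gene-context annotation of probes, and DMR detection.

CpG-island context follows the standard island/shore/shelf geometry: a
probe is *island* when it lies inside a CpG island, *shore* within 0-2 kb
of an island boundary, *shelf* within 2-4 kb, and *inter_cgi* ("open sea")
otherwise; categories are mutually exclusive with precedence
island > shore > shelf > inter_cgi and distances are measured on the same
chromosome only.

Gene context is strand-aware: *promoter* covers 0-1 kb upstream of the
TSS, *promoter_plus* 1-5 kb upstream; UTRs and CDS derive from the BED12
thick coordinates; *intron* is inside the gene span but outside exons;
*intergenic* applies iff nothing else does.  A probe overlapping several
genes keeps all category memberships; summary percentages use a single
label under a declared precedence.

A DMR here is a run of at least ``min_probes`` consecutive (in the
position-sorted manifest) significant probes spanning at most ``max_span``
bp; overlapping qualifying windows are merged into maximal regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneModel, GenomicIntervalSet, ProbeManifest, ValidationError

__all__ = [
    "CGI_CATEGORIES",
    "GENE_CATEGORIES",
    "CGIContext",
    "GeneContext",
    "DMR",
    "annotate_cgi_context",
    "annotate_gene_context",
    "detect_dmrs",
    "SHORE_BP",
    "SHELF_BP",
    "PROMOTER_BP",
    "PROMOTER_PLUS_BP",
]

SHORE_BP = 2_000
SHELF_BP = 4_000
PROMOTER_BP = 1_000
PROMOTER_PLUS_BP = 5_000

CGI_CATEGORIES = ("island", "shore", "shelf", "inter_cgi")
GENE_CATEGORIES = (
    "promoter", "promoter_plus", "five_utr", "cds", "three_utr", "intron", "intergenic",
)


@dataclass
class CGIContext:
    """Per-probe island/shore/shelf/inter_cgi assignment with summary."""

    assignments: pd.Series  # probe_id -> category

    def summary_percent(self) -> pd.Series:
        counts = self.assignments.value_counts()
        out = pd.Series({c: float(counts.get(c, 0)) for c in CGI_CATEGORIES})
        return out / out.sum() * 100.0


@dataclass
class GeneContext:
    """Per-probe gene-context memberships plus a single-label summary."""

    memberships: pd.Series  # probe_id -> frozenset of categories
    labels: pd.Series       # probe_id -> single label under precedence

    def summary_percent(self) -> pd.Series:
        counts = self.labels.value_counts()
        out = pd.Series({c: float(counts.get(c, 0)) for c in GENE_CATEGORIES})
        return out / out.sum() * 100.0


def _merged_islands(cgis: GenomicIntervalSet, chrom: str) -> tuple[np.ndarray, np.ndarray]:
    sub = cgis.for_chrom(chrom)
    if len(sub) == 0:
        return np.array([]), np.array([])
    starts, ends = [], []
    cur_s, cur_e = None, None
    for s, e in zip(sub["start"], sub["end"]):
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            starts.append(cur_s)
            ends.append(cur_e)
            cur_s, cur_e = s, e
    starts.append(cur_s)
    ends.append(cur_e)
    return np.asarray(starts), np.asarray(ends)


def annotate_cgi_context(probes: ProbeManifest, cgis: GenomicIntervalSet) -> CGIContext:
    """Assign island/shore/shelf/inter_cgi to every manifest probe."""
    out = pd.Series(index=probes.df.index, dtype=object, name="cgi_context")
    for chrom, sub in probes.df.groupby("chrom", sort=False):
        pos0 = sub["pos"].to_numpy() - 1  # 0-based points
        starts, ends = _merged_islands(cgis, chrom)
        if len(starts) == 0:
            out.loc[sub.index] = "inter_cgi"
            continue
        idx = np.searchsorted(starts, pos0, side="right") - 1
        inside = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        # distance to the nearest island boundary (bp, >= 1 outside)
        left_gap = np.where(idx >= 0, pos0 - ends[np.clip(idx, 0, None)] + 1, np.inf)
        nxt = np.clip(idx + 1, 0, len(starts) - 1)
        right_gap = np.where(idx + 1 < len(starts), starts[nxt] - pos0, np.inf)
        dist = np.minimum(left_gap, right_gap)
        cat = np.full(len(sub), "inter_cgi", dtype=object)
        cat[dist <= SHELF_BP] = "shelf"
        cat[dist <= SHORE_BP] = "shore"
        cat[inside] = "island"
        out.loc[sub.index] = cat
    return CGIContext(assignments=out)


def _gene_categories_for_probe(p0: int, gene) -> set[str]:
    cats: set[str] = set()
    if gene.strand == "+":
        if gene.start - PROMOTER_BP <= p0 < gene.start:
            cats.add("promoter")
        elif gene.start - PROMOTER_PLUS_BP <= p0 < gene.start - PROMOTER_BP:
            cats.add("promoter_plus")
    else:
        if gene.end <= p0 < gene.end + PROMOTER_BP:
            cats.add("promoter")
        elif gene.end + PROMOTER_BP <= p0 < gene.end + PROMOTER_PLUS_BP:
            cats.add("promoter_plus")
    if gene.start <= p0 < gene.end:
        exonic = any(s <= p0 < e for s, e in gene.exons)
        coding = gene.thick_start < gene.thick_end
        if exonic and coding:
            if gene.thick_start <= p0 < gene.thick_end:
                cats.add("cds")
            elif p0 < gene.thick_start:
                cats.add("five_utr" if gene.strand == "+" else "three_utr")
            else:
                cats.add("three_utr" if gene.strand == "+" else "five_utr")
        else:
            # non-exonic (or non-coding exon): inside the gene body
            cats.add("intron")
    return cats


def annotate_gene_context(probes: ProbeManifest, genes: GeneModel) -> GeneContext:
    """Strand-aware gene-context annotation of every manifest probe."""
    members = {p: set() for p in probes.df.index}
    for chrom, sub in probes.df.groupby("chrom", sort=False):
        pos0 = sub["pos"].to_numpy() - 1
        order = np.argsort(pos0)
        sorted_pos = pos0[order]
        ids = sub.index.to_numpy()[order]
        for gene in genes.for_chrom(chrom):
            lo = gene.start - PROMOTER_PLUS_BP
            hi = gene.end + PROMOTER_PLUS_BP
            i0 = np.searchsorted(sorted_pos, lo, side="left")
            i1 = np.searchsorted(sorted_pos, hi, side="right")
            for p0, pid in zip(sorted_pos[i0:i1], ids[i0:i1]):
                cats = _gene_categories_for_probe(int(p0), gene)
                if cats:
                    members[pid].update(cats)
    memberships = pd.Series(
        {p: frozenset(c) if c else frozenset({"intergenic"}) for p, c in members.items()},
        name="gene_context",
    ).reindex(probes.df.index)
    precedence = [c for c in GENE_CATEGORIES if c != "intergenic"]

    def label(cats: frozenset) -> str:
        for c in precedence:
            if c in cats:
                return c
        return "intergenic"

    labels = memberships.map(label).rename("gene_label")
    return GeneContext(memberships=memberships, labels=labels)


@dataclass
class DMR:
    """Maximal region of consecutive significant probes."""

    chrom: str
    start: int  # 0-based half-open hull of member probe positions
    end: int
    probe_ids: list
    mean_delta_beta: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError("DMR start must be < end")


def detect_dmrs(dmp_table: pd.DataFrame, manifest: ProbeManifest,
                min_probes: int = 5, max_span: int = 1_000,
                alpha: float = 0.05) -> list[DMR]:
    """Scan position-sorted probes for runs of consecutive significant DMPs.

    "Consecutive" means adjacent in the position-sorted manifest with no
    intervening non-significant probe; a window of >= ``min_probes`` such
    probes whose positional span (max - min) is <= ``max_span`` bp
    qualifies, and overlapping qualifying windows merge into maximal DMRs.
    """
    missing = dmp_table.index.difference(manifest.df.index)
    if len(missing):
        raise ValidationError(f"DMP probes absent from manifest: {list(missing[:5])}")
    mdf = manifest.df.loc[manifest.df.index.intersection(dmp_table.index)]
    sig = dmp_table["adj_p"] < alpha
    out: list[DMR] = []
    for chrom, sub in mdf.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="mergesort")
        ids = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        sig_mask = sig.reindex(ids).to_numpy()
        # maximal runs of consecutive significant probes
        i = 0
        n = len(ids)
        while i < n:
            if not sig_mask[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and sig_mask[j + 1]:
                j += 1
            run_ids = ids[i:i + (j - i) + 1]
            run_pos = pos[i:j + 1]
            # qualifying windows within the run, merged
            windows = []
            for a in range(len(run_pos)):
                b = a
                while b + 1 < len(run_pos) and run_pos[b + 1] - run_pos[a] <= max_span:
                    b += 1
                if b - a + 1 >= min_probes:
                    windows.append((a, b))
            merged = []
            for a, b in windows:
                if merged and a <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], b))
                else:
                    merged.append((a, b))
            for a, b in merged:
                member = list(run_ids[a:b + 1])
                out.append(
                    DMR(
                        chrom=chrom,
                        start=int(run_pos[a] - 1),
                        end=int(run_pos[b]),
                        probe_ids=member,
                        mean_delta_beta=float(dmp_table.loc[member, "delta_beta"].mean()),
                    )
                )
            i = j + 1
    return out
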