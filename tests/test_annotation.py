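"""Hand-computed CGI/gene-context fixtures and the DMR window caller."""

import numpy as np
import pandas as pd
import pytest

from episig import annotation as ann
from episig import io


def _manifest(rows):
    df = pd.DataFrame(
        rows, columns=["probe_id", "chrom", "pos", "strand", "snp_overlap", "cross_reactive"]
    ).set_index("probe_id")
    return io.ProbeManifest(df)


@pytest.fixture()
def island():
    # one island on chr1 covering 0-based [1000, 2000)
    return io.GenomicIntervalSet(
        pd.DataFrame([("chr1", 1000, 2000, "cgi1")],
                     columns=["chrom", "start", "end", "name"])
    )


class TestCGIContext:
    def test_hand_built_distances(self, island):
        # positions are 1-based; distances measured from the island boundary
        manifest = _manifest([
            ("p_island", "chr1", 1500, "+", 0, 0),   # inside
            ("p_shore", "chr1", 3500, "+", 0, 0),    # 1,500 bp downstream
            ("p_shelf", "chr1", 5500, "+", 0, 0),    # 3,500 bp downstream
            ("p_open", "chr1", 8001, "+", 0, 0),     # 6,000 bp downstream
            ("p_up_shore", "chr1", 900, "+", 0, 0),  # 100 bp upstream
            ("p_offchrom", "chr9", 1500, "+", 0, 0),
        ])
        ctx = ann.annotate_cgi_context(manifest, island)
        assert ctx.assignments.to_dict() == {
            "p_island": "island",
            "p_shore": "shore",
            "p_shelf": "shelf",
            "p_open": "inter_cgi",
            "p_up_shore": "shore",
            "p_offchrom": "inter_cgi",
        }

    def test_boundary_distances_exact(self, island):
        manifest = _manifest([
            ("p_2000", "chr1", 4000, "+", 0, 0),  # exactly 2,000 bp -> shore
            ("p_2001", "chr1", 4001, "+", 0, 0),  # 2,001 bp -> shelf
            ("p_4000", "chr1", 6000, "+", 0, 0),  # exactly 4,000 bp -> shelf
            ("p_4001", "chr1", 6001, "+", 0, 0),  # 4,001 bp -> open sea
        ])
        ctx = ann.annotate_cgi_context(manifest, island)
        assert list(ctx.assignments) == ["shore", "shelf", "shelf", "inter_cgi"]

    def test_percentages_sum_to_100(self, island):
        manifest = _manifest([
            (f"p{i}", "chr1", 100 * i + 1, "+", 0, 0) for i in range(1, 80)
        ])
        ctx = ann.annotate_cgi_context(manifest, island)
        assert ctx.summary_percent().sum() == pytest.approx(100.0, abs=0.1)

    def test_invariant_to_interval_order(self, island):
        shuffled = io.GenomicIntervalSet(
            pd.DataFrame(
                [("chr1", 5000, 5400, "b"), ("chr1", 1000, 2000, "a")],
                columns=["chrom", "start", "end", "name"],
            )
        )
        manifest = _manifest([(f"p{i}", "chr1", 500 * i + 1, "+", 0, 0) for i in range(1, 20)])
        a = ann.annotate_cgi_context(manifest, shuffled).assignments
        b = ann.annotate_cgi_context(manifest, island).assignments
        # the extra island can only tighten categories, never scramble them
        assert set(a.index) == set(b.index)
        assert (a.loc[b[b == "island"].index] == "island").all()


@pytest.fixture()
def gene_model():
    plus = io.GeneRecord(
        chrom="chr1", start=10_000, end=20_000, name="genePlus", strand="+",
        thick_start=11_000, thick_end=18_000,
        exons=[(10_000, 12_000), (15_000, 20_000)],
    )
    minus = io.GeneRecord(
        chrom="chr2", start=30_000, end=40_000, name="geneMinus", strand="-",
        thick_start=31_000, thick_end=39_000,
        exons=[(30_000, 40_000)],
    )
    return io.GeneModel([plus, minus])


class TestGeneContext:
    def test_hand_built_plus_strand(self, gene_model):
        manifest = _manifest([
            ("p_prom", "chr1", 9_501, "+", 0, 0),       # 500 bp upstream of TSS
            ("p_promplus", "chr1", 7_001, "+", 0, 0),   # 3 kb upstream
            ("p_5utr", "chr1", 10_501, "+", 0, 0),      # exonic, before CDS
            ("p_cds", "chr1", 11_501, "+", 0, 0),       # exonic, in CDS
            ("p_intron", "chr1", 13_001, "+", 0, 0),    # between the exons
            ("p_3utr", "chr1", 19_001, "+", 0, 0),      # exonic, after CDS
            ("p_free", "chr9", 5_000, "+", 0, 0),       # gene-free contig
        ])
        ctx = ann.annotate_gene_context(manifest, gene_model)
        assert ctx.labels.to_dict() == {
            "p_prom": "promoter",
            "p_promplus": "promoter_plus",
            "p_5utr": "five_utr",
            "p_cds": "cds",
            "p_intron": "intron",
            "p_3utr": "three_utr",
            "p_free": "intergenic",
        }

    def test_minus_strand_promoter_is_downstream_in_coordinates(self, gene_model):
        manifest = _manifest([
            ("p_prom", "chr2", 40_501, "+", 0, 0),      # 500 bp past end -> promoter
            ("p_promplus", "chr2", 43_001, "+", 0, 0),  # 3 kb past end
            ("p_5utr", "chr2", 39_501, "+", 0, 0),      # exonic, 3' in coords = 5' UTR
            ("p_3utr", "chr2", 30_501, "+", 0, 0),
        ])
        ctx = ann.annotate_gene_context(manifest, gene_model)
        assert list(ctx.labels) == ["promoter", "promoter_plus", "five_utr", "three_utr"]

    def test_overlapping_gene_memberships_all_reported(self):
        a = io.GeneRecord("chr1", 1_000, 9_000, "A", "+", 2_000, 8_000,
                          exons=[(1_000, 9_000)])
        b = io.GeneRecord("chr1", 4_000, 12_000, "B", "+", 5_000, 11_000,
                          exons=[(4_000, 12_000)])
        manifest = _manifest([("p", "chr1", 6_001, "+", 0, 0)])
        ctx = ann.annotate_gene_context(manifest, io.GeneModel([a, b]))
        assert ctx.memberships.iloc[0] == frozenset({"cds"})
        manifest2 = _manifest([("p", "chr1", 3_501, "+", 0, 0)])
        ctx2 = ann.annotate_gene_context(manifest2, io.GeneModel([a, b]))
        # in A's CDS and in B's promoter simultaneously
        assert ctx2.memberships.iloc[0] == frozenset({"cds", "promoter"})
        assert ctx2.labels.iloc[0] == "promoter"  # precedence


def _dmp(rows):
    df = pd.DataFrame(rows, columns=["probe_id", "delta_beta", "adj_p"]).set_index("probe_id")
    df["t"] = 0.0
    df["p"] = df["adj_p"]
    df["direction"] = np.where(df["delta_beta"] < 0, "hypo", "hyper")
    return df


def _dmr_brute_force(dmp, manifest, min_probes=5, max_span=1000, alpha=0.05):
    """Enumerate every window of position-consecutive probes, keep those with
    all probes significant, >= min_probes members and span <= max_span; merge
    overlapping windows."""
    out = []
    for chrom, sub in manifest.df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        ids = list(sub.index)
        pos = list(sub["pos"])
        sig = [dmp.loc[i, "adj_p"] < alpha for i in ids]
        windows = []
        for i in range(len(ids)):
            for j in range(i + min_probes - 1, len(ids)):
                if not all(sig[i:j + 1]):
                    continue
                if pos[j] - pos[i] <= max_span:
                    windows.append((i, j))
        merged = []
        for i, j in sorted(windows):
            if merged and i <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], j))
            else:
                merged.append((i, j))
        for i, j in merged:
            out.append((chrom, pos[i] - 1, pos[j], tuple(ids[i:j + 1])))
    return sorted(out)


class TestDetectDMRs:
    def test_five_consecutive_within_900bp_is_one_dmr(self):
        manifest = _manifest([
            (f"p{i}", "chr1", 1_000 + i * 225, "+", 0, 0) for i in range(5)
        ])
        dmp = _dmp([(f"p{i}", -0.1, 1e-6) for i in range(5)])
        dmrs = ann.detect_dmrs(dmp, manifest)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert len(d.probe_ids) == 5 and d.end - d.start == 900 + 1
        assert d.mean_delta_beta == pytest.approx(-0.1)

    def test_five_probes_spanning_1200bp_no_dmr(self):
        manifest = _manifest([
            (f"p{i}", "chr1", 1_000 + i * 300, "+", 0, 0) for i in range(5)
        ])
        dmp = _dmp([(f"p{i}", -0.1, 1e-6) for i in range(5)])
        assert ann.detect_dmrs(dmp, manifest) == []

    def test_four_probes_below_minimum(self):
        manifest = _manifest([
            (f"p{i}", "chr1", 1_000 + i * 50, "+", 0, 0) for i in range(4)
        ])
        dmp = _dmp([(f"p{i}", -0.1, 1e-6) for i in range(4)])
        assert ann.detect_dmrs(dmp, manifest) == []

    def test_intervening_nonsignificant_probe_breaks_the_run(self):
        rows, dmps = [], []
        for i in range(9):
            rows.append((f"p{i}", "chr1", 1_000 + i * 100, "+", 0, 0))
            dmps.append((f"p{i}", -0.1, 0.5 if i == 4 else 1e-6))
        assert ann.detect_dmrs(_dmp(dmps), _manifest(rows)) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_window_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        pos = np.sort(rng.choice(np.arange(1, 5_000), size=n, replace=False))
        rows = [(f"p{i}", "chr1", int(pos[i]), "+", 0, 0) for i in range(n)]
        dmps = [(f"p{i}", -0.1, 1e-6 if rng.random() < 0.6 else 0.5) for i in range(n)]
        manifest, dmp = _manifest(rows), _dmp(dmps)
        got = sorted(
            (d.chrom, d.start, d.end, tuple(d.probe_ids))
            for d in ann.detect_dmrs(dmp, manifest)
        )
        assert got == _dmr_brute_force(dmp, manifest)

    def test_planted_signature_yields_no_dmrs(self, default_study):
        # planted probes are scattered, mirroring a DMR-free episignature
        st = default_study
        dmrs = ann.detect_dmrs(st.dmp, st.manifest.subset(list(st.dmp.index)))
        assert dmrs == []
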