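"""End-to-end orchestration: configuration, stage sequencing, audit trail.

``run_discovery_pipeline`` executes preprocess -> match -> differential
methylation -> probe selection -> SVM training -> annotation in order,
writing every table under the output directory with the configuration hash
embedded in a header comment.  All randomness flows from ``config.seed``,
so re-running with an identical configuration reproduces byte-identical
outputs (stage timings go only to the log file, which is excluded from the
output manifest).

``run_validation_pipeline`` scores held-out validation samples with a
frozen model and re-embeds discovery + validation samples by MDS and
hierarchical clustering on the frozen probe set, reporting per-sample MVP
scores and co-clustering with the discovery cases.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import pdist, squareform

from . import annotation as ann
from . import classifier, discovery, io, preprocess

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "PipelineResult",
    "run_discovery_pipeline",
    "run_validation_pipeline",
]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for auditability."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths to all inputs plus every exposed threshold of the workflow."""

    beta_path: str = ""
    detection_p_path: str = ""
    sheet_path: str = ""
    manifest_path: str = ""
    cgi_path: str = ""
    genes_path: str = ""
    cell_reference_path: str = ""
    out_dir: str = "episig_out"

    detection_p_threshold: float = 0.1
    dmp_alpha: float = 0.05
    mvp_high_score: float = 0.75
    holdout_rounds: int = 20
    holdout_frac: float = 0.25
    top_n_cap: int = 500
    dmr_min_probes: int = 5
    dmr_max_span: int = 1_000
    shore_bp: int = 2_000
    shelf_bp: int = 4_000
    promoter_bp: int = 1_000
    promoter_plus_bp: int = 5_000
    match_ratio: int = 4
    cutoff_grid: tuple = discovery.DEFAULT_CUTOFF_GRID
    r_max: float = 0.9
    partition_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "detection_p_threshold", "dmp_alpha", "mvp_high_score", "holdout_rounds",
            "holdout_frac", "top_n_cap", "dmr_min_probes", "dmr_max_span", "shore_bp",
            "shelf_bp", "promoter_bp", "promoter_plus_bp", "match_ratio", "r_max",
            "partition_fraction",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise io.ValidationError(f"config.{name} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cutoff_grid"] = list(self.cutoff_grid)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if "cutoff_grid" in d:
            d["cutoff_grid"] = tuple(d["cutoff_grid"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        # out_dir is where results land, not what they are — excluded
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def for_directory(cls, input_dir, out_dir, **overrides) -> "PipelineConfig":
        """Point every input path at the artifact names used by the
        simulator/CLI inside ``input_dir``."""
        d = Path(input_dir)
        return cls(
            beta_path=str(d / "beta.tsv"),
            detection_p_path=str(d / "detection_p.tsv"),
            sheet_path=str(d / "samples.csv"),
            manifest_path=str(d / "manifest.tsv"),
            cgi_path=str(d / "cgi.bed"),
            genes_path=str(d / "genes.bed12"),
            cell_reference_path=str(d / "cell_reference.tsv"),
            out_dir=str(out_dir),
            **overrides,
        )


@dataclass
class PipelineResult:
    config: PipelineConfig
    filtered_beta: io.BetaMatrix = field(repr=False)
    filter_report: preprocess.FilterReport = field(repr=False)
    cell_proportions: preprocess.CellProportions = field(repr=False)
    flagged_outliers: list = field(repr=False)
    match: discovery.MatchResult = field(repr=False)
    dmp_table: pd.DataFrame = field(repr=False)
    probe_set: discovery.EpisignatureProbeSet = field(repr=False)
    model: classifier.MVPModel = field(repr=False)
    scores: pd.Series = field(repr=False)
    dmrs: list = field(repr=False)
    out_dir: Path = None


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


def _header(config: PipelineConfig, stage: str) -> list[str]:
    return [f"config_hash={config.config_hash}", f"stage={stage} version=1"]


def run_discovery_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full discovery workflow and write all artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"config_hash={config.config_hash}"]
    t_start = time.perf_counter()

    def log(msg):
        log_lines.append(f"[{time.perf_counter() - t_start:8.2f}s] {msg}")

    # ---- load ------------------------------------------------------------
    load = _stage("load")(lambda: (
        io.read_beta_matrix(config.beta_path),
        io.read_detection_p_matrix(config.detection_p_path) if config.detection_p_path else None,
        io.read_sample_sheet(config.sheet_path),
        io.read_manifest(config.manifest_path),
        io.read_bed(config.cgi_path) if config.cgi_path else None,
        io.read_bed12(config.genes_path) if config.genes_path else None,
        io.read_cell_reference(config.cell_reference_path) if config.cell_reference_path else None,
    ))
    beta, detp, sheet, manifest, cgis, genes, cellref = load()
    log(f"loaded {beta.shape[0]} probes x {beta.shape[1]} samples")

    # ---- preprocess ------------------------------------------------------
    @_stage("preprocess")
    def do_preprocess():
        filtered, report = preprocess.filter_probes(
            beta, manifest, detp, p_threshold=config.detection_p_threshold
        )
        cp = preprocess.estimate_cell_proportions(filtered, cellref) if cellref else None
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            flagged = preprocess.pca_outlier_screen(filtered)
        return filtered, report, cp, flagged

    filtered, report, cell_props, flagged = do_preprocess()
    log(f"filter: retained {report.retained}/{report.n_input} "
        f"(removed {report.removed})")
    if flagged:
        log(f"PCA outlier screen flagged (warning only): {flagged}")

    # ---- match -----------------------------------------------------------
    @_stage("match")
    def do_match():
        cases = sheet.where(group_label="case", cohort_role="discovery")
        pool = sheet.where(group_label="control")
        return discovery.match_controls(cases, pool, ratio=config.match_ratio)

    match = do_match()
    log(f"matched {len(match.case_ids)} cases at ratio {match.ratio}")

    # ---- differential methylation ---------------------------------------
    @_stage("differential_methylation")
    def do_dm():
        model_ids = match.case_ids + match.control_ids
        model_sheet = sheet.subset(model_ids)
        model_beta = filtered.select_samples(model_ids)
        cp = None
        if cell_props is not None:
            cp = preprocess.CellProportions(cell_props.fractions.loc[model_ids])
        return discovery.differential_methylation(model_beta, model_sheet, cp), model_sheet, model_beta

    dmp, model_sheet, model_beta = do_dm()
    n_sig = int((dmp["adj_p"] < config.dmp_alpha).sum())
    log(f"differential methylation: {n_sig} probes at adj_p < {config.dmp_alpha}")

    # ---- selection -------------------------------------------------------
    @_stage("selection")
    def do_select():
        labels = np.array([r.group_label for r in model_sheet.records])
        return discovery.select_episignature(
            dmp, model_beta, labels, cutoff_grid=config.cutoff_grid, r_max=config.r_max
        )

    probe_set = do_select()
    log(f"selected {len(probe_set)} probes (cutoff {probe_set.cutoff}, "
        f"silhouette {probe_set.score:.3f}, significant={probe_set.significant})")

    # ---- training --------------------------------------------------------
    @_stage("train")
    def do_train():
        partition = classifier.assemble_training_partition(
            sheet, match, fraction=config.partition_fraction, seed=config.seed
        )
        model = classifier.train_mvp(filtered, partition, probe_set)
        scores = classifier.score_mvp(model, filtered)
        return partition, model, scores

    partition, model, scores = do_train()
    log(f"trained SVM on {len(partition.train_ids)} samples; "
        f"{len(partition.test_ids)} reserved for testing")

    # ---- annotation ------------------------------------------------------
    @_stage("annotate")
    def do_annotate():
        sel_manifest = manifest.subset(probe_set.probes) if probe_set.probes else None
        cgi_ctx = ann.annotate_cgi_context(sel_manifest, cgis) if (sel_manifest and cgis) else None
        gene_ctx = ann.annotate_gene_context(sel_manifest, genes) if (sel_manifest and genes) else None
        dmrs = ann.detect_dmrs(
            dmp, manifest.subset(list(dmp.index)),
            min_probes=config.dmr_min_probes, max_span=config.dmr_max_span,
            alpha=config.dmp_alpha,
        )
        return cgi_ctx, gene_ctx, dmrs

    cgi_ctx, gene_ctx, dmrs = do_annotate()
    log(f"annotation done; {len(dmrs)} DMRs detected")

    # ---- embedding -------------------------------------------------------
    @_stage("embed")
    def do_embed():
        val_ids = [r.sample_id for r in sheet.records
                   if r.group_label == "case" and r.cohort_role == "validation"]
        embed_ids = match.case_ids + match.control_ids + [
            v for v in val_ids if v in filtered.values.columns
        ]
        X = filtered.select_probes(probe_set.probes).values[embed_ids].to_numpy().T
        D = squareform(pdist(X, metric="euclidean"))
        mds = discovery.classical_mds(D, k=2, labels=embed_ids)
        dend = discovery.hierarchical_clustering(X, labels=embed_ids)
        return embed_ids, mds, dend

    embed_ids, mds, dend = do_embed()

    # ---- write artifacts -------------------------------------------------
    @_stage("write")
    def do_write():
        h = lambda s: _header(config, s)
        io.write_table(report.to_frame(), out / "filter_report.tsv", header_comments=h("preprocess"))
        if cell_props is not None:
            io.write_table(cell_props.fractions, out / "cell_proportions.tsv",
                           header_comments=h("preprocess"))
        match_df = pd.DataFrame(
            [(c, i + 1, ctrl) for c, ctrls in sorted(match.matches.items())
             for i, ctrl in enumerate(ctrls)],
            columns=["case_id", "rank", "control_id"],
        ).set_index("case_id")
        io.write_table(match_df, out / "matches.tsv", header_comments=h("match"))
        io.write_table(dmp, out / "dmp_table.tsv", header_comments=h("differential_methylation"))
        sel = pd.DataFrame({"probe_id": probe_set.probes}).set_index("probe_id")
        sel["auc"] = probe_set.auc
        io.write_table(sel, out / "episignature_probes.tsv", header_comments=h("selection"))
        io.write_table(probe_set.selection_log.set_index("cutoff"),
                       out / "selection_log.tsv", header_comments=h("selection"))
        coords = mds.coords.copy()
        role_of = {r.sample_id: r.cohort_role for r in sheet.records}
        group_of = {r.sample_id: r.group_label for r in sheet.records}
        coords["group_label"] = [group_of[s] for s in coords.index]
        coords["cohort_role"] = [role_of[s] for s in coords.index]
        io.write_table(coords, out / "mds.tsv", header_comments=h("embed"))
        (out / "dendrogram.nwk").write_text(dend.to_newick() + "\n", encoding="utf-8")
        score_df = scores.to_frame()
        score_df["group_label"] = [group_of[s] for s in score_df.index]
        score_df["cohort_role"] = [role_of[s] for s in score_df.index]
        score_df["in_training"] = score_df.index.isin(partition.train_ids)
        score_df.index.name = "sample_id"
        io.write_table(score_df, out / "mvp_scores.tsv", header_comments=h("train"))
        if cgi_ctx is not None and gene_ctx is not None:
            per_probe = pd.DataFrame({
                "cgi_context": cgi_ctx.assignments,
                "gene_label": gene_ctx.labels,
                "gene_context": gene_ctx.memberships.map(lambda s: ",".join(sorted(s))),
            })
            per_probe.index.name = "probe_id"
            io.write_table(per_probe, out / "annotation.tsv", header_comments=h("annotate"))
            summary = pd.concat([
                cgi_ctx.summary_percent().rename("percent").to_frame().assign(kind="cgi"),
                gene_ctx.summary_percent().rename("percent").to_frame().assign(kind="gene"),
            ])
            summary.index.name = "category"
            io.write_table(summary, out / "annotation_summary.tsv", header_comments=h("annotate"))
        dmr_df = pd.DataFrame(
            [(d.chrom, d.start, d.end, len(d.probe_ids), d.mean_delta_beta) for d in dmrs],
            columns=["chrom", "start", "end", "n_probes", "mean_delta_beta"],
        )
        io.write_table(dmr_df, out / "dmrs.tsv", header_comments=h("annotate"), index=False)
        (out / "model.json").write_text(
            json.dumps(model.to_dict(), sort_keys=True, indent=1) + "\n", encoding="utf-8"
        )
        config.to_yaml(out / "config.yaml")
        written = [
            "filter_report.tsv", "matches.tsv", "dmp_table.tsv",
            "episignature_probes.tsv", "selection_log.tsv", "mds.tsv",
            "dendrogram.nwk", "mvp_scores.tsv", "dmrs.tsv", "model.json",
        ]
        if cell_props is not None:
            written.append("cell_proportions.tsv")
        if cgi_ctx is not None and gene_ctx is not None:
            written += ["annotation.tsv", "annotation_summary.tsv"]
        # the log carries timings and config.yaml the output location;
        # neither is part of the deterministic scientific output
        manifest_hash = {
            name: hashlib.sha256((out / name).read_bytes()).hexdigest()
            for name in sorted(written)
        }
        (out / "output_manifest.json").write_text(
            json.dumps(manifest_hash, sort_keys=True, indent=1) + "\n", encoding="utf-8"
        )

    do_write()
    log("artifacts written")
    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")

    return PipelineResult(
        config=config, filtered_beta=filtered, filter_report=report,
        cell_proportions=cell_props, flagged_outliers=flagged, match=match,
        dmp_table=dmp, probe_set=probe_set, model=model, scores=scores,
        dmrs=dmrs, out_dir=out,
    )


def run_validation_pipeline(config: PipelineConfig, model_dir=None) -> pd.DataFrame:
    """Score validation-role cases with a frozen model and check that each
    co-clusters with the discovery cases on the frozen probe set.

    Returns a per-sample report (MVP score, cluster assignment,
    co-clustering flag) and writes it to ``<out_dir>/validation_report.tsv``.
    """
    model_dir = Path(model_dir if model_dir is not None else config.out_dir)
    model_path = model_dir / "model.json"
    if not model_path.exists():
        raise PipelineError("validation", f"no trained model at {model_path}")
    model = classifier.MVPModel.from_dict(json.loads(model_path.read_text()))

    beta = io.read_beta_matrix(config.beta_path)
    sheet = io.read_sample_sheet(config.sheet_path)
    val_ids = [r.sample_id for r in sheet.records
               if r.group_label == "case" and r.cohort_role == "validation"]
    if not val_ids:
        raise PipelineError("validation", "validation set is empty")
    disc_ids = [r.sample_id for r in sheet.records
                if r.group_label == "case" and r.cohort_role == "discovery"]
    ctrl_ids = [r.sample_id for r in sheet.records if r.group_label == "control"]
    # embed discovery cases, an equal-size control draw (deterministic: first
    # in sheet order), and the validation cases on the frozen probes
    ctrl_use = ctrl_ids[: max(len(disc_ids) * 2, 10)]
    embed_ids = disc_ids + ctrl_use + val_ids
    sub = beta.select_samples(embed_ids).select_probes(model.probes)
    X = sub.values.to_numpy().T
    dend = discovery.hierarchical_clustering(X, labels=embed_ids)
    clusters = dend.cut(2)
    disc_clusters = [clusters[s] for s in disc_ids]
    case_cluster = max(set(disc_clusters), key=disc_clusters.count)
    scores = classifier.score_mvp(model, beta.select_samples(val_ids))
    report = pd.DataFrame({
        "mvp_score": scores,
        "cluster": [clusters[s] for s in val_ids],
        "coclusters_with_discovery": [clusters[s] == case_cluster for s in val_ids],
        "high_score": scores >= config.mvp_high_score,
    })
    report.index.name = "sample_id"
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_table(report, out / "validation_report.tsv",
                   header_comments=_header(config, "validation"))
    return report
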