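"""Synthetic EPIC-like methylation cohorts with known ground truth.

The generator emulates the data a blood-based episignature study measures:
beta values in [0, 1] with bimodal probe baselines, leukocyte-composition
structure acting through cell-type reference profiles, batch effects on the
logit scale, a planted case-control signature of mostly hypomethylated
probes with small beta-scale effects, sporadic detection failures, and
flagged SNP-overlap / cross-reactive / sex-chromosome probes.  Additional
"other-disorder" cohorts carry their own disjoint planted signatures and
stand in for a reference database of known episignatures.

The generative model, per probe ``g`` and sample ``s``::

    mu0[g,s]  = baseline[g]                      (bimodal mixture draw)
              | R[g,:] . w[s]                    (cell-informative probes)
    m[g,s]    = logit(mu0) + batch_shift[batch(s), g]
    mu1       = expit(m)
    mu2       = clip(mu1 +- delta[g], 0.001, 0.999)   (planted probes, affected
                                                       samples only; beta units)
    beta[g,s] = clip(expit(logit(mu2) + eps), 0.001, 0.999),  eps ~ N(0, noise_sd)

Planted probes are drawn from clean autosomal, non-cell-informative probes
and given mid-range baselines so the beta-scale shift is not destroyed by
clipping; per-probe effect magnitudes are uniform on
[0.5*delta_beta, 1.5*delta_beta] (mean delta_beta).

Every stage draws from its own RNG stream derived deterministically from
``config.seed``, so adding a stage never shifts earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import (
    BetaMatrix,
    CellReference,
    DetectionPMatrix,
    GeneModel,
    GeneRecord,
    GenomicIntervalSet,
    ProbeManifest,
    SampleRecord,
    SampleSheet,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedCohort",
    "simulate_annotation",
    "simulate_cohort",
    "split_discovery_validation",
]

DEFAULT_CHROM_LAYOUT = (
    ("chr1", 20_000_000),
    ("chr2", 20_000_000),
    ("chr3", 15_000_000),
    ("chr4", 15_000_000),
    ("chrX", 10_000_000),
    ("chrY", 3_000_000),
)

SEX_CHROMS = ("chrX", "chrY")

DEFAULT_CELL_TYPES = ("neutrophil", "cd4t", "cd8t", "bcell", "monocyte", "nk")

# stage names -> fixed spawn indices; append only, never reorder
_STAGES = (
    "annotation",
    "samples",
    "baseline",
    "cell_reference",
    "cell_fractions",
    "batch",
    "signature",
    "noise",
    "detection",
    "split",
)


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    idx = _STAGES.index(stage)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(idx,)))


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions.

    Cohort sizes mirror the study design (24 discovery cases, 5 validation
    cases); the control pool (200) and the two other-disorder cohorts of 20
    are generator defaults.  ``delta_beta`` is the mean case-control shift on
    signature probes in beta units; ``noise_sd`` is on the logit scale.
    """

    seed: int = 7
    n_probes: int = 10_000
    chrom_layout: tuple = DEFAULT_CHROM_LAYOUT
    n_cases: int = 24
    n_controls: int = 200
    n_validation_cases: int = 5
    other_cohorts: tuple = (("NDD_A", 20, 200), ("NDD_B", 20, 300))
    signature_size: int = 296
    frac_hypo: float = 0.986
    delta_beta: float = 0.10
    noise_sd: float = 0.15
    n_cell_types: int = 6
    dirichlet_alpha: tuple = (18.0, 4.5, 2.4, 1.5, 2.4, 1.2)
    cell_probe_fraction: float = 0.20
    batch_levels: tuple = ("batch1", "batch2")
    batch_sd: float = 0.10
    detection_fail_rate: float = 1e-4
    snp_overlap_rate: float = 0.03
    cross_reactive_rate: float = 0.03
    sex_chrom_probe_fraction: float = 0.03
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        rates = {
            "frac_hypo": self.frac_hypo,
            "cell_probe_fraction": self.cell_probe_fraction,
            "detection_fail_rate": self.detection_fail_rate,
            "snp_overlap_rate": self.snp_overlap_rate,
            "cross_reactive_rate": self.cross_reactive_rate,
            "sex_chrom_probe_fraction": self.sex_chrom_probe_fraction,
            "missing_rate": self.missing_rate,
        }
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValidationError(f"config.{name} must be in [0, 1], got {r}")
        total_planted = self.signature_size + sum(s for _, _, s in self.other_cohorts)
        if total_planted > self.n_probes:
            raise ValidationError(
                f"planted probes ({total_planted}) exceed n_probes ({self.n_probes})"
            )
        if len(self.dirichlet_alpha) != self.n_cell_types:
            raise ValidationError("dirichlet_alpha length must equal n_cell_types")
        if self.noise_sd < 0 or self.batch_sd < 0 or self.delta_beta < 0:
            raise ValidationError("noise_sd, batch_sd and delta_beta must be >= 0")

    @property
    def cell_types(self) -> tuple:
        return DEFAULT_CELL_TYPES[: self.n_cell_types]


@dataclass
class SimulationTruth:
    """Everything the generator knows and downstream stages must recover."""

    planted: dict  # cohort name -> DataFrame(probe_id index, direction, delta)
    cell_fractions: pd.DataFrame  # samples x cell types, rows sum to 1
    labels: pd.Series  # sample -> group label
    baseline: pd.Series  # probe -> baseline mean

    def __post_init__(self) -> None:
        sums = self.cell_fractions.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError("true cell fractions must sum to 1 per sample")

    def planted_probes(self, cohort: str = "case") -> list[str]:
        return list(self.planted[cohort].index)


@dataclass
class SimulatedCohort:
    beta: BetaMatrix
    detection_p: DetectionPMatrix
    sheet: SampleSheet
    cell_reference: CellReference
    truth: SimulationTruth


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimulationConfig):
    """Generate a probe manifest, CpG islands and gene models.

    Probes are placed part uniformly, part clustered around CpG islands so
    island/shore/shelf contexts are all populated; half of the genes have
    their TSS at an island (CGI promoters), which populates the
    promoter/UTR/CDS contexts.  A small set of sentinel probes is pinned at
    known offsets from the first island and gene of each autosome so that
    every annotation category is occupied on any reasonable configuration.

    Returns ``(manifest, cgis, genes)``.
    """
    rng = _stage_rng(config.seed, "annotation")
    layout = dict(config.chrom_layout)
    autosomes = [c for c in layout if c not in SEX_CHROMS]
    if not autosomes:
        raise ValidationError("chrom_layout must contain at least one autosome")

    n_sex = int(round(config.sex_chrom_probe_fraction * config.n_probes))
    sex_present = [c for c in SEX_CHROMS if c in layout]
    if not sex_present:
        n_sex = 0
    n_auto = config.n_probes - n_sex

    auto_lengths = np.array([layout[c] for c in autosomes], dtype=float)
    weights = auto_lengths / auto_lengths.sum()
    counts = np.floor(weights * n_auto).astype(int)
    counts[0] += n_auto - counts.sum()

    # CpG islands per chromosome
    cgi_rows = []
    islands_by_chrom: dict[str, np.ndarray] = {}
    for chrom, n_chrom in zip(autosomes, counts):
        n_cgi = max(3, int(n_chrom) // 40)
        starts = np.sort(rng.integers(10_000, layout[chrom] - 20_000, size=n_cgi))
        lengths = rng.integers(500, 1500, size=n_cgi)
        ends = starts + lengths
        islands_by_chrom[chrom] = np.column_stack([starts, ends])
        for j, (s, e) in enumerate(zip(starts, ends)):
            cgi_rows.append((chrom, int(s), int(e), f"{chrom}_cgi{j:04d}"))
    cgis = GenomicIntervalSet(
        pd.DataFrame(cgi_rows, columns=["chrom", "start", "end", "name"])
    )

    # genes: half CGI-promoter genes, half uniform
    gene_list: list[GeneRecord] = []
    for chrom, n_chrom in zip(autosomes, counts):
        n_genes = max(2, int(n_chrom) // 60)
        islands = islands_by_chrom[chrom]
        for j in range(n_genes):
            strand = "+" if rng.random() < 0.5 else "-"
            glen = int(rng.integers(8_000, 40_000))
            if j % 2 == 0 and len(islands) > 0:
                isl = islands[rng.integers(0, len(islands))]
                tss = int(isl[0])
            else:
                tss = int(rng.integers(20_000, layout[chrom] - 60_000))
            if strand == "+":
                start, end = tss, min(tss + glen, layout[chrom] - 1)
            else:
                start, end = max(0, tss - glen), tss
            glen = end - start  # clamping at chromosome edges may shorten
            n_exons = int(rng.integers(2, 6))
            if glen < 4 * n_exons:
                continue
            # split span into exons with intron gaps
            cuts = np.sort(rng.choice(np.arange(1, glen - 1), size=2 * n_exons - 2, replace=False))
            bounds = np.concatenate([[0], cuts, [glen]])
            exons = [
                (start + int(bounds[2 * k]), start + int(bounds[2 * k + 1]))
                for k in range(n_exons)
            ]
            exons = [(s, e) for s, e in exons if e > s]
            # CDS from middle of first exon to middle of last exon
            thick_start = (exons[0][0] + exons[0][1]) // 2
            thick_end = (exons[-1][0] + exons[-1][1]) // 2
            if thick_end <= thick_start:
                thick_start = exons[0][0]
                thick_end = exons[-1][1]
            gene_list.append(
                GeneRecord(
                    chrom=chrom,
                    start=start,
                    end=end,
                    name=f"{chrom}_gene{j:04d}",
                    strand=strand,
                    thick_start=thick_start,
                    thick_end=thick_end,
                    exons=exons,
                )
            )
    genes = GeneModel(gene_list)

    # probe positions (1-based)
    pos_by_chrom: dict[str, set[int]] = {c: set() for c in layout}

    def _add(chrom: str, pos: int) -> None:
        pos = int(min(max(pos, 1), layout[chrom] - 1))
        pos_by_chrom[chrom].add(pos)

    # sentinel probes guaranteeing category occupancy
    for chrom in autosomes:
        isl = islands_by_chrom[chrom][0]
        centre = int((isl[0] + isl[1]) // 2)
        for off in (0, 1_200, 3_000, 6_000):
            _add(chrom, centre + off)
        g = next((x for x in gene_list if x.chrom == chrom and x.strand == "+"), None)
        if g is not None:
            _add(chrom, g.start - 500 + 1)          # promoter
            _add(chrom, g.start - 3_000 + 1)        # promoter_plus
            _add(chrom, (g.exons[0][0] + g.thick_start) // 2 + 1)  # 5' UTR
            _add(chrom, (g.thick_start + min(g.thick_end, g.exons[0][1])) // 2 + 1)  # CDS
            _add(chrom, (g.thick_end + g.exons[-1][1]) // 2 + 1)   # 3' UTR
            if len(g.exons) > 1:
                _add(chrom, (g.exons[0][1] + g.exons[1][0]) // 2 + 1)  # intron

    for chrom, n_chrom in zip(autosomes, counts):
        islands = islands_by_chrom[chrom]
        target = int(n_chrom)
        n_clustered = int(0.45 * target)
        centres = islands[rng.integers(0, len(islands), size=n_clustered)]
        mids = (centres[:, 0] + centres[:, 1]) // 2
        offsets = rng.normal(0.0, 2_500.0, size=n_clustered).astype(int)
        for p in mids + offsets:
            _add(chrom, int(p))
        while len(pos_by_chrom[chrom]) < target:
            need = target - len(pos_by_chrom[chrom])
            for p in rng.integers(1, layout[chrom], size=need):
                _add(chrom, int(p))
        # trim overshoot from sentinel additions deterministically
        if len(pos_by_chrom[chrom]) > target:
            keep = sorted(pos_by_chrom[chrom])[:target]
            pos_by_chrom[chrom] = set(keep)

    if n_sex:
        n_x = (2 * n_sex) // 3 if "chrY" in sex_present and "chrX" in sex_present else n_sex
        alloc = {}
        if "chrX" in sex_present:
            alloc["chrX"] = n_x
        if "chrY" in sex_present:
            alloc["chrY"] = n_sex - n_x if "chrX" in sex_present else n_sex
        for chrom, n_chrom in alloc.items():
            while len(pos_by_chrom[chrom]) < n_chrom:
                need = n_chrom - len(pos_by_chrom[chrom])
                for p in rng.integers(1, layout[chrom], size=need):
                    _add(chrom, int(p))

    rows = []
    for chrom, _ in config.chrom_layout:
        for pos in sorted(pos_by_chrom[chrom]):
            rows.append((chrom, pos))
    df = pd.DataFrame(rows, columns=["chrom", "pos"])
    df.index = pd.Index([f"cg{i + 1:08d}" for i in range(len(df))], name="probe_id")
    df["strand"] = np.where(rng.random(len(df)) < 0.5, "+", "-")
    df["snp_overlap"] = rng.random(len(df)) < config.snp_overlap_rate
    df["cross_reactive"] = rng.random(len(df)) < config.cross_reactive_rate
    manifest = ProbeManifest(df)
    return manifest, cgis, genes


# ---------------------------------------------------------------------------
# cohort


def _draw_baseline(rng: np.random.Generator, n: int) -> np.ndarray:
    comp = rng.choice(3, size=n, p=[0.45, 0.45, 0.10])
    out = np.empty(n)
    low = comp == 0
    high = comp == 1
    mid = comp == 2
    out[low] = rng.beta(2.0, 12.0, size=low.sum())
    out[high] = rng.beta(12.0, 2.0, size=high.sum())
    out[mid] = rng.beta(8.0, 8.0, size=mid.sum())
    return np.clip(out, 0.02, 0.98)


def simulate_cohort(config: SimulationConfig, manifest: ProbeManifest,
                    cgis: GenomicIntervalSet, genes: GeneModel) -> SimulatedCohort:
    """Generate beta values, detection p-values, sample sheet, cell reference
    and the ground-truth record for one synthetic study."""
    probe_ids = np.array(manifest.probe_ids)
    n_probes = len(probe_ids)
    chrom = manifest.df["chrom"].to_numpy()

    # --- samples ------------------------------------------------------------
    rng_s = _stage_rng(config.seed, "samples")
    records: list[SampleRecord] = []
    n_all_cases = config.n_cases + config.n_validation_cases

    batches = list(config.batch_levels)

    def _mk(sample_id, group, idx, age_hi):
        # sex and batch rotate in a balanced design so every (sex, batch)
        # stratum of the control pool can serve exact matching
        return SampleRecord(
            sample_id=sample_id,
            group_label=group,
            sex="F" if idx % 2 == 0 else "M",
            age=float(np.round(rng_s.uniform(1.0, age_hi), 1)),
            batch=batches[(idx // 2) % len(batches)],
            array_type="EPIC",
            cohort_role="pool",
        )

    for i in range(n_all_cases):
        records.append(_mk(f"case{i + 1:03d}", "case", i, 26.0))
    for i in range(config.n_controls):
        records.append(_mk(f"ctrl{i + 1:03d}", "control", i, 40.0))
    for name, n, _size in config.other_cohorts:
        for i in range(n):
            records.append(_mk(f"{name}_{i + 1:02d}", name, i, 40.0))
    sheet = SampleSheet(records)
    sheet = split_discovery_validation(sheet, config)
    sample_ids = sheet.sample_ids
    n_samples = len(sample_ids)

    # --- baselines ----------------------------------------------------------
    rng_b = _stage_rng(config.seed, "baseline")
    baseline = _draw_baseline(rng_b, n_probes)

    # --- cell reference -----------------------------------------------------
    rng_cr = _stage_rng(config.seed, "cell_reference")
    n_cell = int(round(config.cell_probe_fraction * n_probes))
    cell_idx = np.sort(rng_cr.choice(n_probes, size=n_cell, replace=False))
    cell_mask = np.zeros(n_probes, dtype=bool)
    cell_mask[cell_idx] = True
    types = list(config.cell_types)
    ref = np.empty((n_cell, len(types)))
    base_logit = logit(baseline[cell_idx])
    for t in range(len(types)):
        ref[:, t] = expit(base_logit + rng_cr.normal(0.0, 1.5, size=n_cell))
    cell_reference = CellReference(
        pd.DataFrame(ref, index=pd.Index(probe_ids[cell_idx], name="probe_id"), columns=types)
    )

    # --- cell fractions -----------------------------------------------------
    rng_cf = _stage_rng(config.seed, "cell_fractions")
    w = rng_cf.dirichlet(np.asarray(config.dirichlet_alpha, dtype=float), size=n_samples)
    cell_fractions = pd.DataFrame(w, index=pd.Index(sample_ids, name="sample_id"), columns=types)

    # --- batch shifts -------------------------------------------------------
    rng_batch = _stage_rng(config.seed, "batch")
    batches = list(config.batch_levels)
    batch_shift = {
        b: rng_batch.normal(0.0, config.batch_sd, size=n_probes) for b in batches
    }

    # --- planted signatures -------------------------------------------------
    rng_sig = _stage_rng(config.seed, "signature")
    eligible = (
        ~np.isin(chrom, SEX_CHROMS)
        & ~manifest.df["snp_overlap"].to_numpy()
        & ~manifest.df["cross_reactive"].to_numpy()
        & ~cell_mask
    )
    eligible_idx = np.flatnonzero(eligible)
    sizes = [("case", config.signature_size)] + [
        (name, size) for name, _n, size in config.other_cohorts
    ]
    total = sum(s for _, s in sizes)
    if total > len(eligible_idx):
        raise ValidationError(
            f"not enough clean autosomal probes ({len(eligible_idx)}) "
            f"for {total} planted probes"
        )
    drawn = rng_sig.choice(eligible_idx, size=total, replace=False)
    planted: dict[str, pd.DataFrame] = {}
    offset = 0
    claimed: set[int] = set()
    for name, size in sizes:
        idx = np.sort(drawn[offset:offset + size])
        offset += size
        if claimed & set(idx.tolist()):
            raise RuntimeError("internal error: planted signature sets overlap")
        claimed.update(idx.tolist())
        n_hypo = int(round(config.frac_hypo * size))
        direction = np.array(["hypo"] * n_hypo + ["hyper"] * (size - n_hypo))
        rng_sig.shuffle(direction)
        delta = rng_sig.uniform(0.5 * config.delta_beta, 1.5 * config.delta_beta, size=size)
        # mid-range baselines leave room for the beta-scale shift
        lo = np.where(direction == "hypo", 0.30, 0.15)
        hi = np.where(direction == "hypo", 0.85, 0.70)
        baseline[idx] = rng_sig.uniform(lo, hi)
        planted[name] = pd.DataFrame(
            {"direction": direction, "delta": delta},
            index=pd.Index(probe_ids[idx], name="probe_id"),
        )

    # --- expected means -----------------------------------------------------
    mu0 = np.tile(baseline[:, None], (1, n_samples))
    mu0[cell_idx, :] = ref @ w.T  # fraction-weighted mix for cell probes

    m = logit(np.clip(mu0, 1e-4, 1 - 1e-4))
    for j, rec in enumerate(sheet.records):
        m[:, j] += batch_shift[rec.batch]
    mu1 = expit(m)

    group_of = {r.sample_id: r.group_label for r in sheet.records}
    probe_pos = {p: i for i, p in enumerate(probe_ids)}
    mu2 = mu1
    for name, table in planted.items():
        cols = [j for j, s in enumerate(sample_ids) if group_of[s] == name]
        if not cols:
            continue
        ridx = np.array([probe_pos[p] for p in table.index])
        sign = np.where(table["direction"].to_numpy() == "hypo", -1.0, 1.0)
        shift = sign * table["delta"].to_numpy()
        block = mu2[np.ix_(ridx, cols)] + shift[:, None]
        mu2[np.ix_(ridx, cols)] = np.clip(block, 0.001, 0.999)

    rng_noise = _stage_rng(config.seed, "noise")
    m2 = logit(np.clip(mu2, 1e-4, 1 - 1e-4)) + rng_noise.normal(
        0.0, config.noise_sd, size=(n_probes, n_samples)
    )
    beta_vals = np.clip(expit(m2), 0.001, 0.999)
    if config.missing_rate > 0:
        miss = rng_noise.random((n_probes, n_samples)) < config.missing_rate
        beta_vals[miss] = np.nan

    beta = BetaMatrix(
        pd.DataFrame(beta_vals, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    )

    # --- detection p --------------------------------------------------------
    rng_det = _stage_rng(config.seed, "detection")
    detp = rng_det.uniform(0.0, 0.05, size=(n_probes, n_samples))
    fail = rng_det.random((n_probes, n_samples)) < config.detection_fail_rate
    detp[fail] = rng_det.uniform(0.11, 1.0, size=int(fail.sum()))
    detection_p = DetectionPMatrix(
        pd.DataFrame(detp, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    )

    truth = SimulationTruth(
        planted=planted,
        cell_fractions=cell_fractions,
        labels=pd.Series(group_of, name="group_label"),
        baseline=pd.Series(baseline, index=pd.Index(probe_ids, name="probe_id"), name="baseline"),
    )
    return SimulatedCohort(
        beta=beta,
        detection_p=detection_p,
        sheet=sheet,
        cell_reference=cell_reference,
        truth=truth,
    )


def write_cohort_artifacts(cohort: SimulatedCohort, manifest: ProbeManifest,
                           cgis: GenomicIntervalSet, genes: GeneModel, outdir) -> dict:
    """Write every simulated artifact in the on-disk formats the pipeline
    reads, plus the ground-truth tables; returns the path map."""
    from pathlib import Path

    from . import io as _io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": out / "beta.tsv",
        "detection_p": out / "detection_p.tsv",
        "sheet": out / "samples.csv",
        "manifest": out / "manifest.tsv",
        "cgi": out / "cgi.bed",
        "genes": out / "genes.bed12",
        "cell_reference": out / "cell_reference.tsv",
        "truth_planted": out / "truth_planted.tsv",
        "truth_cell_fractions": out / "truth_cell_fractions.tsv",
    }
    _io.write_beta_matrix(cohort.beta, paths["beta"])
    dp = cohort.detection_p.values.copy()
    dp.index.name = "probe_id"
    _io.write_table(dp, paths["detection_p"])
    _io.write_sample_sheet(cohort.sheet, paths["sheet"])
    mdf = cohort_manifest_frame(manifest)
    _io.write_table(mdf, paths["manifest"])
    _io.write_bed(cgis, paths["cgi"])
    _io.write_bed12(genes, paths["genes"])
    _io.write_cell_reference(cohort.cell_reference, paths["cell_reference"])
    planted = pd.concat(
        [t.assign(cohort=name) for name, t in cohort.truth.planted.items()]
    )
    _io.write_table(planted, paths["truth_planted"])
    _io.write_table(cohort.truth.cell_fractions, paths["truth_cell_fractions"])
    return {k: str(v) for k, v in paths.items()}


def cohort_manifest_frame(manifest: ProbeManifest) -> pd.DataFrame:
    df = manifest.df.copy()
    df.index.name = "probe_id"
    return df


def split_discovery_validation(sheet: SampleSheet, config: SimulationConfig,
                               seed: int | None = None) -> SampleSheet:
    """Randomly assign case samples to discovery/validation cohort roles.

    Counts follow ``config.n_cases`` / ``config.n_validation_cases``; all
    non-case samples keep the ``pool`` role.  Seeded and reproducible.
    """
    rng = _stage_rng(config.seed if seed is None else seed, "split")
    case_ids = [r.sample_id for r in sheet.records if r.group_label == "case"]
    n_total = config.n_cases + config.n_validation_cases
    if len(case_ids) != n_total:
        raise ValidationError(
            f"split infeasible: {len(case_ids)} cases, config wants "
            f"{config.n_cases} discovery + {config.n_validation_cases} validation"
        )
    val = set(rng.choice(case_ids, size=config.n_validation_cases, replace=False).tolist())
    records = []
    for r in sheet.records:
        if r.group_label == "case":
            role = "validation" if r.sample_id in val else "discovery"
        else:
            role = r.cohort_role
        records.append(
            SampleRecord(
                sample_id=r.sample_id,
                group_label=r.group_label,
                sex=r.sex,
                age=r.age,
                batch=r.batch,
                array_type=r.array_type,
                cohort_role=role,
                extra=dict(r.extra),
            )
        )
    return SampleSheet(records)
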