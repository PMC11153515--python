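"""Readers, writers and validated containers for every on-disk artifact.

All matrices travel as TSV (probe ids in the first column, sample ids in the
header), sample sheets as CSV.  Interval files follow BED conventions:
0-based half-open coordinates; manifest CpG positions are 1-based points.
Readers validate and never alter scientific content — no filtering, no
imputation; missing beta values ("NA" or empty) are merely flagged as NaN.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "BetaMatrix",
    "DetectionPMatrix",
    "SampleRecord",
    "SampleSheet",
    "ProbeManifest",
    "GenomicIntervalSet",
    "GeneRecord",
    "GeneModel",
    "CellReference",
    "read_beta_matrix",
    "read_detection_p_matrix",
    "read_sample_sheet",
    "read_manifest",
    "read_bed",
    "read_bed12",
    "read_cell_reference",
    "read_table",
    "write_table",
    "write_beta_matrix",
    "write_sample_sheet",
]

FLOAT_FORMAT = "%.15g"  # fixed output precision; round-trips below 1e-12

SHEET_COLUMNS = [
    "sample_id",
    "group_label",
    "sex",
    "age",
    "batch",
    "array_type",
    "cohort_role",
]

MANIFEST_COLUMNS = ["probe_id", "chrom", "pos", "strand", "snp_overlap", "cross_reactive"]


class FormatError(ValueError):
    """Structurally malformed input file (ragged rows, missing columns...)."""


class ValidationError(ValueError):
    """Well-formed file whose content violates a domain invariant."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation beta fractions in [0, 1].

    ``values`` is a DataFrame indexed by probe id with sample-id columns.
    NaN entries mark missing measurements and are tolerated; downstream
    policy (see :mod:`episig.preprocess`) decides what to do with them.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe id")
        _check_unique(self.values.columns, "sample id")
        _check_range(self.values, 0.0, 1.0, what="beta value")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def select_probes(self, probe_ids) -> "BetaMatrix":
        missing = [p for p in probe_ids if p not in self.values.index]
        if missing:
            raise ValidationError(f"probes absent from matrix: {missing[:10]}")
        return BetaMatrix(self.values.loc[list(probe_ids)].copy())

    def select_samples(self, sample_ids) -> "BetaMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples absent from matrix: {missing[:10]}")
        return BetaMatrix(self.values[list(sample_ids)].copy())


@dataclass
class DetectionPMatrix:
    """Per-probe, per-sample detection p-values; shape-compatible with a BetaMatrix."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe id")
        _check_unique(self.values.columns, "sample id")
        _check_range(self.values, 0.0, 1.0, what="detection p")


@dataclass
class SampleRecord:
    sample_id: str
    group_label: str
    sex: str
    age: float
    batch: str
    array_type: str
    cohort_role: str
    extra: dict = field(default_factory=dict)


class SampleSheet:
    """Ordered collection of :class:`SampleRecord`, with a DataFrame view.

    Unknown extra columns from the CSV are preserved as opaque attributes in
    ``record.extra`` and survive a write/read round trip.
    """

    def __init__(self, records: list[SampleRecord]):
        seen: set[str] = set()
        for r in records:
            if r.sample_id in seen:
                raise ValidationError(f"duplicate sample_id {r.sample_id!r}")
            seen.add(r.sample_id)
            if not np.isfinite(r.age) or r.age < 0:
                raise ValidationError(f"sample {r.sample_id!r}: age must be >= 0, got {r.age}")
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        extra_keys: list[str] = []
        for r in self.records:
            for k in r.extra:
                if k not in extra_keys:
                    extra_keys.append(k)
        rows = []
        for r in self.records:
            row = {
                "sample_id": r.sample_id,
                "group_label": r.group_label,
                "sex": r.sex,
                "age": r.age,
                "batch": r.batch,
                "array_type": r.array_type,
                "cohort_role": r.cohort_role,
            }
            for k in extra_keys:
                row[k] = r.extra.get(k, "")
            rows.append(row)
        return pd.DataFrame(rows, columns=SHEET_COLUMNS + extra_keys)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleSheet":
        missing = [c for c in SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing mandatory column(s): {missing}")
        extra_cols = [c for c in df.columns if c not in SHEET_COLUMNS]
        records = []
        for _, row in df.iterrows():
            try:
                age = float(row["age"])
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"sample {row['sample_id']!r}: non-numeric age {row['age']!r}") from exc
            records.append(
                SampleRecord(
                    sample_id=str(row["sample_id"]),
                    group_label=str(row["group_label"]),
                    sex=str(row["sex"]),
                    age=age,
                    batch=str(row["batch"]),
                    array_type=str(row["array_type"]),
                    cohort_role=str(row["cohort_role"]),
                    extra={k: row[k] for k in extra_cols},
                )
            )
        return cls(records)

    def subset(self, sample_ids) -> "SampleSheet":
        by_id = {r.sample_id: r for r in self.records}
        missing = [s for s in sample_ids if s not in by_id]
        if missing:
            raise ValidationError(f"samples absent from sheet: {missing[:10]}")
        return SampleSheet([by_id[s] for s in sample_ids])

    def where(self, **conditions) -> "SampleSheet":
        """Records whose attribute equals (or is in) the given value(s)."""
        out = []
        for r in self.records:
            ok = True
            for key, val in conditions.items():
                attr = getattr(r, key)
                if isinstance(val, (list, tuple, set, frozenset)):
                    ok = ok and attr in val
                else:
                    ok = ok and attr == val
            if ok:
                out.append(r)
        return SampleSheet(out)


class ProbeManifest:
    """Per-probe genomic placement and QC flags.

    Positions are 1-based coordinates of the interrogated CpG cytosine.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in MANIFEST_COLUMNS[1:] if c not in df.columns]
        if missing:
            raise FormatError(f"manifest missing column(s): {missing}")
        _check_unique(df.index, "probe id")
        if (df["pos"] < 1).any():
            bad = df.index[df["pos"] < 1][0]
            raise ValidationError(f"manifest probe {bad!r}: pos must be >= 1")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.df.index)

    def subset(self, probe_ids) -> "ProbeManifest":
        return ProbeManifest(self.df.loc[list(probe_ids)].copy())


class GenomicIntervalSet:
    """(chrom, start, end, name) records, 0-based half-open, sorted per chrom."""

    def __init__(self, df: pd.DataFrame):
        for c in ("chrom", "start", "end", "name"):
            if c not in df.columns:
                raise FormatError(f"interval set missing column {c!r}")
        if (df["start"] >= df["end"]).any():
            row = df[df["start"] >= df["end"]].iloc[0]
            raise ValidationError(
                f"interval {row['name']!r}: start {row['start']} >= end {row['end']}"
            )
        self.df = (
            df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.df)

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    @property
    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique())


@dataclass
class GeneRecord:
    chrom: str
    start: int  # 0-based half-open gene span
    end: int
    name: str
    strand: str
    thick_start: int  # CDS span; thick_start == thick_end means non-coding
    thick_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)  # absolute, half-open

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"gene {self.name!r}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.name!r}: strand must be + or -")
        if not (self.start <= self.thick_start <= self.thick_end <= self.end):
            raise ValidationError(f"gene {self.name!r}: CDS outside gene span")
        prev_end = None
        for (s, e) in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValidationError(f"gene {self.name!r}: exon [{s},{e}) outside span")
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"gene {self.name!r}: exon blocks overlap or unordered")
            prev_end = e

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site."""
        return self.start if self.strand == "+" else self.end - 1


class GeneModel:
    """Collection of BED12-style gene records."""

    def __init__(self, genes: list[GeneRecord]):
        self.genes = list(genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def for_chrom(self, chrom: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.chrom == chrom]


@dataclass
class CellReference:
    """Reference beta profiles: probes (rows) x cell types (columns)."""

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.profiles.index, "reference probe id")
        _check_unique(self.profiles.columns, "cell type")
        _check_range(self.profiles, 0.0, 1.0, what="reference beta")

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.profiles.index)


# ---------------------------------------------------------------------------
# helpers


def _check_unique(index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise FormatError(f"duplicate {what} {dup!r}")


def _check_range(df: pd.DataFrame, lo: float, hi: float, what: str) -> None:
    arr = df.to_numpy(dtype=float)
    bad = (arr < lo) | (arr > hi)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{what} out of [{lo}, {hi}] at probe {df.index[i]!r}, "
            f"sample {df.columns[j]!r}: {arr[i, j]}"
        )


def _read_matrix_tsv(path) -> pd.DataFrame:
    lines = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            lines.append(line)
    if not lines:
        raise FormatError(f"{path}: empty file")
    n_fields = lines[0].rstrip("\n").count("\t") + 1
    for i, line in enumerate(lines[1:], start=2):
        if line.rstrip("\n").count("\t") + 1 != n_fields:
            raise FormatError(f"{path}: ragged row at line {i}")
    df = pd.read_csv(
        _io.StringIO("".join(lines)),
        sep="\t",
        index_col=0,
        na_values=["NA"],
        keep_default_na=True,
    )
    df.columns = [str(c) for c in df.columns]
    df.index = [str(i) for i in df.index]
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric value in matrix ({exc})") from exc
    return df


# ---------------------------------------------------------------------------
# readers


def read_beta_matrix(path) -> BetaMatrix:
    """Read a probes x samples beta TSV; "NA" tokens become missing values."""
    return BetaMatrix(_read_matrix_tsv(path))


def read_detection_p_matrix(path) -> DetectionPMatrix:
    return DetectionPMatrix(_read_matrix_tsv(path))


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, comment="#", dtype=str)
    return SampleSheet.from_frame(df)


def _parse_bool(series: pd.Series, path, col: str) -> pd.Series:
    mapping = {"0": False, "1": True, "true": True, "false": False}
    out = series.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = series[out.isna()].iloc[0]
        raise FormatError(f"{path}: column {col!r} has non-boolean value {bad!r}")
    return out.astype(bool)


def read_manifest(path) -> ProbeManifest:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing column(s): {missing}")
    if df["probe_id"].duplicated().any():
        dup = df["probe_id"][df["probe_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate probe id {dup!r}")
    out = pd.DataFrame(index=pd.Index(df["probe_id"], name="probe_id"))
    out["chrom"] = df["chrom"].to_numpy()
    out["pos"] = pd.to_numeric(df["pos"].to_numpy(), errors="raise").astype(int)
    out["strand"] = df["strand"].to_numpy()
    out["snp_overlap"] = _parse_bool(df["snp_overlap"], path, "snp_overlap").to_numpy()
    out["cross_reactive"] = _parse_bool(df["cross_reactive"], path, "cross_reactive").to_numpy()
    return ProbeManifest(out)


def read_bed(path) -> GenomicIntervalSet:
    """Read BED3+ intervals (name defaults to ``region_<i>`` when absent)."""
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {i + 1}: fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"region_{i}"
            rows.append((chrom, start, end, name))
    return GenomicIntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))


def read_bed12(path) -> GeneModel:
    genes = []
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}: line {i + 1}: BED12 requires 12 fields")
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            name = fields[3]
            strand = fields[5]
            thick_start, thick_end = int(fields[6]), int(fields[7])
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}: line {i + 1}: block count mismatch")
            exons = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
            genes.append(
                GeneRecord(
                    chrom=chrom,
                    start=start,
                    end=end,
                    name=name,
                    strand=strand,
                    thick_start=thick_start,
                    thick_end=thick_end,
                    exons=exons,
                )
            )
    return GeneModel(genes)


def read_cell_reference(path) -> CellReference:
    return CellReference(_read_matrix_tsv(path))


def read_table(path, index_col: int | None = 0) -> pd.DataFrame:
    """Read a generic TSV artifact written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# ---------------------------------------------------------------------------
# writers


def write_table(df: pd.DataFrame, path, *, header_comments=(), index: bool = True) -> None:
    """Write a tabular artifact as TSV with deterministic column order and
    fixed float precision; optional ``# ``-prefixed header comment lines."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT, index=index, lineterminator="\n")


def write_beta_matrix(bm: BetaMatrix, path, *, header_comments=()) -> None:
    values = bm.values.copy()
    values.index.name = "probe_id"
    write_table(values, path, header_comments=header_comments)


def write_sample_sheet(sheet: SampleSheet, path, *, header_comments=()) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        sheet.to_frame().to_csv(fh, index=False, lineterminator="\n")


def write_bed(intervals: GenomicIntervalSet, path) -> None:
    intervals.df.to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


def write_bed12(genes: GeneModel, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        g.chrom, g.start, g.end, g.name, 0, g.strand,
                        g.thick_start, g.thick_end, "0,0,0",
                        len(g.exons), sizes, starts,
                    )
                )
                + "\n"
            )


def write_cell_reference(ref: CellReference, path, *, header_comments=()) -> None:
    profiles = ref.profiles.copy()
    profiles.index.name = "probe_id"
    write_table(profiles, path, header_comments=header_comments)
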