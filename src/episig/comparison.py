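"""Cross-cohort DMP overlap and relatedness analyses.

Each cohort contributes a :class:`CohortSignature`: its DMP table, the top-n
most significant probes (n = min(#significant, 500)), and a median
case-minus-control methylation-difference profile.  The overlap matrix
reports, for every ordered cohort pair (y, x), the percentage of y's top
probes also present in x's top set — generally asymmetric.  The cohort tree
clusters the median difference profiles (Euclidean, same clustering engine
as discovery) over the union of all cohorts' top probes, with per-cohort
node attributes (signature size, global mean methylation difference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import discovery
from .io import BetaMatrix, SampleRecord, SampleSheet, ValidationError
from .preprocess import CellProportions

__all__ = [
    "CohortSignature",
    "CohortTree",
    "top_dmps",
    "overlap_matrix",
    "shared_probe_pairs",
    "cohort_tree",
    "build_cohort_signature",
]

TOP_N_CAP = 500
DMP_ALPHA = 0.05


def top_dmps(dmp_table: pd.DataFrame, cap: int = TOP_N_CAP,
             alpha: float = DMP_ALPHA) -> list[str]:
    """Up to ``cap`` most significant probes (adj_p < alpha), ranked by
    adjusted p with ties broken by |delta_beta| descending, then probe id."""
    sig = dmp_table[dmp_table["adj_p"] < alpha]
    if sig.empty:
        return []
    ranked = sig.assign(_abs=sig["delta_beta"].abs())
    ranked = ranked.sort_index(kind="mergesort")  # probe id, last tie-break
    ranked = ranked.sort_values(by=["adj_p", "_abs"], ascending=[True, False],
                                kind="mergesort")
    return list(ranked.head(cap).index)


@dataclass
class CohortSignature:
    """One cohort's DMP set and median methylation-difference profile."""

    cohort_id: str
    dmp_table: pd.DataFrame = field(repr=False)
    median_diff: pd.Series = field(repr=False)  # per-probe median(case - control mean)
    top_probes: list = None

    def __post_init__(self) -> None:
        if self.top_probes is None:
            self.top_probes = top_dmps(self.dmp_table)

    @property
    def n_dmps(self) -> int:
        return len(self.top_probes)

    @property
    def global_mean_diff(self) -> float:
        """Mean methylation difference over the cohort's top probes."""
        if not self.top_probes:
            return float("nan")
        return float(self.median_diff.reindex(self.top_probes).mean())


def overlap_matrix(signatures: list[CohortSignature]) -> pd.DataFrame:
    """Percentage of each (row) cohort's top probes found in each column
    cohort's top set; diagonal 100, rows of empty signatures 0 (warned)."""
    if len(signatures) < 2:
        raise ValidationError("overlap needs at least 2 cohort signatures")
    ids = [s.cohort_id for s in signatures]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate cohort ids")
    sets = {s.cohort_id: set(s.top_probes) for s in signatures}
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for y in ids:
        if not sets[y]:
            warnings.warn(f"cohort {y!r} has an empty top DMP set", stacklevel=2)
            continue
        for x in ids:
            mat.loc[y, x] = 100.0 * len(sets[y] & sets[x]) / len(sets[y])
    return mat


def shared_probe_pairs(signatures: list[CohortSignature]) -> pd.DataFrame:
    """Long-form table of shared top-probe counts for every cohort pair."""
    rows = []
    for i, a in enumerate(signatures):
        for b in signatures[i + 1:]:
            rows.append(
                (a.cohort_id, b.cohort_id, len(set(a.top_probes) & set(b.top_probes)))
            )
    return pd.DataFrame(rows, columns=["cohort_a", "cohort_b", "n_shared"])


@dataclass
class CohortTree:
    dendrogram: discovery.Dendrogram
    newick: str
    attributes: pd.DataFrame  # per cohort: n_dmps (node size), mean_diff (node colour)


def cohort_tree(signatures: list[CohortSignature], probe_universe=None) -> CohortTree:
    """Hierarchical clustering of cohort median-difference profiles.

    Profiles are evaluated on ``probe_universe`` (default: the union of all
    cohorts' top probes); probes absent from a cohort's profile contribute a
    zero difference.  Node attributes carry the signature size and the
    global mean methylation difference of each cohort.
    """
    if len(signatures) < 2:
        raise ValidationError("cohort tree needs at least 2 signatures")
    if probe_universe is None:
        universe: list[str] = []
        seen: set[str] = set()
        for s in signatures:
            for p in s.top_probes:
                if p not in seen:
                    seen.add(p)
                    universe.append(p)
    else:
        universe = list(probe_universe)
    if not universe:
        raise ValidationError("probe universe is empty")
    profiles = np.vstack([
        s.median_diff.reindex(universe).fillna(0.0).to_numpy() for s in signatures
    ])
    labels = [s.cohort_id for s in signatures]
    dend = discovery.hierarchical_clustering(profiles, labels=labels,
                                             metric="euclidean", linkage="complete")
    attrs = pd.DataFrame(
        {
            "n_dmps": [s.n_dmps for s in signatures],
            "mean_diff": [s.global_mean_diff for s in signatures],
        },
        index=pd.Index(labels, name="cohort"),
    )
    return CohortTree(dendrogram=dend, newick=dend.to_newick(), attributes=attrs)


def save_signature(sig: CohortSignature, directory) -> None:
    """Persist a cohort signature as ``<id>.dmp.tsv`` + ``<id>.diff.tsv``."""
    from pathlib import Path

    from .io import write_table

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_table(sig.dmp_table, d / f"{sig.cohort_id}.dmp.tsv")
    write_table(sig.median_diff.to_frame(), d / f"{sig.cohort_id}.diff.tsv")


def load_signatures(directory, cap: int = TOP_N_CAP,
                    alpha: float = DMP_ALPHA) -> list[CohortSignature]:
    """Load every ``<id>.dmp.tsv`` / ``<id>.diff.tsv`` pair in a directory."""
    from pathlib import Path

    from .io import read_table

    d = Path(directory)
    sigs = []
    for dmp_path in sorted(d.glob("*.dmp.tsv")):
        cohort_id = dmp_path.name[: -len(".dmp.tsv")]
        diff_path = d / f"{cohort_id}.diff.tsv"
        if not diff_path.exists():
            raise ValidationError(f"missing difference profile for cohort {cohort_id!r}")
        dmp = read_table(dmp_path)
        diff = read_table(diff_path)["median_diff"]
        sigs.append(CohortSignature(
            cohort_id=cohort_id, dmp_table=dmp, median_diff=diff,
            top_probes=top_dmps(dmp, cap=cap, alpha=alpha),
        ))
    if not sigs:
        raise ValidationError(f"no cohort signatures found in {directory}")
    return sigs


def build_cohort_signature(cohort_id: str, beta: BetaMatrix, sheet: SampleSheet,
                           cell_proportions: CellProportions | None = None,
                           group_label: str | None = None, match_ratio: int = 4,
                           exact_on: tuple = ("sex", "batch", "array_type"),
                           cap: int = TOP_N_CAP, alpha: float = DMP_ALPHA) -> CohortSignature:
    """Run the discovery statistics for one cohort against matched controls
    and package the result as a :class:`CohortSignature`.

    ``group_label`` names the affected group in the sheet (default: the
    cohort id); controls are drawn from the ``control`` group.
    """
    group = group_label if group_label is not None else cohort_id
    affected = sheet.where(group_label=group)
    if len(affected) == 0:
        raise ValidationError(f"no samples with group label {group!r}")
    pool = sheet.where(group_label="control")
    # relabel the affected group as the case cohort for the shared machinery;
    # everything else (including any original case cohort) stays out of it
    affected_relabeled = SampleSheet([
        SampleRecord(
            sample_id=r.sample_id, group_label="case",
            sex=r.sex, age=r.age, batch=r.batch, array_type=r.array_type,
            cohort_role=r.cohort_role, extra=dict(r.extra),
        )
        for r in affected.records
    ])
    relabeled = SampleSheet(affected_relabeled.records + pool.records)
    match = discovery.match_controls(affected_relabeled, pool,
                                     ratio=match_ratio, exact_on=exact_on)
    model_ids = match.case_ids + match.control_ids
    model_sheet = relabeled.subset(model_ids)
    model_beta = beta.select_samples(model_ids)
    cp = None
    if cell_proportions is not None:
        cp = CellProportions(cell_proportions.fractions.loc[model_ids])
    dmp = discovery.differential_methylation(model_beta, model_sheet, cp)
    control_mean = beta.values[match.control_ids].mean(axis=1)
    diffs = beta.values[match.case_ids].sub(control_mean, axis=0)
    median_diff = diffs.median(axis=1)
    median_diff.name = "median_diff"
    return CohortSignature(
        cohort_id=cohort_id,
        dmp_table=dmp,
        median_diff=median_diff,
        top_probes=top_dmps(dmp, cap=cap, alpha=alpha),
    )
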