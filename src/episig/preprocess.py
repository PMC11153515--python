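"""Probe filtering, cell-composition estimation and PCA outlier screening.

Filtering applies, in a fixed precedence order, the standard EPIC QC rules:
SNP-overlapping probes, cross-reactive probes, sex-chromosome probes, probes
with a detection p-value above threshold in any sample, and probes with any
missing beta value.  Each probe is tallied once, under the first rule that
removes it.

Cell-composition estimation is reference-based deconvolution: for each
sample the leukocyte fractions ``w`` minimize ``||b - R w||^2`` subject to
``w >= 0`` and ``sum(w) = 1`` over the reference probe subset.

The PCA screen flags samples whose score on any of the leading principal
axes is an extreme outlier under a robust (median/MAD) criterion; it warns
and records, it never drops samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .io import (
    BetaMatrix,
    CellReference,
    DetectionPMatrix,
    ProbeManifest,
    ValidationError,
)

__all__ = [
    "FilterReport",
    "CellProportions",
    "filter_probes",
    "estimate_cell_proportions",
    "pca_outlier_screen",
]

FILTER_RULES = ("snp_overlap", "cross_reactive", "sex_chromosome", "detection_p", "missing")


@dataclass
class FilterReport:
    """Per-rule removal tallies; retained + sum(removed) = input probes."""

    n_input: int
    removed: dict
    retained: int

    def __post_init__(self) -> None:
        if self.retained + sum(self.removed.values()) != self.n_input:
            raise ValidationError("filter report does not account for every probe")

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(rule, self.removed.get(rule, 0)) for rule in FILTER_RULES]
        rows.append(("retained", self.retained))
        return pd.DataFrame(rows, columns=["stage", "n_probes"]).set_index("stage")


@dataclass
class CellProportions:
    """Sample x cell-type fractions; each row is in [0,1] and sums to 1."""

    fractions: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.fractions.to_numpy()
        if (arr < -1e-9).any() or (arr > 1 + 1e-9).any():
            raise ValidationError("cell fractions must lie in [0, 1]")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
            raise ValidationError("cell fractions must sum to 1 per sample")

    @property
    def cell_types(self) -> list[str]:
        return list(self.fractions.columns)

    def design_columns(self, drop_last: bool = True) -> pd.DataFrame:
        """Covariate columns for regression; one column dropped to avoid the
        sum-to-one singularity."""
        cols = self.fractions.columns[:-1] if drop_last else self.fractions.columns
        return self.fractions[list(cols)]


def filter_probes(beta: BetaMatrix, manifest: ProbeManifest,
                  detection_p: DetectionPMatrix | None = None,
                  p_threshold: float = 0.1) -> tuple[BetaMatrix, FilterReport]:
    """Remove flagged, sex-chromosome, detection-failed and missing probes.

    Precedence: snp_overlap > cross_reactive > sex_chromosome > detection_p
    (exceedance in any sample) > missing beta.  Idempotent: filtering a
    filtered matrix removes nothing.
    """
    if not 0.0 <= p_threshold <= 1.0:
        raise ValidationError(f"p_threshold must be in [0, 1], got {p_threshold}")
    probes = beta.values.index
    missing_manifest = probes.difference(manifest.df.index)
    if len(missing_manifest):
        raise ValidationError(
            f"probes absent from manifest: {list(missing_manifest[:5])}"
        )
    mdf = manifest.df.loc[probes]

    masks = {
        "snp_overlap": mdf["snp_overlap"].to_numpy(copy=True),
        "cross_reactive": mdf["cross_reactive"].to_numpy(),
        "sex_chromosome": mdf["chrom"].isin(["chrX", "chrY"]).to_numpy(),
    }
    if detection_p is not None:
        dp = detection_p.values.reindex(index=probes, columns=beta.values.columns)
        if dp.isna().any().any():
            raise ValidationError("detection-p matrix does not cover the beta matrix")
        masks["detection_p"] = (dp.to_numpy() > p_threshold).any(axis=1)
    else:
        masks["detection_p"] = np.zeros(len(probes), dtype=bool)
    masks["missing"] = beta.values.isna().any(axis=1).to_numpy()

    removed: dict[str, int] = {}
    claimed = np.zeros(len(probes), dtype=bool)
    for rule in FILTER_RULES:
        hit = masks[rule] & ~claimed
        removed[rule] = int(hit.sum())
        claimed |= masks[rule]

    kept = beta.values.loc[~claimed]
    report = FilterReport(n_input=len(probes), removed=removed, retained=len(kept))
    return BetaMatrix(kept.copy()), report


def estimate_cell_proportions(beta: BetaMatrix, reference: CellReference) -> CellProportions:
    """Constrained least-squares deconvolution of leukocyte composition.

    Solves, per sample, ``min ||b - R w||^2  s.t.  w >= 0, sum(w) = 1`` on
    the reference probe subset.  Deterministic; raises if the reference is
    rank-deficient (collinear cell types cannot be separated).
    """
    ref_probes = [p for p in reference.probe_ids if p in beta.values.index]
    if len(ref_probes) < len(reference.cell_types):
        raise ValidationError(
            "fewer informative reference probes than cell types "
            f"({len(ref_probes)} < {len(reference.cell_types)})"
        )
    R = reference.profiles.loc[ref_probes].to_numpy()
    rank = np.linalg.matrix_rank(R)
    if rank < R.shape[1]:
        # name the cell types loading on the null space
        _, _, vt = np.linalg.svd(R)
        null = np.abs(vt[-1])
        guilty = [t for t, v in zip(reference.cell_types, null) if v > 0.3]
        raise ValidationError(f"reference is rank-deficient; collinear cell types: {guilty}")

    B = beta.values.loc[ref_probes].to_numpy()
    if np.isnan(B).any():
        raise ValidationError("missing beta values on reference probes; filter first")
    k = R.shape[1]
    n = B.shape[1]
    out = np.empty((n, k))
    x0 = np.full(k, 1.0 / k)
    constraints = {"type": "eq", "fun": lambda w: w.sum() - 1.0}
    bounds = [(0.0, 1.0)] * k
    for j in range(n):
        b = B[:, j]

        def obj(wv, b=b):
            r = R @ wv - b
            return r @ r

        def grad(wv, b=b):
            return 2.0 * R.T @ (R @ wv - b)

        res = optimize.minimize(
            obj, x0, jac=grad, bounds=bounds, constraints=constraints,
            method="SLSQP", options={"maxiter": 200, "ftol": 1e-14},
        )
        w = np.clip(res.x, 0.0, None)
        out[j] = w / w.sum()
    return CellProportions(
        pd.DataFrame(out, index=pd.Index(beta.sample_ids, name="sample_id"),
                     columns=reference.cell_types)
    )


def pca_outlier_screen(beta: BetaMatrix, k_components: int = 3,
                       sd_threshold: float = 3.0) -> list[str]:
    """Flag samples with extreme scores on the leading principal axes.

    Samples are projected onto the top-``k`` principal axes of the centered
    beta matrix; a sample is flagged when its score on any axis lies more
    than ``sd_threshold`` robust SDs (1.4826 * MAD) from that axis's median.
    Flagging only warns — no sample is ever dropped automatically.
    """
    n = len(beta.sample_ids)
    if n < 4:
        raise ValidationError("PCA outlier screen needs at least 4 samples")
    if k_components >= n:
        raise ValidationError(f"k_components ({k_components}) must be < n_samples ({n})")
    X = beta.values.to_numpy().T  # samples x probes
    if np.isnan(X).any():
        raise ValidationError("missing beta values; filter before the PCA screen")
    X = X - X.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    scores = X @ vt[:k_components].T
    flagged: set[str] = set()
    for axis in range(k_components):
        col = scores[:, axis]
        med = np.median(col)
        mad = np.median(np.abs(col - med))
        scale = 1.4826 * mad
        if scale == 0:
            continue
        for i in np.flatnonzero(np.abs(col - med) > sd_threshold * scale):
            flagged.add(beta.sample_ids[i])
    out = sorted(flagged)
    if out:
        warnings.warn(f"PCA outlier screen flagged samples: {out}", stacklevel=2)
    return out
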