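"""Matched-control selection and episignature discovery statistics.

The differential-methylation model is the limma-style workflow: per probe,
ordinary least squares of the beta value on an intercept, the case
indicator, and cell-composition covariates; per-probe residual variances
are shrunk toward an empirical-Bayes prior estimated across all probes by
moment matching on log variances (scaled inverse-chi-square prior with
``d0`` prior degrees of freedom and prior variance ``s0^2``); the moderated
t-statistic uses the posterior variance and gains ``d0`` degrees of
freedom.  P-values are adjusted with the Benjamini-Hochberg step-up.

Probe-set selection sweeps a grid of significance cutoffs (or top-N sizes),
prunes inter-probe correlation, and keeps the probe set with the best
case/control separation (mean silhouette width), mirroring the
"vary the p-value cutoffs, measure importance by ROC and correlation,
select the best clustering" strategy of episignature discovery.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.special import polygamma
from sklearn.metrics import roc_auc_score, silhouette_score
from statsmodels.stats.multitest import multipletests

from .io import BetaMatrix, SampleSheet, ValidationError
from .preprocess import CellProportions

__all__ = [
    "MatchResult",
    "ProbeModelFit",
    "VariancePrior",
    "EpisignatureProbeSet",
    "MDSCoordinates",
    "Dendrogram",
    "match_controls",
    "fit_probe_models",
    "squeeze_variances",
    "trigamma_inverse",
    "moderated_t_test",
    "benjamini_hochberg",
    "build_dmp_table",
    "differential_methylation",
    "probe_auc",
    "prune_correlated",
    "evaluate_separation",
    "select_episignature",
    "classical_mds",
    "hierarchical_clustering",
]

DEFAULT_CUTOFF_GRID = (1e-12, 1e-8, 1e-4, 0.05)
DMP_ALPHA = 0.05

# minimum silhouette for a selection to count as a real signature rather
# than noise (null cohorts score near 0, planted ones well above)
MIN_SEPARATION = 0.25


# ---------------------------------------------------------------------------
# matching


@dataclass
class MatchResult:
    """Case -> matched-control assignment, without replacement."""

    matches: dict  # case_id -> list of control ids
    ratio: int
    exact_on: tuple
    nearest_on: str

    @property
    def control_ids(self) -> list[str]:
        out: list[str] = []
        for case in sorted(self.matches):
            out.extend(self.matches[case])
        return out

    @property
    def case_ids(self) -> list[str]:
        return sorted(self.matches)


def match_controls(cases: SampleSheet, pool: SampleSheet, ratio: int = 4,
                   exact_on: tuple = ("sex", "batch", "array_type"),
                   nearest_on: str = "age") -> MatchResult:
    """Greedy nearest-neighbour matching without replacement.

    Cases are processed in sample-id order; a control is eligible only if it
    matches the case exactly on every categorical variable in ``exact_on``;
    among eligible controls the ``ratio`` nearest in ``nearest_on`` are
    taken, ties in the distance broken by control id.  Raises (naming the
    case) when a case cannot be given ``ratio`` controls — no silent
    relaxation of the matching constraints.
    """
    if ratio < 1:
        raise ValidationError("matching ratio must be >= 1")
    case_ids = set(r.sample_id for r in cases)
    if case_ids & set(r.sample_id for r in pool):
        raise ValidationError("control pool overlaps the case set")
    available = {r.sample_id: r for r in pool.records}
    matches: dict[str, list[str]] = {}
    for case in sorted(cases.records, key=lambda r: r.sample_id):
        eligible = [
            c for c in available.values()
            if all(getattr(c, k) == getattr(case, k) for k in exact_on)
        ]
        eligible.sort(key=lambda c: (abs(getattr(c, nearest_on) - getattr(case, nearest_on)),
                                     c.sample_id))
        if len(eligible) < ratio:
            raise ValidationError(
                f"insufficient eligible controls for case {case.sample_id!r}: "
                f"need {ratio}, found {len(eligible)}"
            )
        chosen = [c.sample_id for c in eligible[:ratio]]
        for cid in chosen:
            del available[cid]
        matches[case.sample_id] = chosen
    return MatchResult(matches=matches, ratio=ratio, exact_on=tuple(exact_on),
                       nearest_on=nearest_on)


# ---------------------------------------------------------------------------
# linear model + empirical Bayes


@dataclass
class ProbeModelFit:
    """Per-probe OLS summaries from the case/control + covariates design."""

    probe_ids: list
    delta_beta: np.ndarray  # case-indicator coefficient, beta units
    s2: np.ndarray          # residual variance per probe
    df_residual: float      # n - p, constant across (complete-data) probes
    v: float                # unscaled variance of the case coefficient
    n_samples: int


def fit_probe_models(beta: BetaMatrix, sheet: SampleSheet,
                     cell_proportions: CellProportions | None = None) -> ProbeModelFit:
    """OLS of beta on [intercept, case indicator, cell-fraction covariates].

    One cell-fraction column is dropped to avoid the sum-to-one singularity.
    Returns the case coefficient (adjusted case-control beta difference),
    residual variance, residual df and the unscaled coefficient variance.
    """
    samples = sheet.sample_ids
    Y = beta.values[samples].to_numpy()
    if np.isnan(Y).any():
        raise ValidationError("missing beta values; filter probes before model fitting")
    labels = np.array([1.0 if r.group_label == "case" else 0.0 for r in sheet.records])
    if labels.min() == labels.max():
        raise ValidationError("both cases and controls are required in the design")
    cols = [np.ones(len(samples)), labels]
    names = ["intercept", "case"]
    if cell_proportions is not None:
        cp = cell_proportions.design_columns().reindex(samples)
        if cp.isna().any().any():
            raise ValidationError("cell proportions missing for some design samples")
        for c in cp.columns:
            cols.append(cp[c].to_numpy())
            names.append(str(c))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, vt = np.linalg.svd(X)
        null = np.abs(vt[-1])
        guilty = [n for n, v in zip(names, null) if v > 0.3]
        raise ValidationError(f"rank-deficient design; collinear columns: {guilty}")
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = Y @ X @ xtx_inv  # probes x p
    resid = Y - coef @ X.T
    df_resid = X.shape[0] - X.shape[1]
    if df_resid < 1:
        raise ValidationError("residual degrees of freedom must be >= 1")
    s2 = (resid ** 2).sum(axis=1) / df_resid
    return ProbeModelFit(
        probe_ids=list(beta.values.index),
        delta_beta=coef[:, 1],
        s2=s2,
        df_residual=float(df_resid),
        v=float(xtx_inv[1, 1]),
        n_samples=len(samples),
    )


@dataclass
class VariancePrior:
    """Scaled inverse-chi-square prior on residual variances.

    ``d0 = 0`` is the no-shrinkage limit (ordinary t-test); ``d0 = +inf``
    collapses every posterior variance onto ``s0_2`` (z-test).
    """

    d0: float   # prior degrees of freedom in [0, +inf]
    s0_2: float  # prior variance

    def __post_init__(self) -> None:
        if not self.d0 >= 0:
            raise ValidationError("prior degrees of freedom must be >= 0")
        if not self.s0_2 > 0:
            raise ValidationError("prior variance must be > 0")


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve psi'(x) = y for x by Newton iteration on 1/psi'."""
    if y <= 0:
        raise ValidationError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) / x < tol:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df_residual: float) -> tuple[VariancePrior, np.ndarray]:
    """Estimate the variance prior and shrink per-probe variances toward it.

    Moment matching on ``z = log s^2``: the excess of Var(z) over
    ``psi'(d_g/2)`` estimates ``psi'(d0/2)`` (trigamma inversion by Newton
    iteration); when the excess is <= 0 the probe variances are consistent
    with a single common variance and ``d0 = +inf``.  ``s0^2`` comes from
    the mean equation of the log-variance distribution.  Posterior
    variances are ``(d0 s0^2 + d_g s^2) / (d0 + d_g)``.
    """
    s2 = np.asarray(s2, dtype=float)
    if len(s2) < 10:
        raise ValidationError("variance squeeze needs at least 10 probes")
    if (s2 <= 0).any() or not np.isfinite(s2).all():
        raise ValidationError("residual variances must be positive and finite")
    d = float(df_residual)
    z = np.log(s2)
    e = z - polygamma(0, d / 2.0) + np.log(d / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(polygamma(1, d / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_2 = float(np.exp(e_mean + polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s0_2 + d * s2) / (d0 + d)
    else:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
        post = np.full_like(s2, s0_2)
    prior = VariancePrior(d0=d0, s0_2=s0_2)
    return prior, post


def moderated_t_test(fit: ProbeModelFit, prior: VariancePrior) -> pd.DataFrame:
    """Moderated t and two-sided p per probe (pre-adjustment).

    ``t = delta / (s_tilde sqrt(v))`` on ``d0 + d_g`` degrees of freedom;
    ``d0 = 0`` reduces to the ordinary t-test, ``d0 = +inf`` to a z-test
    with the pooled prior variance.
    """
    if fit.v <= 0:
        raise ValidationError("unscaled coefficient variance must be > 0")
    d = fit.df_residual
    if np.isinf(prior.d0):
        s_tilde2 = np.full_like(fit.s2, prior.s0_2)
        t = fit.delta_beta / np.sqrt(s_tilde2 * fit.v)
        p = 2.0 * stats.norm.sf(np.abs(t))
        df_total = np.inf
    else:
        s_tilde2 = (prior.d0 * prior.s0_2 + d * fit.s2) / (prior.d0 + d)
        t = fit.delta_beta / np.sqrt(s_tilde2 * fit.v)
        df_total = prior.d0 + d
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {"delta_beta": fit.delta_beta, "t": t, "df_total": df_total, "p": p},
        index=pd.Index(fit.probe_ids, name="probe_id"),
    )


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_dmp_table(fit: ProbeModelFit, prior: VariancePrior) -> pd.DataFrame:
    """Full DMP table: effect, moderated t, p, BH-adjusted p, direction."""
    table = moderated_t_test(fit, prior)
    table["adj_p"] = benjamini_hochberg(table["p"].to_numpy())
    table["direction"] = np.where(table["delta_beta"] < 0, "hypo", "hyper")
    return table


def differential_methylation(beta: BetaMatrix, sheet: SampleSheet,
                             cell_proportions: CellProportions | None = None) -> pd.DataFrame:
    """Fit, squeeze and test in one call; returns the DMP table."""
    fit = fit_probe_models(beta, sheet, cell_proportions)
    prior, _ = squeeze_variances(fit.s2, fit.df_residual)
    return build_dmp_table(fit, prior)


# ---------------------------------------------------------------------------
# probe-set selection


def probe_auc(values, labels) -> float:
    """Direction-agnostic Mann-Whitney AUC of one probe; ties count 1/2."""
    labels = np.asarray(labels).astype(bool)
    if labels.all() or (~labels).all():
        raise ValidationError("probe AUC needs both classes present")
    a = roc_auc_score(labels, np.asarray(values, dtype=float))
    return float(max(a, 1.0 - a))


def prune_correlated(candidates, beta: BetaMatrix, r_max: float = 0.9) -> list[str]:
    """Greedy correlation pruning in rank order.

    A probe is dropped iff its absolute Pearson correlation with any
    already-retained probe exceeds ``r_max``.  Deterministic.
    """
    candidates = list(candidates)
    if not candidates:
        return []
    X = beta.select_probes(candidates).values.to_numpy()
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf  # constant probes correlate with nothing
    Z = (X - mu) / sd
    n = X.shape[1]
    retained_idx: list[int] = []
    for i in range(len(candidates)):
        if retained_idx:
            r = np.abs(Z[retained_idx] @ Z[i] / n)
            if (r > r_max).any():
                continue
        retained_idx.append(i)
    return [candidates[i] for i in retained_idx]


def evaluate_separation(values: np.ndarray, labels) -> float:
    """Mean silhouette width of the case/control labelling (Euclidean)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] == 0:
        raise ValidationError("separation needs a non-empty sample x probe matrix")
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValidationError("separation needs >= 2 samples in each class")
    return float(silhouette_score(values, labels, metric="euclidean"))


@dataclass
class EpisignatureProbeSet:
    """Selected episignature probes plus the selection audit trail."""

    probes: list
    cutoff: float
    score: float
    significant: bool
    r_max: float
    selection_log: pd.DataFrame = field(repr=False)
    auc: pd.Series = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.probes)


def _ranked_probes(dmp_table: pd.DataFrame) -> pd.DataFrame:
    """Rows sorted by adj_p ascending, |delta_beta| descending, probe id."""
    order = dmp_table.assign(_abs=dmp_table["delta_beta"].abs())
    order = order.sort_index(kind="mergesort")
    order = order.sort_values(by=["adj_p", "_abs"], ascending=[True, False],
                              kind="mergesort")
    return order.drop(columns="_abs")


def select_episignature(dmp_table: pd.DataFrame, beta: BetaMatrix, labels,
                        cutoff_grid=DEFAULT_CUTOFF_GRID,
                        r_max: float = 0.9) -> EpisignatureProbeSet:
    """Sweep cutoffs, prune correlation, keep the best-separating probe set.

    Grid entries <= 1 are adjusted-p cutoffs; integer entries > 1 are top-N
    probe counts.  Candidates are ranked by adjusted p (ties by
    ``|delta_beta|`` descending, then probe id), pruned with
    :func:`prune_correlated`, and scored by mean silhouette width of the
    case/control labelling; exact score ties break toward the smaller set.
    A best score below ``MIN_SEPARATION`` flags the selection as
    non-significant (no real signature found).
    """
    cutoff_grid = list(cutoff_grid)
    if not cutoff_grid:
        raise ValidationError("cutoff grid must not be empty")
    labels = np.asarray(labels)
    ranked = _ranked_probes(dmp_table)
    rows = []
    best = None  # (score, cutoff, probes)
    for cutoff in cutoff_grid:
        if cutoff <= 1:
            cand = list(ranked[ranked["adj_p"] < cutoff].index)
        else:
            cand = list(ranked.head(int(cutoff)).index)
        retained = prune_correlated(cand, beta, r_max=r_max) if cand else []
        if len(retained) >= 1:
            try:
                score = evaluate_separation(
                    beta.select_probes(retained).values.to_numpy().T, labels
                )
            except ValidationError:
                score = float("-inf")
        else:
            score = float("-inf")
        rows.append((cutoff, len(cand), len(retained), score))
        key = (score, -len(retained))
        if best is None or key > (best[0], -len(best[2])):
            best = (score, cutoff, retained)
    log = pd.DataFrame(rows, columns=["cutoff", "n_candidates", "n_after_prune", "score"])
    score, cutoff, probes = best
    if not probes or not np.isfinite(score):
        return EpisignatureProbeSet(
            probes=[], cutoff=float(cutoff), score=float("nan"), significant=False,
            r_max=r_max, selection_log=log, auc=pd.Series(dtype=float),
        )
    # folded AUC is symmetric in the label coding, so any binarization works
    bool_labels = labels == np.unique(labels)[0]
    auc = pd.Series({p: probe_auc(beta.values.loc[p].to_numpy(), bool_labels) for p in probes})
    return EpisignatureProbeSet(
        probes=probes, cutoff=float(cutoff), score=float(score),
        significant=bool(score > MIN_SEPARATION), r_max=r_max,
        selection_log=log, auc=auc,
    )


# ---------------------------------------------------------------------------
# embedding + clustering


@dataclass
class MDSCoordinates:
    coords: pd.DataFrame  # samples x k
    eigenvalues: np.ndarray


def classical_mds(distance: np.ndarray, k: int = 2, labels=None) -> MDSCoordinates:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers ``-D^2/2``, eigendecomposes, and returns the top-``k``
    coordinates scaled by the square root of the eigenvalues (negative
    eigenvalues truncated at zero).  Deterministic up to sign.
    """
    D = np.asarray(distance, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValidationError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    lam = np.clip(evals[:k], 0.0, None)
    coords = evecs[:, :k] * np.sqrt(lam)[None, :]
    idx = pd.Index(labels if labels is not None else range(n), name="sample_id")
    df = pd.DataFrame(coords, index=idx, columns=[f"dim{i + 1}" for i in range(k)])
    return MDSCoordinates(coords=df, eigenvalues=evals)


class Dendrogram:
    """Agglomerative merge tree over samples, newick-serializable."""

    def __init__(self, linkage_matrix: np.ndarray, labels: list[str]):
        self.linkage = linkage_matrix
        self.labels = list(labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> dict:
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, assign)}

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 4 * len(self.labels) + 100))

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        try:
            left = walk(tree.left, tree.dist)
            right = walk(tree.right, tree.dist)
            return f"({left},{right});"
        finally:
            sys.setrecursionlimit(old)


def hierarchical_clustering(values: np.ndarray, labels=None, metric: str = "euclidean",
                            linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of samples (rows); default complete linkage
    with Euclidean distances, matching standard methylation heatmaps."""
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("clustering needs >= 2 samples")
    if np.isnan(X).any():
        raise ValidationError("NaN in clustering input")
    Z = hierarchy.linkage(X, method=linkage, metric=metric)
    labs = list(labels) if labels is not None else [str(i) for i in range(X.shape[0])]
    if len(labs) != X.shape[0]:
        raise ValidationError("label count must match sample count")
    return Dendrogram(Z, labs)
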