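"""SVM training, MVP scoring and the two cross-validation protocols.

The classifier is a linear support vector machine trained on the selected
episignature probes.  Label 1 is the case cohort; label 0 is its matched
controls plus a seeded 75% of every other available cohort (unmatched
controls and other-disorder samples), so the model learns to separate the
disorder both from health and from other episignatures.  The remaining 25%
is reserved for testing.  Decision values are mapped to a methylation
variant pathogenicity (MVP) score in [0, 1] by Platt sigmoid calibration
fitted on the training decision values; the mapping is monotone, so a more
case-like methylation profile never lowers the score.

``cross_validate`` re-runs the entire pipeline — matching, differential
methylation, probe selection, training — on the retained samples of each
round, so held-out samples influence nothing (no leakage).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from . import discovery
from .io import BetaMatrix, SampleSheet, ValidationError
from .preprocess import CellProportions

__all__ = [
    "TrainingPartition",
    "MVPModel",
    "CVResult",
    "assemble_training_partition",
    "train_mvp",
    "score_mvp",
    "cross_validate",
]

CLASSIFICATION_THRESHOLD = 0.5  # decision rule for CV accuracy
HIGH_SCORE_BOUND = 0.75         # descriptive "high score" bound, reported separately


@dataclass
class TrainingPartition:
    """Train/test split following the 75/25 composition scheme."""

    train_ids: list
    train_labels: np.ndarray  # 1 = case, 0 = control/other
    test_ids: list
    fraction_other_in_train: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValidationError("train and test sets overlap")
        if len(self.train_ids) != len(self.train_labels):
            raise ValidationError("label count must match training ids")


def assemble_training_partition(sheet: SampleSheet, matched: discovery.MatchResult,
                                fraction: float = 0.75, seed: int = 0) -> TrainingPartition:
    """Compose the training set: cases + matched controls + 75% of the rest.

    The "rest" is every pool sample that is neither a case nor a matched
    control (unmatched controls, other-disorder cohorts); the draw is seeded
    and stratified per cohort (``group_label``); the remaining 25% becomes
    the test set.  Validation-role cases are excluded entirely.
    """
    if not 0.0 < fraction < 1.0:
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    case_ids = list(matched.case_ids)
    control_ids = list(matched.control_ids)
    in_model = set(case_ids) | set(control_ids)
    other = [
        r for r in sheet.records
        if r.sample_id not in in_model and r.group_label != "case"
    ]
    if not other:
        raise ValidationError("no other-cohort samples available for the 75/25 draw")
    rng = np.random.default_rng(seed)
    train_ids = case_ids + control_ids
    labels = [1] * len(case_ids) + [0] * len(control_ids)
    test_ids: list[str] = []
    groups = sorted(set(r.group_label for r in other))
    for g in groups:
        members = sorted(r.sample_id for r in other if r.group_label == g)
        n_train = int(round(fraction * len(members)))
        perm = rng.permutation(len(members))
        chosen = [members[i] for i in perm[:n_train]]
        train_ids.extend(chosen)
        labels.extend([0] * len(chosen))
        test_ids.extend(members[i] for i in perm[n_train:])
    return TrainingPartition(
        train_ids=train_ids,
        train_labels=np.asarray(labels),
        test_ids=sorted(test_ids),
        fraction_other_in_train=fraction,
        seed=seed,
    )


@dataclass
class MVPModel:
    """Frozen probe list + linear SVM + Platt calibration."""

    probes: list
    weights: np.ndarray
    bias: float
    platt_a: float
    platt_b: float
    metadata: dict = field(default_factory=dict)

    def decision_function(self, beta: BetaMatrix) -> pd.Series:
        missing = [p for p in self.probes if p not in beta.values.index]
        if missing:
            raise ValidationError(f"matrix is missing frozen probes: {missing[:10]}")
        X = beta.values.loc[list(self.probes)].to_numpy().T
        if np.isnan(X).any():
            raise ValidationError("missing beta values on frozen probes")
        return pd.Series(X @ self.weights + self.bias, index=beta.sample_ids)

    def to_dict(self) -> dict:
        return {
            "probes": list(self.probes),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MVPModel":
        return cls(
            probes=list(d["probes"]),
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            platt_a=float(d["platt_a"]),
            platt_b=float(d["platt_b"]),
            metadata=dict(d.get("metadata", {})),
        )


def train_mvp(beta: BetaMatrix, partition: TrainingPartition, probe_set) -> MVPModel:
    """Train the linear SVM with inverse-class-frequency weights and fit the
    sigmoid score calibration on the training decision values."""
    probes = list(probe_set.probes) if hasattr(probe_set, "probes") else list(probe_set)
    if not probes:
        raise ValidationError("empty probe set")
    missing = [p for p in probes if p not in beta.values.index]
    if missing:
        raise ValidationError(f"probes absent from matrix: {missing[:10]}")
    y = np.asarray(partition.train_labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("training set must contain both classes")
    X = beta.values.loc[probes, partition.train_ids].to_numpy().T
    clf = SVC(kernel="linear", C=1.0, class_weight="balanced")
    clf.fit(X, y)
    d = clf.decision_function(X)
    # Platt scaling: logistic fit of the labels on the decision values
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    lr.fit(d.reshape(-1, 1), y)
    train_hash = hashlib.sha256(
        (",".join(sorted(partition.train_ids))).encode()
    ).hexdigest()
    return MVPModel(
        probes=probes,
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        platt_a=float(lr.coef_[0, 0]),
        platt_b=float(lr.intercept_[0]),
        metadata={
            "n_train": len(partition.train_ids),
            "seed": partition.seed,
            "fraction_other_in_train": partition.fraction_other_in_train,
            "train_ids_sha256": train_hash,
            "calibration": "platt_sigmoid",
        },
    )


def score_mvp(model: MVPModel, beta: BetaMatrix) -> pd.Series:
    """Calibrated MVP score in [0, 1] per sample, monotone in the SVM
    decision value."""
    d = model.decision_function(beta)
    return pd.Series(expit(model.platt_a * d.to_numpy() + model.platt_b),
                     index=d.index, name="mvp_score")


@dataclass
class CVResult:
    mode: str
    rounds: list  # per round: dict(held_out, scores, predicted, train_ids, ...)
    threshold: float

    @property
    def accuracy(self) -> float:
        correct = 0
        total = 0
        for r in self.rounds:
            for sid, pred in r["predicted"].items():
                total += 1
                truth = 1 if r["true_labels"][sid] == "case" else 0
                correct += int(pred == truth)
        return correct / total if total else float("nan")

    @property
    def held_out_counts(self) -> dict:
        counts: dict[str, int] = {}
        for r in self.rounds:
            for sid in r["held_out"]:
                counts[sid] = counts.get(sid, 0) + 1
        return counts


def _run_round(beta, retained_sheet, cell_proportions, held_ids, *, match_ratio,
               cutoff_grid, r_max, partition_seed, exact_on, threshold, group_of):
    cases_r = retained_sheet.where(group_label="case")
    pool_r = retained_sheet.where(group_label="control")
    match_r = discovery.match_controls(cases_r, pool_r, ratio=match_ratio,
                                       exact_on=exact_on)
    model_ids = match_r.case_ids + match_r.control_ids
    model_sheet = retained_sheet.subset(model_ids)
    model_beta = beta.select_samples(model_ids)
    cp = None
    if cell_proportions is not None:
        cp = CellProportions(cell_proportions.fractions.loc[model_ids])
    dmp = discovery.differential_methylation(model_beta, model_sheet, cp)
    labels = np.array([r.group_label for r in model_sheet.records])
    probe_set = discovery.select_episignature(dmp, model_beta, labels,
                                              cutoff_grid=cutoff_grid, r_max=r_max)
    if not probe_set.probes:
        raise ValidationError("probe selection returned an empty set in a CV round")
    partition = assemble_training_partition(retained_sheet, match_r,
                                            fraction=0.75, seed=partition_seed)
    model = train_mvp(beta, partition, probe_set)
    score_ids = held_ids if held_ids else partition.train_ids
    scores = score_mvp(model, beta.select_samples(score_ids))
    predicted = {sid: int(s >= threshold) for sid, s in scores.items()}
    return {
        "held_out": list(held_ids),
        "scores": scores,
        "predicted": predicted,
        "true_labels": {sid: group_of[sid] for sid in score_ids},
        "train_ids": list(partition.train_ids),
        "n_probes": len(probe_set.probes),
    }


def cross_validate(beta: BetaMatrix, sheet: SampleSheet,
                   cell_proportions: CellProportions | None = None,
                   mode: str = "loo", rounds: int = 20, holdout_frac: float = 0.25,
                   seed: int = 0, match_ratio: int = 4,
                   cutoff_grid=discovery.DEFAULT_CUTOFF_GRID, r_max: float = 0.9,
                   threshold: float = CLASSIFICATION_THRESHOLD,
                   exact_on: tuple = ("sex", "batch", "array_type")) -> CVResult:
    """Leave-one-out or repeated leave-25%-out cross-validation.

    Every round re-runs matching, differential methylation, probe selection
    and SVM training on the retained samples only, then scores the held-out
    samples.  LOO holds out each case exactly once; ``repeated_holdout``
    holds out a seeded ``holdout_frac`` of cases together with their
    (globally) matched controls for ``rounds`` rounds.
    """
    if rounds < 1:
        raise ValidationError("rounds must be >= 1")
    if mode not in ("loo", "repeated_holdout"):
        raise ValidationError(f"unknown CV mode {mode!r}")
    group_of = {r.sample_id: r.group_label for r in sheet.records}
    case_ids = sorted(r.sample_id for r in sheet.records if r.group_label == "case")
    if not case_ids:
        raise ValidationError("no case samples in the sheet")
    all_ids = sheet.sample_ids
    results = []
    common = dict(match_ratio=match_ratio, cutoff_grid=cutoff_grid, r_max=r_max,
                  exact_on=exact_on, threshold=threshold, group_of=group_of)

    if mode == "loo":
        for i, held in enumerate(case_ids):
            retained = sheet.subset([s for s in all_ids if s != held])
            results.append(
                _run_round(beta, retained, cell_proportions, [held],
                           partition_seed=seed + i, **common)
            )
    else:
        # global matching defines the case-control groups held out jointly
        match0 = discovery.match_controls(sheet.where(group_label="case"),
                                          sheet.where(group_label="control"),
                                          ratio=match_ratio, exact_on=exact_on)
        rng = np.random.default_rng(seed)
        n_held = int(round(holdout_frac * len(case_ids)))
        for i in range(rounds):
            held_cases = sorted(
                rng.choice(case_ids, size=n_held, replace=False).tolist()
            ) if n_held else []
            held = list(held_cases)
            for c in held_cases:
                held.extend(match0.matches[c])
            retained = sheet.subset([s for s in all_ids if s not in set(held)])
            results.append(
                _run_round(beta, retained, cell_proportions, held,
                           partition_seed=seed + i, **common)
            )
    return CVResult(mode=mode, rounds=results, threshold=threshold)
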