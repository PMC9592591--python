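"""Repeated stratified one-replicate-out evaluation of profile classifiers.

Organ (or strain) discrimination from N-glycan profiles is scored by a
repeated holdout scheme: in every repetition exactly one replicate of
each class is drawn uniformly at random as the test set and the rest
train four classifier families — a CART decision tree, a single-hidden-
layer feed-forward network, a random forest and an RBF-kernel SVM with
feature standardisation.  Hyperparameters are tuned once by inner
cross-validated grid search on the first training split and the tuned
settings are reused across repetitions; per-class F1 scores are then
averaged over repetitions and summarised as mean +/- SE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .quantification import ProfileMatrix

__all__ = [
    "ALGORITHMS",
    "SplitScheme",
    "EvaluationReport",
    "stratified_split",
    "f1_per_class",
    "evaluate",
    "select_features_in_reference",
]

ALGORITHMS = ("decision_tree", "neural_network", "random_forest", "svm")


@dataclass(frozen=True)
class SplitScheme:
    """One stratified holdout split: one test replicate per class."""

    test_index: tuple[int, ...]
    train_index: tuple[int, ...]
    seed: int
    repetition: int = 0


def stratified_split(
    labels: Sequence[str], seed: int, repetition: int = 0
) -> SplitScheme:
    """Hold out exactly one sample per class, uniformly at random.

    Reproducible: the same (seed, repetition) pair yields the same
    split.  Classes with fewer than two replicates cannot be split.
    """
    labels = list(labels)
    rng = np.random.default_rng(np.random.SeedSequence([seed, repetition]))
    by_class: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    test: list[int] = []
    for lab in sorted(by_class):
        idx = by_class[lab]
        if len(idx) < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 replicates")
        test.append(idx[rng.integers(len(idx))])
    test_set = set(test)
    train = [i for i in range(len(labels)) if i not in test_set]
    return SplitScheme(tuple(sorted(test)), tuple(train), seed, repetition)


def f1_per_class(
    y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str] | None = None
) -> pd.Series:
    """Per-class F1 = 2PR/(P+R), with F1 = 0 when P + R = 0."""
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    scores = f1_score(
        list(y_true), list(y_pred), labels=list(classes), average=None, zero_division=0
    )
    return pd.Series(scores, index=list(classes), name="f1")


def default_estimators(seed: int) -> dict[str, object]:
    """The four classifier families at their base configurations."""
    return {
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "neural_network": Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPClassifier(
                        hidden_layer_sizes=(10,),
                        solver="lbfgs",
                        max_iter=500,
                        random_state=seed,
                    ),
                ),
            ]
        ),
        "random_forest": RandomForestClassifier(n_estimators=100, random_state=seed),
        "svm": Pipeline(
            [("scale", StandardScaler()), ("svc", SVC(kernel="rbf", random_state=seed))]
        ),
    }


# Small default search grids; the tuned values are recorded in the report.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "decision_tree": {"min_samples_split": [2, 4]},
    "neural_network": {"mlp__hidden_layer_sizes": [(5,), (10,)], "mlp__alpha": [1e-4, 1e-1]},
    "random_forest": {"max_features": ["sqrt", 0.3]},
    "svm": {"svc__C": [1.0, 10.0], "svc__gamma": ["scale", 0.01]},
}


@dataclass
class EvaluationReport:
    """Per-algorithm, per-class F1 summary over holdout repetitions.

    ``per_class`` columns: algorithm, class_label, f1_mean, f1_se.
    ``overall`` columns: algorithm, f1_mean, f1_se — the unweighted mean
    of the per-class means, with SE taken across classes.  SE values are
    NaN when they cannot be estimated (a single repetition / class).
    """

    per_class: pd.DataFrame
    overall: pd.DataFrame
    n_reps: int
    seed: int
    tuning: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "seed": self.seed,
            "tuning": self.tuning,
            "per_class": self.per_class.to_dict(orient="records"),
            "overall": self.overall.to_dict(orient="records"),
        }


def _tune(
    name: str,
    estimator,
    grid: Mapping[str, list],
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    cv_folds: int,
):
    if not grid:
        return estimator, {}
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(estimator, dict(grid), cv=cv, scoring="f1_macro", n_jobs=1)
    search.fit(X, y)
    return search.best_estimator_, dict(search.best_params_)


def evaluate(
    matrix: ProfileMatrix,
    algorithms: Sequence[str] = ALGORITHMS,
    n_reps: int = 1000,
    seed: int = 0,
    tune: bool = True,
    grids: Mapping[str, Mapping[str, list]] | None = None,
    cv_folds: int = 3,
) -> EvaluationReport:
    """Repeated stratified-holdout evaluation of the classifier families.

    Each repetition holds out one replicate per class, fits every
    algorithm on the rest and records per-class F1 on the held-out
    samples.  Tuning (when enabled) runs once on the first repetition's
    training set and the chosen hyperparameters are reused throughout;
    the tuned values are recorded in the report.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    unknown = set(algorithms) - set(ALGORITHMS)
    if unknown:
        raise ValueError(f"unknown algorithms: {sorted(unknown)}")
    X = matrix.values.to_numpy(dtype=float)
    y = matrix.class_labels.to_numpy()
    classes = sorted(set(y))
    if (X.std(axis=0) == 0).all():
        import warnings

        warnings.warn("all features are constant; classification is degenerate")

    grids = DEFAULT_GRIDS if grids is None else grids
    base = default_estimators(seed)
    first = stratified_split(y, seed, repetition=0)
    tuned: dict[str, object] = {}
    tuning_record: dict[str, dict] = {}
    for name in algorithms:
        est = base[name]
        if tune:
            est, best = _tune(
                name, est, grids.get(name, {}), X[list(first.train_index)],
                y[list(first.train_index)], seed, cv_folds,
            )
        else:
            best = {}
        tuned[name] = est
        tuning_record[name] = best

    f1_store: dict[str, np.ndarray] = {
        name: np.empty((n_reps, len(classes))) for name in algorithms
    }
    for rep in range(n_reps):
        split = stratified_split(y, seed, repetition=rep)
        tr, te = list(split.train_index), list(split.test_index)
        for name in algorithms:
            model = clone(tuned[name])
            model.fit(X[tr], y[tr])
            pred = model.predict(X[te])
            f1_store[name][rep] = f1_per_class(y[te], pred, classes).to_numpy()

    per_class_rows = []
    overall_rows = []
    for name in algorithms:
        scores = f1_store[name]  # reps x classes
        means = scores.mean(axis=0)
        if n_reps > 1:
            ses = scores.std(axis=0, ddof=1) / np.sqrt(n_reps)
        else:
            ses = np.full(len(classes), np.nan)
        for cls, m, s in zip(classes, means, ses):
            per_class_rows.append((name, cls, m, s))
        overall_rows.append(
            (
                name,
                means.mean(),
                means.std(ddof=1) / np.sqrt(len(classes)) if len(classes) > 1 else np.nan,
            )
        )
    per_class = pd.DataFrame(
        per_class_rows, columns=["algorithm", "class_label", "f1_mean", "f1_se"]
    )
    overall = pd.DataFrame(overall_rows, columns=["algorithm", "f1_mean", "f1_se"])
    return EvaluationReport(per_class, overall, n_reps, seed, tuning_record)


def select_features_in_reference(
    matrix: ProfileMatrix, reference: Sequence[str]
) -> ProfileMatrix:
    """Restrict features to glycoforms in a reference library.

    Used for strain discrimination, where the non-reference strains'
    glycoforms are selected in concordance with the reference strain's
    library before evaluation.
    """
    keep = [c for c in matrix.values.columns if c in set(reference)]
    return ProfileMatrix(
        matrix.values[keep].copy(), matrix.mask[keep].copy(), matrix.samples.copy()
    )
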