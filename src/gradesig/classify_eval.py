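"""Train/test splitting, repeated cross-validation, the pure classifiers
(KNN, SVM radial/sigmoid, unpenalised logistic regression) and the
sensitivity / specificity / balanced-accuracy metrics.

The positive class is grade 3 throughout (detecting the higher grade is the
clinically meaningful "positive"); every report header records this.
Selection methods must be fitted on the training split only — the evaluation
grid enforces that by taking already-computed signatures and a split, and
judging every (selector, classifier) pair on the same held-out test samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.model_selection import RepeatedKFold
from sklearn.svm import SVC

from .core_io import ExpressionMatrix, PhenotypeTable, GRADE2, GRADE3
from .filter_select import SignatureSet

__all__ = [
    "SplitSpec",
    "CvSpec",
    "ConfusionCounts",
    "EvalResult",
    "split_train_test",
    "cross_validate",
    "train_classifier",
    "FittedClassifier",
    "sensitivity",
    "specificity",
    "balanced_accuracy",
    "confusion_from_predictions",
    "evaluate_grid",
    "round_half_away",
    "CLASSIFIER_KINDS",
]

CLASSIFIER_KINDS = ("knn", "svm_radial", "svm_sigmoid", "logistic")
POSITIVE_CLASS = GRADE3


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Decimal rounding with halves away from zero (0.6535 -> 0.654)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SplitSpec:
    train_n: int = 72
    test_n: int = 35
    stratified: bool = True
    seed: int = 0


@dataclass
class CvSpec:
    folds: int = 10
    repeats: int = 3
    seed: int = 0


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalResult:
    selector: str
    classifier: str
    hyperparams: dict
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    confusion: ConfusionCounts


def split_train_test(pheno: PhenotypeTable, spec: SplitSpec) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive train/test sample ids, reproducible from the seed.

    Stratified allocation keeps class proportions within one sample of the
    cohort proportions (largest-remainder apportionment of the train count).
    """
    ids = np.array(pheno.sample_ids)
    n = len(ids)
    if spec.train_n + spec.test_n != n:
        raise ValueError(f"train_n + test_n must equal cohort size {n}")
    if n < spec.train_n + 2:
        raise ValueError("need at least two test samples")
    rng = np.random.default_rng(spec.seed)

    if not spec.stratified:
        perm = rng.permutation(n)
        train = sorted(ids[perm[: spec.train_n]].tolist())
        test = sorted(ids[perm[spec.train_n :]].tolist())
    else:
        grades = pheno.grades_for(ids.tolist())
        classes = [GRADE2, GRADE3]
        quotas = {}
        exact = {g: (grades == g).sum() * spec.train_n / n for g in classes}
        floors = {g: int(np.floor(exact[g])) for g in classes}
        remainder = spec.train_n - sum(floors.values())
        by_frac = sorted(classes, key=lambda g: exact[g] - floors[g], reverse=True)
        for g in classes:
            quotas[g] = floors[g] + (1 if g in by_frac[:remainder] else 0)
        train_parts, test_parts = [], []
        for g in classes:
            members = ids[grades == g]
            perm = rng.permutation(len(members))
            train_parts.extend(members[perm[: quotas[g]]].tolist())
            test_parts.extend(members[perm[quotas[g] :]].tolist())
        train, test = sorted(train_parts), sorted(test_parts)

    train_grades = set(pheno.grades_for(train))
    test_grades = set(pheno.grades_for(test))
    if len(train_grades) < 2 or len(test_grades) < 2:
        raise ValueError("a class is absent from the train or test side")
    return train, test


class FittedClassifier:
    """A classifier plus the training z-scoring statistics it was fit under."""

    def __init__(self, kind: str, model, mean: np.ndarray, sd: np.ndarray, hyperparams: dict):
        self.kind = kind
        self.model = model
        self.mean = mean
        self.sd = sd
        self.hyperparams = hyperparams

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(self._transform(X))


def _make_estimator(kind: str, hyperparams: dict):
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=hyperparams.get("k", 5))
    if kind == "svm_radial":
        return SVC(kernel="rbf", C=1.0, gamma="scale")
    if kind == "svm_sigmoid":
        return SVC(kernel="sigmoid", C=1.0, gamma="scale")
    if kind == "logistic":
        return LogisticRegression(C=np.inf, max_iter=500)
    raise ValueError(f"unknown classifier kind {kind!r}")


def train_classifier(kind: str, hyperparams: dict, X_train: np.ndarray, y_train: np.ndarray) -> FittedClassifier:
    """Fit one classifier on z-scored features (training statistics only).

    Logistic regression is unpenalised with bounded iterations; on separable
    data sklearn's convergence warning is forwarded rather than suppressed.
    """
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xz = (X_train - mean) / sd
    model = _make_estimator(kind, hyperparams)
    model.fit(Xz, y_train)
    if kind == "logistic":
        proba = model.predict_proba(Xz).max(axis=1)
        if proba.min() > 0.99:
            warnings.warn(
                "logistic fit shows (quasi-)separation: fitted probabilities are "
                "numerically 0 or 1; coefficients are unstable",
                RuntimeWarning,
                stacklevel=2,
            )
    return FittedClassifier(kind, model, mean, sd, dict(hyperparams))


def knn_grid(train_n: int) -> list[dict]:
    return [{"k": k} for k in range(1, min(21, train_n - 1) + 1, 2)]


def cross_validate(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    grid: list[dict],
    cv: CvSpec | None = None,
) -> tuple[dict, dict]:
    """Repeated k-fold CV accuracy per hyperparameter set; returns the winner.

    Grid order is the tie-break: the first entry attaining the maximal mean
    accuracy wins, so callers order grids from least to most complex (KNN: k
    ascending; penalised models: lambda descending).  Folds missing a class
    are skipped with a warning.
    """
    cv = cv or CvSpec()
    if not grid:
        raise ValueError("empty hyperparameter grid")
    splitter = RepeatedKFold(
        n_splits=min(cv.folds, len(y)), n_repeats=cv.repeats, random_state=cv.seed
    )
    folds = list(splitter.split(X))
    means: dict = {}
    for params in grid:
        scores = []
        for tr, te in folds:
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                warnings.warn("skipping CV fold lacking both classes", RuntimeWarning, stacklevel=2)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                fitted = train_classifier(kind, params, X[tr], y[tr])
            scores.append(float(np.mean(fitted.predict(X[te]) == y[te])))
        if not scores:
            raise ValueError("no valid CV folds")
        means[tuple(sorted(params.items()))] = float(np.mean(scores))
    best_score = max(means.values())
    # first grid entry achieving the max wins the tie
    for params in grid:
        if means[tuple(sorted(params.items()))] == best_score:
            return dict(params), means
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("no positive samples: sensitivity undefined")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        raise ZeroDivisionError("no negative samples: specificity undefined")
    return c.tn / (c.tn + c.fp)


def balanced_accuracy(sens: float, spec: float) -> float:
    return (sens + spec) / 2


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Confusion counts with grade3 as the positive class."""
    pos = np.asarray(y_true) == POSITIVE_CLASS
    pred_pos = np.asarray(y_pred) == POSITIVE_CLASS
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
    )


# ---------------------------------------------------------------------------
# Evaluation grid
# ---------------------------------------------------------------------------

def evaluate_grid(
    signatures: list[SignatureSet],
    expr: ExpressionMatrix,
    pheno: PhenotypeTable,
    split: SplitSpec | None = None,
    cv: CvSpec | None = None,
    classifiers: tuple[str, ...] = CLASSIFIER_KINDS,
) -> tuple[list[EvalResult], pd.DataFrame]:
    """One EvalResult per (selector ∪ all_genes) × classifier on a shared split.

    Every pair is trained on the same training samples and judged on the same
    held-out test samples.  Empty signatures yield an NA row with a warning.
    """
    if not signatures:
        raise ValueError("no signatures supplied")
    split = split or SplitSpec(
        train_n=int(round(len(pheno.sample_ids) * 72 / 107)),
        test_n=len(pheno.sample_ids) - int(round(len(pheno.sample_ids) * 72 / 107)),
    )
    cv = cv or CvSpec()
    train_ids, test_ids = split_train_test(pheno, split)
    y_train = pheno.grades_for(train_ids)
    y_test = pheno.grades_for(test_ids)

    results: list[EvalResult] = []
    rows = []
    sets: list[tuple[str, list[str] | None]] = [("all_genes", None)]
    sets += [(sig.method, list(sig.genes)) for sig in signatures]

    for name, genes in sets:
        if genes is not None and len(genes) == 0:
            warnings.warn(f"signature {name!r} is empty; reporting NA row", RuntimeWarning, stacklevel=2)
            for kind in classifiers:
                rows.append(
                    {"selector": name, "classifier": kind, "hyperparams": None,
                     "sensitivity": np.nan, "specificity": np.nan,
                     "balanced_accuracy": np.nan, "TP": np.nan, "FP": np.nan,
                     "TN": np.nan, "FN": np.nan}
                )
            continue
        sub = expr if genes is None else expr.subset_genes(genes)
        X_train = sub.subset_samples(train_ids).values.T
        X_test = sub.subset_samples(test_ids).values.T
        for kind in classifiers:
            grid = knn_grid(len(train_ids)) if kind == "knn" else [{}]
            if len(grid) == 1:
                best = dict(grid[0])  # nothing to tune: the single entry is chosen
            else:
                best, _ = cross_validate(kind, X_train, y_train, grid, cv)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                fitted = train_classifier(kind, best, X_train, y_train)
            conf = confusion_from_predictions(y_test, fitted.predict(X_test))
            sens, spec_ = sensitivity(conf), specificity(conf)
            res = EvalResult(name, kind, best, sens, spec_, balanced_accuracy(sens, spec_), conf)
            results.append(res)
            rows.append(
                {"selector": name, "classifier": kind, "hyperparams": repr(best),
                 "sensitivity": sens, "specificity": spec_,
                 "balanced_accuracy": res.balanced_accuracy,
                 "TP": conf.tp, "FP": conf.fp, "TN": conf.tn, "FN": conf.fn}
            )

    report = pd.DataFrame(rows)
    report.attrs["positive_class"] = POSITIVE_CLASS
    report.attrs["train_ids"] = train_ids
    report.attrs["test_ids"] = test_ids
    return results, report
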