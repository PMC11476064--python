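"""Wrapper and embedded selectors: Boruta shadow features, iterative
random-forest importance reduction, and L1-penalised logistic (LASSO) paths.

All three share a permutation-importance z-score: the mean decrease in
training accuracy when a feature's column is shuffled, divided by the
standard deviation of the decrease over repeats.  Shadow features (per-column
permuted copies of the real features) provide Boruta's importance null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import RepeatedKFold

from .core_io import ExpressionMatrix, PhenotypeTable, GRADE3
from .filter_select import SignatureSet

__all__ = [
    "BorutaConfig",
    "RfIterConfig",
    "LassoConfig",
    "permutation_importance_z",
    "boruta_select",
    "rf_iterative_select",
    "lasso_select",
]

CONFIRMED = "Confirmed"
TENTATIVE = "Tentative"
REJECTED = "Rejected"


@dataclass
class BorutaConfig:
    max_runs: int = 1000
    alpha: float = 0.01
    importance: str = "permutation_z"
    ntree: int = 100
    n_repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_runs < 10:
            raise ValueError("max_runs must be at least 10")
        if self.importance != "permutation_z":
            raise ValueError("only permutation_z importance is implemented")


@dataclass
class RfIterConfig:
    ntree: int = 100
    importance_cut: float = 2.0
    mtry_grid: list[int] | None = None  # default: sqrt(p) halving down to 2
    cv_folds: int = 10
    cv_repeats: int = 3
    n_repeats: int = 5
    max_iterations: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.importance_cut <= 0:
            raise ValueError("importance_cut must be positive")


@dataclass
class LassoConfig:
    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.01, 0.351, 0.01), 4)
    )
    alpha_mix: float = 1.0  # pure L1
    cv_folds: int = 10
    cv_repeats: int = 3
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.lambda_grid, dtype=float)
        if grid.size == 0 or np.any(grid < 0):
            raise ValueError("lambda grid must be nonempty and nonnegative")
        if self.alpha_mix != 1.0:
            raise ValueError("only pure L1 (alpha_mix = 1) is supported")
        self.lambda_grid = grid


# ---------------------------------------------------------------------------
# Permutation importance
# ---------------------------------------------------------------------------

def permutation_importance_z(
    forest,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 5,
    rng: np.random.Generator | None = None,
    chunk_rows: int = 200_000,
) -> np.ndarray:
    """Permutation-importance z-score per feature.

    For each feature and repeat, its column is shuffled and the drop in
    accuracy on (X, y) recorded; z = mean drop / sd of drops.  All permuted
    copies are stacked and predicted in large blocks, which is far cheaper
    than one predict call per permutation.
    """
    rng = rng or np.random.default_rng()
    n, p = X.shape
    base_acc = float(np.mean(forest.predict(X) == y))

    drops = np.empty((p, n_repeats))
    jobs = [(f, r) for f in range(p) for r in range(n_repeats)]
    per_block = max(chunk_rows // n, 1)
    for start in range(0, len(jobs), per_block):
        block = jobs[start : start + per_block]
        stacked = np.tile(X, (len(block), 1, 1))
        for b, (f, _) in enumerate(block):
            stacked[b, :, f] = rng.permutation(X[:, f])
        preds = forest.predict(stacked.reshape(-1, p)).reshape(len(block), n)
        for b, (f, r) in enumerate(block):
            drops[f, r] = base_acc - float(np.mean(preds[b] == y))

    mean = drops.mean(axis=1)
    sd = drops.std(axis=1, ddof=1) if n_repeats > 1 else np.zeros(p)
    z = np.where((mean == 0) & (sd == 0), 0.0, mean / np.maximum(sd, 1e-12))
    return z


def _fit_forest(X: np.ndarray, y: np.ndarray, ntree: int, seed: int, mtry: int | None = None):
    forest = RandomForestClassifier(
        n_estimators=ntree,
        max_features=mtry if mtry is not None else "sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


def _base_stats(expr: ExpressionMatrix, pheno: PhenotypeTable) -> pd.DataFrame:
    grades = pheno.grades_for(expr.sample_ids)
    mask = grades == GRADE3
    log2fc = expr.values[:, mask].mean(axis=1) - expr.values[:, ~mask].mean(axis=1)
    return pd.DataFrame({"gene_id": expr.gene_ids, "log2fc": log2fc})


# ---------------------------------------------------------------------------
# Boruta
# ---------------------------------------------------------------------------

def boruta_select(
    expr: ExpressionMatrix, pheno: PhenotypeTable, cfg: BorutaConfig | None = None
) -> SignatureSet:
    """Shadow-feature all-relevant selection.

    Each run pairs every surviving feature with a shuffled shadow copy, fits a
    forest on real + shadow columns, and scores a *hit* for features whose
    importance exceeds the maximum shadow importance.  Hits accumulate into a
    two-sided binomial test (hit probability 0.5, Bonferroni over features):
    significantly more hits than expected confirms a feature, significantly
    fewer rejects it.  After the loop, remaining tentative features are
    resolved by the rough fix: confirmed iff their median importance over runs
    exceeds the median of the per-run maximum shadow importance.
    """
    cfg = cfg or BorutaConfig()
    grades = pheno.grades_for(expr.sample_ids)
    if min((grades == g).sum() for g in np.unique(grades)) < 2:
        raise ValueError("each class needs at least two samples")
    X = expr.values.T.copy()
    y = (grades == GRADE3).astype(int)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least two features")
    rng = np.random.default_rng(cfg.seed)

    decision = np.full(p, TENTATIVE, dtype=object)
    hits = np.zeros(p, dtype=int)
    runs_of = np.zeros(p, dtype=int)
    imp_history: list[list[float]] = [[] for _ in range(p)]
    shadow_max_history: list[float] = []

    for run in range(cfg.max_runs):
        active = np.flatnonzero(decision != REJECTED)
        testable = np.flatnonzero(decision == TENTATIVE)
        if len(testable) == 0:
            break
        shadows = np.column_stack([rng.permutation(X[:, f]) for f in active])
        X_run = np.column_stack([X[:, active], shadows])
        forest = _fit_forest(X_run, y, cfg.ntree, seed=int(rng.integers(2**31)))
        z = permutation_importance_z(forest, X_run, y, cfg.n_repeats, rng)
        real_z, shadow_z = z[: len(active)], z[len(active) :]
        shadow_max = float(shadow_z.max())
        shadow_max_history.append(shadow_max)
        for pos, f in enumerate(active):
            imp_history[f].append(float(real_z[pos]))
            if real_z[pos] > shadow_max:
                hits[f] += 1
            runs_of[f] += 1
        # two-sided binomial decision, Bonferroni over the feature count
        for f in testable:
            res = stats.binomtest(int(hits[f]), int(runs_of[f]), 0.5)
            if res.pvalue * p < cfg.alpha:
                decision[f] = CONFIRMED if hits[f] > runs_of[f] / 2 else REJECTED

    # rough fix for whatever stayed tentative
    shadow_median = float(np.median(shadow_max_history)) if shadow_max_history else np.inf
    for f in np.flatnonzero(decision == TENTATIVE):
        med = float(np.median(imp_history[f])) if imp_history[f] else -np.inf
        decision[f] = CONFIRMED if med > shadow_median else REJECTED

    with np.errstate(invalid="ignore"):
        pvals = np.array(
            [stats.binomtest(int(hits[f]), max(int(runs_of[f]), 1), 0.5).pvalue for f in range(p)]
        )
    stats_df = _base_stats(expr, pheno)
    stats_df["score"] = [float(np.median(h)) if h else 0.0 for h in imp_history]
    stats_df["p"] = pvals
    stats_df["adj_p"] = np.minimum(pvals * p, 1.0)  # Bonferroni, as in the decision rule
    stats_df["selected"] = decision == CONFIRMED
    stats_df["decision"] = decision
    stats_df = stats_df[["gene_id", "score", "log2fc", "p", "adj_p", "selected", "decision"]]
    genes = stats_df.loc[stats_df["selected"], "gene_id"].tolist()
    return SignatureSet(
        "boruta",
        genes,
        stats_df,
        extras={"hits": hits.tolist(), "runs": runs_of.tolist(), "config": cfg.__dict__.copy()},
    )


# ---------------------------------------------------------------------------
# Iterative RF reduction
# ---------------------------------------------------------------------------

def _repeated_cv_ba(make_model, X: np.ndarray, y: np.ndarray, folds: int, repeats: int, seed: int) -> float:
    """Mean balanced accuracy over repeated plain k-fold CV; degenerate folds skipped."""
    cv = RepeatedKFold(n_splits=min(folds, len(y)), n_repeats=repeats, random_state=seed)
    scores = []
    for train_idx, test_idx in cv.split(X):
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            warnings.warn("skipping CV fold lacking both classes", RuntimeWarning, stacklevel=2)
            continue
        model = make_model()
        model.fit(X[train_idx], y[train_idx])
        scores.append(balanced_accuracy_score(y[test_idx], model.predict(X[test_idx])))
    if not scores:
        raise ValueError("no valid CV folds")
    return float(np.mean(scores))


def _default_mtry_grid(p: int) -> list[int]:
    grid = []
    m = max(int(round(np.sqrt(p))), 2)
    while m > 2:
        grid.append(m)
        m = max(m // 2, 2)
    grid.append(2)
    return sorted(set(grid), reverse=True)


def rf_iterative_select(
    expr: ExpressionMatrix, pheno: PhenotypeTable, cfg: RfIterConfig | None = None
) -> SignatureSet:
    """Iterative importance > cut reduction with an mtry grid per iteration.

    Each iteration scores the mtry grid by repeated CV balanced accuracy,
    fits a forest at the best mtry, and keeps genes whose permutation
    importance z exceeds ``importance_cut``.  The loop ends when the gene set
    stabilises or would fall below two genes; the returned signature is the
    iteration with the highest recorded CV balanced accuracy.  If the very
    first reduction empties the set, the full-gene model is the documented
    fallback.
    """
    cfg = cfg or RfIterConfig()
    grades = pheno.grades_for(expr.sample_ids)
    y = (grades == GRADE3).astype(int)
    rng = np.random.default_rng(cfg.seed)

    current = list(expr.gene_ids)
    trace: list[dict] = []
    iteration_sets: list[list[str]] = []

    for it in range(cfg.max_iterations):
        sub = expr.subset_genes(current)
        X = sub.values.T
        grid = cfg.mtry_grid or _default_mtry_grid(len(current))
        grid = [m for m in grid if m <= len(current)] or [min(2, len(current))]
        best_mtry, best_ba = None, -1.0
        for mtry in grid:
            ba = _repeated_cv_ba(
                lambda m=mtry: RandomForestClassifier(
                    n_estimators=cfg.ntree, max_features=m, random_state=cfg.seed, n_jobs=1
                ),
                X,
                y,
                cfg.cv_folds,
                cfg.cv_repeats,
                seed=cfg.seed + it,
            )
            if ba > best_ba:
                best_ba, best_mtry = ba, mtry
        trace.append(
            {"iteration": it, "n_genes": len(current), "mtry": best_mtry, "cv_balanced_accuracy": best_ba}
        )
        iteration_sets.append(list(current))

        forest = _fit_forest(X, y, cfg.ntree, seed=int(rng.integers(2**31)), mtry=best_mtry)
        z = permutation_importance_z(forest, X, y, cfg.n_repeats, rng)
        keep = [g for g, zi in zip(current, z) if zi > cfg.importance_cut]
        if len(keep) < 2 or keep == current:
            break
        current = keep

    best_it = int(np.argmax([t["cv_balanced_accuracy"] for t in trace]))
    final_genes = iteration_sets[best_it]

    stats_df = _base_stats(expr, pheno)
    stats_df["score"] = np.nan
    stats_df["p"] = np.nan
    stats_df["adj_p"] = np.nan
    stats_df["selected"] = stats_df["gene_id"].isin(final_genes)
    stats_df = stats_df[["gene_id", "score", "log2fc", "p", "adj_p", "selected"]]
    return SignatureSet(
        "rf",
        final_genes,
        stats_df,
        extras={"trace": trace, "best_iteration": best_it, "config": {"ntree": cfg.ntree}},
    )


# ---------------------------------------------------------------------------
# LASSO
# ---------------------------------------------------------------------------

def _lasso_model(lam: float, n: int, seed: int) -> LogisticRegression:
    # glmnet-style lambda maps to sklearn C = 1 / (n * lambda)
    return LogisticRegression(
        l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear", max_iter=2000, random_state=seed
    )


def lasso_select(
    expr: ExpressionMatrix, pheno: PhenotypeTable, cfg: LassoConfig | None = None
) -> SignatureSet:
    """L1-penalised logistic selection over a lambda grid.

    Lambda is chosen by repeated-CV balanced accuracy with ties resolved
    toward the larger (more parsimonious) lambda; the signature is the set of
    genes with nonzero coefficients in the final fit at that lambda.
    """
    cfg = cfg or LassoConfig()
    grades = pheno.grades_for(expr.sample_ids)
    y = (grades == GRADE3).astype(int)
    X = expr.values.T.copy()
    sd = X.std(axis=0, ddof=0)
    if np.all(sd == 0):
        raise ValueError("all features are constant")
    if cfg.standardize:
        X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)

    grid = np.asarray(cfg.lambda_grid, dtype=float)
    if X.shape[1] >= X.shape[0]:
        nonzero = grid[grid > 0]
        if nonzero.size < grid.size:
            warnings.warn(
                "lambda = 0 dropped: unpenalised fit is non-identifiable with "
                "more features than samples",
                RuntimeWarning,
                stacklevel=2,
            )
        grid = nonzero
    if grid.size == 0:
        raise ValueError("no usable lambda values")

    best_lam, best_ba = None, -np.inf
    cv_scores = {}
    for lam in sorted(grid, reverse=True):  # ties go to the larger lambda
        ba = _repeated_cv_ba(
            lambda lam=lam: _lasso_model(lam, len(y), cfg.seed),
            X,
            y,
            cfg.cv_folds,
            cfg.cv_repeats,
            seed=cfg.seed,
        )
        cv_scores[float(lam)] = ba
        if ba > best_ba:
            best_ba, best_lam = ba, float(lam)

    final = _lasso_model(best_lam, len(y), cfg.seed)
    final.fit(X, y)
    coefs = final.coef_.ravel()

    stats_df = _base_stats(expr, pheno)
    stats_df["score"] = coefs
    stats_df["p"] = np.nan
    stats_df["adj_p"] = np.nan
    stats_df["selected"] = coefs != 0
    stats_df = stats_df[["gene_id", "score", "log2fc", "p", "adj_p", "selected"]]
    genes = stats_df.loc[stats_df["selected"], "gene_id"].tolist()
    return SignatureSet(
        "lasso",
        genes,
        stats_df,
        extras={"lambda": best_lam, "cv_balanced_accuracy": cv_scores, "model": final},
    )
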