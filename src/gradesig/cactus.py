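"""CACTUS: ROC-threshold flip abstraction, margin-error feature filtration,
and product-of-conditional-probability classification.

The method abstracts each gene to a two-state "flip" — U when a sample's
expression exceeds the gene's ROC-derived cut-off, D otherwise.  Each gene's
cut-off maximises single-feature training accuracy p_i.  Features are then
filtered by a binomial margin of error

    ME(z, p, n) = z · sqrt(p (1 − p) / n),

with n the number of features in the dataset and z an arbitrary confidence
multiplier (default 5).  Classification of a sample scores each class s by
the cost function  C_s = Π_i σ_{s,i}(f_i),  the product over selected genes
of the smoothed conditional flip probabilities P(flip | class); the class
with the greater cost wins.  Costs are accumulated in log space so long
products never underflow.

The fitted object follows a model/results convention: ``CactusModel.fit``
returns a :class:`CactusResults` carrying the cut-offs, flip codes, selected
genes, σ table and a ``summary()`` frame.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, PhenotypeTable, GRADE2, GRADE3
from .filter_select import SignatureSet

__all__ = [
    "CactusConfig",
    "FlipMatrix",
    "CactusModel",
    "CactusResults",
    "roc_cutoff",
    "abstract_flips",
    "margin_error",
    "cactus_select",
    "fit_significance",
    "cactus_classify",
]

FLIP_UP = "U"
FLIP_DOWN = "D"


@dataclass
class CactusConfig:
    z: float = 5.0
    smoothing: float = 1.0  # Laplace add-count; 0 reproduces hard zero costs
    selection_rule: str = "band_below_max"  # or "above_half"
    balanced_accuracy: bool = False

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("z must be positive")
        if self.smoothing < 0:
            raise ValueError("smoothing must be nonnegative")
        if self.selection_rule not in ("band_below_max", "above_half"):
            raise ValueError("unknown selection rule")


@dataclass
class FlipMatrix:
    """Two-state abstraction of an expression matrix: U iff value > cutoff."""

    gene_ids: list[str]
    sample_ids: list[str]
    codes: np.ndarray  # '<U1' array, genes × samples
    cutoffs: dict[str, float]

    def flips_for_sample(self, sample_id: str) -> dict[str, str]:
        j = self.sample_ids.index(sample_id)
        return {g: self.codes[i, j] for i, g in enumerate(self.gene_ids)}


def roc_cutoff(
    values: np.ndarray, labels: np.ndarray, balanced: bool = False
) -> tuple[float, float]:
    """Best single-feature threshold and its training accuracy.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted values plus ±inf sentinels; both orientations (positive class
    above or below) are tried and ties go to the smallest cutoff.  With
    ``balanced`` the criterion is the mean of the two per-class accuracies.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    pos = labels == classes[1]
    n = len(values)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())

    distinct, inverse = np.unique(values, return_inverse=True)
    m = len(distinct)
    candidates = np.concatenate(([-np.inf], (distinct[:-1] + distinct[1:]) / 2, [np.inf]))

    # counts of samples / positives with value <= each candidate threshold
    total_at = np.bincount(inverse, minlength=m)
    pos_at = np.bincount(inverse, weights=pos.astype(float), minlength=m)
    below = np.concatenate(([0], np.cumsum(total_at)))
    pos_below = np.concatenate(([0.0], np.cumsum(pos_at)))
    neg_below = below - pos_below

    tp_above = n_pos - pos_below  # orientation: positive class above the cut
    tn_above = neg_below
    tp_below = pos_below  # orientation: positive class below the cut
    tn_below = n_neg - neg_below
    if balanced:
        acc_above = 0.5 * (tp_above / n_pos + tn_above / n_neg)
        acc_below = 0.5 * (tp_below / n_pos + tn_below / n_neg)
    else:
        acc_above = (tp_above + tn_above) / n
        acc_below = (tp_below + tn_below) / n

    # scan candidates in increasing order, "above" orientation first, taking
    # the first strict maximum -> ties break to the smallest cutoff
    interleaved = np.empty(2 * len(candidates))
    interleaved[0::2] = acc_above
    interleaved[1::2] = acc_below
    best = int(np.argmax(interleaved))
    return float(candidates[best // 2]), float(interleaved[best])


def abstract_flips(expr: ExpressionMatrix, cutoffs: dict[str, float]) -> FlipMatrix:
    """Code every cell U (strictly above the gene's cutoff) or D."""
    missing = [g for g in expr.gene_ids if g not in cutoffs]
    if missing:
        raise KeyError(f"missing cutoffs for genes: {missing[:5]}")
    cut = np.array([cutoffs[g] for g in expr.gene_ids])
    codes = np.where(expr.values > cut[:, None], FLIP_UP, FLIP_DOWN)
    return FlipMatrix(list(expr.gene_ids), list(expr.sample_ids), codes, dict(cutoffs))


def margin_error(z: float, p: float, n: int) -> float:
    """Binomial margin of error z·sqrt(p(1−p)/n)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    return z * math.sqrt(p * (1 - p) / n)


def cactus_select(p_vector: np.ndarray, cfg: CactusConfig, n: int | None = None) -> np.ndarray:
    """Indices of features surviving the margin-error filtration.

    band_below_max keeps feature i when p_i ≥ max_j p_j − ME(z, p_i, n);
    above_half keeps it when p_i ≥ 0.5 + ME(z, p_i, n).
    """
    p_vector = np.asarray(p_vector, dtype=float)
    if p_vector.size == 0:
        raise ValueError("empty accuracy vector")
    n = int(n) if n is not None else p_vector.size
    me = np.array([margin_error(cfg.z, p, n) for p in p_vector])
    if cfg.selection_rule == "band_below_max":
        keep = p_vector >= p_vector.max() - me
    else:
        keep = p_vector >= 0.5 + me
    return np.flatnonzero(keep)


def fit_significance(
    flips: FlipMatrix,
    pheno: PhenotypeTable,
    selected: list[str],
    smoothing: float = 1.0,
    p_acc: dict[str, float] | None = None,
    n_features: int | None = None,
) -> "CactusResults":
    """Estimate the conditional flip probabilities σ_{s,i}(f) per class.

    σ_{s,i}(f) = (count of flip f for gene i in class s + smoothing) /
    (n_s + 2·smoothing), so σ(U) + σ(D) = 1 for every (gene, class).
    """
    if not selected:
        raise ValueError("no selected genes")
    grades = pheno.grades_for(flips.sample_ids)
    sigma: dict[str, dict[str, dict[str, float]]] = {}
    priors: dict[str, float] = {}
    for grade in (GRADE2, GRADE3):
        mask = grades == grade
        n_s = int(mask.sum())
        if n_s == 0:
            raise ValueError(f"no samples of class {grade}")
        priors[grade] = n_s / len(grades)
        sigma[grade] = {}
        for gene in selected:
            i = flips.gene_ids.index(gene)
            n_up = int(np.sum(flips.codes[i, mask] == FLIP_UP))
            s_up = (n_up + smoothing) / (n_s + 2 * smoothing)
            sigma[grade][gene] = {FLIP_UP: s_up, FLIP_DOWN: 1.0 - s_up}
    return CactusResults(
        selected=list(selected),
        cutoffs={g: flips.cutoffs[g] for g in selected},
        sigma=sigma,
        priors=priors,
        accuracy={g: (p_acc or {}).get(g, float("nan")) for g in selected},
        n_features=n_features if n_features is not None else len(flips.gene_ids),
        smoothing=smoothing,
    )


def cactus_classify(
    model: "CactusResults", sample_flips: dict[str, str]
) -> tuple[str, dict[str, float]]:
    """Predict a class from one sample's flips; returns per-class log cost.

    log C_s = Σ_i log σ_{s,i}(f_i) over selected genes.  An exact tie goes to
    the class with the larger training prior, then grade2.  With zero
    smoothing an unseen flip yields −inf log cost (hard zero product).
    """
    missing = [g for g in model.selected if g not in sample_flips]
    if missing:
        raise KeyError(f"sample lacks flips for selected genes: {missing[:5]}")
    log_cost: dict[str, float] = {}
    for grade in (GRADE2, GRADE3):
        total = 0.0
        for gene in model.selected:
            s = model.sigma[grade][gene][sample_flips[gene]]
            total += math.log(s) if s > 0 else -math.inf
        log_cost[grade] = total
    if log_cost[GRADE2] == log_cost[GRADE3] or (
        math.isinf(log_cost[GRADE2]) and math.isinf(log_cost[GRADE3])
    ):
        if model.priors[GRADE3] > model.priors[GRADE2]:
            return GRADE3, log_cost
        return GRADE2, log_cost
    return max(log_cost, key=log_cost.get), log_cost


@dataclass
class CactusResults:
    """Fitted CACTUS model: selected genes, cut-offs, σ table and accuracies."""

    selected: list[str]
    cutoffs: dict[str, float]
    sigma: dict[str, dict[str, dict[str, float]]]
    priors: dict[str, float]
    accuracy: dict[str, float]
    n_features: int
    smoothing: float
    config: CactusConfig | None = None

    def predict(self, expr: ExpressionMatrix) -> np.ndarray:
        """Hard class labels for each sample of ``expr`` (selected genes only)."""
        sub = expr.subset_genes(self.selected)
        flips = abstract_flips(sub, self.cutoffs)
        out = []
        for sid in flips.sample_ids:
            pred, _ = cactus_classify(self, flips.flips_for_sample(sid))
            out.append(pred)
        return np.array(out)

    def summary(self) -> pd.DataFrame:
        rows = []
        for gene in self.selected:
            rows.append(
                {
                    "gene_id": gene,
                    "cutoff": self.cutoffs[gene],
                    "single_feature_accuracy": self.accuracy.get(gene, float("nan")),
                    "sigma_grade2_U": self.sigma[GRADE2][gene][FLIP_UP],
                    "sigma_grade3_U": self.sigma[GRADE3][gene][FLIP_UP],
                }
            )
        return pd.DataFrame(rows)

    def to_signature_set(self, all_stats: pd.DataFrame) -> SignatureSet:
        return SignatureSet("cactus", list(self.selected), all_stats)

    # -- JSON round trip ----------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "selected": self.selected,
            "cutoffs": self.cutoffs,
            "sigma": self.sigma,
            "priors": self.priors,
            "accuracy": self.accuracy,
            "n_features": self.n_features,
            "smoothing": self.smoothing,
            "config": self.config.__dict__.copy() if self.config else None,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CactusResults":
        d = json.loads(Path(path).read_text())
        cfg = CactusConfig(**d["config"]) if d.get("config") else None
        return cls(
            selected=d["selected"],
            cutoffs=d["cutoffs"],
            sigma=d["sigma"],
            priors=d["priors"],
            accuracy=d["accuracy"],
            n_features=d["n_features"],
            smoothing=d["smoothing"],
            config=cfg,
        )


class CactusModel:
    """Unfitted CACTUS specification bound to training data."""

    def __init__(
        self,
        expr: ExpressionMatrix,
        pheno: PhenotypeTable,
        config: CactusConfig | None = None,
    ) -> None:
        pheno.check_covers(expr)
        self.expr = expr
        self.pheno = pheno
        self.config = config or CactusConfig()

    def fit(self) -> CactusResults:
        cfg = self.config
        grades = self.pheno.grades_for(self.expr.sample_ids)
        cutoffs: dict[str, float] = {}
        acc = np.empty(self.expr.n_genes)
        for i, gene in enumerate(self.expr.gene_ids):
            cutoffs[gene], acc[i] = roc_cutoff(
                self.expr.values[i], grades, balanced=cfg.balanced_accuracy
            )
        keep_idx = cactus_select(acc, cfg, n=self.expr.n_genes)
        selected = [self.expr.gene_ids[i] for i in keep_idx]
        flips = abstract_flips(self.expr, cutoffs)
        results = fit_significance(
            flips,
            self.pheno,
            selected,
            smoothing=cfg.smoothing,
            p_acc={self.expr.gene_ids[i]: float(acc[i]) for i in keep_idx},
            n_features=self.expr.n_genes,
        )
        results.config = cfg
        results.all_accuracy = pd.DataFrame(  # type: ignore[attr-defined]
            {"gene_id": self.expr.gene_ids, "accuracy": acc}
        )
        return results

    @classmethod
    def from_dataframe(
        cls, expr_df: pd.DataFrame, pheno_df: pd.DataFrame, config: CactusConfig | None = None
    ) -> "CactusModel":
        return cls(ExpressionMatrix.from_frame(expr_df), PhenotypeTable(pheno_df), config)
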