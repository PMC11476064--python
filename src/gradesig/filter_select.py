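"""Filter-style signature selectors: differential expression and Relief/STIR.

Differential expression (DGE) scores each gene with a two-sample t statistic
between grades (pooled variance by default, Welch or a moderated variant by
config), adjusts p-values with Benjamini–Hochberg, and selects genes passing
an adjusted-p and/or absolute log2FC threshold.

STIR turns classic fixed-k ReliefF neighbour differences into a formal test:
for each gene it compares the pool of |x_i − x_j| over nearest-miss pairs
(other class) against the pool over nearest-hit pairs (same class) with a
Welch-type t statistic, yielding p-values that are BH-adjusted across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, PhenotypeTable, GRADE2, GRADE3

__all__ = [
    "DgeConfig",
    "StirConfig",
    "SignatureSet",
    "ReliefSummaries",
    "bh_adjust",
    "dge_select",
    "relief_weights",
    "stir_select",
]


@dataclass
class DgeConfig:
    adj_p_cut: float = 0.01
    lfc_cut: float = 1.0
    rule: str = "or"  # select on adj_p OR |log2fc| (literal reading of the rule)
    test: str = "pooled_t"  # pooled_t | welch_t | moderated_t

    def __post_init__(self) -> None:
        if self.adj_p_cut < 0 or self.lfc_cut < 0:
            raise ValueError("cuts must be nonnegative")
        if self.rule not in ("or", "and"):
            raise ValueError("rule must be 'or' or 'and'")
        if self.test not in ("pooled_t", "welch_t", "moderated_t"):
            raise ValueError("unknown test")


@dataclass
class StirConfig:
    """k defaults to floor(n_samples / 6) when left as None."""

    k: int | None = None
    alpha: float = 0.01
    metric: str = "manhattan"
    two_sided: bool = False

    def __post_init__(self) -> None:
        if self.metric != "manhattan":
            raise ValueError("only the manhattan metric is supported")


@dataclass
class SignatureSet:
    """A selector's output: method tag, selected gene ids, per-gene statistics.

    ``stats`` covers every tested gene with columns
    gene_id, score, log2fc, p, adj_p, selected.
    """

    method: str
    genes: list[str]
    stats: pd.DataFrame
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"gene_id", "score", "log2fc", "p", "adj_p", "selected"}
        missing = required - set(self.stats.columns)
        if missing:
            raise ValueError(f"stats missing columns: {sorted(missing)}")
        tested = set(self.stats["gene_id"])
        stray = set(self.genes) - tested
        if stray:
            raise ValueError(f"selected genes missing from stats: {sorted(stray)[:5]}")

    def __len__(self) -> int:
        return len(self.genes)

    def write_tsv(self, path) -> None:
        self.stats.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving, ≤ 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def _group_split(expr: ExpressionMatrix, pheno: PhenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    grades = pheno.grades_for(expr.sample_ids)
    x2 = expr.values[:, grades == GRADE2]
    x3 = expr.values[:, grades == GRADE3]
    if x2.shape[1] < 2 or x3.shape[1] < 2:
        raise ValueError("each grade needs at least two samples")
    return x2, x3


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def dge_select(
    expr: ExpressionMatrix, pheno: PhenotypeTable, cfg: DgeConfig | None = None
) -> SignatureSet:
    """Two-sample t-test per gene with BH adjustment and threshold selection.

    log2fc is grade3 mean − grade2 mean.  Under ``rule='or'`` a gene is
    selected when adj_p < adj_p_cut OR |log2fc| > lfc_cut; under ``'and'``
    both must hold.
    """
    cfg = cfg or DgeConfig()
    x2, x3 = _group_split(expr, pheno)
    n2, n3 = x2.shape[1], x3.shape[1]
    m2, m3 = x2.mean(axis=1), x3.mean(axis=1)
    log2fc = m3 - m2
    v2, v3 = x2.var(axis=1, ddof=1), x3.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        if cfg.test == "welch_t":
            se2 = v2 / n2 + v3 / n3
            t = log2fc / np.sqrt(se2)
            df = se2**2 / ((v2 / n2) ** 2 / (n2 - 1) + (v3 / n3) ** 2 / (n3 - 1))
        else:
            sp2 = ((n2 - 1) * v2 + (n3 - 1) * v3) / (n2 + n3 - 2)
            if cfg.test == "moderated_t":
                # method-of-moments shrinkage of per-gene variances toward
                # the grand mean, weighted by how much gene-to-gene spread
                # exceeds the chi-square sampling noise
                df_res = n2 + n3 - 2
                grand = sp2.mean()
                sampling_var = 2 * grand**2 / df_res
                excess = max(sp2.var(ddof=1) - sampling_var, 0.0)
                w = excess / (excess + sampling_var) if excess + sampling_var > 0 else 0.0
                sp2 = w * sp2 + (1 - w) * grand
            t = log2fc / np.sqrt(sp2 * (1 / n2 + 1 / n3))
            df = np.full_like(t, n2 + n3 - 2, dtype=float)

    t = np.where(np.isfinite(t), t, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(p), p, 1.0)
    adj_p = bh_adjust(p)

    by_p = adj_p < cfg.adj_p_cut
    by_fc = np.abs(log2fc) > cfg.lfc_cut
    selected = (by_p | by_fc) if cfg.rule == "or" else (by_p & by_fc)

    stats_df = pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "score": t,
            "log2fc": log2fc,
            "p": p,
            "adj_p": adj_p,
            "selected": selected,
        }
    )
    genes = stats_df.loc[stats_df["selected"], "gene_id"].tolist()
    return SignatureSet("dge", genes, stats_df, extras={"config": cfg.__dict__.copy()})


# ---------------------------------------------------------------------------
# Relief / STIR
# ---------------------------------------------------------------------------

@dataclass
class ReliefSummaries:
    """Per-gene moments of the hit- and miss-pair absolute differences."""

    gene_ids: list[str]
    hit_mean: np.ndarray
    hit_var: np.ndarray
    hit_n: int
    miss_mean: np.ndarray
    miss_var: np.ndarray
    miss_n: int
    log2fc: np.ndarray
    k: int


def relief_weights(
    expr: ExpressionMatrix, pheno: PhenotypeTable, cfg: StirConfig | None = None
) -> ReliefSummaries:
    """Fixed-k ReliefF neighbour differences on range-scaled features.

    Features are min-max scaled to [0, 1]; neighbourhoods use Manhattan
    distance.  For every sample, its k nearest same-class samples (hits) and
    k nearest other-class samples (misses) contribute |x_i − x_neighbour| to
    the per-gene hit and miss pools.
    """
    cfg = cfg or StirConfig()
    grades = pheno.grades_for(expr.sample_ids)
    n = expr.n_samples
    class_sizes = [int((grades == g).sum()) for g in (GRADE2, GRADE3)]
    k = cfg.k if cfg.k is not None else max(n // 6, 1)
    if not 1 <= k < min(class_sizes):
        raise ValueError(f"k={k} must satisfy 1 <= k < min class size {min(class_sizes)}")

    x = expr.values
    rng_span = x.max(axis=1) - x.min(axis=1)
    if np.all(rng_span == 0):
        raise ValueError("all features are constant")
    scale = np.where(rng_span == 0, 1.0, rng_span)
    xs = (x - x.min(axis=1, keepdims=True)) / scale[:, None]  # genes × samples in [0,1]

    # pairwise Manhattan distances between samples, accumulated over gene
    # chunks to bound peak memory on large matrices
    d = np.zeros((n, n))
    for start in range(0, xs.shape[0], 256):
        chunk = xs[start : start + 256]
        d += np.abs(chunk[:, :, None] - chunk[:, None, :]).sum(axis=0)
    np.fill_diagonal(d, np.inf)

    same = grades[:, None] == grades[None, :]
    hit_pairs: list[tuple[np.ndarray, np.ndarray]] = []
    miss_pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(n):
        d_hit = np.where(same[i], d[i], np.inf)
        d_miss = np.where(~same[i], d[i], np.inf)
        hits = np.argsort(d_hit, kind="stable")[:k]
        misses = np.argsort(d_miss, kind="stable")[:k]
        hit_pairs.append((np.full(k, i), hits))
        miss_pairs.append((np.full(k, i), misses))

    def pool_moments(pairs: list[tuple[np.ndarray, np.ndarray]]):
        ii = np.concatenate([a for a, _ in pairs])
        jj = np.concatenate([b for _, b in pairs])
        diffs = np.abs(xs[:, ii] - xs[:, jj])  # genes × pairs
        return diffs.mean(axis=1), diffs.var(axis=1, ddof=1), diffs.shape[1]

    hit_mean, hit_var, hit_n = pool_moments(hit_pairs)
    miss_mean, miss_var, miss_n = pool_moments(miss_pairs)

    grades_mask = grades == GRADE3
    log2fc = x[:, grades_mask].mean(axis=1) - x[:, ~grades_mask].mean(axis=1)
    return ReliefSummaries(
        list(expr.gene_ids), hit_mean, hit_var, hit_n, miss_mean, miss_var, miss_n, log2fc, k
    )


def stir_select(summaries: ReliefSummaries, cfg: StirConfig | None = None) -> SignatureSet:
    """Welch-type t test of miss-pool vs hit-pool differences, BH-adjusted.

    The statistic is (miss mean − hit mean) over the pooled standard error of
    the two difference pools, with Welch–Satterthwaite degrees of freedom.
    p is one-sided (miss > hit) unless ``two_sided`` is set; genes with
    adj_p < alpha are selected.
    """
    cfg = cfg or StirConfig()
    se2 = summaries.miss_var / summaries.miss_n + summaries.hit_var / summaries.hit_n
    num = summaries.miss_mean - summaries.hit_mean
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / np.sqrt(se2)
        df = se2**2 / (
            (summaries.miss_var / summaries.miss_n) ** 2 / (summaries.miss_n - 1)
            + (summaries.hit_var / summaries.hit_n) ** 2 / (summaries.hit_n - 1)
        )
    zero = se2 == 0
    t = np.where(zero, 0.0, t)
    df = np.where(zero | ~np.isfinite(df), 1.0, df)
    if cfg.two_sided:
        p = 2 * stats.t.sf(np.abs(t), df)
    else:
        p = stats.t.sf(t, df)
    p = np.where(zero, 1.0, p)
    adj_p = bh_adjust(p)
    selected = adj_p < cfg.alpha

    stats_df = pd.DataFrame(
        {
            "gene_id": summaries.gene_ids,
            "score": t,
            "log2fc": summaries.log2fc,
            "p": p,
            "adj_p": adj_p,
            "selected": selected,
        }
    )
    genes = stats_df.loc[stats_df["selected"], "gene_id"].tolist()
    return SignatureSet("stir", genes, stats_df, extras={"k": summaries.k})
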