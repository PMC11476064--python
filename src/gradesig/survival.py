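"""Survival screening of signature genes: Kaplan–Meier/log-rank grade
comparison, per-gene univariate Cox, grade × gene interaction Cox, and
Schoenfeld-residual proportional-hazards filtering.

Gene expression is standardised to unit SD before entering a Cox model, so
hazard ratios are per SD of expression.  Partial-likelihood fits use Efron
tie handling (lifelines' default).  Genes whose Schoenfeld test rejects
proportional hazards are excluded from downstream tables with a logged
exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, proportional_hazard_test

from .core_io import ExpressionMatrix, PhenotypeTable, GRADE2, GRADE3
from .concord_enrich import OverlapPartition, overlap_partition

__all__ = [
    "CoxFit",
    "km_logrank",
    "cox_univariate",
    "cox_interaction",
    "schoenfeld_filter",
    "survival_concordance",
]


@dataclass
class CoxFit:
    """Per-term Cox estimates (HR scale, per SD of expression) plus PH tests."""

    gene: str
    terms: list[str]
    log_hr: dict[str, float]
    hr: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p: dict[str, float]
    ph_p: dict[str, float]
    ph_global_p: float
    converged: bool
    n: int
    n_events: int

    def row(self, term: str) -> dict:
        return {
            "gene": self.gene,
            "term": term,
            "HR": self.hr.get(term, np.nan),
            "ci_low": self.ci_low.get(term, np.nan),
            "ci_high": self.ci_high.get(term, np.nan),
            "p": self.p.get(term, np.nan),
            "ph_p": self.ph_p.get(term, np.nan),
            "converged": self.converged,
        }


def _survival_frame(pheno: PhenotypeTable) -> pd.DataFrame:
    df = pheno.data.copy()
    if df["months"].isna().any():
        raise ValueError("phenotype table lacks survival months for some samples")
    df["months"] = df["months"].astype(float).clip(lower=1e-9)
    df["event"] = df["event"].astype(int)
    return df


def km_logrank(pheno: PhenotypeTable) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan–Meier curves per grade plus the two-group log-rank test.

    Returns (curves, chi-square statistic, p).  Each curve is a step-function
    table with columns ``time`` and ``survival``.  A grade with zero events
    makes the comparison undefined and raises.
    """
    df = _survival_frame(pheno)
    curves: dict[str, pd.DataFrame] = {}
    groups = {}
    for grade in (GRADE2, GRADE3):
        part = df[df["grade"] == grade]
        if len(part) == 0 or part["event"].sum() == 0:
            raise ValueError(f"group {grade} has no events; log-rank p undefined")
        kmf = KaplanMeierFitter()
        kmf.fit(part["months"], part["event"])
        sf = kmf.survival_function_
        curves[grade] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
        groups[grade] = part
    res = logrank_test(
        groups[GRADE2]["months"], groups[GRADE3]["months"],
        event_observed_A=groups[GRADE2]["event"], event_observed_B=groups[GRADE3]["event"],
    )
    return curves, float(res.test_statistic), float(res.p_value)


def _standardized_gene(expr: ExpressionMatrix, gene: str, sample_ids: list[str]) -> np.ndarray:
    x = expr.subset_samples(sample_ids).values[expr.gene_index([gene])[0]]
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _na_fit(gene: str, terms: list[str], n: int, n_events: int) -> CoxFit:
    nan = {t: float("nan") for t in terms}
    return CoxFit(gene, terms, dict(nan), dict(nan), dict(nan), dict(nan),
                  dict(nan), dict(nan), float("nan"), False, n, n_events)


def _fit_cox(gene: str, df: pd.DataFrame, terms: list[str]) -> CoxFit:
    n_events = int(df["event"].sum())
    if n_events < 2:
        raise ValueError("need at least two events")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="months", event_col="event")
            ph = proportional_hazard_test(cph, df, time_transform="km")
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        return _na_fit(gene, terms, len(df), n_events)

    summary = cph.summary
    ph_p = {t: float(ph.summary.loc[t, "p"]) for t in terms}
    return CoxFit(
        gene=gene,
        terms=terms,
        log_hr={t: float(summary.loc[t, "coef"]) for t in terms},
        hr={t: float(summary.loc[t, "exp(coef)"]) for t in terms},
        ci_low={t: float(np.exp(summary.loc[t, "coef lower 95%"])) for t in terms},
        ci_high={t: float(np.exp(summary.loc[t, "coef upper 95%"])) for t in terms},
        p={t: float(summary.loc[t, "p"]) for t in terms},
        ph_p=ph_p,
        ph_global_p=float(min(ph_p.values())),
        converged=True,
        n=len(df),
        n_events=n_events,
    )


def cox_univariate(expr: ExpressionMatrix, pheno: PhenotypeTable, gene: str) -> CoxFit:
    """Single-gene Cox fit; the HR is per SD of the gene's expression."""
    df = _survival_frame(pheno)
    df = df[["months", "event"]].copy()
    df[gene] = _standardized_gene(expr, gene, pheno.sample_ids)
    return _fit_cox(gene, df, [gene])


def cox_interaction(expr: ExpressionMatrix, pheno: PhenotypeTable, gene: str) -> CoxFit:
    """Three-term Cox fit: gene, grade3 indicator, and their interaction."""
    base = _survival_frame(pheno)
    if base.groupby("grade")["event"].sum().min() < 1:
        raise ValueError("both grades need at least one event")
    df = base[["months", "event"]].copy()
    z = _standardized_gene(expr, gene, pheno.sample_ids)
    grade3 = (base["grade"] == GRADE3).to_numpy(dtype=float)
    df[gene] = z
    df["grade3"] = grade3
    df[f"{gene}:grade3"] = z * grade3
    return _fit_cox(gene, df, [gene, "grade3", f"{gene}:grade3"])


def schoenfeld_filter(fits: list[CoxFit], alpha_ph: float = 0.05) -> tuple[list[CoxFit], list[CoxFit]]:
    """Partition fits into (meets PH, violates PH) by the Schoenfeld test.

    A fit violates PH when any of its terms' PH-test p-values falls below
    ``alpha_ph``; exclusions are logged via a warning so downstream tables can
    trace what was dropped.  Non-converged fits are excluded as violations.
    """
    meets, violates = [], []
    for fit in fits:
        ok = fit.converged and all(
            (np.isnan(p) or p >= alpha_ph) for p in fit.ph_p.values()
        ) and not all(np.isnan(list(fit.ph_p.values())))
        if fit.converged and ok:
            meets.append(fit)
        else:
            violates.append(fit)
    if violates:
        warnings.warn(
            f"excluding {len(violates)} gene(s) failing the proportional-hazards check: "
            f"{[f.gene for f in violates[:5]]}",
            RuntimeWarning,
            stacklevel=2,
        )
    return meets, violates


def survival_concordance(
    significant_per_method: dict[str, set[str]], mode: str = "univariate"
) -> OverlapPartition:
    """Venn partition of significant survival genes across signature methods."""
    if mode not in ("univariate", "interaction"):
        raise ValueError("mode must be 'univariate' or 'interaction'")
    if len(significant_per_method) < 2:
        raise ValueError("need at least two methods")
    return overlap_partition({m: set(v) for m, v in significant_per_method.items()})
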