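"""Signature-set concordance, volcano tables, and hypergeometric
over-representation analysis (ORA) against GMT gene-set collections.

Concordance is reported as the full Venn partition: one count per nonempty
membership pattern, which always sums to the size of the union.  ORA tests
each gene-set term with the hypergeometric upper tail (probability of
observing at least the realised overlap when drawing the selected genes from
the universe) and BH-adjusts across tested terms.  The universe is the set of
analysed genes intersected with the collection's membership, the standard
ORA convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .filter_select import bh_adjust

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "overlap_partition",
    "OverlapPartition",
    "volcano_table",
    "ora_test",
    "term_concordance",
]


@dataclass
class GeneSetCollection:
    """Named gene-set collection: term id → (description, member gene ids)."""

    name: str
    terms: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for term, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {term!r} has no members")
            if len(set(members)) != len(members):
                raise ValueError(f"term {term!r} has duplicate members")

    @property
    def all_members(self) -> set[str]:
        out: set[str] = set()
        for _, members in self.terms.values():
            out.update(members)
        return out


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Standard GMT: term <tab> description <tab> member genes..."""
    path = Path(path)
    terms: dict[str, tuple[str, list[str]]] = {}
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{line_no}: GMT line needs term, description, >=1 member")
        term, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
        if term in terms:
            raise ValueError(f"{path}:{line_no}: duplicate term {term!r}")
        terms[term] = (desc, members)
    return GeneSetCollection(name or path.stem, terms)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([term, desc, *members])
        for term, (desc, members) in collection.terms.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class OverlapPartition:
    """Venn partition of named sets: counts per exact membership pattern."""

    pattern_counts: dict[frozenset, int]
    unique_counts: dict[str, int]
    pairwise: pd.DataFrame
    union_size: int

    def count(self, *names: str) -> int:
        return self.pattern_counts.get(frozenset(names), 0)


def overlap_partition(sets: dict[str, set[str]]) -> OverlapPartition:
    """Counts for every nonempty membership pattern across 2–6 named sets.

    Pattern counts partition the union (they sum to its size); per-set totals
    are recoverable by marginalising the patterns containing that set.
    """
    names = list(sets)
    if not 2 <= len(names) <= 6:
        raise ValueError("need between 2 and 6 sets")
    if len(set(names)) != len(names):
        raise ValueError("duplicate set names")
    universe = set().union(*sets.values())
    patterns: dict[frozenset, int] = {}
    for element in universe:
        member_of = frozenset(n for n in names if element in sets[n])
        patterns[member_of] = patterns.get(member_of, 0) + 1
    unique = {n: patterns.get(frozenset([n]), 0) for n in names}
    pairwise = pd.DataFrame(
        [[len(sets[a] & sets[b]) for b in names] for a in names],
        index=names,
        columns=names,
    )
    return OverlapPartition(patterns, unique, pairwise, len(universe))


def volcano_table(
    stats: pd.DataFrame,
    selected: list[str],
    lfc_line: float = 1.0,
    p_line: float = 0.01,
) -> pd.DataFrame:
    """Volcano-plot-ready table: log2fc, −log10 adj_p, selection/threshold flags.

    ``stats`` must cover every selected gene (columns gene_id, log2fc, adj_p).
    The output is sorted by adjusted p.
    """
    missing = set(selected) - set(stats["gene_id"])
    if missing:
        raise KeyError(f"selected genes missing from stats: {sorted(missing)[:5]}")
    out = stats[["gene_id", "log2fc", "adj_p"]].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_adj_p"] = -np.log10(out["adj_p"])
    out["selected"] = out["gene_id"].isin(set(selected))
    out["passes_lfc"] = out["log2fc"].abs() > lfc_line
    out["passes_p"] = out["adj_p"] < p_line
    return out.sort_values("adj_p", kind="stable").reset_index(drop=True)


def ora_test(
    selected: list[str] | set[str],
    universe: list[str] | set[str],
    collection: GeneSetCollection,
    alpha: float = 0.01,
    min_size: int = 5,
    max_size: int = 500,
    adjust: bool = True,
    restrict_universe: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` in each term.

    Per term with K in-universe members, the p-value is P(X ≥ overlap) for X
    hypergeometric(M=|universe|, K, N=|selected|).  Terms whose in-universe
    size falls outside [min_size, max_size] are skipped.  Columns: term,
    description, overlap, set_size, universe_size, selected_size, p, adj_p,
    significant (adj_p < alpha, or raw p when ``adjust`` is False).

    ``restrict_universe`` intersects the universe with the collection's
    membership first (the convention for annotation-backed collections where
    unannotated genes carry no information); the pipeline entry points enable
    it, while the default keeps M = |universe| exactly as supplied.
    """
    universe = set(universe)
    selected = set(selected)
    if not universe:
        raise ValueError("empty universe")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    eff_universe = universe & collection.all_members if restrict_universe else universe
    eff_selected = selected & eff_universe
    M, N = len(eff_universe), len(eff_selected)

    rows = []
    for term, (desc, members) in collection.terms.items():
        in_univ = set(members) & eff_universe
        K = len(in_univ)
        if not min_size <= K <= max_size:
            continue
        k = len(in_univ & eff_selected)
        p = float(hypergeom.sf(k - 1, M, K, N)) if M else 1.0
        rows.append(
            {"term": term, "description": desc, "overlap": k, "set_size": K,
             "universe_size": M, "selected_size": N, "p": min(p, 1.0)}
        )
    df = pd.DataFrame(rows, columns=["term", "description", "overlap", "set_size",
                                     "universe_size", "selected_size", "p"])
    if len(df):
        df["adj_p"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = (df["adj_p"] if adjust else df["p"]) < alpha
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        df["adj_p"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


def term_concordance(results_per_method: dict[str, set[str]]) -> OverlapPartition:
    """Venn partition of significant term ids across methods.

    Methods with no significant terms participate as empty sets (their
    singleton patterns are simply zero); this mirrors selectors for which no
    term reaches significance without treating them as errors.
    """
    if len(results_per_method) < 2:
        raise ValueError("need at least two methods")
    return overlap_partition({m: set(v) for m, v in results_per_method.items()})
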