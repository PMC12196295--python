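"""Over-representation analysis of gene sets against a flat term->gene table.

The test is the one-sided Fisher / hypergeometric over-representation test
used throughout GO-style analyses: for a query set of n genes drawn from a
universe of N, a term covering K universe genes and overlapping the query in
k genes gets p = P(X >= k) for X ~ Hypergeom(N, K, n), followed by
Benjamini-Hochberg correction across all tested terms.

The annotation table is taken as flat: no term ancestry propagation is
performed, so parent terms receive only the genes explicitly annotated to
them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import normalize_gene_id

logger = logging.getLogger(__name__)

#: Term-size bounds (after universe intersection) applied by default.
MIN_TERM_SIZE = 3
MAX_TERM_SIZE = 500


@dataclass
class AnnotationTable:
    """Flat term -> gene annotation with one row per (term, gene) pair."""

    table: pd.DataFrame  # columns: term_id, term_name, gene_id

    def __post_init__(self) -> None:
        req = ["term_id", "term_name", "gene_id"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation table missing columns: {missing}")
        t = self.table[req].copy()
        t["gene_id"] = t["gene_id"].map(normalize_gene_id)
        t = t.drop_duplicates(subset=["term_id", "gene_id"]).reset_index(drop=True)
        if (t.groupby("term_id").size() == 0).any():
            raise ValueError("empty annotation term")
        self.table = t

    def term_sets(self) -> dict[str, set[str]]:
        """Per-term gene sets (normalized ids)."""
        return {
            tid: set(sub["gene_id"])
            for tid, sub in self.table.groupby("term_id", sort=True)
        }

    def term_names(self) -> dict[str, str]:
        return dict(
            self.table.drop_duplicates("term_id")[["term_id", "term_name"]].values
        )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrich(
    query: set[str],
    annotations: AnnotationTable,
    universe: set[str],
    min_term_size: int = MIN_TERM_SIZE,
    max_term_size: int = MAX_TERM_SIZE,
) -> pd.DataFrame:
    """One-sided over-representation test for every annotation term.

    Parameters
    ----------
    query
        Gene set of interest (e.g. the rescued transcripts); must be a
        subset of ``universe``.
    annotations
        Flat term -> gene table; each term is intersected with the universe
        before testing, and terms falling outside the size bounds (or
        entirely outside the universe) are dropped with a warning.
    universe
        Background gene set, typically all genes tested for differential
        expression.

    Returns
    -------
    DataFrame with one row per tested term: term_id, term_name, k (overlap),
    K (term size in universe), n (query size), N (universe size),
    odds_ratio, gene_hits, p (one-sided hypergeometric tail) and q
    (BH-adjusted), sorted by (q, p, term_id).
    """
    universe = {normalize_gene_id(g) for g in universe}
    query = {normalize_gene_id(g) for g in query}
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    stray = query - universe
    if stray:
        raise ValueError(
            f"{len(stray)} query genes outside the universe, e.g. {sorted(stray)[:5]}"
        )
    N = len(universe)
    n = len(query)
    names = annotations.term_names()
    rows = []
    n_dropped = 0
    for tid, genes in annotations.term_sets().items():
        in_univ = genes & universe
        if not in_univ:
            n_dropped += 1
            continue
        K = len(in_univ)
        if K < min_term_size or K > max_term_size:
            continue
        hits = sorted(in_univ & query)
        k = len(hits)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        a, b, c, d = k, K - k, n - k, N - K - n + k
        odds = (a * d / (b * c)) if b * c > 0 else np.inf
        rows.append(
            {
                "term_id": tid,
                "term_name": names.get(tid, tid),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "odds_ratio": odds,
                "gene_hits": ",".join(hits),
                "p": min(p, 1.0),
            }
        )
    if n_dropped:
        logger.warning("%d terms entirely outside the universe were dropped", n_dropped)
    res = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "k", "K", "n", "N",
            "odds_ratio", "gene_hits", "p",
        ],
    )
    if len(res):
        res["q"] = bh_adjust(res["p"].to_numpy())
        res = res.sort_values(["q", "p", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        res["q"] = pd.Series(dtype=float)
    return res
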