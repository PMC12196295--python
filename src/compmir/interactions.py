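"""Curated miRNA->gene interaction tables and evidence filtering.

Interaction evidence is pooled from multiple curated databases (NPInter,
RegNetwork, Rise, STRING, TarBase, TransmiR in the original study) under
union semantics: an edge exists if any retained source reports it.
Interactions a source itself classifies as "weak" are excluded before any
downstream use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .containers import normalize_gene_id, normalize_mir_id

logger = logging.getLogger(__name__)

KNOWN_SOURCES = (
    "NPInter", "RegNetwork", "Rise", "STRING", "TarBase", "TransmiR", "synthetic",
)
STRENGTHS = ("strong", "weak", "unspecified")


@dataclass
class InteractionTable:
    """miRNA->gene edges with provenance and evidence strength.

    Ids are normalized on construction (species prefix stripped and
    lowercased for miRNAs, uppercased for gene symbols) so that joins
    against expression matrices are case- and prefix-insensitive.
    Duplicate (mir, gene, source) triples are collapsed.
    """

    table: pd.DataFrame  # columns: mir_id, gene_id, source_db, strength

    def __post_init__(self) -> None:
        req = ["mir_id", "gene_id", "source_db", "strength"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise ValueError(f"interaction table missing columns: {missing}")
        t = self.table[req].copy()
        if t["mir_id"].astype(str).str.strip().eq("").any():
            raise ValueError("empty miRNA id in interaction table")
        if t["gene_id"].astype(str).str.strip().eq("").any():
            raise ValueError("empty gene id in interaction table")
        t["mir_id"] = t["mir_id"].map(normalize_mir_id)
        t["gene_id"] = t["gene_id"].map(normalize_gene_id)
        unknown = set(t["strength"]) - set(STRENGTHS)
        if unknown:
            logger.warning(
                "unknown strength labels %s treated as 'unspecified'", sorted(unknown)
            )
            t.loc[t["strength"].isin(unknown), "strength"] = "unspecified"
        n0 = len(t)
        t = t.drop_duplicates(subset=["mir_id", "gene_id", "source_db"]).reset_index(
            drop=True
        )
        if len(t) < n0:
            logger.info("collapsed %d duplicate interaction rows", n0 - len(t))
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    def edges(self) -> set[tuple[str, str]]:
        """Distinct (mir, gene) pairs under union-of-sources semantics."""
        return set(map(tuple, self.table[["mir_id", "gene_id"]].drop_duplicates().values))

    def targets_of(self) -> dict[str, set[str]]:
        """mir -> set of target genes, pooled over sources."""
        pairs = self.table[["mir_id", "gene_id"]].drop_duplicates()
        return {m: set(sub["gene_id"]) for m, sub in pairs.groupby("mir_id", sort=True)}


def filter_weak(raw: InteractionTable) -> InteractionTable:
    """Drop edges whose evidence a source classifies as weak.

    Edges of unspecified strength are retained (sources without a strength
    classification contribute all their edges). Per-source removal counts
    are logged. Idempotent.
    """
    t = raw.table
    removed = t[t["strength"] == "weak"]
    if len(removed):
        for src, sub in removed.groupby("source_db"):
            logger.info("filter_weak: removed %d weak edges from %s", len(sub), src)
    return InteractionTable(t[t["strength"] != "weak"].reset_index(drop=True))
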