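"""Core in-memory containers: count matrices with a two-factor design.

The experimental design throughout is two genotypes (WT, TG) crossed with
two ages (3 and 6 months). Counts are raw, non-negative integers as produced
by featureCounts-style quantification; all normalization happens downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "TG")
AGES = (3, 6)


@dataclass
class CountMatrix:
    """Feature x sample matrix of raw counts plus the per-sample design.

    Parameters
    ----------
    values
        Non-negative integer array of shape ``(n_features, n_samples)``.
    feature_ids
        Unique feature identifiers, one per row.
    sample_ids
        Unique sample identifiers, one per column.
    design
        DataFrame indexed by sample id with columns ``genotype`` (WT/TG)
        and ``age`` (3/6), aligned to ``sample_ids``.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    design: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("count matrix must be 2-dimensional")
        nf, ns = self.values.shape
        if len(self.feature_ids) != nf:
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {nf} rows"
            )
        if len(self.sample_ids) != ns:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {ns} columns")
        if len(set(self.feature_ids)) != nf:
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != ns:
            raise ValueError("duplicate sample ids")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.allclose(self.values, np.round(self.values)):
                bad = np.argwhere(self.values != np.round(self.values))[0]
                raise ValueError(
                    f"non-integer count at feature {self.feature_ids[bad[0]]}, "
                    f"sample {self.sample_ids[bad[1]]}"
                )
            self.values = self.values.astype(np.int64)
        if (self.values < 0).any():
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative count at feature {self.feature_ids[bad[0]]}, "
                f"sample {self.sample_ids[bad[1]]}"
            )
        missing = [s for s in self.sample_ids if s not in self.design.index]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        self.design = self.design.loc[self.sample_ids, ["genotype", "age"]].copy()
        bad_gt = set(self.design["genotype"]) - set(GENOTYPES)
        if bad_gt:
            raise ValueError(f"unknown genotype levels: {sorted(bad_gt)}")
        self.design["age"] = self.design["age"].astype(int)
        bad_age = set(self.design["age"]) - set(AGES)
        if bad_age:
            raise ValueError(f"unknown age levels: {sorted(bad_age)}")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_mask(self, genotype: str | None = None, age: int | None = None) -> np.ndarray:
        """Boolean sample mask for a design cell (either factor optional)."""
        mask = np.ones(self.n_samples, dtype=bool)
        if genotype is not None:
            mask &= (self.design["genotype"] == genotype).to_numpy()
        if age is not None:
            mask &= (self.design["age"] == int(age)).to_numpy()
        return mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


def normalize_gene_id(gene: str) -> str:
    """Canonical gene id for joins: trimmed, uppercased symbol."""
    return str(gene).strip().upper()


_SPECIES_PREFIXES = ("mmu-", "hsa-", "rno-")


def normalize_mir_id(mir: str) -> str:
    """Canonical miRNA id: trimmed, species prefix dropped, lowercased."""
    m = str(mir).strip()
    low = m.lower()
    for pre in _SPECIES_PREFIXES:
        if low.startswith(pre):
            low = low[len(pre):]
            break
    return low
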