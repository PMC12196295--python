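"""Reinstatement calls and compensatory-miR identification.

The inference chain: genes significantly downregulated in the disease
genotype (TG) at the early time point are "deregulated"; a deregulated gene
is "reinstated" if its normalized expression in TG rises by more than 50%
from 3 to 6 months (fold change strictly greater than 1.5); a reinstated
gene targeted by at least one miRNA that is itself significantly
downregulated across the TG time course is "rescued"; and a downregulated
miRNA with at least ``k_min`` (default 5, inclusive) rescued targets is a
"compensatory miR".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .containers import normalize_gene_id, normalize_mir_id
from .interactions import InteractionTable

#: Fold-change a deregulated gene must strictly exceed (TG 6 mo over 3 mo)
#: to count as reinstated: an increase of more than 50%.
R_MIN = 1.5
#: Minimum number of rescued targets for a miR to be called compensatory.
K_MIN = 5


@dataclass
class ReinstatementCall:
    """Per-gene recovery of expression across the TG time course."""

    table: pd.DataFrame  # index gene_id; mean_tg3, mean_tg6, recovery_ratio, reinstated

    @property
    def reinstated(self) -> set[str]:
        return set(self.table.index[self.table["reinstated"]])


@dataclass
class CompensatoryCall:
    """Joint output of the compensatory inference.

    Set-chain invariant: rescued subset of reinstated subset of the
    deregulated (down) genes; every compensatory miR's target set is a
    subset of the rescued genes with at least ``k_min`` members.
    """

    dereg_down_genes: set[str]
    reinstated_genes: set[str]
    down_mirs: set[str]
    rescued_genes: set[str]
    comp_mirs: dict[str, set[str]]  # miR -> rescued targets (>= k_min each)
    k_min: int = K_MIN
    frac_reinstated: float = 0.0
    frac_rescued: float = 0.0
    empty_denominator: bool = field(default=False)

    def validate(self) -> None:
        if not self.rescued_genes <= self.reinstated_genes:
            raise ValueError("rescued genes must be a subset of reinstated genes")
        if not self.reinstated_genes <= self.dereg_down_genes:
            raise ValueError("reinstated genes must be a subset of deregulated genes")
        for m, targets in self.comp_mirs.items():
            if not targets <= self.rescued_genes:
                raise ValueError(f"targets of {m} outside the rescued set")
            if len(targets) < self.k_min:
                raise ValueError(f"compensatory miR {m} has < {self.k_min} targets")
        for frac in (self.frac_reinstated, self.frac_rescued):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "dereg_down_genes": sorted(self.dereg_down_genes),
            "reinstated_genes": sorted(self.reinstated_genes),
            "down_mirs": sorted(self.down_mirs),
            "rescued_genes": sorted(self.rescued_genes),
            "comp_mirs": {m: sorted(t) for m, t in sorted(self.comp_mirs.items())},
            "k_min": self.k_min,
            "frac_reinstated": self.frac_reinstated,
            "frac_rescued": self.frac_rescued,
            "empty_denominator": self.empty_denominator,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompensatoryCall":
        return cls(
            dereg_down_genes=set(d["dereg_down_genes"]),
            reinstated_genes=set(d["reinstated_genes"]),
            down_mirs=set(d["down_mirs"]),
            rescued_genes=set(d["rescued_genes"]),
            comp_mirs={m: set(t) for m, t in d["comp_mirs"].items()},
            k_min=d.get("k_min", K_MIN),
            frac_reinstated=d["frac_reinstated"],
            frac_rescued=d["frac_rescued"],
            empty_denominator=d.get("empty_denominator", False),
        )


def call_reinstatement(
    tpm: pd.DataFrame,
    design: pd.DataFrame,
    dereg_down: set[str],
    r_min: float = R_MIN,
    pseudocount: float = 0.5,
) -> ReinstatementCall:
    """Call reinstated genes on the TG time course.

    A deregulated gene is reinstated iff
    ``(mean_TG6 + c) / (mean_TG3 + c) > r_min`` strictly, with group means
    taken over the normalized (counts-per-million) expression of the TG
    samples at each age.

    Parameters
    ----------
    tpm
        Normalized expression, features x samples.
    design
        Sample design with genotype and age, indexed by sample id.
    dereg_down
        The deregulated (downregulated at 3 months) gene set; every id must
        be present in ``tpm``.
    """
    genes = sorted(dereg_down)
    missing = [g for g in genes if g not in tpm.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:10]}"
                       + ("..." if len(missing) > 10 else ""))
    design = design.loc[tpm.columns]
    tg3 = tpm.columns[(design["genotype"] == "TG") & (design["age"].astype(int) == 3)]
    tg6 = tpm.columns[(design["genotype"] == "TG") & (design["age"].astype(int) == 6)]
    if len(tg3) == 0 or len(tg6) == 0:
        raise ValueError("both TG age groups must be non-empty")
    sub = tpm.loc[genes]
    mean3 = sub[tg3].mean(axis=1)
    mean6 = sub[tg6].mean(axis=1)
    ratio = (mean6 + pseudocount) / (mean3 + pseudocount)
    table = pd.DataFrame(
        {
            "mean_tg3": mean3,
            "mean_tg6": mean6,
            "recovery_ratio": ratio,
            "reinstated": ratio > r_min,
        }
    )
    table.index.name = "gene_id"
    return ReinstatementCall(table)


def call_compensatory(
    dereg_down: set[str],
    reinstated: set[str],
    down_mirs: set[str],
    interactions: InteractionTable,
    k_min: int = K_MIN,
) -> CompensatoryCall:
    """Identify rescued genes and compensatory miRs.

    ``rescued`` are the reinstated genes targeted by at least one
    downregulated miR; a miR is compensatory if it is downregulated and has
    at least ``k_min`` rescued targets (inclusive). The interaction table
    should already be weak-filtered; edges are pooled across sources.
    """
    dereg_down = {normalize_gene_id(g) for g in dereg_down}
    reinstated = {normalize_gene_id(g) for g in reinstated}
    down_mirs = {normalize_mir_id(m) for m in down_mirs}
    if not reinstated <= dereg_down:
        raise ValueError("reinstated set must be a subset of the deregulated set")
    targets = interactions.targets_of()
    rescued: set[str] = set()
    for m in down_mirs:
        rescued |= targets.get(m, set()) & reinstated
    comp = {}
    for m in sorted(down_mirs):
        hits = targets.get(m, set()) & rescued
        if len(hits) >= k_min:
            comp[m] = hits
    call = CompensatoryCall(
        dereg_down_genes=dereg_down,
        reinstated_genes=reinstated,
        down_mirs=down_mirs,
        rescued_genes=rescued,
        comp_mirs=comp,
        k_min=k_min,
        frac_reinstated=(len(reinstated) / len(dereg_down)) if dereg_down else 0.0,
        frac_rescued=(len(rescued) / len(reinstated)) if reinstated else 0.0,
        empty_denominator=not dereg_down or not reinstated,
    )
    call.validate()
    return call


def control_target_counts(
    call: CompensatoryCall,
    up_genes_tg3: set[str],
    interactions: InteractionTable,
) -> pd.DataFrame:
    """Per-compensatory-miR target counts in rescued vs control (up@3) sets.

    The control column counts each miR's targets among the genes
    upregulated in TG at 3 months — the specificity display contrasting
    rescued-target counts with an unrelated gene set.
    """
    up_genes = {normalize_gene_id(g) for g in up_genes_tg3}
    targets = interactions.targets_of()
    rows = []
    for m in sorted(call.comp_mirs):
        t = targets.get(m, set())
        rows.append(
            {
                "mir_id": m,
                "n_rescued_targets": len(call.comp_mirs[m]),
                "n_control_targets": len(t & up_genes),
            }
        )
    return pd.DataFrame(rows, columns=["mir_id", "n_rescued_targets",
                                       "n_control_targets"])
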