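"""Synthetic mRNA/miRNA count data with planted compensatory structure.

The generator emulates the study design the pipeline targets: two genotypes
(WT control, TG disease model) sampled at 3 and 6 months, a block of genes
downregulated in TG at 3 months of which a subset returns to baseline by 6
months ("reinstated"), and a set of miRNAs downregulated across the TG time
course whose targets are exactly those recovering genes. Counts are
negative-binomially distributed around library-size-scaled group means, so
the full analysis chain (size factors, NB Wald tests, reinstatement calls,
compensatory-miR identification, enrichment) can be validated against the
planted truth without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, normalize_gene_id, normalize_mir_id
from .enrichment import AnnotationTable
from .interactions import InteractionTable

#: Group sizes mirroring the study's cohorts (WT@3, TG@3, WT@6, TG@6).
DEFAULT_GROUP_SIZES = {("WT", 3): 5, ("TG", 3): 6, ("WT", 6): 15, ("TG", 6): 16}

_DB_NAMES = ("NPInter", "RegNetwork", "Rise", "STRING", "TarBase", "TransmiR")


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset.

    Effect log2 fold changes are negative (planted downregulation);
    ``dispersion`` is the NB overdispersion alpha in Var = mu + alpha*mu^2
    (0 gives Poisson counts). ``mean_expression_log_range`` bounds the
    natural log of baseline group means; ``library_size_range`` bounds the
    per-sample multiplicative depth factors (drawn log-uniformly).
    ``decoy_edge_rate`` is the per-(miR, gene) probability of a random
    non-planted interaction edge.
    """

    n_genes: int = 2000
    n_mirs: int = 1000
    samples_per_group: dict[tuple[str, int], int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    frac_dereg_genes: float = 0.10
    frac_reinstated: float = 0.50
    n_comp_mirs: int = 10
    targets_per_mir: int = 8
    dereg_lfc: float = -1.5
    mir_down_lfc: float = -1.5
    dispersion: float = 0.1
    mean_expression_log_range: tuple[float, float] = (3.0, 8.0)
    library_size_range: tuple[float, float] = (0.5, 2.0)
    decoy_edge_rate: float = 0.002
    decoy_weak_frac: float = 0.3
    allow_decoys_on_reinstated: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_dereg_genes", "frac_reinstated", "decoy_edge_rate",
                     "decoy_weak_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 1 or self.n_mirs < 1:
            raise ValueError("n_genes and n_mirs must be positive")
        if self.targets_per_mir < 1:
            raise ValueError("targets_per_mir must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        expected = set(DEFAULT_GROUP_SIZES)
        if set(self.samples_per_group) != expected:
            raise ValueError(f"samples_per_group must cover exactly {sorted(expected)}")
        if any(n < 1 for n in self.samples_per_group.values()):
            raise ValueError("every (genotype, age) cell needs >= 1 sample")
        lo, hi = self.mean_expression_log_range
        if not lo <= hi:
            raise ValueError("invalid mean_expression_log_range")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValueError("library_size_range must be positive and ordered")
        n_dereg = round(self.frac_dereg_genes * self.n_genes)
        n_reinst = round(self.frac_reinstated * n_dereg)
        if self.n_comp_mirs > 0 and self.targets_per_mir > n_reinst:
            raise ValueError(
                f"targets_per_mir={self.targets_per_mir} exceeds the "
                f"{n_reinst} reinstated genes available as targets"
            )
        if self.n_comp_mirs > self.n_mirs:
            raise ValueError("n_comp_mirs exceeds n_mirs")


@dataclass
class PlantedTruth:
    """Ground truth of the planted effects, for recovery testing.

    Invariants: reinstated genes are a subset of the deregulated genes;
    every compensatory miR has at least ``targets_per_mir`` true edges into
    reinstated genes; null genes carry no planted effect.
    """

    dereg_genes: set[str]
    reinstated_genes: set[str]
    comp_mirs: set[str]
    true_edges: set[tuple[str, str]]
    null_genes: set[str]

    def validate(self, targets_per_mir: int = 1) -> None:
        if not self.reinstated_genes <= self.dereg_genes:
            raise ValueError("reinstated genes must be a subset of deregulated genes")
        if self.null_genes & self.dereg_genes:
            raise ValueError("null genes overlap deregulated genes")
        per_mir: dict[str, int] = {m: 0 for m in self.comp_mirs}
        for m, g in self.true_edges:
            if m in per_mir and g in self.reinstated_genes:
                per_mir[m] += 1
        short = [m for m, c in per_mir.items() if c < targets_per_mir]
        if short:
            raise ValueError(f"comp miRs with too few true edges: {sorted(short)}")

    def normalized(self) -> "PlantedTruth":
        """Truth with ids mapped through the join normalization."""
        return PlantedTruth(
            dereg_genes={normalize_gene_id(g) for g in self.dereg_genes},
            reinstated_genes={normalize_gene_id(g) for g in self.reinstated_genes},
            comp_mirs={normalize_mir_id(m) for m in self.comp_mirs},
            true_edges={
                (normalize_mir_id(m), normalize_gene_id(g)) for m, g in self.true_edges
            },
            null_genes={normalize_gene_id(g) for g in self.null_genes},
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "dereg_genes": sorted(self.dereg_genes),
                "reinstated_genes": sorted(self.reinstated_genes),
                "comp_mirs": sorted(self.comp_mirs),
                "true_edges": sorted(map(list, self.true_edges)),
                "null_genes": sorted(self.null_genes),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        return cls(
            dereg_genes=set(d["dereg_genes"]),
            reinstated_genes=set(d["reinstated_genes"]),
            comp_mirs=set(d["comp_mirs"]),
            true_edges={tuple(e) for e in d["true_edges"]},
            null_genes=set(d["null_genes"]),
        )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, Var = mu + alpha*mu^2) counts via gamma-Poisson mixing."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mean)
    return rng.poisson(lam)


def _sample_layout(spg: dict[tuple[str, int], int]) -> pd.DataFrame:
    rows = []
    for (gt, age) in ((("WT", 3)), ("TG", 3), ("WT", 6), ("TG", 6)):
        for i in range(spg[(gt, age)]):
            rows.append({"sample_id": f"{gt}{age}_{i + 1:02d}", "genotype": gt, "age": age})
    return pd.DataFrame(rows).set_index("sample_id")


def generate_dataset(
    config: SimConfig,
) -> tuple[CountMatrix, CountMatrix, InteractionTable, AnnotationTable, PlantedTruth]:
    """Draw a full synthetic dataset plus its planted truth.

    Returns the mRNA count matrix, the miRNA count matrix, the interaction
    table (all planted edges, strength "strong", plus random decoys), a
    default annotation table (see :func:`generate_annotations`), and the
    planted truth. Identical configs (including seed) give bit-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_ids = [f"Gene{i + 1:05d}" for i in range(config.n_genes)]
    mir_ids = [f"mmu-miR-{i + 1:04d}" for i in range(config.n_mirs)]
    design = _sample_layout(config.samples_per_group)

    n_dereg = round(config.frac_dereg_genes * config.n_genes)
    n_reinst = round(config.frac_reinstated * n_dereg)
    dereg_idx = rng.choice(config.n_genes, size=n_dereg, replace=False)
    reinst_idx = rng.choice(dereg_idx, size=n_reinst, replace=False) if n_dereg else np.array([], dtype=int)
    comp_idx = rng.choice(config.n_mirs, size=config.n_comp_mirs, replace=False)

    dereg = [gene_ids[i] for i in sorted(dereg_idx)]
    reinstated = [gene_ids[i] for i in sorted(reinst_idx)]
    comp_mirs = [mir_ids[i] for i in sorted(comp_idx)]

    # baseline group means, log-uniform across features
    lo, hi = config.mean_expression_log_range
    gene_base = np.exp(rng.uniform(lo, hi, size=config.n_genes))
    mir_base = np.exp(rng.uniform(lo, hi, size=config.n_mirs))

    # per-group expected means encode the planted effects
    dereg_mask = np.zeros(config.n_genes, dtype=bool)
    dereg_mask[dereg_idx] = True
    reinst_mask = np.zeros(config.n_genes, dtype=bool)
    reinst_mask[reinst_idx] = True
    persist_mask = dereg_mask & ~reinst_mask

    gene_group_mean = {}
    for (gt, age) in DEFAULT_GROUP_SIZES:
        mu = gene_base.copy()
        if gt == "TG" and age == 3:
            mu[dereg_mask] *= 2.0 ** config.dereg_lfc
        elif gt == "TG" and age == 6:
            mu[persist_mask] *= 2.0 ** config.dereg_lfc  # deficit persists
        gene_group_mean[(gt, age)] = mu

    comp_mask = np.zeros(config.n_mirs, dtype=bool)
    comp_mask[comp_idx] = True
    mir_group_mean = {}
    for (gt, age) in DEFAULT_GROUP_SIZES:
        mu = mir_base.copy()
        if gt == "TG" and age == 6:
            mu[comp_mask] *= 2.0 ** config.mir_down_lfc
        mir_group_mean[(gt, age)] = mu

    # library depth factors, one per sample per assay
    ls_lo, ls_hi = np.log(config.library_size_range[0]), np.log(config.library_size_range[1])
    lib_mrna = np.exp(rng.uniform(ls_lo, ls_hi, size=len(design)))
    lib_mir = np.exp(rng.uniform(ls_lo, ls_hi, size=len(design)))

    def draw(group_mean: dict, base_n: int, lib: np.ndarray) -> np.ndarray:
        counts = np.zeros((base_n, len(design)), dtype=np.int64)
        for j, (sid, row) in enumerate(design.iterrows()):
            mu = group_mean[(row["genotype"], int(row["age"]))] * lib[j]
            counts[:, j] = _nb_counts(rng, mu, config.dispersion)
        return counts

    mrna = CountMatrix(draw(gene_group_mean, config.n_genes, lib_mrna),
                       gene_ids, list(design.index), design)
    mir = CountMatrix(draw(mir_group_mean, config.n_mirs, lib_mir),
                      mir_ids, list(design.index), design)

    # planted edges: each compensatory miR targets reinstated genes
    true_edges: set[tuple[str, str]] = set()
    rows = []
    for m in comp_mirs:
        targets = rng.choice(reinstated, size=config.targets_per_mir, replace=False)
        for g in sorted(targets):
            true_edges.add((m, g))
            rows.append({"mir_id": m, "gene_id": g,
                         "source_db": _DB_NAMES[rng.integers(len(_DB_NAMES))],
                         "strength": "strong"})

    # decoy edges; by default never from comp miRs into reinstated genes,
    # so the planted compensatory structure stays identifiable
    reinst_set = set(reinstated)
    comp_set = set(comp_mirs)
    for m in mir_ids:
        forbidden = {g for (mm, g) in true_edges if mm == m}
        if m in comp_set and not config.allow_decoys_on_reinstated:
            forbidden |= reinst_set
        eligible = [g for g in gene_ids if g not in forbidden]
        k = rng.binomial(len(eligible), config.decoy_edge_rate)
        if k == 0:
            continue
        for g in rng.choice(eligible, size=k, replace=False):
            strength = ("weak" if rng.random() < config.decoy_weak_frac
                        else ("strong" if rng.random() < 0.5 else "unspecified"))
            rows.append({"mir_id": m, "gene_id": g,
                         "source_db": _DB_NAMES[rng.integers(len(_DB_NAMES))],
                         "strength": strength})
    interactions = InteractionTable(pd.DataFrame(
        rows, columns=["mir_id", "gene_id", "source_db", "strength"]))

    truth = PlantedTruth(
        dereg_genes=set(dereg),
        reinstated_genes=set(reinstated),
        comp_mirs=set(comp_mirs),
        true_edges=true_edges,
        null_genes=set(gene_ids) - set(dereg),
    )
    truth.validate(config.targets_per_mir if config.n_comp_mirs else 1)

    annotations = generate_annotations(truth, n_terms=50,
                                       term_size_range=(10, 100),
                                       enriched_term_frac=0.1,
                                       seed=int(rng.integers(2**31)))
    return mrna, mir, interactions, annotations, truth


def generate_annotations(
    truth: PlantedTruth,
    n_terms: int,
    term_size_range: tuple[int, int],
    enriched_term_frac: float,
    seed: int,
) -> AnnotationTable:
    """Random functional-term annotation with optional planted enrichment.

    The first ``round(enriched_term_frac * n_terms)`` terms (lowest term
    ids) are preferentially loaded with reinstated genes (~70% of their
    members where available); the remainder draw genes uniformly from the
    whole gene universe.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    universe = sorted(truth.dereg_genes | truth.null_genes)
    lo, hi = term_size_range
    if not 1 <= lo <= hi or hi > len(universe):
        raise ValueError("term_size_range outside [1, n_genes]")
    rng = np.random.default_rng(seed)
    n_enriched = round(enriched_term_frac * n_terms)
    reinstated = sorted(truth.reinstated_genes)
    rows = []
    for t in range(n_terms):
        tid = f"TERM{t + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        if t < n_enriched and reinstated:
            n_hit = min(int(round(0.7 * size)), len(reinstated))
            hits = list(rng.choice(reinstated, size=n_hit, replace=False))
            rest_pool = [g for g in universe if g not in set(hits)]
            rest = list(rng.choice(rest_pool, size=size - n_hit, replace=False))
            genes = hits + rest
            name = f"planted enriched process {t + 1}"
        else:
            genes = list(rng.choice(universe, size=size, replace=False))
            name = f"random process {t + 1}"
        for g in genes:
            rows.append({"term_id": tid, "term_name": name, "gene_id": g})
    return AnnotationTable(pd.DataFrame(rows))
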