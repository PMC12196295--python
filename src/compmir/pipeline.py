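"""End-to-end orchestration: counts in, compensatory network and report out.

Stage order: differential expression on the four study contrasts ->
reinstatement and compensatory-miR calls -> bipartite network with core
truncation -> functional enrichment of the rescued transcripts. Every
intermediate artifact is written to the output directory, and the run
report (JSON + Markdown) is byte-stable: rerunning on identical config and
inputs reproduces it exactly (timings go to run.log only).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .compensatory import (
    K_MIN,
    R_MIN,
    call_compensatory,
    call_reinstatement,
    control_target_counts,
)
from .diffexpr import (
    PSEUDOCOUNT,
    Contrast,
    DEThresholds,
    classify_deg,
    nb_wald,
    standard_contrasts,
    tpm_normalize,
)
from .enrichment import fisher_enrich
from .interactions import filter_weak
from .io import (
    read_annotations,
    read_count_matrix,
    read_interactions,
    write_de_result,
)
from .network import build_network, edge_list_frame, node_attr_frame, truncate_core, write_graphml

logger = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All inputs and constants of one pipeline run.

    The defaults collect the analysis constants: FDR < 0.05, log2FC
    cutoffs 0.1 (loose) and 0.26 (strict), reinstatement fold change 1.5,
    >= 5 targets per compensatory miR, 1000 paths for core truncation.
    """

    mrna_counts: str
    mir_counts: str
    sample_sheet: str
    interactions: str
    annotations: str
    outdir: str
    fdr_max: float = 0.05
    lfc_min_loose: float = 0.1
    lfc_min_strict: float = 0.26
    r_min: float = R_MIN
    k_min: int = K_MIN
    max_paths: int = 1000
    pseudocount: float = PSEUDOCOUNT
    seed: int = 0
    schema_version: int = CONFIG_SCHEMA_VERSION

    def thresholds(self) -> DEThresholds:
        return DEThresholds(self.fdr_max, self.lfc_min_loose, self.lfc_min_strict)

    def input_paths(self) -> list[str]:
        return [self.mrna_counts, self.mir_counts, self.sample_sheet,
                self.interactions, self.annotations]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        version = raw.pop("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def content_hash(self) -> str:
        """SHA-256 over the analysis parameters and every input file's bytes.

        Paths are excluded so that moving identical inputs elsewhere keeps
        the hash stable.
        """
        h = hashlib.sha256()
        path_fields = set(
            ["outdir", "mrna_counts", "mir_counts", "sample_sheet",
             "interactions", "annotations"]
        )
        cfg = {k: v for k, v in asdict(self).items() if k not in path_fields}
        h.update(json.dumps(cfg, sort_keys=True).encode())
        for p in self.input_paths():
            h.update(Path(p).read_bytes())
        return h.hexdigest()


@dataclass
class RunReport:
    """Per-stage record of one pipeline run; serialized as JSON + Markdown."""

    version: str
    config_hash: str
    n_genes: int = 0
    n_mirs: int = 0
    n_samples: int = 0
    n_interactions_raw: int = 0
    n_interactions_filtered: int = 0
    deg_counts: dict = field(default_factory=dict)  # contrast -> {loose/strict up/down}
    n_dereg_down: int = 0
    n_reinstated: int = 0
    frac_reinstated: float = 0.0
    n_down_mirs: int = 0
    n_rescued: int = 0
    frac_rescued: float = 0.0
    n_comp_mirs: int = 0
    network_nodes: int = 0
    network_edges: int = 0
    core_paths_used: int = 0
    core_coverage: float = 0.0
    n_enriched_terms_q05: int = 0
    failed_stage: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    def to_markdown(self) -> str:
        lines = [
            "# Compensatory-miR pipeline report",
            "",
            f"- software version: {self.version}",
            f"- config hash: `{self.config_hash}`",
            f"- input: {self.n_genes} genes, {self.n_mirs} miRNAs, "
            f"{self.n_samples} samples",
            f"- interactions: {self.n_interactions_raw} raw, "
            f"{self.n_interactions_filtered} after weak-edge filtering",
            "",
            "## Differential expression (FDR < 0.05)",
            "",
            "| contrast | up (loose) | down (loose) | up (strict) | down (strict) |",
            "|---|---|---|---|---|",
        ]
        for name, c in self.deg_counts.items():
            lines.append(
                f"| {name} | {c['up_loose']} | {c['down_loose']} "
                f"| {c['up_strict']} | {c['down_strict']} |"
            )
        lines += [
            "",
            "## Compensatory inference",
            "",
            f"- deregulated (down, strict) genes at 3 months: {self.n_dereg_down}",
            f"- reinstated genes: {self.n_reinstated} "
            f"({100 * self.frac_reinstated:.1f}% of deregulated)",
            f"- miRNAs down across the TG time course: {self.n_down_mirs}",
            f"- rescued transcripts: {self.n_rescued} "
            f"({100 * self.frac_rescued:.1f}% of reinstated)",
            f"- compensatory miRs (>= k targets): {self.n_comp_mirs}",
            "",
            "## Network",
            "",
            f"- full bipartite network: {self.network_nodes} nodes, "
            f"{self.network_edges} edges",
            f"- core truncation: {self.core_paths_used} paths, "
            f"coverage {100 * self.core_coverage:.1f}% of rescued transcripts",
            "",
            "## Enrichment",
            "",
            f"- terms with q < 0.05: {self.n_enriched_terms_q05}",
            "",
        ]
        return "\n".join(lines)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis and write all artifacts to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("compmir")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    report = RunReport(version=__version__, config_hash=config.content_hash())
    stage = "setup"
    t0 = time.monotonic()
    try:
        stage = "load"
        mrna = read_count_matrix(config.mrna_counts, config.sample_sheet)
        mir = read_count_matrix(config.mir_counts, config.sample_sheet)
        raw_interactions = read_interactions(config.interactions)
        annotations = read_annotations(config.annotations)
        report.n_genes, report.n_samples = mrna.n_features, mrna.n_samples
        report.n_mirs = mir.n_features
        report.n_interactions_raw = len(raw_interactions)
        logger.info("loaded %d genes, %d miRNAs, %d samples",
                    report.n_genes, report.n_mirs, report.n_samples)

        stage = "diffexpr"
        th = config.thresholds()
        de_mrna = {}
        for contrast in standard_contrasts():
            res = nb_wald(mrna, contrast, pseudocount=config.pseudocount)
            de_mrna[contrast.name] = res
            write_de_result(res, outdir / f"de_mrna_{contrast.name.replace('@', '_at_')}.tsv")
        mir_contrast = Contrast("6_vs_3@TG", ("genotype", "TG"), ("age", 3, 6))
        de_mir = nb_wald(mir, mir_contrast, pseudocount=config.pseudocount)
        write_de_result(de_mir, outdir / "de_mir_6_vs_3_at_TG.tsv")
        for name, res in de_mrna.items():
            counts = {}
            for which in ("loose", "strict"):
                up, down = classify_deg(res, th, which)
                counts[f"up_{which}"], counts[f"down_{which}"] = len(up), len(down)
            report.deg_counts[name] = counts
        logger.info("DE complete: %s", report.deg_counts)

        stage = "reinstatement"
        up3_strict, dereg_down = classify_deg(de_mrna["TG_vs_WT@3"], th, "strict")
        cpm = tpm_normalize(mrna)
        reinst = call_reinstatement(cpm, mrna.design, dereg_down,
                                    r_min=config.r_min,
                                    pseudocount=config.pseudocount)
        reinst.table.to_csv(outdir / "reinstatement.tsv", sep="\t",
                            float_format="%.10g")
        report.n_dereg_down = len(dereg_down)
        report.n_reinstated = len(reinst.reinstated)

        stage = "compensatory"
        _, down_mirs = classify_deg(de_mir, th, "strict")
        interactions = filter_weak(raw_interactions)
        report.n_interactions_filtered = len(interactions)
        call = call_compensatory(dereg_down, reinst.reinstated, down_mirs,
                                 interactions, k_min=config.k_min)
        (outdir / "compensatory_call.json").write_text(
            json.dumps(call.to_dict(), indent=1, sort_keys=True)
        )
        control = control_target_counts(call, up3_strict, interactions)
        control.to_csv(outdir / "comp_mir_targets.tsv", sep="\t", index=False)
        report.n_down_mirs = len(down_mirs)
        report.n_rescued = len(call.rescued_genes)
        report.n_comp_mirs = len(call.comp_mirs)
        report.frac_reinstated = call.frac_reinstated
        report.frac_rescued = call.frac_rescued

        stage = "network"
        net = build_network(call, interactions)
        report.network_nodes, report.network_edges = net.number_of_nodes(), net.number_of_edges()
        write_graphml(net, str(outdir / "network.graphml"))
        edge_list_frame(net).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
        node_attr_frame(net).to_csv(outdir / "network_nodes.tsv", sep="\t", index=False)
        if call.comp_mirs:
            core = truncate_core(net, set(call.comp_mirs), config.max_paths)
            write_graphml(core.graph, str(outdir / "core_network.graphml"))
            report.core_paths_used = core.paths_used
            report.core_coverage = core.coverage

        stage = "enrichment"
        universe = de_mrna["TG_vs_WT@3"].tested_features()
        if call.rescued_genes:
            enr = fisher_enrich(call.rescued_genes, annotations, universe)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                       float_format="%.10g")
            summary = enr[["term_name", "k", "n", "q"]].copy()
            summary["gene_ratio"] = summary["k"] / summary["n"]
            summary[["term_name", "gene_ratio", "q"]].to_csv(
                outdir / "enrichment_summary.tsv", sep="\t", index=False,
                float_format="%.10g")
            report.n_enriched_terms_q05 = int((enr["q"] < 0.05).sum())

        stage = "report"
        (outdir / "report.json").write_text(report.to_json())
        (outdir / "report.md").write_text(report.to_markdown())
        logger.info("pipeline finished in %.1f s", time.monotonic() - t0)
    except Exception as exc:
        report.failed_stage = stage
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return report
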