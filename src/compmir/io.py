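"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: TSV count matrices (features in rows, header =
sample ids) or MatrixMarket triplets with ``_features.tsv``/``_samples.tsv``
sidecars, a TSV sample sheet (sample_id, genotype, age), TSV interaction
and annotation tables, and JSON for planted truth and compensatory calls.
Writer/reader pairs round-trip exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CountMatrix
from .enrichment import AnnotationTable
from .interactions import InteractionTable


def write_sample_sheet(design: pd.DataFrame, path: str | Path) -> None:
    out = design.reset_index()
    out.columns = ["sample_id", "genotype", "age"]
    out.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genotype": str})
    req = {"sample_id", "genotype", "age"}
    missing = req - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in sheet: {dup}")
    return sheet.set_index("sample_id")[["genotype", "age"]]


def write_count_matrix(cm: CountMatrix, path: str | Path, fmt: str = "tsv") -> None:
    """Write counts as TSV or as a MatrixMarket triplet with sidecars."""
    path = Path(path)
    if fmt == "tsv":
        cm.to_frame().rename_axis("feature_id").to_csv(path, sep="\t")
    elif fmt == "mtx":
        spio.mmwrite(str(path), sparse.coo_matrix(cm.values))
        stem = path.with_suffix("")
        pd.Series(cm.feature_ids).to_csv(f"{stem}_features.tsv", sep="\t",
                                         index=False, header=False)
        pd.Series(cm.sample_ids).to_csv(f"{stem}_samples.tsv", sep="\t",
                                        index=False, header=False)
    else:
        raise ValueError(f"unknown count-matrix format: {fmt}")


def read_count_matrix(path: str | Path, sample_sheet_path: str | Path) -> CountMatrix:
    """Load a TSV or MatrixMarket count matrix and validate it against the sheet."""
    path = Path(path)
    design = read_sample_sheet(sample_sheet_path)
    if path.suffix == ".mtx":
        values = np.asarray(spio.mmread(str(path)).todense())
        stem = path.with_suffix("")
        features = pd.read_csv(f"{stem}_features.tsv", sep="\t", header=None)[0].astype(str).tolist()
        samples = pd.read_csv(f"{stem}_samples.tsv", sep="\t", header=None)[0].astype(str).tolist()
    else:
        frame = pd.read_csv(path, sep="\t", index_col=0)
        features = [str(f) for f in frame.index]
        samples = [str(c) for c in frame.columns]
        values = frame.to_numpy()
    only_matrix = [s for s in samples if s not in design.index]
    only_sheet = [s for s in design.index if s not in samples]
    if only_matrix or only_sheet:
        raise ValueError(
            f"sample mismatch: in matrix only {only_matrix}, in sheet only {only_sheet}"
        )
    return CountMatrix(values, features, samples, design)


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def read_interactions(path: str | Path) -> InteractionTable:
    return InteractionTable(pd.read_csv(path, sep="\t", dtype=str))


def write_annotations(ann: AnnotationTable, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> AnnotationTable:
    return AnnotationTable(pd.read_csv(path, sep="\t", dtype=str))


def write_de_result(res, path: str | Path) -> None:
    out = res.table.reset_index()
    out.columns = ["feature_id", "base_mean", "log2fc", "se", "p", "fdr", "tested"]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_de_result(path: str | Path, contrast: str):
    from .diffexpr import DEResult

    t = pd.read_csv(path, sep="\t", index_col="feature_id")
    t.columns = ["base_mean", "log2fc", "se_log2fc", "wald_p", "fdr", "tested"]
    t["tested"] = t["tested"].astype(bool)
    return DEResult(contrast=contrast, table=t)
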