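from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from compmir import SimConfig, generate_dataset
from compmir.containers import CountMatrix
from compmir.io import (
    write_annotations,
    write_count_matrix,
    write_interactions,
    write_sample_sheet,
)
from compmir.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic dataset (seed 1) with its planted truth."""
    return generate_dataset(SimConfig(seed=1))


def write_dataset(dataset, directory: Path) -> PipelineConfig:
    """Write a generated dataset to disk and return a pipeline config for it."""
    mrna, mir, interactions, annotations, _ = dataset
    directory.mkdir(parents=True, exist_ok=True)
    write_count_matrix(mrna, directory / "mrna_counts.tsv")
    write_count_matrix(mir, directory / "mir_counts.tsv")
    write_sample_sheet(mrna.design, directory / "samples.tsv")
    write_interactions(interactions, directory / "interactions.tsv")
    write_annotations(annotations, directory / "annotations.tsv")
    return PipelineConfig(
        mrna_counts=str(directory / "mrna_counts.tsv"),
        mir_counts=str(directory / "mir_counts.tsv"),
        sample_sheet=str(directory / "samples.tsv"),
        interactions=str(directory / "interactions.tsv"),
        annotations=str(directory / "annotations.tsv"),
        outdir=str(directory / "out"),
    )


@pytest.fixture(scope="session")
def default_run(default_dataset, tmp_path_factory):
    """One full pipeline run on the default dataset, shared across tests."""
    base = tmp_path_factory.mktemp("default_run")
    config = write_dataset(default_dataset, base)
    report = run_pipeline(config)
    return config, report, Path(config.outdir), default_dataset[4]


def two_group_matrix(counts: np.ndarray, n_ref: int, n_alt: int) -> CountMatrix:
    """Wrap a plain array as a WT-vs-TG CountMatrix at age 3."""
    n = n_ref + n_alt
    ids = [f"s{i}" for i in range(n)]
    design = pd.DataFrame(
        {"genotype": ["WT"] * n_ref + ["TG"] * n_alt, "age": [3] * n}, index=ids
    )
    features = [f"g{i}" for i in range(counts.shape[0])]
    return CountMatrix(counts, features, ids, design)
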