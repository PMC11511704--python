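import numpy as np
import pandas as pd
import pytest

from dbscreen.matrix import AbundanceMatrix, NormalizedMatrix
from dbscreen.pipeline import PipelineConfig, run_pipeline
from dbscreen.simulate import demo_config, generate_cohort


@pytest.fixture(scope="session")
def demo_cohort():
    """One deterministic study-shaped cohort shared across tests."""
    return generate_cohort(demo_config(seed=7, n_proteins=400))


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """A completed pipeline run on the demo cohort."""
    outdir = tmp_path_factory.mktemp("run") / "demo"
    config = PipelineConfig(
        outdir=str(outdir), cohort=demo_config(n_proteins=400), seed=11
    )
    manifest = run_pipeline(config)
    return outdir, manifest


@pytest.fixture
def toy_matrix():
    """3 proteins x 3 samples with one missing cell and an ACTB anchor."""
    values = pd.DataFrame(
        {
            "S1": [100.0, 10.0, 1.0],
            "S2": [200.0, 20.0, np.nan],
            "S3": [50.0, 5.0, 0.5],
        },
        index=pd.Index(["ACTB", "GENE1", "GENE2"], name="protein"),
    )
    peptides = pd.Series([30, 5, 2], index=values.index, name="peptides")
    return AbundanceMatrix(values, peptides)


def complete_log2(n_proteins=20, n_samples=6, seed=0, prefix="S"):
    """Small complete log2 matrix for transform-level tests."""
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(
        rng.normal(10, 2, (n_proteins, n_samples)),
        index=pd.Index([f"G{i:03d}" for i in range(n_proteins)], name="protein"),
        columns=[f"{prefix}{j + 1}" for j in range(n_samples)],
    )
    return NormalizedMatrix(values, "log2")
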