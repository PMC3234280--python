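import numpy as np
import pandas as pd
import pytest

from tsog import GeneSampleMatrix, generate_cohort
from tsog.config import SimulationConfig, ThresholdConfig


@pytest.fixture(scope="session")
def thresholds():
    return ThresholdConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted cohort reused across test modules."""
    cfg = SimulationConfig(
        n_genes=120, n_tumor=20, n_normal=5, n_chromosomes=4, seed=11
    )
    return generate_cohort(cfg)


def make_matrix(values, genes=None, samples=None, modality="expression", groups=None,
                dialect=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(values.shape[1])]
    data = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)
    return GeneSampleMatrix(modality, data, dict(groups or {}), dialect=dialect)
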