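"""Shared fixtures: small simulated studies reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from pmlsubtypes import (ExpressionDataset, SimulationConfig, generate_multidataset)


@pytest.fixture(scope="session")
def default_study():
    """One default-configuration four-dataset simulation (seed 11)."""
    cfg = SimulationConfig(seed=11)
    datasets, truth = generate_multidataset(cfg)
    return cfg, datasets, truth


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for fast end-to-end style tests."""
    cfg = SimulationConfig(
        seed=7, n_genes=400, module_size=25, n_shared_modules=6,
        n_private_modules_per_dataset=1, progression_module_index=3,
        n_samples_per_dataset={"biopsy": 120, "brush": 60, "tumor": 150, "mouse": 40},
        subtype_pattern={
            "Proliferative": {"M4": 1, "M5": 1, "M6": -1},
            "Inflammatory": {"M1": 1, "M2": 1, "M4": -1, "M5": -1, "M6": -1},
            "Secretory": {"M6": 1, "M1": -1, "M2": -1, "M5": -1},
            "Normal-like": {"M1": 1, "M6": 1, "M3": -1},
        },
    )
    datasets, truth = generate_multidataset(cfg)
    return cfg, datasets, truth


def make_dataset(values: np.ndarray, scale: str = "log",
                 metadata: pd.DataFrame | None = None, name: str = "toy",
                 gene_prefix: str = "g", sample_prefix: str = "s") -> ExpressionDataset:
    """Wrap a bare array in an ExpressionDataset with generated ids."""
    g, n = values.shape
    genes = [f"{gene_prefix}{i + 1}" for i in range(g)]
    samples = [f"{sample_prefix}{j + 1}" for j in range(n)]
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionDataset(df, metadata if metadata is None else
                             metadata.set_axis(samples), scale=scale, name=name)
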