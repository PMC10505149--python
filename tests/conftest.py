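"""Shared fixtures: small planted-marker cohorts generated at test time."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tootrace import SyntheticConfig, generate_cohort

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_cohort():
    """The default study cohort: 4 classes x 60 samples, 500 genes,
    5 markers/class at 8-fold change, seed 1."""
    return generate_cohort(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A 3-class, 30-gene cohort with 3 planted markers per class."""
    return generate_cohort(
        SyntheticConfig(
            n_classes=3,
            samples_per_class=20,
            n_genes=30,
            markers_per_class=3,
            seed=1,
        )
    )


@pytest.fixture(scope="session")
def mini_grid_cohort():
    """A miniature cohort for full-grid runs: few samples, but a gene
    space larger than the largest nominal budget on the grid axis."""
    return generate_cohort(
        SyntheticConfig(
            n_classes=3,
            samples_per_class=15,
            n_genes=1000,
            markers_per_class=3,
            seed=7,
        )
    )


@pytest.fixture()
def tiny_matrix():
    """A hand-sized 4-sample x 3-gene raw expression matrix."""
    return pd.DataFrame(
        [[2.0, 3.0, 5.0], [1.0, 1.0, 2.0], [0.0, 1.0, 3.0], [4.0, 0.5, 0.5]],
        index=["s1", "s2", "s3", "s4"],
        columns=["gA", "gB", "gC"],
    )


def random_expression(rng: np.random.Generator, n_samples: int, n_genes: int) -> pd.DataFrame:
    """Strictly positive random TPM-like matrix."""
    values = rng.lognormal(mean=1.0, sigma=1.0, size=(n_samples, n_genes))
    return pd.DataFrame(
        values,
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"g{j}" for j in range(n_genes)],
    )
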