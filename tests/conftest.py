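import warnings

import numpy as np
import pandas as pd
import pytest

import agetrends as at

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def cohort():
    """A small deterministic cohort shared across tests."""
    return at.simulate_cohort(at.CohortConfig(n_samples=40, seed=7))


@pytest.fixture(scope="session")
def small_counts(cohort):
    truths = at.default_gene_truths(n_genes=60, seed=7)
    counts, truth = at.simulate_counts(cohort, truths, seed=8)
    return counts, truth


@pytest.fixture()
def toy_samples():
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(6)],
            "age": [4.0, 9.0, 14.0, 21.0, 28.0, 33.0],
            "sex": ["F", "M", "F", "M", "F", "M"],
            "batch": ["b1", "b1", "b2", "b2", "b1", "b2"],
        }
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
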