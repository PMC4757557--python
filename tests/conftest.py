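import numpy as np
import pandas as pd
import pytest

from aplnet import CohortSpec, MutationMatrix, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """Six patients x four genes with known carrier structure."""
    df = pd.DataFrame(
        {
            "GA": [1, 1, 1, 0, 0, 0],
            "GB": [1, 1, 0, 0, 0, 0],
            "GC": [0, 0, 0, 1, 1, 0],
            "GD": [0, 0, 0, 0, 0, 0],
        },
        index=[f"P{i}" for i in range(6)],
    )
    return MutationMatrix(df)


@pytest.fixture
def background_cohort():
    """25-patient cohort of independent genes at background rate 0.2."""
    matrix, _ = generate_cohort(
        CohortSpec(n_patients=25, genes=[f"G{i:03d}" for i in range(50)],
                   background_rate=0.2, rng_seed=99)
    )
    return matrix
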