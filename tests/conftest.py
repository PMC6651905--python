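import numpy as np
import pandas as pd
import pytest

from markersurv.io import ClinicalTable, ExpressionMatrix
from markersurv.synthetic import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cohort():
    """A 300-sample cohort with 10 module genes and bimodal marker."""
    return generate_cohort(CohortConfig(n_samples=300, n_genes=30, seed=11))


@pytest.fixture
def tiny_expression():
    return ExpressionMatrix(
        feature_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [0.5, 0.1, 0.9, 0.3]]
        ),
    )


@pytest.fixture
def tiny_clinical():
    return ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "dfs_time": [5.0, 3.0, 8.0, 1.0],
                "dfs_event": [1, 0, 1, 1],
                "stage": ["I", "II", "I", "III"],
            }
        )
    )
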