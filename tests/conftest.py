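import numpy as np
import pandas as pd
import pytest

from immunosig.matrix import CohortAnnotation, ExpressionMatrix, housekeeping_normalize


@pytest.fixture
def small_matrix():
    """3 genes x 2 samples with one housekeeping gene."""
    df = pd.DataFrame(
        {"S1": [10.0, 20.0, 5.0], "S2": [12.0, 18.0, 7.0]},
        index=["GENE_A", "GENE_B", "HK1"],
    )
    return ExpressionMatrix(df, housekeeping=["HK1"])


@pytest.fixture
def cohort_12():
    """A 12-sample annotation: 8 responders, 4 non-responders with PFS."""
    rng = np.random.default_rng(7)
    n = 12
    resp = ["responder"] * 8 + ["non_responder"] * 4
    best = np.concatenate([rng.uniform(-60, -5, 8), rng.uniform(5, 60, 4)])
    pfs = np.concatenate([rng.exponential(13, 8), rng.exponential(3.5, 4)])
    return CohortAnnotation(
        pd.DataFrame(
            {
                "sample_id": [f"S{i:03d}" for i in range(1, n + 1)],
                "response": resp,
                "best_change_pct": np.round(best, 1),
                "pfs_months": np.round(pfs, 3),
                "event": 1,
            }
        )
    )


@pytest.fixture
def normalized_small(small_matrix):
    return housekeeping_normalize(small_matrix)
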