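import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import bsig

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_study():
    """A compact simulated study (fast, planted truth) shared across tests."""
    config = bsig.SimulationConfig(n_genes=400, seed=11)
    return bsig.simulate_expression_study(config), config


@pytest.fixture
def tiny_matrix():
    """3 genes x 8 naive samples (4 HC, 4 SLE) with hand-set values."""
    cols = [f"HC{i}_naive" for i in range(1, 5)] + [f"SLE{i}_naive" for i in range(1, 5)]
    data = pd.DataFrame(
        np.array(
            [
                [1.0, 2.0, 3.0, 4.0, 3.0, 4.0, 5.0, 6.0],
                [5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0],
                [2.0, 2.5, 1.5, 2.0, 1.0, 0.5, 1.5, 1.0],
            ]
        ),
        index=["GA", "GB", "GC"],
        columns=cols,
    )
    sheet = bsig.SampleSheet(
        pd.DataFrame(
            {
                "sample_id": cols,
                "donor_id": [c.split("_")[0] for c in cols],
                "group": ["HC"] * 4 + ["SLE"] * 4,
                "subset": ["naive"] * 8,
            }
        )
    )
    return bsig.ExpressionMatrix(data), sheet
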