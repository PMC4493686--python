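import numpy as np
import pandas as pd
import pytest

from funcnet.expression import ExpressionMatrix


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples with one missing cell."""
    df = pd.DataFrame(
        {
            "S1": [1.0, 5.0, 2.0],
            "S2": [2.0, 5.0, np.nan],
            "S3": [3.0, 5.0, 4.0],
            "S4": [4.0, 5.0, 6.0],
        },
        index=["gA", "gB", "gC"],
    )
    return ExpressionMatrix(df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
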