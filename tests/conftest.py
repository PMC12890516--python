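import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from myofiber.proteome import AbundanceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix():
    """6 proteins x 6 samples (two groups of 3), complete, log2 scale."""
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.normal(25, 2, size=(6, 6)),
        index=[f"p{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(6)],
    )
    groups = pd.Series(
        ["a"] * 3 + ["b"] * 3, index=values.columns
    )
    return AbundanceMatrix(values=values, groups=groups, scale="log2")
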