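import numpy as np
import pandas as pd
import pytest

from betanull.community_data import CommunityMatrix


@pytest.fixture
def small_cm():
    """4 samples x 5 species with group metadata."""
    counts = pd.DataFrame(
        [
            [3, 0, 1, 0, 2],
            [0, 2, 1, 0, 0],
            [1, 1, 0, 4, 0],
            [0, 0, 2, 1, 1],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=["spA", "spB", "spC", "spD", "spE"],
    )
    meta = pd.DataFrame(
        {"group": ["g1", "g1", "g2", "g2"]}, index=counts.index
    )
    return CommunityMatrix(counts, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
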