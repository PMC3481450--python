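import itertools

import numpy as np
import pandas as pd
import pytest

from modnet.io_prep import ExpressionMatrix, ProbeTable

ALL_SIGN_TRIPLES = list(itertools.product("+-0", repeat=3))


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture
def small_matrix():
    """3 genes x 5 samples, hand-written values."""
    data = pd.DataFrame(
        [
            [0.1, 0.5, -0.2, 1.0, 0.3],
            [1.2, -0.4, 0.0, 0.8, -1.1],
            [-0.3, 0.2, 0.9, -0.6, 0.4],
        ],
        index=["gA", "gB", "gC"],
        columns=["0", "1", "2", "4", "8"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def probe_table(rng):
    """12 probes over 6 samples mapping onto 5 genes, with absent calls."""
    probes = [f"p{i:02d}" for i in range(12)]
    genes = ["g1", "g1", "g2", "g2", "g2", "g3", "g3", "g4", "g4", "g4", "g5", "g5"]
    data = pd.DataFrame(
        rng.normal(size=(12, 6)),
        index=probes,
        columns=[str(h) for h in (0, 1, 2, 4, 8, 12)],
    )
    flags = pd.DataFrame(False, index=data.index, columns=data.columns)
    flags.loc["p03"] = True          # absent everywhere -> dropped
    flags.loc["p07", "0":"4"] = True  # absent in some samples only -> kept
    return ProbeTable(data, dict(zip(probes, genes)), flags)
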