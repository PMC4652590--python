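import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from gslhc.core_io import ExpressionMatrix, GeneSet, GeneSetCollection


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def small_matrix():
    """4 genes x 3 instances with distinct values (no rank ties)."""
    return ExpressionMatrix(
        row_ids=("g1", "g2", "g3", "g4"),
        col_ids=("i1", "i2", "i3"),
        values=np.array(
            [
                [2.0, -1.0, 0.3],
                [1.0, 2.5, -0.2],
                [-0.5, 0.5, 1.9],
                [0.1, -2.0, -1.1],
            ]
        ),
        value_kind="log_ratio",
    )


@pytest.fixture()
def small_collection():
    return GeneSetCollection(
        (
            GeneSet("S1", "C2", frozenset({"g1", "g2"})),
            GeneSet("S2", "C3", frozenset({"g3", "g4"})),
            GeneSet("S3", "C5", frozenset({"g1", "g3", "g4"})),
        )
    )
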