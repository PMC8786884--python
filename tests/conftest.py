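import numpy as np
import pandas as pd
import pytest

from cocoanet.correlation import CorrelationMatrix
from cocoanet.lcms_io import make_peak_table


@pytest.fixture
def small_table():
    """6 samples, 2 stages x 2 origins, 5 compounds, fixed values."""
    rng = np.random.default_rng(42)
    return make_peak_table(
        rng.uniform(0.1, 10.0, size=(6, 5)),
        stage=["unfermented", "unfermented", "unfermented",
               "fermented", "fermented", "fermented"],
        origin=["Ghana", "Ghana", "Brazil", "Ghana", "Brazil", "Brazil"],
    )


def matrix_from_array(values, ids=None, method="spearman"):
    """Wrap a symmetric array (diagonal forced to 1) as a CorrelationMatrix."""
    arr = np.asarray(values, dtype=float)
    np.fill_diagonal(arr, 1.0)
    if ids is None:
        ids = [f"s{k}" for k in range(arr.shape[0])]
    frame = pd.DataFrame(arr, index=ids, columns=ids)
    return CorrelationMatrix(values=frame, method=method)


@pytest.fixture
def four_node_matrix():
    """A1,A2,B1,B2 with fixed pairwise correlations for hand-counted toys.

    Positive pairs: (A1,A2)=0.9, (A1,B1)=0.6, (B1,B2)=0.8, (A2,B2)=0.4;
    (A1,B2)=-0.2 and (A2,B1)=0.0 never form edges.
    """
    ids = ["A1", "A2", "B1", "B2"]
    arr = np.array(
        [
            [1.0, 0.9, 0.6, -0.2],
            [0.9, 1.0, 0.0, 0.4],
            [0.6, 0.0, 1.0, 0.8],
            [-0.2, 0.4, 0.8, 1.0],
        ]
    )
    return matrix_from_array(arr, ids)


@pytest.fixture
def four_node_labels():
    return pd.Series(
        {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}, name="labels"
    )
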