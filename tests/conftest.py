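import numpy as np
import pandas as pd
import pytest

from stressomics.types import de_table


@pytest.fixture
def toy_de():
    """Six-feature DE table exercising both flag thresholds and directions."""
    logfc = np.array([1.0, -1.0, 0.1, 0.5, -0.5, np.log2(1.2)])
    p = np.array([0.01, 0.02, 0.001, 0.05, 0.2, 0.01])
    return de_table(
        [f"g{i}" for i in range(6)], logfc, logfc * 3, p, np.minimum(p * 6, 1),
        "susceptible-vs-control", "toy",
    )


@pytest.fixture
def ranked_six():
    """Six-gene ranked list with simple metrics for hand-computed ES checks."""
    return pd.Series(
        [3.0, 2.0, 1.0, -1.0, -2.0, -3.0],
        index=["a", "b", "c", "d", "e", "f"],
        name="metric",
    )


def make_de(features, logfc, p, contrast="susceptible-vs-control", dataset="ds"):
    logfc = np.asarray(logfc, dtype=float)
    p = np.asarray(p, dtype=float)
    from stressomics.diffexpr import bh_adjust

    return de_table(features, logfc, logfc, p, bh_adjust(p), contrast, dataset)
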