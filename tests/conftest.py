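import numpy as np
import pandas as pd
import pytest

from modscape.io import ExpressionMatrix
from modscape.synthio import SimParams, simulate_experiment


@pytest.fixture(scope="session")
def planted_experiment():
    """5000-gene 4x3 design with planted effects at the default conditions."""
    params = SimParams(n_genes=5000, seed=101)
    matrix, truth = simulate_experiment(params)
    return params, matrix, truth


@pytest.fixture(scope="session")
def null_experiment():
    """No planted effects anywhere: pure noise around per-gene baselines."""
    params = SimParams(
        n_genes=5000,
        effect_fraction_per_group={"MMF": 0.0, "DRF": 0.0, "IDMF": 0.0},
        seed=202,
    )
    matrix, truth = simulate_experiment(params)
    return params, matrix, truth


def make_de_table(log2fc, genes=None, detected=None, p=None):
    """Assemble a minimal DE table for set-statistics tests."""
    log2fc = np.asarray(log2fc, dtype=float)
    n = log2fc.size
    genes = genes if genes is not None else [f"G{i:05d}" for i in range(n)]
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "fc": np.exp2(log2fc),
            "p": np.ones(n) if p is None else np.asarray(p, dtype=float),
            "detected": np.ones(n, dtype=bool) if detected is None else detected,
        },
        index=pd.Index(genes, name="gene"),
    )


@pytest.fixture
def de_table_factory():
    return make_de_table


@pytest.fixture
def toy_matrix():
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [2.0, 2.0, 2.0, 2.0]],
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data, {"s1": "CTL", "s2": "CTL", "s3": "TRT", "s4": "TRT"})
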