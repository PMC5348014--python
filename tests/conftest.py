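import numpy as np
import pandas as pd
import pytest

from rewirenet.io import ExpressionMatrix


def make_expression(values, genes=None, samples=None, conditions=None,
                    replicates=None):
    """Small helper to build an ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, float)
    n_g, n_s = values.shape
    genes = genes or [f"G{i:02d}" for i in range(n_g)]
    samples = samples or [f"S{i}" for i in range(n_s)]
    conditions = conditions or ["PB"] * n_s
    replicates = replicates or list(range(1, n_s + 1))
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(
        df,
        pd.Series(conditions, index=samples),
        pd.Series(replicates, index=samples),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def four_condition_expr():
    """2 replicates of each of PB/PT/RB/RT for three genes."""
    samples = ["PB_1", "PB_2", "PT_1", "PT_2", "RB_1", "RB_2", "RT_1", "RT_2"]
    conditions = [s.split("_")[0] for s in samples]
    replicates = [int(s.split("_")[1]) for s in samples]
    values = [
        [2, 2, 4, 4, 1, 1, 1, 1],   # up under treatment, down in resistance
        [5, 5, 5, 5, 5, 5, 5, 5],   # flat
        [4, 4, 2, 2, 8, 8, 8, 8],   # down under treatment, up in resistance
    ]
    return make_expression(values, genes=["DYS_UP", "FLAT", "DYS_DOWN"],
                           samples=samples, conditions=conditions,
                           replicates=replicates)
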