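import numpy as np
import pandas as pd
import pytest

from qtlgsa.io_formats import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def small_expr():
    """3 genes x 4 samples, two strains with duplicate arrays."""
    values = pd.DataFrame(
        [[8.0, 8.2, 7.1, 7.3], [5.0, 5.4, 6.0, 6.2], [9.9, 9.7, 9.8, 9.6]],
        index=["g1", "g2", "g3"],
        columns=["hi_1", "hi_2", "lo_1", "lo_2"],
    )
    groups = {"hi_1": "high", "hi_2": "high", "lo_1": "low", "lo_2": "low"}
    return ExpressionMatrix(values, groups)


def random_expression(rng, n_features=20, n_samples=6, n_groups=2, prefix="f"):
    values = pd.DataFrame(
        rng.normal(8, 2, size=(n_features, n_samples)),
        index=[f"{prefix}{i:03d}" for i in range(n_features)],
        columns=[f"s{j:02d}" for j in range(n_samples)],
    )
    groups = {c: f"grp{j % n_groups}" for j, c in enumerate(values.columns)}
    return ExpressionMatrix(values, groups)
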