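import numpy as np
import pandas as pd
import pytest

import immstrat as im
from immstrat.io import ExpressionMatrix


@pytest.fixture(scope="session")
def default_cohort() -> im.SyntheticCohort:
    """One default-condition cohort shared by read-only tests."""
    return im.generate_cohort(im.SyntheticConfig(seed=101))


@pytest.fixture(scope="session")
def small_cohort() -> im.SyntheticCohort:
    """A reduced cohort (fewer samples/genes) for fast pipeline checks."""
    config = im.SyntheticConfig(
        n_samples=150, n_panel_genes=200, n_background_genes=300, seed=7
    )
    return im.generate_cohort(config)


@pytest.fixture()
def tiny_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
            index=["g1", "g2", "g3"],
            columns=["s1", "s2"],
        )
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
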