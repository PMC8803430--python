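import numpy as np
import pandas as pd
import pytest

from tacesig import io
from tacesig.simulate import generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """40-sample cohort, 200 genes, 20 planted DEGs at effect 2."""
    return generate_cohort(20, 20, 200, 20, 2.0, seed=101)


@pytest.fixture(scope="session")
def dev_cohort():
    """Development-sized cohort: 81 responders / 66 nonresponders,
    400 genes with 10 strongly informative planted genes at effect 2."""
    return generate_cohort(81, 66, 400, 10, 2.0, seed=7)


@pytest.fixture(scope="session")
def dev_zscored(dev_cohort):
    m, labels, truth = dev_cohort
    return io.zscore(m), labels, truth


@pytest.fixture()
def tiny_matrix():
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3"],
    )
    return io.ExpressionMatrix(df)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
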