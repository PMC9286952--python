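import numpy as np
import pytest

from iaoadbn import escc_spec, generate_blobs, generate_cohort
from iaoadbn.mrmr import FeatureTable


@pytest.fixture(scope="session")
def escc_cohort():
    """Default-size synthetic cohort (298 patients, 147 positives)."""
    return generate_cohort(escc_spec(n=298, seed=0))


@pytest.fixture(scope="session")
def blobs_separable():
    """Well-separated 2-D two-cluster set."""
    return generate_blobs(300, 2, 10.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_table(rng):
    """Six-feature table with a label copy, a duplicate, and noise columns."""
    n = 200
    label = (rng.random(n) < 0.5).astype(int)
    f1 = label.astype(float)
    f2 = f1.copy()
    noise = rng.random((n, 4))
    values = np.column_stack([f1, f2, noise])
    return FeatureTable(values, ["f1", "f2", "n1", "n2", "n3", "n4"], label)
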