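import numpy as np
import pandas as pd
import pytest

from metabscreen.io_prep import table_from_cohort, pool_controls
from metabscreen.simulate import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort with strong planted effects: fast to regenerate,
    hard to misclassify."""
    spec = CohortSpec(
        n_hs=15, n_bcrt=15, n_crc=30, n_features=40, n_differential=8,
        log2fc_range=(1.5, 2.5), missing_rate=0.02, batch_size=20, seed=42,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return table_from_cohort(small_cohort)


@pytest.fixture(scope="session")
def study_labels(small_cohort):
    meta = small_cohort.metadata
    study = meta[meta["qc_role"] == "study"]
    return pool_controls(study.set_index("sample_id")["group"])


def planted_matrix(n_per_class=40, p=20, informative=(0, 1), shift=2.0, seed=0):
    """Autoscaled-style matrix with a planted mean shift on a few columns."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, p))
    y = np.array(["CTRL"] * n_per_class + ["CRC"] * n_per_class)
    for j in informative:
        X[n_per_class:, j] += shift
    cols = [f"F{j:02d}" for j in range(p)]
    return pd.DataFrame(X, columns=cols), pd.Series(y)
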