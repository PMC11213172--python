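import numpy as np
import pandas as pd
import pytest

from methylsieve import MethylationDataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_dataset(values: np.ndarray, scale: str = "percent",
                 groups=("control", "positive"), batches=None,
                 probe_prefix: str = "p") -> MethylationDataset:
    """Small helper: n x m matrix with the first half of samples in
    groups[0], the rest in groups[1]."""
    n, m = values.shape
    sample_ids = [f"s{j:02d}" for j in range(m)]
    labels = [groups[0]] * (m // 2) + [groups[1]] * (m - m // 2)
    df = pd.DataFrame(values, index=[f"{probe_prefix}{i:03d}" for i in range(n)],
                      columns=sample_ids)
    g = pd.Series(labels, index=sample_ids)
    b = pd.Series(batches, index=sample_ids) if batches is not None else None
    return MethylationDataset(df, scale, g, b)


@pytest.fixture
def two_group_separable() -> MethylationDataset:
    """6 probes x 20 samples, 3 strongly separating probes on M scale."""
    rng = np.random.default_rng(7)
    n_per = 10
    X = rng.normal(0.0, 0.5, size=(6, 2 * n_per))
    for i in range(3):
        X[i, n_per:] += 4.0
    return make_dataset(X, scale="mvalue")
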