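import numpy as np
import pytest

from multigrn.datasets import ExpressionDataset, SampleMetadata


@pytest.fixture
def steady_dataset():
    """3 genes x 4 steady-state samples with simple known values."""
    genes = ["gA", "gB", "gC"]
    samples = ["s1", "s2", "s3", "s4"]
    values = np.arange(12, dtype=float).reshape(3, 4)
    return ExpressionDataset("demo", genes, samples, values,
                             SampleMetadata.steady_state(samples))


@pytest.fixture
def timeseries_metadata():
    """One series s1 -> s2 -> s3 (t = 0, 30, 60) plus steady-state s4."""
    samples = ["s1", "s2", "s3", "s4"]
    return SampleMetadata(
        samples,
        np.array([True, True, True, False]),
        np.array([True, False, False, False]),
        [None, "s1", "s2", None],
        np.array([np.nan, 30.0, 30.0, np.nan]))


def orthogonal_design(p: int, n: int, rng) -> np.ndarray:
    """Rows A_k with <A_k, A_l> = n * delta_kl (standardized-orthogonal)."""
    q, _ = np.linalg.qr(rng.standard_normal((n, p)))
    return np.sqrt(n) * q.T


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
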