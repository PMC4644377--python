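import numpy as np
import pytest

from chromsig.intervals import GenomicInterval, PeakSet


@pytest.fixture
def toy_peaksets():
    """Three samples with a shared region and sample-specific peaks."""
    a = PeakSet("A", [GenomicInterval("chr1", 100, 200),
                      GenomicInterval("chr1", 1000, 1100)])
    b = PeakSet("B", [GenomicInterval("chr1", 150, 250),
                      GenomicInterval("chr2", 500, 700)])
    c = PeakSet("C", [GenomicInterval("chr1", 400, 500),
                      GenomicInterval("chr1", 1050, 1150)])
    return [a, b, c]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def simulate_survival(n, beta, censoring_scale, seed, p=None):
    """Exponential-hazard survival data for a coefficient vector."""
    rng = np.random.default_rng(seed)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    p = p if p is not None else beta.size
    X = rng.standard_normal((n, p))
    lp = X[:, : beta.size] @ beta
    t_event = rng.exponential(np.exp(-lp))
    t_cens = rng.exponential(censoring_scale, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return X, np.maximum(time, 1e-9), event
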