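import numpy as np
import pytest

import topohic as th
from topohic.simulate import PrecatenaneParams, TerminusParams, WingParams


@pytest.fixture
def small_genome():
    return th.Genome("toy", 12, circular=True, sequence="AACCGGTTCCGG")


@pytest.fixture
def sim_params_small():
    """A 500-kb circular genome with all feature geometry scaled down."""
    return th.SimParams(
        genome_length=500_000, bin_size=5_000, dif=250_000, oriC=20_000,
        terminus=TerminusParams(span=(200_000, 300_000)),
        precatenane=PrecatenaneParams(beta=0.4, d_lo=20_000, d_hi=60_000),
        wings=WingParams(alpha=1.5, anchor_width=25_000, guard=100_000),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_symmetric_counts(rng, n, scale=50.0):
    """Random symmetric nonnegative count matrix with positive marginals."""
    a = rng.poisson(scale, size=(n, n)).astype(float)
    m = np.triu(a) + np.triu(a, 1).T
    m += np.diag(rng.poisson(scale, size=n).astype(float))
    return m
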