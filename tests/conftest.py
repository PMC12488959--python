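import math

import numpy as np
import pytest

from upsit_norms import load_norms


def sample_with_min_mass(rng, n):
    """Random integer score sample in which every distinct score has >= 2% mass.

    The strict mid-rank oracle bound (100/n + 1) for constructed tables is a
    theorem exactly when every observed score's quantile plateau spans at
    least two integer grid percents; this sampler guarantees that regime.
    Scores rarer than that take the between-percentiles interpolation, whose
    error is bounded by the neighbouring scores' spread instead.
    """
    min_c = max(1, math.ceil(0.02 * n))
    k = int(rng.integers(3, min(41, n // min_c) + 1))
    scores = rng.choice(41, size=k, replace=False)
    extra = rng.multinomial(n - k * min_c, rng.dirichlet(np.ones(k)))
    return np.repeat(scores, min_c + extra)


@pytest.fixture(scope="session")
def published_norms():
    """The packaged revised-test (2020) norm set."""
    return load_norms("upsit_r_2020")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
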