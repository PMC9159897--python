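import warnings

import numpy as np
import pytest

from rehabspc import ShortSeriesWarning, reference_tables


@pytest.fixture(autouse=True)
def _silence_short_series_warning():
    # many unit fixtures use deliberately short series
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ShortSeriesWarning)
        yield


@pytest.fixture(scope="session")
def ref_tables():
    return reference_tables()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


def random_2x2(rng, n_max=100):
    """A random non-degenerate 2x2 table of counts."""
    while True:
        n = int(rng.integers(4, n_max + 1))
        cells = rng.multinomial(n, rng.dirichlet(np.ones(4))).reshape(2, 2)
        if cells.sum(axis=0).min() > 0 and cells.sum(axis=1).min() > 0:
            return cells
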