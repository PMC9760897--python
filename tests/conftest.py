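import numpy as np
import pytest

from edmchaos.edm_core import EmbeddedBlock
from edmchaos.io_model import ReplicateSeries, SpeciesInfo


@pytest.fixture
def two_species():
    return (
        SpeciesInfo("prey", "prey", "individuals"),
        SpeciesInfo("predator", "predator", "individuals"),
    )


@pytest.fixture
def make_series(two_species):
    """Factory for a two-species ReplicateSeries on a regular grid."""

    def _make(prey, predator, *, rid="r1", step=1.0):
        prey = np.asarray(prey, dtype=float)
        predator = np.asarray(predator, dtype=float)
        return ReplicateSeries(
            replicate_id=rid,
            species=two_species,
            times=step * np.arange(len(prey)),
            abundances=np.column_stack([prey, predator]),
        )

    return _make


@pytest.fixture
def make_univariate():
    """Factory for a single-species series from a 1-D array."""

    def _make(x, *, rid="u1"):
        x = np.asarray(x, dtype=float)
        return ReplicateSeries(
            replicate_id=rid,
            species=(SpeciesInfo("x", "other", "a.u."),),
            times=np.arange(len(x), dtype=float),
            abundances=x[:, None],
        )

    return _make


def random_block(rng, n, dim, *, n_queries=None, times_offset=0.0):
    """A random embedded block (library) and optionally a query block."""
    lib = EmbeddedBlock(
        rows=rng.uniform(-1, 1, (n, dim)),
        targets=rng.uniform(-1, 1, n),
        row_times=np.arange(n, dtype=float),
    )
    if n_queries is None:
        return lib
    q = EmbeddedBlock(
        rows=rng.uniform(-1, 1, (n_queries, dim)),
        targets=rng.uniform(-1, 1, n_queries),
        row_times=times_offset + np.arange(n_queries, dtype=float),
    )
    return lib, q
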