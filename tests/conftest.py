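import warnings

import numpy as np
import pytest

import retrodyn as rd

#: Master seed for every stochastic fixture in the suite.
MASTER_SEED = 20211109


@pytest.fixture(scope="session")
def basic_params():
    return rd.default_parameters("basic")


@pytest.fixture(scope="session")
def ribosome_params():
    return rd.default_parameters("ribosome")


@pytest.fixture(scope="session")
def small_basic_ensemble(basic_params):
    """60 basic-model cells over 300 generations (buffer 100)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rd.simulate_population(
            basic_params, 60, 300, 100, [250, 250, 100], MASTER_SEED
        )


def make_toy_ensemble(s_extinction, n_generations=10, buffer=0, params=None):
    """Synthetic ensemble with prescribed Alu extinction generations.

    ``s_extinction`` maps each cell to its first S=0 generation (None for a
    cell whose S survives).  L and R_L are held at 1 so L1 never dies.
    """
    params = params or rd.default_parameters("basic")
    n = len(s_extinction)
    counts = np.ones((n, n_generations + 1, 3), dtype=np.int64)
    for c, ext in enumerate(s_extinction):
        if ext is not None:
            counts[c, ext:, 1] = 0
    return rd.PopulationEnsemble(
        counts=counts,
        params=params,
        buffer=buffer,
        master_seed=None,
        cell_seeds=None,
        cell_ids=np.arange(n),
        n_requested=n,
        n_excluded=0,
    )
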