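import numpy as np
import pytest

import planktospec as pk


@pytest.fixture(scope="session")
def gp():
    """Canonical growth constants (a(N) saturating at 1.4, half-sat at N=1)."""
    return pk.canonical_growth()


@pytest.fixture(scope="session")
def ds():
    """Canonical sloppy size control division spec."""
    return pk.canonical_division()


@pytest.fixture(scope="session")
def ds_ideal():
    return pk.canonical_idealised_division()


@pytest.fixture(scope="session")
def m01():
    """Constant background mortality m0 = 0.1."""
    return pk.canonical_mortality(0.1)


@pytest.fixture(scope="session")
def chemostat():
    return pk.canonical_chemostat()


@pytest.fixture(scope="session")
def coupled_ideal(gp, ds_ideal, chemostat):
    """Coupled phyto-zoo steady state, idealised division (shared: ~1 s)."""
    return pk.solve_coupled_steady_state(pk.canonical_predation(), ds_ideal,
                                         gp, chemostat)


@pytest.fixture(scope="session")
def coupled_general(gp, ds, chemostat):
    """Coupled phyto-zoo steady state, sloppy division (shared: ~2 s)."""
    return pk.solve_coupled_steady_state(pk.canonical_predation(), ds,
                                         gp, chemostat)


@pytest.fixture(scope="session")
def cohort_initial():
    """Gaussian cohort at x = 0.5, width 0.05, unit total number."""
    def make(grid):
        x = grid.centers
        p = np.exp(-(x - 0.5) ** 2 / (2 * 0.05 ** 2))
        return p / np.trapezoid(p, x)
    return make
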