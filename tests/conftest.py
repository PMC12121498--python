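"""Shared fixtures: analytic models, a fitted-surface playground, tables."""

import numpy as np
import pytest

from pipvib import model_systems as ms
from pipvib import normal_modes as nm
from pipvib.interface.tables import load_fixture_tables

TRIATOMIC_MASSES_AMU = [15.99491461956, 1.00782503207, 1.00782503207]


@pytest.fixture(scope="session")
def morse():
    """1D Morse in mass-scaled coordinates, omega = 0.01 a.u. (~2195 cm^-1)."""
    return ms.make_morse_1d(D=0.057, a=0.01 / np.sqrt(2 * 0.057), mu=1.0)


@pytest.fixture(scope="session")
def fermi():
    """Default 2-mode stretch-bend model with 2:1 Fermi coupling."""
    return ms.make_coupled_morse_fermi()


@pytest.fixture(scope="session")
def three_mode():
    """Morse stretch + two cubic-coupled harmonic bends (pairwise couplings)."""
    return ms.MorseBendBend()


@pytest.fixture(scope="session")
def triatomic():
    return ms.make_triatomic()


@pytest.fixture(scope="session")
def triatomic_modes(triatomic):
    geom = triatomic.reference_geometry().ravel()
    hess = nm.hessian(triatomic, geom)
    return nm.harmonic_analysis(hess, TRIATOMIC_MASSES_AMU, geom)


@pytest.fixture(scope="session")
def random_surface():
    """Seeded random PIP surface: 4 atoms, partition 22, order 3."""
    return ms.make_random_pip_surface(4, "22", 3, coefficient_scale=0.01, seed=7)


@pytest.fixture(scope="session")
def center4():
    rng = np.random.default_rng(0)
    return rng.normal(0, 1, (4, 3)) * 1.5 + np.arange(4)[:, None]


@pytest.fixture(scope="session")
def training_set(random_surface, center4):
    return ms.sample_training_set(random_surface, center4,
                                  displacement_sigma=0.1, n_points=120,
                                  noise_sigma=0.0, seed=3,
                                  elements=("C", "C", "H", "H"))


@pytest.fixture(scope="session")
def tables():
    return load_fixture_tables()
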