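"""Shared fixtures: thermodynamic contexts and reusable sampled data.

Expensive Langevin/WHAM inputs are session-scoped so several tests can share
one ladder.
"""

import numpy as np
import pytest

import alchemycle as ac

#: temperature at which kT = 1 kcal/mol exactly, for unit-free toy checks
T_UNIT = 1.0 / ac.KB_KCAL_MOL_K


@pytest.fixture(scope="session")
def ctx300():
    return ac.ThermoContext(temperature=300.0)


@pytest.fixture(scope="session")
def ctx_exp():
    return ac.ThermoContext(temperature=298.15)


@pytest.fixture(scope="session")
def ctx_unit():
    """Context with kT = 1 kcal/mol."""
    return ac.ThermoContext(temperature=T_UNIT)


@pytest.fixture(scope="session")
def harmonic_toy():
    """The k0=1 → k1=4 harmonic alchemy toy; exact ΔG = 0.5·ln 4 at kT = 1."""
    return ac.HarmonicAlchemySpec(k0=1.0, k1=4.0, seed=1234)


@pytest.fixture(scope="session")
def gaussian_well_ladder(ctx300):
    """Umbrella ladder over a Gaussian binding well, with its generating potential."""
    pot = ac.BindingPotential1D("gaussian_well", depth=-6.0, width=1.5)
    lang = ac.LangevinParams(diffusion=50.0, timestep=1e-4, n_steps=20_000, seed=77)
    windows = ac.run_umbrella_protocol(pot, ac.PullProtocol(), lang, ctx300, margin=1.0)
    return pot, windows


@pytest.fixture(scope="session")
def gaussian_well_pmf(gaussian_well_ladder, ctx300):
    pot, windows = gaussian_well_ladder
    return pot, ac.wham_solve(windows, ctx300)
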