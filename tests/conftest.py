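import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spax

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lib():
    return spax.reference_library()


@pytest.fixture(scope="session")
def grid():
    return spax.acquisition_grid()


@pytest.fixture(scope="session")
def small_phantom(lib):
    """64x128 fibrosis phantom with 2%-of-peak noise and its simulation."""
    spec = spax.fibrosis_phantom((64, 128), seed=7)
    stack, truth = spax.simulate_stack(spec, lib)
    return spec, stack, truth


@pytest.fixture(scope="session")
def noiseless_phantom(lib):
    spec = spax.fibrosis_phantom((64, 128), seed=7, noise_frac_of_peak=0.0)
    stack, truth = spax.simulate_stack(spec, lib)
    return spec, stack, truth


def uniform_spec(grid, lib, name="hbo2", shape=(4, 6), value=1.0, **kw):
    """Homogeneous single-chromophore phantom spec."""
    conc = {name: np.full(shape, value)}
    mu0 = spax.Spectrum(grid, np.zeros(len(grid)), "mu0")
    kw.setdefault("mu_eff", mu0)
    return spax.PhantomSpec(shape=shape, concentrations=conc, **kw)
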