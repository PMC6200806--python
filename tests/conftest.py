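import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phasemammo as pm

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

PITCH = 0.071  # mm


@pytest.fixture(scope="session")
def gammex():
    return pm.gammex_like_phantom()


@pytest.fixture(scope="session")
def mono_spectrum():
    """Default monochromatic 25 keV sample-plane spectrum."""
    source = pm.SourceConfig(pm.electron_energy_for(25.0, 1.2), 1.2)
    rate = pm.sample_plane_fluence_rate(source, 2.4e10)
    return pm.make_spectrum(25.0, 0.0, rate, 1)


@pytest.fixture(scope="session")
def interferometer():
    return pm.InterferometerConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def standin_dgn(value_by_thickness=None, constant=0.6):
    """Tiny synthetic DgN table for closed-form oracles.

    By default constant everywhere; ``value_by_thickness`` maps grid
    thicknesses to values for thickness-correction tests.
    """
    e = np.array([10.0, 50.0])
    t = np.array([2.0, 4.0, 5.0, 8.0])
    g = np.array([0.0, 1.0])
    v = np.full((e.size, t.size, g.size), constant)
    if value_by_thickness:
        for i, ti in enumerate(t):
            if ti in value_by_thickness:
                v[:, i, :] = value_by_thickness[ti]
    return pm.DgNTable(e, t, g, v)


def standin_mu_en(constant=0.1566):
    """Flat (mu_en/rho)_air stand-in table (m^2/kg)."""
    return pm.MuEnTable(np.array([1.0, 100.0]), np.array([constant, constant]))
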