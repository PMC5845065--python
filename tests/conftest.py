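"""Shared fixtures: reference materials, geometries and pre-computed
simulation fields (session-scoped, since the method-of-lines runs are
the expensive part of the suite)."""

import pytest

import viscopulse as vp

# tube used throughout the formula-validation runs: L = 10 m, and a
# radius/thickness/density combination giving the stated wave speeds
FIG_GEOM = vp.TubeGeometry(r=0.004, e=0.0005, L=10.0, rho=1000.0)
_SCALE = FIG_GEOM.e / (2.0 * FIG_GEOM.rho * FIG_GEOM.r)  # c^2 per Pa

#: moduli such that c0 = 4 m/s, c1 = 3 m/s (hence c = 5 m/s)
E0_C4 = 16.0 / _SCALE
E1_C3 = 9.0 / _SCALE
#: modulus such that the Maxwell speed is 5 m/s
E1_C5 = 25.0 / _SCALE

PDMS = vp.ZenerMaterial(E0=2.114e6, E1=0.9365e6, tau=0.2611)
PDMS_MAXWELL = vp.MaxwellMaterial(E1=2.827e6, tau=13.38)
CAROTID = vp.TubeGeometry(r=0.004, e=0.0005, L=1.0, rho=1000.0)

PULSE = vp.PulseSpec(p_max=1.0, T=0.2)


@pytest.fixture(scope="session")
def fig_geom():
    return FIG_GEOM


@pytest.fixture(scope="session")
def pdms():
    return PDMS


@pytest.fixture(scope="session")
def carotid():
    return CAROTID


@pytest.fixture(scope="session")
def pulse():
    return PULSE


def zener_c43(tau):
    """Zener material with c0 = 4, c1 = 3 m/s on the reference tube."""
    return vp.ZenerMaterial(E0=E0_C4, E1=E1_C3, tau=tau)


def maxwell_c5(tau):
    """Maxwell material with c = 5 m/s on the reference tube."""
    return vp.MaxwellMaterial(E1=E1_C5, tau=tau)


@pytest.fixture(scope="session")
def underdamped_maxwell_field():
    """All-modes-underdamped Maxwell run: tau = 2 s, c = 5 m/s."""
    return vp.simulate_maxwell(maxwell_c5(2.0), FIG_GEOM, PULSE,
                               vp.SimulationGrid(N=512))


@pytest.fixture(scope="session")
def underdamped_maxwell_field_fine():
    return vp.simulate_maxwell(maxwell_c5(2.0), FIG_GEOM, PULSE,
                               vp.SimulationGrid(N=1024))


@pytest.fixture(scope="session")
def slow_zener_field():
    """Zener run in the valid-envelope regime: tau = 2 s, c0=4, c1=3."""
    return vp.simulate_zener(zener_c43(2.0), FIG_GEOM, PULSE,
                             vp.SimulationGrid(N=512))


@pytest.fixture(scope="session")
def fast_zener_field():
    """Zener run far outside the envelope regime: tau = 0.05 s."""
    return vp.simulate_zener(zener_c43(0.05), FIG_GEOM, PULSE,
                             vp.SimulationGrid(N=512))


@pytest.fixture(scope="session")
def noiseless_pdms_record():
    return vp.generate_synthetic_record(PDMS)


@pytest.fixture(scope="session")
def noiseless_pdms_zener_fit(noiseless_pdms_record):
    return vp.fit_material(noiseless_pdms_record, "zener",
                           init=(1e6, 1e6, 0.1), restarts=2, seed=0)
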