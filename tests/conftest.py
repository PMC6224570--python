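import math

import numpy as np
import pytest

from polhop import Azo2D, CavityMode, Curve1D
from polhop.units import HARTREE_PER_EV


@pytest.fixture(scope="session")
def azo():
    return Azo2D()


@pytest.fixture(scope="session")
def cavity_13():
    """The reference strong-coupling cavity: 1.3 eV, g = 0.010 au, z-pol."""
    return CavityMode.from_ev(1.3, 0.010)


@pytest.fixture(scope="session")
def cavity_off():
    """Zero-coupling cavity (far off-resonant so photon states are inert)."""
    return CavityMode(omega=5.0 * HARTREE_PER_EV, g=0.0,
                      lam=np.array([0.0, 0.0, 1.0]))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def resonant_theta(model, cavity, alpha):
    """Torsion where E1 - E0 = omega at fixed bend (uncoupled seam)."""
    from scipy.optimize import brentq

    def f(th):
        d = model.evaluate(np.array([th, alpha]))
        return d.e1 - d.e0 - cavity.omega

    return brentq(f, 0.55 * math.pi, math.pi - 1e-9, xtol=1e-14)


def make_lz_model(slope=0.03, coupling=0.004, mass=2000.0):
    """Symmetric linear-crossing model for Landau-Zener checks."""
    from polhop.units import EV_PER_HARTREE

    return Curve1D(
        c11_ev=0.0, a11_ev=slope * EV_PER_HARTREE, x11=0.0, w11=1.0,
        c22_ev=0.0, a22_ev=-slope * EV_PER_HARTREE, x22=0.0, w22=1.0,
        c12_ev=coupling * EV_PER_HARTREE, mu0_au=0.0, mass=mass,
    )


def lz_diabatic_survival(slope, coupling, velocity):
    """Closed-form Landau-Zener probability of staying on the diabat."""
    return math.exp(
        -2.0 * math.pi * coupling**2 / (velocity * (2.0 * slope))
    )


def make_scatter_model(mass=1000.0):
    """1-D polaritonic validation model: flat ground diabat and a
    tanh-descending excited diabat (no electronic coupling), constant
    out-of-plane transition dipole."""
    return Curve1D(
        c11_ev=0.0, a11_ev=0.0,
        c22_ev=2.0, a22_ev=-1.5, x22=0.0, w22=1.0,
        c12_ev=0.0, mu0_au=1.0, mass=mass,
    )


def random_geometries(model, rng, n, theta_range=(0.2, math.pi - 0.2),
                      alpha_range=(1.6, 2.6)):
    """Random azo2d geometries away from the planarity singular lines."""
    out = []
    for _ in range(n):
        th = rng.uniform(*theta_range) * rng.choice([-1.0, 1.0])
        al = rng.uniform(*alpha_range)
        out.append(model.make_geometry([th, al]))
    return out
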