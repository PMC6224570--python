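"""Two-state molecular electronic models.

All models expose the same contract: at a nuclear configuration they
provide the two adiabatic electronic energies, their gradients, the
transition-dipole vector with its gradient, and the diabatic-to-adiabatic
mixing angle.  Electronic wavefunction overlaps between nearby
geometries are built from mixing-angle differences.

Two analytic families are shipped:

``azo2d``
    A two-dimensional photoswitch surrogate in a torsion (theta) and a
    bend (alpha) coordinate.  It features a ground-state torsional
    double well (trans/cis), an excited state descending toward a
    twisted conical intersection at theta = 90 deg, a bend coordinate
    that modulates the gap, and an out-of-plane transition dipole that
    vanishes at planar geometries (theta = 0 or 180 deg).

``curve1d``
    One-dimensional avoided-crossing models (tanh-saturated diabats
    with constant diabatic coupling) used for validation against
    closed-form Landau-Zener results and exact wavepacket dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .units import (
    EV_PER_HARTREE,
    HARTREE_PER_EV,
    RAD_PER_DEG,
    wrap_angle,
)

__all__ = [
    "Geometry",
    "ElectronicStructureData",
    "TwoStateDiabaticModel",
    "Azo2D",
    "Curve1D",
    "classify_isomer",
    "get_model",
    "MODEL_REGISTRY",
]


class InvalidGeometryError(ValueError):
    """Raised for non-finite or otherwise unusable nuclear coordinates."""


@dataclass(frozen=True)
class Geometry:
    """Nuclear configuration in internal coordinates.

    Parameters
    ----------
    coords : array
        Internal coordinates in radians (angular) or bohr (linear).
    inertias : array
        Strictly positive effective inertia of each coordinate in
        atomic units.
    """

    coords: np.ndarray
    inertias: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        inertias = np.asarray(self.inertias, dtype=float)
        if coords.ndim != 1 or inertias.shape != coords.shape:
            raise InvalidGeometryError(
                "coords and inertias must be 1-D arrays of equal length"
            )
        if not np.all(np.isfinite(coords)):
            raise InvalidGeometryError("non-finite coordinate")
        if not (np.all(np.isfinite(inertias)) and np.all(inertias > 0)):
            raise InvalidGeometryError("inertias must be finite and positive")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "inertias", inertias)

    @property
    def n_dof(self) -> int:
        return self.coords.size


@dataclass
class ElectronicStructureData:
    """Adiabatic two-state electronic data at a single geometry.

    Energies in hartree, gradients in hartree per coordinate unit,
    dipoles in atomic units, ``mixing_angle`` in radians.
    """

    e0: float
    e1: float
    grad0: np.ndarray
    grad1: np.ndarray
    mu_vec: np.ndarray
    grad_mu_vec: np.ndarray  # shape (3, n_dof)
    mixing_angle: float


class TwoStateDiabaticModel:
    """Base class: analytic 2x2 diabatic potential plus transition dipole.

    Subclasses implement :meth:`diabats` and :meth:`dipole`; the
    adiabatic quantities follow from the closed-form diagonalization of
    the 2x2 diabatic matrix::

        E_{0,1} = (h11 + h22)/2 -/+ sqrt(((h22 - h11)/2)^2 + h12^2)

    The mixing angle ``phi`` is defined so that the ground adiabatic
    state is ``(cos phi, sin phi)`` in the diabatic basis, with
    ``phi in (-pi/2, pi/2]``.
    """

    name = "base"

    #: default per-coordinate inertias, set by subclasses
    inertias: np.ndarray

    @property
    def n_dof(self) -> int:
        return self.inertias.size

    # -- subclass surface ------------------------------------------------
    def diabats(self, q: np.ndarray):
        """Return ``(h11, h22, h12, dh11, dh22, dh12)`` in hartree."""
        raise NotImplementedError

    def dipole(self, q: np.ndarray):
        """Return ``(mu (3,), dmu (3, n_dof))`` in atomic units."""
        raise NotImplementedError

    def reference_geometry(self) -> Geometry:
        raise NotImplementedError

    # -- shared machinery ------------------------------------------------
    def make_geometry(self, coords) -> Geometry:
        return Geometry(np.asarray(coords, dtype=float), self.inertias.copy())

    def _coords_of(self, q) -> np.ndarray:
        coords = q.coords if isinstance(q, Geometry) else np.asarray(q, dtype=float)
        # NaN/inf both poison the sum, so one scalar check suffices
        if not math.isfinite(float(coords.sum())):
            raise InvalidGeometryError("non-finite coordinate")
        return coords

    def evaluate(self, q) -> ElectronicStructureData:
        """Adiabatic energies, gradients, dipole and mixing angle at ``q``."""
        coords = self._coords_of(q)
        h11, h22, h12, dh11, dh22, dh12 = self.diabats(coords)
        mean = 0.5 * (h11 + h22)
        delta = 0.5 * (h22 - h11)
        r = math.hypot(delta, h12)
        e0 = mean - r
        e1 = mean + r
        dmean = 0.5 * (dh11 + dh22)
        ddelta = 0.5 * (dh22 - dh11)
        r_safe = r if r > 1e-300 else 1e-300
        dr = (delta * ddelta + h12 * dh12) / r_safe
        grad0 = dmean - dr
        grad1 = dmean + dr
        phi = 0.5 * math.atan2(-2.0 * h12, h22 - h11)
        mu, dmu = self.dipole(coords)
        return ElectronicStructureData(
            e0=e0,
            e1=e1,
            grad0=grad0,
            grad1=grad1,
            mu_vec=mu,
            grad_mu_vec=dmu,
            mixing_angle=phi,
        )

    def mixing_angle(self, q) -> float:
        coords = self._coords_of(q)
        h11, h22, h12, *_ = self.diabats(coords)
        return 0.5 * math.atan2(-2.0 * h12, h22 - h11)

    def electronic_overlap(self, q_a, q_b) -> np.ndarray:
        """Overlap matrix between adiabatic states at two geometries.

        ``s[i, j] = <psi_i(q_a) | psi_j(q_b)>`` assuming a shared
        diabatic basis, i.e. a rotation by the mixing-angle difference.
        The difference is wrapped into (-pi/2, pi/2], which fixes the
        arbitrary eigenvector signs so that the overlap stays close to
        the identity along a continuous path.
        """
        return overlap_from_mixing(self.mixing_angle(q_a), self.mixing_angle(q_b))


def overlap_from_mixing(phi_a: float, phi_b: float) -> np.ndarray:
    """Adiabatic overlap rotation from two mixing angles (see
    :meth:`TwoStateDiabaticModel.electronic_overlap`)."""
    dphi = phi_b - phi_a
    # wrap modulo pi into (-pi/2, pi/2] (sign-fixing branch choice)
    dphi = dphi - math.pi * math.floor(dphi / math.pi + 0.5)
    if dphi <= -0.5 * math.pi:
        dphi += math.pi
    c, s = math.cos(dphi), math.sin(dphi)
    return np.array([[c, -s], [s, c]])


class Azo2D(TwoStateDiabaticModel):
    """Azobenzene-like 2-D photoswitch surrogate.

    Coordinates: ``theta`` (torsion, radians; trans at 180 deg, cis at
    0 deg) and ``alpha`` (bend, radians).  Diabatic matrix elements::

        h11 = A0 sin^2(th) + (c_cis/2)(1 + cos th) + (k0/2)(al - al0)^2
        h22 = Ev - A1 sin^2(th) + (k1/2)(al - al1)^2
        h12 = gamma12 cos(th)

    plus a constant shift making the adiabatic ground energy exactly
    zero at the trans reference geometry ``(180 deg, al0)``.  The
    transition dipole is purely out-of-plane, ``mu = (0, 0, mu0 sin th)``,
    so it vanishes identically at planar geometries.

    Default stiffness/inertia values give a bending period of ~30 fs
    and an excited-state torsional descent of ~100 fs.
    """

    name = "azo2d"

    #: physically meaningful bend range (radians) used by scans
    ALPHA_RANGE = (80.0 * RAD_PER_DEG, 180.0 * RAD_PER_DEG)

    def __init__(
        self,
        a0_ev: float = 1.6,
        c_cis_ev: float = 0.6,
        ev_vert_ev: float = 2.8,
        a1_ev: float = 1.4,
        alpha0_deg: float = 115.0,
        alpha1_deg: float = 130.0,
        k0_ev: float = 8.84,
        k1_ev: float = 8.84,
        gamma12_ev: float = 0.15,
        mu0_au: float = 1.0,
        inertia_torsion: float = 2.0e5,
        inertia_bend: float = 1.27e4,
    ):
        self.a0 = a0_ev * HARTREE_PER_EV
        self.c_cis = c_cis_ev * HARTREE_PER_EV
        self.ev_vert = ev_vert_ev * HARTREE_PER_EV
        self.a1 = a1_ev * HARTREE_PER_EV
        self.alpha0 = alpha0_deg * RAD_PER_DEG
        self.alpha1 = alpha1_deg * RAD_PER_DEG
        self.k0 = k0_ev * HARTREE_PER_EV
        self.k1 = k1_ev * HARTREE_PER_EV
        self.gamma12 = gamma12_ev * HARTREE_PER_EV
        self.mu0 = mu0_au
        self.inertias = np.array([inertia_torsion, inertia_bend], dtype=float)
        params = [
            self.a0, self.c_cis, self.ev_vert, self.a1, self.alpha0,
            self.alpha1, self.k0, self.k1, self.gamma12, self.mu0,
        ]
        if not all(math.isfinite(p) for p in params):
            raise ValueError("model parameters must be finite")
        # shift so the adiabatic ground energy is exactly 0 at the trans
        # reference geometry (theta=180 deg, alpha=alpha0)
        self._shift = 0.0
        ref = self.evaluate(self.reference_geometry())
        self._shift = ref.e0

    def reference_geometry(self) -> Geometry:
        return self.make_geometry([math.pi, self.alpha0])

    def diabats(self, q):
        th, al = q
        sin_th = math.sin(th)
        cos_th = math.cos(th)
        sin2th = math.sin(2.0 * th)
        da0 = al - self.alpha0
        da1 = al - self.alpha1
        h11 = (
            self.a0 * sin_th * sin_th
            + 0.5 * self.c_cis * (1.0 + cos_th)
            + 0.5 * self.k0 * da0 * da0
            - self._shift
        )
        h22 = (
            self.ev_vert
            - self.a1 * sin_th * sin_th
            + 0.5 * self.k1 * da1 * da1
            - self._shift
        )
        h12 = self.gamma12 * cos_th
        dh11 = np.array(
            [self.a0 * sin2th - 0.5 * self.c_cis * sin_th, self.k0 * da0]
        )
        dh22 = np.array([-self.a1 * sin2th, self.k1 * da1])
        dh12 = np.array([-self.gamma12 * sin_th, 0.0])
        return h11, h22, h12, dh11, dh22, dh12

    def dipole(self, q):
        th = q[0]
        s = math.sin(th)
        # planarity: the out-of-plane component is exactly zero at
        # theta = n*pi (sin(math.pi) alone leaves ~1e-16)
        if th == 0.0 or th % math.pi == 0.0:
            s = 0.0
        mu = np.array([0.0, 0.0, self.mu0 * s])
        dmu = np.zeros((3, 2))
        dmu[2, 0] = self.mu0 * math.cos(th)
        return mu, dmu

    def vertical_gap_ev(self, q) -> float:
        """Adiabatic gap E1 - E0 in eV (convenience for scans)."""
        d = self.evaluate(q)
        return (d.e1 - d.e0) * EV_PER_HARTREE


class Curve1D(TwoStateDiabaticModel):
    """One-dimensional avoided-crossing model.

    Diabats are tanh-saturated linear curves with constant coupling::

        h11 = c11 + a11 tanh((x - x11)/w11)
        h22 = c22 + a22 tanh((x - x22)/w22)
        h12 = c12

    and a constant transition dipole ``mu = (0, 0, mu0)``.  Near the
    crossing the diabats are linear, so scattering at fixed incidence
    momentum can be compared with the Landau-Zener closed form.
    """

    name = "curve1d"

    def __init__(
        self,
        c11_ev: float = 0.0,
        a11_ev: float = 0.0,
        x11: float = 0.0,
        w11: float = 1.0,
        c22_ev: float = 2.0,
        a22_ev: float = -1.5,
        x22: float = 0.0,
        w22: float = 1.0,
        c12_ev: float = 0.0,
        mu0_au: float = 1.0,
        mass: float = 2000.0,
    ):
        self.c11 = c11_ev * HARTREE_PER_EV
        self.a11 = a11_ev * HARTREE_PER_EV
        self.x11 = x11
        self.w11 = w11
        self.c22 = c22_ev * HARTREE_PER_EV
        self.a22 = a22_ev * HARTREE_PER_EV
        self.x22 = x22
        self.w22 = w22
        self.c12 = c12_ev * HARTREE_PER_EV
        self.mu0 = mu0_au
        self.inertias = np.array([mass], dtype=float)

    def reference_geometry(self) -> Geometry:
        return self.make_geometry([0.0])

    def diabats(self, q):
        x = q[0]
        t1 = math.tanh((x - self.x11) / self.w11)
        t2 = math.tanh((x - self.x22) / self.w22)
        h11 = self.c11 + self.a11 * t1
        h22 = self.c22 + self.a22 * t2
        h12 = self.c12
        dh11 = np.array([self.a11 * (1.0 - t1 * t1) / self.w11])
        dh22 = np.array([self.a22 * (1.0 - t2 * t2) / self.w22])
        dh12 = np.array([0.0])
        return h11, h22, h12, dh11, dh22, dh12

    def dipole(self, q):
        mu = np.array([0.0, 0.0, self.mu0])
        dmu = np.zeros((3, 1))
        return mu, dmu


def classify_isomer(q) -> str:
    """Classify a photoswitch geometry as ``"trans"`` or ``"cis"``.

    The torsion (first coordinate) is wrapped to (-180, 180] deg;
    |theta| >= 90 deg is trans (90 deg exactly counts as trans).
    """
    coords = q.coords if isinstance(q, Geometry) else np.asarray(q, dtype=float)
    theta = wrap_angle(float(coords[0]))
    return "trans" if abs(theta) >= 0.5 * math.pi else "cis"


MODEL_REGISTRY = {
    "azo2d": Azo2D,
    "curve1d": Curve1D,
}


def get_model(name: str, **params) -> TwoStateDiabaticModel:
    """Instantiate a registered model by name with parameter overrides."""
    try:
        cls = MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        ) from None
    return cls(**params)
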