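"""Thermal sampling of ground-state phase points and vertical excitation.

Initial conditions for the excited-state swarm are snapshots of a
single long ground-electronic-state trajectory coupled to a stochastic
velocity-rescaling (canonical) thermostat; each snapshot is then
promoted vertically (coordinates and momenta untouched) to the upper
polariton.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .dynamics import PolaritonicSurface, TrajectoryState
from .electronic_models import TwoStateDiabaticModel
from .polariton import CavityMode
from .units import AU_PER_FS, KB_HARTREE

__all__ = [
    "ThermalSamplingSettings",
    "PhaseSpacePoint",
    "thermal_sample",
    "select_initial_points",
    "vertical_excite",
]


@dataclass(frozen=True)
class PhaseSpacePoint:
    """Nuclear coordinates and conjugate momenta (atomic units)."""

    coords: np.ndarray
    momenta: np.ndarray


@dataclass
class ThermalSamplingSettings:
    """Canonical ground-state sampling parameters (interface units: fs, K)."""

    temperature: float = 300.0
    total_time_fs: float = 10000.0
    equilibration_fs: float = 1000.0
    stride_fs: float = 30.0
    thermostat_tau_fs: float = 100.0
    dt_fs: float = 0.25
    rng_seed: int = 0

    def __post_init__(self):
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        if not self.equilibration_fs < self.total_time_fs:
            raise ValueError("equilibration must be shorter than the run")
        if not self.stride_fs > 0:
            raise ValueError("sampling stride must be positive")


def _svr_rescale(
    e_kin: float,
    e_kin_target: float,
    ndof: int,
    c: float,
    rng: np.random.Generator,
) -> float:
    """Stochastic velocity-rescaling factor alpha^2 (Bussi-style).

    ``c = exp(-dt/tau)``; the new kinetic energy is drawn from the
    canonical-sampling update and the squared rescale factor returned.
    """
    r1 = rng.standard_normal()
    if ndof > 1:
        rsum = float(np.sum(rng.standard_normal(ndof - 1) ** 2))
    else:
        rsum = 0.0
    k_new = (
        e_kin * c
        + e_kin_target * (1.0 - c) * (r1 * r1 + rsum) / ndof
        + 2.0 * r1 * math.sqrt(e_kin * e_kin_target * c * (1.0 - c) / ndof)
    )
    if k_new < 0.0:
        k_new = 0.0
    return k_new / e_kin if e_kin > 0 else 1.0


def thermal_sample(
    model: TwoStateDiabaticModel,
    settings: ThermalSamplingSettings,
    return_series: bool = False,
):
    """Sample phase points from a thermostatted ground-state trajectory.

    Velocity-Verlet dynamics on the adiabatic ground electronic surface
    (cavity coupling plays no role on S0) with a stochastic
    velocity-rescaling canonical thermostat.  Snapshots are collected
    after the equilibration window every ``stride_fs``.

    With ``return_series=True`` also returns the per-step kinetic-energy
    series (after equilibration) for diagnostics.
    """
    rng = np.random.default_rng(np.random.SeedSequence([settings.rng_seed]))
    dt = settings.dt_fs * AU_PER_FS
    n_steps = int(round(settings.total_time_fs / settings.dt_fs))
    n_equil = int(round(settings.equilibration_fs / settings.dt_fs))
    stride = max(1, int(round(settings.stride_fs / settings.dt_fs)))
    ndof = model.n_dof
    inertias = model.inertias
    kt = KB_HARTREE * settings.temperature
    e_kin_target = 0.5 * ndof * kt
    c_ts = math.exp(-settings.dt_fs / settings.thermostat_tau_fs)

    q = model.reference_geometry().coords.copy()
    p = np.zeros(ndof)
    # start with thermal momenta so equilibration is short
    p[:] = rng.standard_normal(ndof) * np.sqrt(inertias * kt)
    force = -model.evaluate(q).grad0

    points: List[PhaseSpacePoint] = []
    ekin_series = [] if return_series else None

    for i in range(1, n_steps + 1):
        p_half = p + 0.5 * dt * force
        q = q + dt * p_half / inertias
        force = -model.evaluate(q).grad0
        p = p_half + 0.5 * dt * force
        e_kin = float(0.5 * np.sum(p * p / inertias))
        if e_kin > 0.0:
            alpha2 = _svr_rescale(e_kin, e_kin_target, ndof, c_ts, rng)
            p = p * math.sqrt(alpha2)
        if i > n_equil:
            if return_series:
                ekin_series.append(float(0.5 * np.sum(p * p / inertias)))
            if (i - n_equil) % stride == 0:
                points.append(PhaseSpacePoint(q.copy(), p.copy()))

    if return_series:
        return points, np.asarray(ekin_series)
    return points


def select_initial_points(
    points: List[PhaseSpacePoint], n: int
) -> List[PhaseSpacePoint]:
    """Pick ``n`` evenly spaced snapshots; error if too few are available."""
    if len(points) < n:
        raise ValueError(
            f"only {len(points)} thermal snapshots available, {n} requested; "
            "increase total_time_fs or decrease stride_fs"
        )
    idx = np.linspace(0, len(points) - 1, n).round().astype(int)
    return [points[i] for i in idx]


def vertical_excite(
    point: PhaseSpacePoint,
    model: TwoStateDiabaticModel,
    cavity: CavityMode,
    surface: Optional[PolaritonicSurface] = None,
) -> TrajectoryState:
    """Franck-Condon promotion of a ground-state phase point to the
    upper polariton.

    Coordinates and momenta are unchanged; the active state becomes the
    upper polariton (the higher-energy member of the rotating
    {|S1,0>, |S0,1>} block, with dominant-|S1,0> tie-break at exact
    degeneracy) and the amplitudes collapse onto it.
    """
    if surface is None:
        surface = PolaritonicSurface(model, cavity)
    sp = surface.solve(np.asarray(point.coords, dtype=float))
    active = sp.sol.upper_polariton_index()
    a = np.zeros(surface.n_states, dtype=complex)
    a[active] = 1.0
    return TrajectoryState(
        t=0.0,
        coords=np.asarray(point.coords, dtype=float).copy(),
        momenta=np.asarray(point.momenta, dtype=float).copy(),
        inertias=model.inertias.copy(),
        active=active,
        A=a,
        point=sp,
    )
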