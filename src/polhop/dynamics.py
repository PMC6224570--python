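"""Fewest-switches surface hopping on polaritonic surfaces.

Nuclei follow velocity-Verlet trajectories on the gradient of the
active polaritonic state; the quantum amplitudes are integrated with
the local-diabatization (LD) scheme built from wavefunction overlaps
between successive geometries; hops are drawn with the fewest-switches
prescription adapted to LD, with isotropic momentum rescaling on
accepted hops and an optional energy-based decoherence correction.

The engine is generic over an N-state *surface provider*.  Two are
shipped: :class:`PolaritonicSurface` (four light-matter states) and
:class:`BareElectronicSurface` (two photon-free electronic states, used
as the reference for the exact zero-coupling reduction).

Implementation notes on the LD propagator: the one-step propagator is
the symmetric split

    U = exp(-i E(t+dt) dt/2) T^T exp(-i E(t) dt/2)

with T the Loewdin orthogonalization of the polaritonic overlap matrix.
It agrees with the averaged-Hamiltonian LD propagator to O(dt^3), is
exactly unitary, and - because it only uses diagonal phases and matrix
products - reduces bitwise to the photon-free propagator when the
coupling vanishes.  The Loewdin step uses the Newton-Schulz iteration
for the same reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from .electronic_models import TwoStateDiabaticModel, overlap_from_mixing
from .polariton import (
    CavityMode,
    PolaritonSolution,
    build_hamiltonian,
    polaritonic_gradient,
    polaritonic_overlap,
    solve_polaritons,
)
from .units import AU_PER_FS, EV_PER_HARTREE, FS_PER_AU, HARTREE_PER_EV

__all__ = [
    "SimulationSettings",
    "TrajectoryState",
    "Trajectory",
    "EnsembleResult",
    "HopEvent",
    "PolaritonicSurface",
    "BareElectronicSurface",
    "vv_step",
    "initial_state",
    "ld_propagate",
    "lowdin_orthonormalize",
    "fssh_step",
    "apply_decoherence",
    "run_trajectory",
    "run_ensemble",
    "trajectory_rng",
]


class PropagationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# surface providers
# ---------------------------------------------------------------------------


@dataclass
class SurfacePoint:
    """Cached solution of the electronic/polaritonic problem at one
    geometry: sorted energies (hartree) and the coefficient matrix C of
    the adiabatic states over the uncoupled basis."""

    energies: np.ndarray
    C: np.ndarray
    elec: object = None
    sol: Optional[PolaritonSolution] = None

    def s01_weight(self, state: int) -> float:
        if self.sol is None:
            return 0.0
        return self.sol.s01_weight(state)


class PolaritonicSurface:
    """Four polaritonic states of a molecule coupled to one cavity mode."""

    def __init__(self, model: TwoStateDiabaticModel, cavity: CavityMode):
        self.model = model
        self.cavity = cavity
        self.n_states = 4

    def solve(self, coords: np.ndarray, previous: Optional[SurfacePoint] = None
              ) -> SurfacePoint:
        elec = self.model.evaluate(coords)
        prev_sol = previous.sol if previous is not None else None
        sol = solve_polaritons(build_hamiltonian(elec, self.cavity), prev_sol)
        return SurfacePoint(energies=sol.energies, C=sol.C, elec=elec, sol=sol)

    def gradient(self, point: SurfacePoint, state: int) -> np.ndarray:
        # degeneracies are traversed rather than fatal during dynamics:
        # the Hellmann-Feynman expression stays finite there
        return polaritonic_gradient(
            point.elec, self.cavity, point.sol, state, on_degenerate="ignore"
        )

    def overlap(self, point_a: SurfacePoint, point_b: SurfacePoint,
                coords_a: np.ndarray, coords_b: np.ndarray) -> np.ndarray:
        # mixing angles are already cached in the solved points
        s_el = overlap_from_mixing(
            point_a.elec.mixing_angle, point_b.elec.mixing_angle
        )
        return polaritonic_overlap(point_a.sol, point_b.sol, s_el)


class BareElectronicSurface:
    """Photon-free two-state electronic surface provider.

    ``energy_offset`` adds a constant (e.g. the cavity zero-point
    omega/2) to both energies; it has no effect on the dynamics and
    exists so that total energies can be compared directly with a
    zero-coupling polaritonic run.
    """

    def __init__(self, model: TwoStateDiabaticModel, energy_offset: float = 0.0):
        self.model = model
        self.energy_offset = energy_offset
        self.n_states = 2

    def solve(self, coords: np.ndarray, previous: Optional[SurfacePoint] = None
              ) -> SurfacePoint:
        elec = self.model.evaluate(coords)
        energies = np.array(
            [elec.e0 + self.energy_offset, elec.e1 + self.energy_offset]
        )
        return SurfacePoint(energies=energies, C=np.eye(2), elec=elec, sol=None)

    def gradient(self, point: SurfacePoint, state: int) -> np.ndarray:
        return point.elec.grad1 if state == 1 else point.elec.grad0

    def overlap(self, point_a, point_b, coords_a, coords_b) -> np.ndarray:
        return overlap_from_mixing(
            point_a.elec.mixing_angle, point_b.elec.mixing_angle
        )


# ---------------------------------------------------------------------------
# settings / records
# ---------------------------------------------------------------------------


@dataclass
class SimulationSettings:
    """Knobs of a surface-hopping run (interface units: fs)."""

    dt_fs: float = 0.1
    n_steps: int = 1000
    decoherence: str = "energy"  # "energy" | "none"
    decoherence_alpha: float = 0.1  # hartree
    rescale_policy: str = "isotropic"
    rng_seed: int = 0
    energy_drift_tol_ev: float = 0.27
    store_amplitudes: bool = True

    def __post_init__(self):
        if not self.dt_fs > 0:
            raise ValueError("dt must be positive")
        if self.decoherence_alpha < 0:
            raise ValueError("decoherence alpha must be >= 0")
        if self.decoherence not in ("energy", "none"):
            raise ValueError("decoherence must be 'energy' or 'none'")
        if self.rescale_policy != "isotropic":
            raise ValueError("only isotropic momentum rescaling is implemented")

    @property
    def dt_au(self) -> float:
        return self.dt_fs * AU_PER_FS


@dataclass
class TrajectoryState:
    """Instantaneous state of one trajectory (atomic units)."""

    t: float
    coords: np.ndarray
    momenta: np.ndarray
    inertias: np.ndarray
    active: int
    A: np.ndarray
    point: SurfacePoint
    force: np.ndarray = None

    def kinetic_energy(self) -> float:
        return float(0.5 * np.sum(self.momenta * self.momenta / self.inertias))

    def total_energy(self) -> float:
        return self.kinetic_energy() + float(self.point.energies[self.active])

    def norm(self) -> float:
        return float(np.sum(self.A.real**2 + self.A.imag**2))


@dataclass
class HopEvent:
    step: int
    t_fs: float
    source: int
    target: int
    accepted: bool


@dataclass
class Trajectory:
    """Full per-step record of one surface-hopping trajectory."""

    t_fs: np.ndarray
    coords: np.ndarray  # (n+1, d), radians/bohr
    momenta: np.ndarray
    active: np.ndarray  # (n+1,)
    energies: np.ndarray  # (n+1, n_states), hartree
    c_s01_sq: np.ndarray  # (n+1,), |C_{S0,1}|^2 of the active state
    active_char: np.ndarray  # (n+1, n_states), |C_i(active)|^2
    amp_char: np.ndarray  # (n+1, n_states), |sum_G C_iG A_G|^2
    A: Optional[np.ndarray]  # (n+1, n_states) complex, or None
    hops: List[HopEvent]
    failed: bool
    traj_id: int
    dt_fs: float
    meta: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.t_fs.size - 1

    def accepted_hops(self, between: Optional[tuple] = None) -> int:
        n = 0
        for h in self.hops:
            if not h.accepted:
                continue
            if between is not None and {h.source, h.target} != set(between):
                continue
            n += 1
        return n

    def to_dataframe(self):
        import pandas as pd

        d = self.coords.shape[1]
        data = {"t_fs": self.t_fs}
        for k in range(d):
            data[f"q{k}"] = self.coords[:, k]
        for k in range(d):
            data[f"p{k}"] = self.momenta[:, k]
        data["active"] = self.active
        for s in range(self.energies.shape[1]):
            data[f"E{s + 1}_ev"] = self.energies[:, s] * EV_PER_HARTREE
        data["c_s01_sq"] = self.c_s01_sq
        return pd.DataFrame(data)


@dataclass
class EnsembleResult:
    """A swarm of independent trajectories on a common time grid."""

    trajectories: List[Trajectory]
    settings: SimulationSettings
    meta: dict = field(default_factory=dict)

    @property
    def t_fs(self) -> np.ndarray:
        return self.trajectories[0].t_fs

    @property
    def n_states(self) -> int:
        return self.trajectories[0].energies.shape[1]

    def __len__(self) -> int:
        return len(self.trajectories)

    def failed(self) -> List[Trajectory]:
        return [t for t in self.trajectories if t.failed]


# ---------------------------------------------------------------------------
# elementary steps
# ---------------------------------------------------------------------------


def vv_step(state: TrajectoryState, surface, dt: float) -> TrajectoryState:
    """One velocity-Verlet step on the active adiabatic surface.

    The new surface solution is re-solved and sign-fixed against the
    previous geometry's solution.
    """
    if state.force is None:
        state.force = -surface.gradient(state.point, state.active)
    p_half = state.momenta + (0.5 * dt) * state.force
    coords = state.coords + dt * (p_half / state.inertias)
    point = surface.solve(coords, previous=state.point)
    force = -surface.gradient(point, state.active)
    momenta = p_half + (0.5 * dt) * force
    return TrajectoryState(
        t=state.t + dt,
        coords=coords,
        momenta=momenta,
        inertias=state.inertias,
        active=state.active,
        A=state.A,
        point=point,
        force=force,
    )


def lowdin_orthonormalize(s: np.ndarray, tol: float = 1e-13,
                          max_iter: int = 60) -> np.ndarray:
    """Loewdin orthogonalization T = S (S^T S)^(-1/2).

    Computed with the Newton-Schulz iteration X <- X (3I - X^T X)/2,
    which converges quadratically for near-orthogonal overlaps and is
    built purely from matrix products (this keeps exact zero blocks
    exactly zero).  A rank-deficient overlap does not converge and
    raises :class:`PropagationError`.
    """
    n = s.shape[0]
    eye = np.eye(n)
    x = s
    for _ in range(max_iter):
        g = x.T @ x
        dev = float(np.max(np.abs(g - eye)))
        if dev < tol:
            return x
        if not math.isfinite(dev):
            break
        x = x @ (1.5 * eye - 0.5 * g)
    raise PropagationError(
        f"overlap orthogonalization failed (deviation {dev:.3e}); "
        "the overlap matrix is singular or the step is too large"
    )


def _matvec(u: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Complex matrix-vector product with a fixed scalar summation order.

    Exactly-zero amplitude components are skipped, so a state vector
    confined to a subspace propagates with bit-identical arithmetic to
    the same propagation in the reduced space (BLAS kernels do not
    guarantee this across matrix sizes).
    """
    n = a.size
    out = np.empty(n, dtype=complex)
    for i in range(n):
        acc = 0j
        row = u[i]
        for j in range(n):
            aj = a[j]
            if aj != 0j:
                acc = acc + row[j] * aj
        out[i] = acc
    return out


def _ld_propagator(energies_a: np.ndarray, energies_b: np.ndarray,
                   s: np.ndarray, dt: float) -> np.ndarray:
    """One-step LD propagator U = P_b T^T P_a with half-step phases
    P = exp(-i E dt / 2)."""
    t_mat = lowdin_orthonormalize(s)
    phase_a = np.exp((-0.5j * dt) * energies_a)
    phase_b = np.exp((-0.5j * dt) * energies_b)
    return (phase_b[:, None] * t_mat.T) * phase_a[None, :]


def ld_propagate(A: np.ndarray, sol_t: PolaritonSolution,
                 sol_next: PolaritonSolution, elec_ov: np.ndarray,
                 dt: float):
    """Propagate amplitudes across one nuclear step with the LD scheme.

    Returns ``(A', U)`` with ``A' = U A`` and U unitary.
    """
    s = polaritonic_overlap(sol_t, sol_next, elec_ov)
    u = _ld_propagator(sol_t.energies, sol_next.energies, s, dt)
    return _matvec(u, A), u


@dataclass
class HopOutcome:
    active: int
    momenta: np.ndarray
    event: Optional[HopEvent]
    p_leave: float


def fssh_step(
    A_prev: np.ndarray,
    A_new: np.ndarray,
    U: np.ndarray,
    active: int,
    rng: np.random.Generator,
    momenta: np.ndarray,
    inertias: np.ndarray,
    energies: np.ndarray,
    step: int = 0,
    t_fs: float = 0.0,
) -> HopOutcome:
    """Fewest-switches hop decision for one LD step.

    The probability of leaving the active state k is
    ``max(0, (|A_k|^2 - |A'_k|^2) / |A_k|^2)`` (zero when |A_k|^2 is
    numerically empty); it is partitioned among target states in
    proportion to their positive population gain over the step.  An
    accepted hop rescales all momenta isotropically to conserve total
    energy; if the kinetic energy cannot pay the potential-energy jump
    the hop is frustrated and both state and momenta are unchanged.
    """
    pk_prev = A_prev[active].real ** 2 + A_prev[active].imag ** 2
    pk_new = A_new[active].real ** 2 + A_new[active].imag ** 2
    if pk_prev < 1e-12:
        p_leave = 0.0
    else:
        p_leave = max(0.0, (pk_prev - pk_new) / pk_prev)
    r = rng.random()
    if r >= p_leave or p_leave <= 0.0:
        return HopOutcome(active, momenta, None, p_leave)

    gains = (A_new.real**2 + A_new.imag**2) - (A_prev.real**2 + A_prev.imag**2)
    gains[active] = 0.0
    np.maximum(gains, 0.0, out=gains)
    total = float(np.sum(gains))
    if total <= 0.0:
        return HopOutcome(active, momenta, None, p_leave)

    acc = 0.0
    target = -1
    for l in range(gains.size):
        if l == active or gains[l] == 0.0:
            continue
        acc += p_leave * (gains[l] / total)
        if r < acc:
            target = l
            break
    if target < 0:
        return HopOutcome(active, momenta, None, p_leave)

    e_kin = float(0.5 * np.sum(momenta * momenta / inertias))
    de = float(energies[active] - energies[target])
    avail = e_kin + de
    if avail < 0.0 or e_kin <= 0.0:
        event = HopEvent(step, t_fs, active, target, accepted=False)
        return HopOutcome(active, momenta, event, p_leave)
    scale = math.sqrt(avail / e_kin)
    event = HopEvent(step, t_fs, active, target, accepted=True)
    return HopOutcome(target, momenta * scale, event, p_leave)


def apply_decoherence(
    A: np.ndarray,
    active: int,
    energies: np.ndarray,
    e_kin: float,
    dt: float,
    alpha: float,
) -> np.ndarray:
    """Energy-based decoherence damping.

    Every non-active amplitude l is damped by exp(-dt / tau_l) with
    ``tau_l = (1/|E_l - E_active|) (1 + alpha/E_kin)`` (atomic units);
    the active amplitude is rescaled to restore unit norm.  With zero
    kinetic energy the damping time diverges and the step is a no-op.
    """
    if not e_kin > 0.0:
        return A
    out = A.copy()
    rate_scale = dt / (1.0 + alpha / e_kin)
    e_act = energies[active]
    for l in range(A.size):
        if l == active:
            continue
        de = abs(energies[l] - e_act)
        if de > 0.0:
            out[l] = out[l] * math.exp(-rate_scale * de)
    p_act = out[active].real ** 2 + out[active].imag ** 2
    p_other = 0.0
    for l in range(A.size):
        if l != active:
            p_other += out[l].real ** 2 + out[l].imag ** 2
    if p_act > 1e-30:
        out[active] = out[active] * math.sqrt(max(1.0 - p_other, 0.0) / p_act)
    else:
        norm = math.sqrt(p_act + p_other)
        if norm > 0.0:
            out /= norm
    return out


# ---------------------------------------------------------------------------
# trajectory / ensemble drivers
# ---------------------------------------------------------------------------


def initial_state(surface, coords, momenta, inertias, active: int,
                  t: float = 0.0) -> TrajectoryState:
    """Build a TrajectoryState with amplitudes collapsed on ``active``."""
    coords = np.asarray(coords, dtype=float)
    momenta = np.asarray(momenta, dtype=float)
    inertias = np.asarray(inertias, dtype=float)
    point = surface.solve(coords)
    A = np.zeros(surface.n_states, dtype=complex)
    A[active] = 1.0
    return TrajectoryState(
        t=t, coords=coords, momenta=momenta, inertias=inertias,
        active=active, A=A, point=point,
    )


def trajectory_rng(master_seed: int, traj_id: int) -> np.random.Generator:
    """Deterministic per-trajectory RNG: child seed (master_seed, traj_id).

    Hop draws use this stream; cavity-loss post-processing uses an
    independent scheme (see :mod:`polhop.cavity_losses`).
    """
    return np.random.default_rng(np.random.SeedSequence([master_seed, traj_id]))


def run_trajectory(
    surface,
    init: TrajectoryState,
    settings: SimulationSettings,
    rng: Optional[np.random.Generator] = None,
    traj_id: int = 0,
) -> Trajectory:
    """Propagate one surface-hopping trajectory for ``settings.n_steps``.

    Records every step.  A trajectory whose total energy drifts beyond
    ``settings.energy_drift_tol_ev`` between hops is flagged failed and
    stopped (never silently kept).
    """
    if rng is None:
        rng = trajectory_rng(settings.rng_seed, traj_id)
    dt = settings.dt_au
    n_steps = settings.n_steps
    n_states = surface.n_states
    d = init.coords.size

    t_fs = np.empty(n_steps + 1)
    coords = np.empty((n_steps + 1, d))
    momenta = np.empty((n_steps + 1, d))
    active = np.empty(n_steps + 1, dtype=np.int64)
    energies = np.empty((n_steps + 1, n_states))
    c_s01 = np.empty(n_steps + 1)
    active_char = np.empty((n_steps + 1, n_states))
    amp_char = np.empty((n_steps + 1, n_states))
    amps = np.empty((n_steps + 1, n_states), dtype=complex) \
        if settings.store_amplitudes else None
    hops: List[HopEvent] = []

    state = init
    if state.force is None:
        state = replace(state)
        state.force = -surface.gradient(state.point, state.active)

    def record(i: int, st: TrajectoryState):
        t_fs[i] = st.t * FS_PER_AU
        coords[i] = st.coords
        momenta[i] = st.momenta
        active[i] = st.active
        energies[i] = st.point.energies
        c_s01[i] = st.point.s01_weight(st.active)
        active_char[i] = st.point.C[:, st.active] ** 2
        unc = st.point.C @ st.A
        amp_char[i] = unc.real**2 + unc.imag**2
        if amps is not None:
            amps[i] = st.A

    record(0, state)
    e_ref = state.total_energy()
    drift_tol = settings.energy_drift_tol_ev * HARTREE_PER_EV
    failed = False
    last = 0

    for i in range(1, n_steps + 1):
        prev = state
        state = vv_step(prev, surface, dt)
        s_ov = surface.overlap(prev.point, state.point, prev.coords, state.coords)
        u = _ld_propagator(prev.point.energies, state.point.energies, s_ov, dt)
        a_new = _matvec(u, prev.A)

        hop = fssh_step(
            prev.A, a_new, u, state.active, rng,
            state.momenta, state.inertias, state.point.energies,
            step=i, t_fs=state.t * FS_PER_AU,
        )
        if hop.event is not None:
            hops.append(hop.event)
        if hop.active != state.active:
            state.active = hop.active
            state.momenta = hop.momenta
            state.force = -surface.gradient(state.point, state.active)
            e_ref = state.total_energy()

        if settings.decoherence == "energy":
            a_new = apply_decoherence(
                a_new, state.active, state.point.energies,
                state.kinetic_energy(), dt, settings.decoherence_alpha,
            )
        state.A = a_new
        record(i, state)
        last = i

        e_tot = state.total_energy()
        if not math.isfinite(e_tot) or abs(e_tot - e_ref) > drift_tol:
            failed = True
            break

    if failed:
        last_slice = slice(0, last + 1)
        return Trajectory(
            t_fs=t_fs[last_slice], coords=coords[last_slice],
            momenta=momenta[last_slice], active=active[last_slice],
            energies=energies[last_slice], c_s01_sq=c_s01[last_slice],
            active_char=active_char[last_slice], amp_char=amp_char[last_slice],
            A=amps[last_slice] if amps is not None else None,
            hops=hops, failed=True, traj_id=traj_id, dt_fs=settings.dt_fs,
        )
    return Trajectory(
        t_fs=t_fs, coords=coords, momenta=momenta, active=active,
        energies=energies, c_s01_sq=c_s01, active_char=active_char,
        amp_char=amp_char, A=amps, hops=hops, failed=False,
        traj_id=traj_id, dt_fs=settings.dt_fs,
    )


def run_ensemble(
    surface,
    inits: Sequence[TrajectoryState],
    settings: SimulationSettings,
    meta: Optional[dict] = None,
    ids: Optional[Sequence[int]] = None,
) -> EnsembleResult:
    """Run an independent swarm of trajectories.

    Trajectory ``i`` uses the deterministic child RNG
    ``SeedSequence([settings.rng_seed, ids[i]])`` (``ids`` defaults to
    ``range(len(inits))``), so results are reproducible and independent
    of execution order: permuting ``(inits, ids)`` together permutes the
    trajectories without changing any of them.
    """
    if len(inits) == 0:
        raise ValueError("at least one initial condition is required")
    if ids is None:
        ids = range(len(inits))
    trajectories = []
    for tid, init in zip(ids, inits):
        rng = trajectory_rng(settings.rng_seed, tid)
        trajectories.append(
            run_trajectory(surface, init, settings, rng=rng, traj_id=tid)
        )
    bad = [t.traj_id for t in trajectories if t.failed]
    result = EnsembleResult(
        trajectories=trajectories, settings=settings, meta=dict(meta or {}),
    )
    result.meta.setdefault("failed_traj_ids", bad)
    return result
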