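"""Light-molecule Hamiltonian in the four-state uncoupled basis.

The molecule (two electronic states) is coupled to one quantized cavity
mode truncated at one photon.  Ordered uncoupled basis:

    0: |S0,0>   1: |S1,0>   2: |S0,1>   3: |S1,1>

The total Hamiltonian is

    H = diag(E0, E1, E0, E1) + omega*(n + 1/2)
        + g (mu . lam) [(b+ + b) coupling pattern]

where the dipolar interaction connects states differing by one photon
with opposite electronic character: (|S1,0>, |S0,1>) (rotating block)
and (|S0,0>, |S1,1>) (counter-rotating block, responsible for the Lamb
shift of the outer states).  Under the one-photon truncation the two
2x2 blocks are exactly decoupled, which is exploited by the closed-form
helpers used as test oracles; the production path diagonalizes the full
4x4 matrix numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .electronic_models import ElectronicStructureData, TwoStateDiabaticModel
from .units import EV_PER_HARTREE, HARTREE_PER_EV, RAD_PER_DEG, rad_to_deg

__all__ = [
    "CavityMode",
    "PolaritonSolution",
    "DegeneracyError",
    "build_hamiltonian",
    "solve_polaritons",
    "polaritonic_gradient",
    "polaritonic_overlap",
    "scan_ppes",
    "PPESScan",
    "PHOTON_NUMBER",
    "ELEC_INDEX",
    "BASIS_LABELS",
]

#: photon occupation of each uncoupled basis state
PHOTON_NUMBER = np.array([0, 0, 1, 1])
#: electronic index (0 = S0, 1 = S1) of each uncoupled basis state
ELEC_INDEX = np.array([0, 1, 0, 1])
BASIS_LABELS = ("S0,0", "S1,0", "S0,1", "S1,1")

#: index of |S0,1> in the uncoupled basis (the lossy state)
IDX_S01 = 2


class DegeneracyError(RuntimeError):
    """Adiabatic gradient requested at a (near-)degenerate eigenvalue."""


@dataclass(frozen=True)
class CavityMode:
    """Single cavity mode: photon energy (hartree), coupling constant g
    (au) and unit polarization vector lam."""

    omega: float
    g: float
    lam: np.ndarray

    def __post_init__(self):
        lam = np.asarray(self.lam, dtype=float)
        if lam.shape != (3,):
            raise ValueError("polarization must be a 3-vector")
        if abs(np.linalg.norm(lam) - 1.0) > 1e-8:
            raise ValueError("polarization vector must have unit norm")
        if not (self.omega > 0):
            raise ValueError("photon energy must be positive")
        if self.g < 0:
            raise ValueError("coupling constant must be non-negative")
        object.__setattr__(self, "lam", lam)

    @classmethod
    def from_ev(cls, omega_ev: float, g: float, lam=(0.0, 0.0, 1.0)) -> "CavityMode":
        return cls(omega=omega_ev * HARTREE_PER_EV, g=g, lam=np.asarray(lam, float))

    @property
    def omega_ev(self) -> float:
        return self.omega * EV_PER_HARTREE


@dataclass
class PolaritonSolution:
    """Eigensolution of the 4x4 light-molecule Hamiltonian.

    ``energies`` are sorted ascending (hartree); column ``C[:, G]`` is
    the expansion of polaritonic state ``G`` over the ordered uncoupled
    basis; ``V = g (mu . lam)`` is the coupling element (hartree).
    """

    energies: np.ndarray
    C: np.ndarray
    V: float

    def s01_weight(self, state: int) -> float:
        """|C_{S0,1}|^2 of polaritonic state ``state`` (photon-loss weight)."""
        c = self.C[IDX_S01, state]
        return c * c

    def character(self, state: int) -> np.ndarray:
        """Squared expansion coefficients of ``state`` over the basis."""
        return self.C[:, state] ** 2

    def upper_polariton_index(self) -> int:
        """Sorted index of the upper polariton |+>.

        The |-> / |+> pair is identified as the two states with dominant
        weight on the rotating block {|S1,0>, |S0,1>}; |+> is the
        higher-energy member.  At an exact degeneracy the tie is broken
        by dominant |S1,0> character.
        """
        w = self.C[1, :] ** 2 + self.C[2, :] ** 2
        pair = np.sort(np.argsort(w)[-2:])
        i, j = int(pair[0]), int(pair[1])
        if self.energies[j] > self.energies[i]:
            return j
        if self.energies[j] < self.energies[i]:
            return i
        return j if self.C[1, j] ** 2 >= self.C[1, i] ** 2 else i

    def lower_polariton_index(self) -> int:
        w = self.C[1, :] ** 2 + self.C[2, :] ** 2
        pair = np.sort(np.argsort(w)[-2:])
        up = self.upper_polariton_index()
        return int(pair[0]) if up == int(pair[1]) else int(pair[1])


def coupling_element(elec: ElectronicStructureData, cavity: CavityMode) -> float:
    """V = g (mu . lam) in hartree."""
    return cavity.g * float(np.dot(elec.mu_vec, cavity.lam))


def build_hamiltonian(
    elec: ElectronicStructureData, cavity: CavityMode
) -> np.ndarray:
    """Assemble the 4x4 total Hamiltonian in the uncoupled basis.

    Diagonal: (E0 + w/2, E1 + w/2, E0 + 3w/2, E1 + 3w/2).  The coupling
    V = g (mu . lam) enters the rotating entry (1,2) and the
    counter-rotating entry (0,3); all other off-diagonal entries vanish
    because the interaction only connects states whose photon occupation
    differs by one.
    """
    v = coupling_element(elec, cavity)
    h = np.zeros((4, 4))
    h[0, 0] = elec.e0 + 0.5 * cavity.omega
    h[1, 1] = elec.e1 + 0.5 * cavity.omega
    h[2, 2] = elec.e0 + 1.5 * cavity.omega
    h[3, 3] = elec.e1 + 1.5 * cavity.omega
    h[1, 2] = h[2, 1] = v
    h[0, 3] = h[3, 0] = v
    return h


def _tie_break_order(energies: np.ndarray, C: np.ndarray) -> None:
    """Reorder exactly-degenerate adjacent pairs by dominant uncoupled
    character (photon number first, then electronic index).  In place."""
    for i in range(3):
        if energies[i + 1] == energies[i]:
            ki = int(np.argmax(np.abs(C[:, i])))
            kj = int(np.argmax(np.abs(C[:, i + 1])))
            if (PHOTON_NUMBER[ki], ELEC_INDEX[ki]) > (PHOTON_NUMBER[kj], ELEC_INDEX[kj]):
                energies[[i, i + 1]] = energies[[i + 1, i]]
                C[:, [i, i + 1]] = C[:, [i + 1, i]]


def _fix_signs(C: np.ndarray, previous: Optional[PolaritonSolution]) -> None:
    """Fix eigenvector signs, in place.

    Against a previous solution: the largest-magnitude overlap of each
    column with the previous columns is made positive.  Without one:
    the largest-magnitude component of each column is made positive.
    """
    ref = previous.C.T @ C if previous is not None else C
    idx = np.abs(ref).argmax(axis=0)
    flip = ref[idx, np.arange(C.shape[1])] < 0.0
    if flip.any():
        C[:, flip] = -C[:, flip]


def solve_polaritons(
    h: np.ndarray, previous: Optional[PolaritonSolution] = None
) -> PolaritonSolution:
    """Diagonalize the 4x4 Hamiltonian into a :class:`PolaritonSolution`.

    Energies are sorted ascending; eigenvector signs are fixed against
    ``previous`` when given.  At exactly zero coupling the solution is
    built directly from the diagonal (a stable permutation), so the
    zero-coupling limit is a bitwise-exact relabeling of the uncoupled
    states.
    """
    v = h[1, 2]
    if v == 0.0 and h[0, 3] == 0.0:
        diag = np.diag(h).copy()
        order = np.argsort(diag, kind="stable")
        energies = diag[order]
        C = np.zeros((4, 4))
        C[order, np.arange(4)] = 1.0
    else:
        energies, C = np.linalg.eigh(h)
        _tie_break_order(energies, C)
    _fix_signs(C, previous)
    return PolaritonSolution(energies=energies, C=C, V=float(v))


def block_eigenvalues(
    elec: ElectronicStructureData, cavity: CavityMode
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form eigenvalues of the two decoupled 2x2 blocks.

    Returns ``(outer, rotating)`` where ``outer`` holds the Lamb-shifted
    (|S0,0>, |S1,1>)-like eigenvalues and ``rotating`` the (|->, |+>)
    pair, each sorted ascending.
    """
    v = coupling_element(elec, cavity)
    w = cavity.omega

    def eig2(a, b):
        mean = 0.5 * (a + b)
        r = math.hypot(0.5 * (b - a), v)
        return np.array([mean - r, mean + r])

    outer = eig2(elec.e0 + 0.5 * w, elec.e1 + 1.5 * w)
    rotating = eig2(elec.e1 + 0.5 * w, elec.e0 + 1.5 * w)
    return outer, rotating


def polariton_gap(elec: ElectronicStructureData, cavity: CavityMode) -> float:
    """|+> minus |-> energy gap (hartree), from the rotating 2x2 block:
    sqrt((E1 - E0 - omega)^2 + 4 V^2)."""
    v = coupling_element(elec, cavity)
    d = elec.e1 - elec.e0 - cavity.omega
    return math.sqrt(d * d + 4.0 * v * v)


def polaritonic_gradient(
    elec: ElectronicStructureData,
    cavity: CavityMode,
    sol: PolaritonSolution,
    state: int,
    on_degenerate: str = "raise",
) -> np.ndarray:
    """Hellmann-Feynman gradient of polaritonic state ``state``.

    grad E_G = sum_ij C_iG C_jG grad H_ij, combining the electronic
    gradients on the diagonal and ``g lam . grad mu`` on the two
    coupling entries.

    With ``on_degenerate="raise"`` (default) a :class:`DegeneracyError`
    is raised when the eigenvalue gap to a neighbouring state is below
    1e-10 hartree, where the adiabatic gradient is ill-defined; pass
    ``"ignore"`` to evaluate the Hellmann-Feynman expression anyway.
    """
    if on_degenerate not in ("raise", "ignore"):
        raise ValueError("on_degenerate must be 'raise' or 'ignore'")
    if on_degenerate == "raise":
        e = sol.energies
        for other in range(4):
            if other != state and abs(e[other] - e[state]) < 1e-10:
                raise DegeneracyError(
                    f"states {state} and {other} degenerate "
                    f"(gap {abs(e[other] - e[state]):.3e} hartree)"
                )
    c = sol.C[:, state]
    grad_v = cavity.g * (cavity.lam @ elec.grad_mu_vec)
    grad = (
        (c[0] * c[0]) * elec.grad0
        + (c[1] * c[1]) * elec.grad1
        + (c[2] * c[2]) * elec.grad0
        + (c[3] * c[3]) * elec.grad1
        + (2.0 * (c[1] * c[2] + c[0] * c[3])) * grad_v
    )
    return grad


def polaritonic_overlap(
    sol_a: PolaritonSolution, sol_b: PolaritonSolution, elec_ov: np.ndarray
) -> np.ndarray:
    """Overlap matrix between polaritonic states at two geometries.

    S_GG' = sum_ij C_iG(a) C_jG'(b) s^el_ij delta(n_i, n_j): the
    electronic overlap acts within each photon-number sector and the
    photon states are orthonormal across geometries.
    """
    m = np.zeros((4, 4))
    m[:2, :2] = elec_ov
    m[2:, 2:] = elec_ov
    return sol_a.C.T @ m @ sol_b.C


@dataclass
class PPESScan:
    """Result of a polaritonic potential-energy-surface scan."""

    table: pd.DataFrame
    min_gap: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# polaritonic PES scan; angles in degrees, energies in eV\n"
            )
            if self.min_gap:
                fh.write(f"# minimum |+>-|-> gap: {self.min_gap}\n")
            self.table.to_csv(fh, index=False)


def scan_ppes(
    model: TwoStateDiabaticModel,
    cavity: CavityMode,
    thetas_deg,
    alphas_deg,
    refine: bool = True,
) -> PPESScan:
    """Tabulate the four polaritonic energies over a (theta, alpha) grid.

    Also records the |->/|+> gap and locates the minimum-gap point by a
    local optimization seeded at the best grid point.  A minimum-gap
    point where both the uncoupled crossing condition E1 - E0 = omega
    and mu . lam = 0 hold (within tolerance) is flagged as a polaritonic
    conical intersection.
    """
    thetas = np.atleast_1d(np.asarray(thetas_deg, dtype=float))
    alphas = np.atleast_1d(np.asarray(alphas_deg, dtype=float))
    if thetas.size == 0 or alphas.size == 0:
        raise ValueError("empty scan grid")

    rows = []
    for th_deg in thetas:
        for al_deg in alphas:
            q = np.array([th_deg, al_deg]) * RAD_PER_DEG
            elec = model.evaluate(q)
            sol = solve_polaritons(build_hamiltonian(elec, cavity))
            gap = polariton_gap(elec, cavity)
            row = {
                "theta_deg": th_deg,
                "alpha_deg": al_deg,
                **{
                    f"E{i + 1}_ev": sol.energies[i] * EV_PER_HARTREE
                    for i in range(4)
                },
                "gap_pm_ev": gap * EV_PER_HARTREE,
                **{
                    f"c_s01_sq_{i}": sol.s01_weight(i) for i in range(4)
                },
            }
            rows.append(row)
    table = pd.DataFrame(rows)

    min_gap: dict = {}
    i_best = int(table["gap_pm_ev"].idxmin())
    q0 = np.array(
        [table.loc[i_best, "theta_deg"], table.loc[i_best, "alpha_deg"]]
    ) * RAD_PER_DEG
    if refine:
        from scipy.optimize import least_squares

        # gap^2 = (E1 - E0 - omega)^2 + (2V)^2: minimize the smooth
        # residual vector instead of the conical gap itself
        def residuals(q):
            elec = model.evaluate(q)
            return np.array(
                [
                    elec.e1 - elec.e0 - cavity.omega,
                    2.0 * coupling_element(elec, cavity),
                ]
            )

        res = least_squares(
            residuals, q0, xtol=1e-15, ftol=1e-15, gtol=1e-15,
            diff_step=1e-7,
        )
        q_min = res.x
    else:
        q_min = q0
    elec = model.evaluate(q_min)
    gap_min = polariton_gap(elec, cavity)
    mu_lam = float(np.dot(elec.mu_vec, cavity.lam))
    resonance = elec.e1 - elec.e0 - cavity.omega
    min_gap = {
        "theta_deg": rad_to_deg(float(q_min[0])),
        "alpha_deg": rad_to_deg(float(q_min[1])),
        "gap_ev": gap_min * EV_PER_HARTREE,
        "mu_dot_lam_au": mu_lam,
        "resonance_residual_ev": resonance * EV_PER_HARTREE,
        "is_polaritonic_ci": bool(
            gap_min * EV_PER_HARTREE < 1e-6
            and abs(mu_lam) * cavity.g * EV_PER_HARTREE < 1e-6
            and abs(resonance) * EV_PER_HARTREE < 1e-4
        ),
    }
    return PPESScan(table=table, min_gap=min_gap)
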