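"""Monte Carlo photon-loss post-processing of stored trajectories.

The finite cavity lifetime is applied *a posteriori* to a lossless
surface-hopping swarm: each trajectory is replicated R times, and each
replica draws, at every recorded step, a loss event with probability

    p_cav(t) = (dt / tau_c) * |C_{S0,1}(t)|^2

where |C_{S0,1}|^2 is the weight of the one-photon ground-electronic
basis state in the *active* polaritonic state.  On a loss the replica
collapses to |S0,0> and is stopped; the (very unlikely) back-transfer
out of |S0,1> after a loss is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import EnsembleResult, Trajectory

__all__ = [
    "LossSettings",
    "ReplicaOutcome",
    "LossEnsemble",
    "loss_resample",
    "ensemble_losses",
]


@dataclass
class LossSettings:
    """Photon-loss Monte Carlo parameters."""

    tau_c_fs: float
    n_replicas: int = 5
    rng_seed: int = 0

    def __post_init__(self):
        if not self.tau_c_fs > 0:
            raise ValueError("photon lifetime must be positive")
        if self.n_replicas < 1:
            raise ValueError("need at least one replica")

    @property
    def kappa_per_fs(self) -> float:
        """Decay rate kappa = 1/tau_c (fs^-1)."""
        return 1.0 / self.tau_c_fs


@dataclass
class ReplicaOutcome:
    """Loss history of one replica: collapse step/time or survival."""

    traj_id: int
    replica: int
    collapsed: bool
    step: Optional[int]  # first step index with a loss event
    time_fs: Optional[float]


def replica_rng(settings: LossSettings, traj_id: int, replica: int
                ) -> np.random.Generator:
    """Independent loss stream per (trajectory, replica).

    The lifetime does not enter the seed, so sweeping tau_c with the
    same ``rng_seed`` uses common random numbers across lifetimes.
    """
    return np.random.default_rng(
        np.random.SeedSequence([settings.rng_seed, traj_id, replica])
    )


def loss_probabilities(traj: Trajectory, tau_c_fs: float) -> np.ndarray:
    """Per-step loss probability (dt/tau_c)|C_{S0,1}|^2 for steps 1..n."""
    c = traj.c_s01_sq
    if c is None or c.size < 1:
        raise ValueError("trajectory carries no |C_{S0,1}|^2 record")
    dts = np.diff(traj.t_fs)
    # hazard accumulated over (t_{i-1}, t_i], evaluated at the step start
    return (dts / tau_c_fs) * c[:-1]


def loss_resample(
    traj: Trajectory,
    settings: LossSettings,
    rng: np.random.Generator,
    traj_id: Optional[int] = None,
    replica: int = 0,
) -> ReplicaOutcome:
    """Draw one replica's loss history from a stored trajectory."""
    p = loss_probabilities(traj, settings.tau_c_fs)
    u = rng.random(p.size)
    hits = np.nonzero(u < p)[0]
    tid = traj.traj_id if traj_id is None else traj_id
    if hits.size == 0:
        return ReplicaOutcome(tid, replica, False, None, None)
    step = int(hits[0]) + 1
    return ReplicaOutcome(tid, replica, True, step, float(traj.t_fs[step]))


@dataclass
class LossEnsemble:
    """Replicated swarm with photon losses applied."""

    settings: LossSettings
    outcomes: List[ReplicaOutcome]
    t_fs: np.ndarray
    populations: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_replicas_total(self) -> int:
        return len(self.outcomes)

    def survival_fraction(self, t_fs: float) -> float:
        """Fraction of replicas not yet collapsed at time ``t_fs``."""
        n = len(self.outcomes)
        dead = sum(
            1 for o in self.outcomes
            if o.collapsed and o.time_fs is not None and o.time_fs <= t_fs
        )
        return 1.0 - dead / n

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# photon-loss populations; t in fs, populations are "
                f"fractions; tau_c = {self.settings.tau_c_fs} fs, "
                f"{self.settings.n_replicas} replicas/trajectory\n"
            )
            self.populations.to_csv(fh, index=False)


def ensemble_losses(
    ensemble: EnsembleResult,
    settings: LossSettings,
    trajectories: Optional[Sequence[Trajectory]] = None,
) -> LossEnsemble:
    """Apply the loss Monte Carlo to a whole (lossless) ensemble.

    Each trajectory spawns ``settings.n_replicas`` replicas with
    independent, deterministic random streams.  The populations table
    reports, on the common time grid:

    - ``pop_ground``: collapsed fraction plus the fraction of surviving
      replicas whose active polaritonic state is |S0,0>-dominant
      (|C_{S0,0}|^2 > 1/2),
    - ``pop_state{k}``: surviving fraction on each sorted polaritonic
      state k (aliases ``pop_minus`` = state 1, ``pop_plus`` = state 2),
    - ``pop_S00 .. pop_S11``: mean uncoupled-state weights of the active
      state; collapsed replicas count as pure |S0,0>.  The
      survivors-only accounting is emitted alongside with suffix
      ``_surv``.
    - ``n_surviving``: surviving replica count.
    """
    trajs = list(trajectories) if trajectories is not None \
        else [t for t in ensemble.trajectories if not t.failed]
    if not trajs:
        raise ValueError("no usable trajectories in ensemble")
    nt = min(t.t_fs.size for t in trajs)
    t_grid = trajs[0].t_fs[:nt]
    n_states = trajs[0].energies.shape[1]

    outcomes: List[ReplicaOutcome] = []
    # accumulators over replicas
    n_rep = len(trajs) * settings.n_replicas
    pop_state = np.zeros((nt, n_states))
    unc_all = np.zeros((nt, 4))
    unc_surv = np.zeros((nt, 4))
    ground = np.zeros(nt)
    surviving = np.zeros(nt)

    for traj in trajs:
        active = traj.active[:nt]
        char = traj.active_char[:nt]  # (nt, n_states) over uncoupled basis
        s00_dom = char[:, 0] > 0.5
        unc = char if char.shape[1] == 4 else None
        for r in range(settings.n_replicas):
            rng = replica_rng(settings, traj.traj_id, r)
            out = loss_resample(traj, settings, rng, replica=r)
            outcomes.append(out)
            cut = out.step if out.collapsed else nt
            cut = min(cut, nt)
            alive = np.zeros(nt, dtype=bool)
            alive[:cut] = True
            surviving += alive
            ground[:cut] += s00_dom[:cut]
            ground[cut:] += 1.0  # collapsed -> |S0,0> for all later times
            for k in range(n_states):
                pop_state[:cut, k] += active[:cut] == k
            if unc is not None:
                unc_all[:cut] += unc[:cut]
                unc_all[cut:, 0] += 1.0
                unc_surv[:cut] += unc[:cut]

    data = {"t_fs": t_grid, "pop_ground": ground / n_rep}
    for k in range(n_states):
        data[f"pop_state{k}"] = pop_state[:, k] / n_rep
    if n_states == 4:
        data["pop_minus"] = data["pop_state1"]
        data["pop_plus"] = data["pop_state2"]
        labels = ("S00", "S10", "S01", "S11")
        for i, lab in enumerate(labels):
            data[f"pop_{lab}"] = unc_all[:, i] / n_rep
        with np.errstate(invalid="ignore", divide="ignore"):
            surv_safe = np.where(surviving > 0, surviving, 1.0)
            for i, lab in enumerate(labels):
                data[f"pop_{lab}_surv"] = np.where(
                    surviving > 0, unc_surv[:, i] / surv_safe, np.nan
                )
    data["n_surviving"] = surviving.astype(int)
    populations = pd.DataFrame(data)

    return LossEnsemble(
        settings=settings,
        outcomes=outcomes,
        t_fs=t_grid,
        populations=populations,
        meta={"n_trajectories": len(trajs)},
    )
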