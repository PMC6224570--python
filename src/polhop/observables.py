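"""Ensemble analysis: populations, quantum yield, oscillation coordinate."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dynamics import EnsembleResult
from .electronic_models import classify_isomer
from .units import DEG_PER_RAD

__all__ = [
    "population_series",
    "quantum_yield",
    "YieldResult",
    "oscillation_coordinate",
    "OscillationResult",
    "ground_state_population",
    "onset_time",
]

_UNCOUPLED_LABELS_4 = ("S00", "S10", "S01", "S11")


def _usable(ensemble: EnsembleResult, include_failed: bool):
    trajs = ensemble.trajectories if include_failed else [
        t for t in ensemble.trajectories if not t.failed
    ]
    if not trajs:
        raise ValueError("ensemble contains no usable trajectories")
    nt = min(t.t_fs.size for t in trajs)
    return trajs, nt


def population_series(
    ensemble: EnsembleResult, include_failed: bool = False
) -> pd.DataFrame:
    """Polaritonic and uncoupled-state populations versus time.

    Polaritonic population of state G = fraction of trajectories whose
    active state is G.  Uncoupled populations are reported twice: from
    the active state's composition (``unc_*``, mean |C_i(active)|^2,
    the quantity the loss model uses) and from the full amplitude
    vector (``amp_*``, mean |sum_G C_iG A_G|^2).
    """
    trajs, nt = _usable(ensemble, include_failed)
    n_states = trajs[0].energies.shape[1]
    n = len(trajs)
    pol = np.zeros((nt, n_states))
    unc = np.zeros((nt, n_states))
    amp = np.zeros((nt, n_states))
    for t in trajs:
        for k in range(n_states):
            pol[:, k] += t.active[:nt] == k
        unc += t.active_char[:nt]
        amp += t.amp_char[:nt]
    pol /= n
    unc /= n
    amp /= n
    data = {"t_fs": trajs[0].t_fs[:nt]}
    labels = (
        _UNCOUPLED_LABELS_4 if n_states == 4
        else tuple(f"S{i}" for i in range(n_states))
    )
    for k in range(n_states):
        data[f"pol_{k}"] = pol[:, k]
    for k, lab in enumerate(labels):
        data[f"unc_{lab}"] = unc[:, k]
    for k, lab in enumerate(labels):
        data[f"amp_{lab}"] = amp[:, k]
    return pd.DataFrame(data)


def ground_state_population(
    ensemble: EnsembleResult, include_failed: bool = False
) -> pd.DataFrame:
    """Electronic ground-state population (S0 character of the active
    state, summed over photon occupations) versus time."""
    trajs, nt = _usable(ensemble, include_failed)
    n_states = trajs[0].energies.shape[1]
    pop = np.zeros(nt)
    for t in trajs:
        if n_states == 4:
            pop += t.active_char[:nt, 0] + t.active_char[:nt, 2]
        else:
            pop += t.active_char[:nt, 0]
    return pd.DataFrame(
        {"t_fs": trajs[0].t_fs[:nt], "pop_s0": pop / len(trajs)}
    )


def onset_time(t_fs: np.ndarray, series: np.ndarray, level: float
               ) -> Optional[float]:
    """First time the series reaches ``level`` (None if never)."""
    idx = np.nonzero(np.asarray(series) >= level)[0]
    if idx.size == 0:
        return None
    return float(t_fs[idx[0]])


@dataclass
class YieldResult:
    """Photoisomerization quantum yield with bookkeeping.

    ``yield_frac`` counts trajectories that both reached the lowest
    polaritonic (ground) state and ended in the cis region, over all
    counted trajectories; still-excited trajectories are non-reactive
    and reported separately.
    """

    yield_frac: float
    stderr: float
    n_total: int
    n_cis_ground: int
    n_trans_ground: int
    n_excited: int
    n_failed: int = 0
    meta: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "yield": self.yield_frac,
            "stderr": self.stderr,
            "n_total": self.n_total,
            "n_cis_ground": self.n_cis_ground,
            "n_trans_ground": self.n_trans_ground,
            "n_excited": self.n_excited,
            "n_failed": self.n_failed,
            **self.meta,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def quantum_yield(ensemble: EnsembleResult) -> YieldResult:
    """Fraction of trajectories ending as the cis photoproduct.

    A trajectory is reactive if its final active state is the lowest
    polaritonic state (index 0) *and* its final torsion classifies as
    cis.  Trajectories still electronically/polaritonically excited at
    the end of the run count as non-reactive.
    """
    trajs = [t for t in ensemble.trajectories if not t.failed]
    n_failed = len(ensemble.trajectories) - len(trajs)
    if not trajs:
        raise ValueError("ensemble contains no usable trajectories")
    n_cis = n_trans = n_exc = 0
    for t in trajs:
        if t.active[-1] != 0:
            n_exc += 1
        elif classify_isomer(t.coords[-1]) == "cis":
            n_cis += 1
        else:
            n_trans += 1
    n = len(trajs)
    y = n_cis / n
    stderr = math.sqrt(y * (1.0 - y) / n)
    return YieldResult(
        yield_frac=y, stderr=stderr, n_total=n,
        n_cis_ground=n_cis, n_trans_ground=n_trans, n_excited=n_exc,
        n_failed=n_failed,
    )


@dataclass
class OscillationResult:
    """Averaged coordinate series over the oscillating sub-ensemble."""

    table: pd.DataFrame  # t_fs + mean coordinates (degrees for angles)
    n_selected: int
    traj_ids: list

    @property
    def empty(self) -> bool:
        return self.n_selected == 0


def oscillation_coordinate(
    ensemble: EnsembleResult,
    min_hops: int = 2,
    between: tuple = (1, 2),
) -> OscillationResult:
    """Mean coordinates over trajectories flagged as oscillating.

    A trajectory oscillates if it logged at least ``min_hops`` accepted
    hops between the two polaritonic states in ``between`` (default:
    the |->/|+> pair, sorted indices 1 and 2).  An empty selection is
    returned explicitly (``empty`` flag), never as silent zeros.
    """
    trajs, nt = _usable(ensemble, include_failed=False)
    selected = [
        t for t in trajs if t.accepted_hops(between=between) >= min_hops
    ]
    if not selected:
        return OscillationResult(
            table=pd.DataFrame(), n_selected=0, traj_ids=[]
        )
    nt = min(t.t_fs.size for t in selected)
    d = selected[0].coords.shape[1]
    mean = np.zeros((nt, d))
    for t in selected:
        mean += t.coords[:nt]
    mean /= len(selected)
    data = {"t_fs": selected[0].t_fs[:nt]}
    names = ["theta_deg", "alpha_deg"] if d == 2 else [
        f"q{k}" for k in range(d)
    ]
    for k, name in enumerate(names):
        col = mean[:, k]
        if name.endswith("_deg"):
            col = col * DEG_PER_RAD
        data[name] = col
    return OscillationResult(
        table=pd.DataFrame(data),
        n_selected=len(selected),
        traj_ids=[t.traj_id for t in selected],
    )
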