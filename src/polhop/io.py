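"""Readers/writers for phase points, trajectories and ensembles."""

from __future__ import annotations

from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .dynamics import EnsembleResult, HopEvent, SimulationSettings, Trajectory
from .initial_conditions import PhaseSpacePoint
from .units import DEG_PER_RAD, RAD_PER_DEG

__all__ = [
    "write_phase_points_csv",
    "read_phase_points_csv",
    "write_populations_csv",
    "save_ensemble",
    "load_ensemble",
    "write_trajectory_csv",
]


def write_phase_points_csv(points: List[PhaseSpacePoint], path) -> None:
    """Phase points as CSV (angles in degrees, momenta in au)."""
    d = points[0].coords.size
    if d == 2:
        cols = ["theta_deg", "alpha_deg", "p_theta", "p_alpha"]
    else:
        cols = [f"q{k}" for k in range(d)] + [f"p{k}" for k in range(d)]
    rows = []
    for pt in points:
        coords = pt.coords * DEG_PER_RAD if d == 2 else pt.coords
        rows.append(list(coords) + list(pt.momenta))
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        fh.write("# sampled ground-state phase points; angles deg, momenta au\n")
        df.to_csv(fh, index=False)


def read_phase_points_csv(path) -> List[PhaseSpacePoint]:
    df = pd.read_csv(path, comment="#")
    cols = list(df.columns)
    d = len(cols) // 2
    pts = []
    angular = cols[0].endswith("_deg")
    for _, row in df.iterrows():
        coords = row.iloc[:d].to_numpy(dtype=float)
        if angular:
            coords = coords * RAD_PER_DEG
        momenta = row.iloc[d:].to_numpy(dtype=float)
        pts.append(PhaseSpacePoint(coords, momenta))
    return pts


def write_populations_csv(df: pd.DataFrame, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write("# populations vs time; t in fs, populations are fractions\n")
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, index=False)


def write_trajectory_csv(traj: Trajectory, path) -> None:
    df = traj.to_dataframe()
    with open(path, "w") as fh:
        fh.write(
            "# trajectory record; t in fs, coordinates rad/bohr, momenta au, "
            "energies eV\n"
        )
        df.to_csv(fh, index=False)


def save_ensemble(ensemble: EnsembleResult, path) -> None:
    """Serialize an ensemble to a single .npz archive (runtime artifact)."""
    payload = {}
    meta = {
        "n_traj": len(ensemble.trajectories),
        "settings": vars(ensemble.settings),
        "meta": ensemble.meta,
    }
    import json

    payload["__meta__"] = np.frombuffer(
        json.dumps(meta, default=str).encode(), dtype=np.uint8
    )
    for i, t in enumerate(ensemble.trajectories):
        p = f"t{i}_"
        payload[p + "t_fs"] = t.t_fs
        payload[p + "coords"] = t.coords
        payload[p + "momenta"] = t.momenta
        payload[p + "active"] = t.active
        payload[p + "energies"] = t.energies
        payload[p + "c_s01_sq"] = t.c_s01_sq
        payload[p + "active_char"] = t.active_char
        payload[p + "amp_char"] = t.amp_char
        if t.A is not None:
            payload[p + "A"] = t.A
        payload[p + "hops"] = np.array(
            [
                (h.step, h.t_fs, h.source, h.target, int(h.accepted))
                for h in t.hops
            ],
            dtype=float,
        ).reshape(-1, 5)
        payload[p + "flags"] = np.array(
            [int(t.failed), t.traj_id, t.dt_fs], dtype=float
        )
    np.savez_compressed(path, **payload)


def load_ensemble(path) -> EnsembleResult:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        n = meta["n_traj"]
        settings_raw = dict(meta["settings"])
        for key in ("dt_fs", "decoherence_alpha", "energy_drift_tol_ev"):
            if key in settings_raw:
                settings_raw[key] = float(settings_raw[key])
        for key in ("n_steps", "rng_seed"):
            if key in settings_raw:
                settings_raw[key] = int(settings_raw[key])
        if "store_amplitudes" in settings_raw:
            settings_raw["store_amplitudes"] = (
                str(settings_raw["store_amplitudes"]) in ("True", "true", "1")
            )
        settings = SimulationSettings(**settings_raw)
        trajectories = []
        for i in range(n):
            p = f"t{i}_"
            hops = [
                HopEvent(int(h[0]), float(h[1]), int(h[2]), int(h[3]),
                         bool(h[4]))
                for h in data[p + "hops"]
            ]
            flags = data[p + "flags"]
            trajectories.append(
                Trajectory(
                    t_fs=data[p + "t_fs"],
                    coords=data[p + "coords"],
                    momenta=data[p + "momenta"],
                    active=data[p + "active"].astype(np.int64),
                    energies=data[p + "energies"],
                    c_s01_sq=data[p + "c_s01_sq"],
                    active_char=data[p + "active_char"],
                    amp_char=data[p + "amp_char"],
                    A=data[p + "A"] if (p + "A") in data.files else None,
                    hops=hops,
                    failed=bool(flags[0]),
                    traj_id=int(flags[1]),
                    dt_fs=float(flags[2]),
                )
            )
    return EnsembleResult(
        trajectories=trajectories, settings=settings,
        meta=meta.get("meta", {}),
    )
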