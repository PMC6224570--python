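"""Run configuration: TOML/JSON loading, validation, lossless round-trip.

Interface units are fixed here: photon energy in eV, coupling constant
and dipoles in au, times in fs, angles in degrees, temperature in K.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional

from .cavity_losses import LossSettings
from .dynamics import SimulationSettings
from .electronic_models import MODEL_REGISTRY, get_model
from .initial_conditions import ThermalSamplingSettings
from .polariton import CavityMode

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid configuration; message lists the offending keys."""


def _build(cls, section: dict, where: str):
    import inspect

    allowed = set(inspect.signature(cls).parameters)
    bad = sorted(set(section) - allowed)
    if bad:
        raise ConfigError(f"unknown keys in [{where}]: {bad}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{where}] section: {exc}") from exc


@dataclass
class CavityConfig:
    photon_energy_ev: float = 1.3
    g_au: float = 0.010
    polarization: List[float] = field(default_factory=lambda: [0.0, 0.0, 1.0])

    def build(self) -> CavityMode:
        return CavityMode.from_ev(
            self.photon_energy_ev, self.g_au, self.polarization
        )


@dataclass
class ModelConfig:
    name: str = "azo2d"
    params: dict = field(default_factory=dict)

    def build(self):
        if self.name not in MODEL_REGISTRY:
            raise ConfigError(
                f"unknown model {self.name!r}; available: "
                f"{sorted(MODEL_REGISTRY)}"
            )
        return get_model(self.name, **self.params)


@dataclass
class LossConfig:
    lifetimes_fs: List[float] = field(default_factory=lambda: [10.0, 50.0, 100.0])
    n_replicas: int = 5
    rng_seed: int = 0

    def build(self) -> List[LossSettings]:
        return [
            LossSettings(tau_c_fs=tau, n_replicas=self.n_replicas,
                         rng_seed=self.rng_seed)
            for tau in self.lifetimes_fs
        ]


@dataclass
class RunConfig:
    """Fully resolved configuration of a simulation campaign."""

    model: ModelConfig = field(default_factory=ModelConfig)
    cavity: CavityConfig = field(default_factory=CavityConfig)
    sampling: ThermalSamplingSettings = field(
        default_factory=ThermalSamplingSettings
    )
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    losses: LossConfig = field(default_factory=LossConfig)
    n_trajectories: int = 300
    seed: int = 0
    output_dir: str = "polhop_out"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        known = {
            "model", "cavity", "sampling", "simulation", "losses",
            "n_trajectories", "seed", "output_dir",
        }
        bad = sorted(set(raw) - known)
        if bad:
            raise ConfigError(f"unknown top-level keys: {bad}")
        cfg = cls(
            model=_build(ModelConfig, raw.get("model", {}), "model"),
            cavity=_build(CavityConfig, raw.get("cavity", {}), "cavity"),
            sampling=_build(
                ThermalSamplingSettings, raw.get("sampling", {}), "sampling"
            ),
            simulation=_build(
                SimulationSettings, raw.get("simulation", {}), "simulation"
            ),
            losses=_build(LossConfig, raw.get("losses", {}), "losses"),
            n_trajectories=int(raw.get("n_trajectories", 300)),
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "polhop_out")),
        )
        if cfg.n_trajectories < 1:
            raise ConfigError("n_trajectories must be >= 1")
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def write_resolved(self, path) -> None:
        """Write the fully resolved configuration next to the outputs."""
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    # convenience builders -------------------------------------------------
    def build_model(self):
        return self.model.build()

    def build_cavity(self) -> CavityMode:
        return self.cavity.build()


def load_config(path) -> RunConfig:
    """Load a TOML (or JSON) configuration file."""
    path = Path(path)
    text = path.read_bytes()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        import tomllib

        try:
            raw = tomllib.loads(text.decode())
        except tomllib.TOMLDecodeError:
            # accept JSON content regardless of extension
            try:
                raw = json.loads(text)
            except json.JSONDecodeError:
                raise ConfigError(f"{path} is neither valid TOML nor JSON")
    return RunConfig.from_dict(raw)
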