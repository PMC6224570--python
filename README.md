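# polhop

Surface-hopping photochemistry of a single molecule strongly coupled to
one quantized cavity mode.

The package builds *polaritonic* potential energy surfaces from a
two-state molecular model plus a single photon mode (extended
Jaynes–Cummings Hamiltonian with counter-rotating terms, photon basis
truncated at one quantum), propagates fewest-switches surface-hopping
(FSSH) trajectory swarms on them — velocity-Verlet nuclei,
local-diabatization (LD) integration of the electronic/photonic
amplitudes, energy-based decoherence correction — and post-processes the
stored swarms with a stochastic photon-loss Monte Carlo that collapses
trajectories to the ground state at a rate set by the cavity lifetime.

Two analytic molecular models ship with the package:

- **`azo2d`** — a 2-D azobenzene-like photoswitch surrogate in a torsion
  (`theta`, trans at 180°) and a bend (`alpha`) coordinate: a
  ground-state trans/cis double well, an excited state descending to a
  twisted conical intersection at `theta = 90°`, a bend-modulated gap,
  and an out-of-plane transition dipole vanishing at planar geometries
  (which produces a *polaritonic* conical intersection for out-of-plane
  field polarization).
- **`curve1d`** — 1-D avoided-crossing models (tanh diabats, constant
  coupling) for validation against the Landau–Zener closed form and
  exact grid-based wavepacket propagation (split-operator oracle in
  `polhop.oracle`).

## Command line

All commands take a TOML (or JSON) configuration and an output
directory; interface units are eV (energies), au (coupling constant g
and dipoles), fs (times), degrees (angles).  Every run writes the fully
resolved configuration next to its outputs.

```bash
polhop sample  -c config.toml -o out/   # thermostatted ground-state sampling
polhop run     -c config.toml -o out/   # vertical excitation + FSSH ensemble
polhop losses  -c config.toml -o out/   # photon-loss sweep (one CSV per tau_c)
polhop analyze -c config.toml -o out/   # populations, quantum yield, oscillation
polhop scan    -c config.toml -o out/   # polaritonic PES maps + minimum gap
polhop oracle  -c config.toml -o out/   # 1-D exact-vs-FSSH validation
```

A minimal configuration:

```toml
seed = 1
n_trajectories = 300

[model]
name = "azo2d"

[cavity]
photon_energy_ev = 1.3
g_au = 0.010
polarization = [0.0, 0.0, 1.0]

[simulation]
dt_fs = 0.25
n_steps = 2400

[losses]
lifetimes_fs = [10.0, 50.0, 100.0]
n_replicas = 5
```

## Library sketch

```python
from polhop import Azo2D, CavityMode
from polhop.dynamics import PolaritonicSurface, SimulationSettings, run_ensemble
from polhop.initial_conditions import (ThermalSamplingSettings,
                                       select_initial_points,
                                       thermal_sample, vertical_excite)
from polhop.observables import population_series, quantum_yield
from polhop.cavity_losses import LossSettings, ensemble_losses

model = Azo2D()
cavity = CavityMode.from_ev(1.3, 0.010)            # E_ph, g, z-polarized
points = select_initial_points(
    thermal_sample(model, ThermalSamplingSettings(rng_seed=11)), 300)
surface = PolaritonicSurface(model, cavity)
inits = [vertical_excite(p, model, cavity, surface) for p in points]
ens = run_ensemble(surface, inits,
                   SimulationSettings(dt_fs=0.25, n_steps=2400, rng_seed=5))
print(quantum_yield(ens).yield_frac)
losses = ensemble_losses(ens, LossSettings(tau_c_fs=50.0, n_replicas=5))
```

## Acceptance

`tests/test_acceptance.py` implements the acceptance criteria
(eigen-oracle, Rabi-splitting law, polaritonic conical intersection,
bitwise zero-coupling reduction to photon-free FSSH, conservation
suite, FSSH internal consistency, agreement with exact wavepacket
dynamics, thermostat statistics, photon-loss statistics, and the
mechanistic trends of the strongly coupled photoswitch: sustained
polariton population oscillations, quantum-yield ordering across
coupling conditions, early ground-state retrieval, and oscillatory
retrieval under losses).

`scripts/acceptance.py --seed <int> --out <path>` runs a fast
end-to-end self-check and writes the (empty) numeric-target report;
there are no quantitative literature targets reproducible at desk
scale, so all acceptance is test-based.
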