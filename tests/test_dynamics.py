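import math

import numpy as np
import pytest

from polhop.dynamics import (
    BareElectronicSurface,
    PolaritonicSurface,
    PropagationError,
    SimulationSettings,
    apply_decoherence,
    fssh_step,
    initial_state,
    ld_propagate,
    lowdin_orthonormalize,
    run_ensemble,
    run_trajectory,
    trajectory_rng,
    vv_step,
)
from polhop.electronic_models import Curve1D, TwoStateDiabaticModel
from polhop.polariton import (
    CavityMode,
    build_hamiltonian,
    solve_polaritons,
)
from polhop.units import AU_PER_FS, EV_PER_HARTREE, HARTREE_PER_EV

from conftest import lz_diabatic_survival, make_lz_model, random_geometries


class FlatModel(TwoStateDiabaticModel):
    """Constant surfaces: zero gradient everywhere."""

    name = "flat"

    def __init__(self, mass=2000.0):
        self.inertias = np.array([mass])

    def reference_geometry(self):
        return self.make_geometry([0.0])

    def diabats(self, q):
        z = np.zeros(1)
        return 0.0, 0.1, 0.0, z, z, z

    def dipole(self, q):
        return np.array([0.0, 0.0, 1.0]), np.zeros((3, 1))


class HarmonicModel(TwoStateDiabaticModel):
    """Uncoupled harmonic surfaces (analytic oracle available)."""

    name = "harmonic"

    def __init__(self, k=0.005, mass=2000.0):
        self.k = k
        self.inertias = np.array([mass])

    def reference_geometry(self):
        return self.make_geometry([0.0])

    def diabats(self, q):
        x = q[0]
        h = 0.5 * self.k * x * x
        grad = np.array([self.k * x])
        return h, h + 0.2, 0.0, grad, grad, np.zeros(1)

    def dipole(self, q):
        return np.array([0.0, 0.0, 1.0]), np.zeros((3, 1))


def off_cavity():
    return CavityMode(omega=5.0 * HARTREE_PER_EV, g=0.0,
                      lam=np.array([0.0, 0.0, 1.0]))


class TestVVStep:
    def test_flat_surface_uniform_motion(self):
        model = FlatModel()
        surf = BareElectronicSurface(model)
        st = initial_state(surf, [0.0], [10.0], model.inertias, 0)
        dt = 0.1 * AU_PER_FS
        for _ in range(100):
            st = vv_step(st, surf, dt)
        assert st.coords[0] == pytest.approx(10.0 / 2000.0 * 100 * dt, rel=1e-12)
        assert st.momenta[0] == 10.0

    def test_harmonic_energy_conservation(self):
        model = HarmonicModel()
        surf = BareElectronicSurface(model)
        st = initial_state(surf, [1.0], [0.0], model.inertias, 0)
        dt = 0.1 * AU_PER_FS
        e0 = st.total_energy()
        prev = e0
        for _ in range(2000):
            st = vv_step(st, surf, dt)
            e = st.total_energy()
            assert abs(e - prev) < 1e-9  # per-step
            prev = e
        assert abs(st.total_energy() - e0) < 1e-7

    def test_harmonic_analytic_trajectory(self):
        model = HarmonicModel()
        surf = BareElectronicSurface(model)
        x0 = 0.8
        st = initial_state(surf, [x0], [0.0], model.inertias, 0)
        dt = 0.05 * AU_PER_FS
        omega = math.sqrt(model.k / model.inertias[0])
        n = 3000
        for _ in range(n):
            st = vv_step(st, surf, dt)
        assert st.coords[0] == pytest.approx(
            x0 * math.cos(omega * n * dt), abs=2e-3
        )

    def test_time_reversal(self, azo, cavity_13):
        surf = PolaritonicSurface(azo, cavity_13)
        st = initial_state(
            surf, [2.8, 2.0], [5.0, -3.0], azo.inertias, 2
        )
        dt = 0.1 * AU_PER_FS
        n = 200
        fwd = st
        for _ in range(n):
            fwd = vv_step(fwd, surf, dt)
        back = fwd
        back.momenta = -back.momenta
        back.force = None
        for _ in range(n):
            back = vv_step(back, surf, dt)
        np.testing.assert_allclose(back.coords, st.coords, atol=1e-8)
        np.testing.assert_allclose(back.momenta, -st.momenta, atol=1e-8)


class TestLowdin:
    def test_orthonormalizes(self, rng):
        base = np.linalg.qr(rng.standard_normal((4, 4)))[0]
        s = base + 1e-4 * rng.standard_normal((4, 4))
        t = lowdin_orthonormalize(s)
        np.testing.assert_allclose(t.T @ t, np.eye(4), atol=1e-12)

    def test_singular_overlap_raises(self):
        s = np.zeros((4, 4))
        s[0, 0] = 1.0
        with pytest.raises(PropagationError):
            lowdin_orthonormalize(s)


class TestLDPropagate:
    def _sols(self, azo, cavity, qa, qb):
        sa = solve_polaritons(build_hamiltonian(azo.evaluate(qa), cavity))
        sb = solve_polaritons(
            build_hamiltonian(azo.evaluate(qb), cavity), previous=sa
        )
        return sa, sb

    def test_adiabatic_limit_pure_phases(self, azo, cavity_13):
        q = np.array([2.5, 2.0])
        sa, _ = self._sols(azo, cavity_13, q, q)
        a = np.array([0.5, 0.5, 0.5, 0.5], dtype=complex)
        dt = 4.0
        a_new, u = ld_propagate(a, sa, sa, np.eye(2), dt)
        expected = np.exp(-1j * sa.energies * dt) * a
        np.testing.assert_allclose(a_new, expected, atol=1e-12)

    def test_diabatic_limit_population_swap(self, azo, cavity_13):
        """A sudden electronic character swap permutes the amplitude
        magnitudes (populations follow the diabats)."""
        q = np.array([2.5, 2.0])
        sa, _ = self._sols(azo, cavity_13, q, q)
        swap = np.array([[0.0, -1.0], [1.0, 0.0]])  # delta-phi = 90 deg
        a = np.array([1.0, 0.0, 0.0, 0.0], dtype=complex)
        a_new, u = ld_propagate(a, sa, sa, swap, 1.0)
        probs = np.abs(a_new) ** 2
        assert probs[0] == pytest.approx(0.0, abs=1e-12)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unitarity_and_substepping_oracle(self, azo, cavity_13, rng):
        """U is unitary to 1e-10 and one LD step agrees with a 100x
        finer integration along the interpolated path to 1e-6."""
        qa = np.array([2.6, 2.0])
        qb = np.array([2.597, 2.0018])
        sa, sb = self._sols(azo, cavity_13, qa, qb)
        s_el = azo.electronic_overlap(qa, qb)
        a = rng.standard_normal(4) + 1j * rng.standard_normal(4)
        a /= np.linalg.norm(a)
        dt = 0.03 * AU_PER_FS
        a_one, u = ld_propagate(a, sa, sb, s_el, dt)
        np.testing.assert_allclose(
            u.conj().T @ u, np.eye(4), atol=1e-10
        )
        assert np.sum(np.abs(a_one) ** 2) == pytest.approx(1.0, abs=1e-10)
        # fine-grained oracle: 100 substeps along linear interpolation
        n_sub = 100
        a_fine = a.copy()
        prev = solve_polaritons(build_hamiltonian(azo.evaluate(qa), cavity_13))
        q_prev = qa
        for i in range(1, n_sub + 1):
            q_i = qa + (qb - qa) * (i / n_sub)
            sol_i = solve_polaritons(
                build_hamiltonian(azo.evaluate(q_i), cavity_13), previous=prev
            )
            s_i = azo.electronic_overlap(q_prev, q_i)
            a_fine, _ = ld_propagate(a_fine, prev, sol_i, s_i, dt / n_sub)
            prev, q_prev = sol_i, q_i
        np.testing.assert_allclose(
            np.abs(a_one) ** 2, np.abs(a_fine) ** 2, atol=1e-6
        )


class TestFsshStep:
    def _energetics(self):
        return dict(
            momenta=np.array([20.0]),
            inertias=np.array([2000.0]),
            energies=np.array([0.0, 0.05, 0.08, 0.12]),
        )

    def test_identity_propagator_no_hop(self, rng):
        a = np.array([0.6, 0.8, 0.0, 0.0], dtype=complex)
        out = fssh_step(a, a, np.eye(4), 1, rng, **self._energetics())
        assert out.p_leave == 0.0
        assert out.active == 1
        assert out.event is None

    def test_complete_transfer_forces_hop(self, rng):
        a0 = np.array([0.0, 1.0, 0.0, 0.0], dtype=complex)
        a1 = np.array([1.0, 0.0, 0.0, 0.0], dtype=complex)
        u = np.eye(4)[[1, 0, 2, 3]]
        out = fssh_step(a0, a1, u, 1, rng, **self._energetics())
        assert out.p_leave == pytest.approx(1.0)
        assert out.active == 0
        assert out.event.accepted

    def test_empty_active_population_no_hop(self, rng):
        a0 = np.zeros(4, dtype=complex)
        a1 = np.zeros(4, dtype=complex)
        a0[0] = a1[0] = 1.0
        out = fssh_step(a0, a1, np.eye(4), 2, rng, **self._energetics())
        assert out.p_leave == 0.0

    def test_hop_conserves_total_energy(self, rng):
        en = self._energetics()
        a0 = np.array([0.0, 1.0, 0.0, 0.0], dtype=complex)
        a1 = np.array([0.0, 0.0, 1.0, 0.0], dtype=complex)
        u = np.eye(4)[[0, 2, 1, 3]]
        out = fssh_step(a0, a1, u, 1, rng, **en)
        assert out.active == 2
        ek_before = 0.5 * np.sum(en["momenta"] ** 2 / en["inertias"])
        ek_after = 0.5 * np.sum(out.momenta**2 / en["inertias"])
        e = en["energies"]
        assert ek_before + e[1] == pytest.approx(ek_after + e[2], abs=1e-14)

    def test_frustrated_hop(self, rng):
        en = self._energetics()
        en["momenta"] = np.array([2.0])  # E_kin = 1e-3 < dE = 0.07
        a0 = np.array([0.0, 1.0, 0.0, 0.0], dtype=complex)
        a1 = np.array([0.0, 0.0, 0.0, 1.0], dtype=complex)
        u = np.eye(4)[[0, 3, 2, 1]]
        out = fssh_step(a0, a1, u, 1, rng, **en)
        assert out.active == 1
        assert out.event is not None and not out.event.accepted
        np.testing.assert_array_equal(out.momenta, en["momenta"])


class TestDecoherence:
    def test_stated_formula_example(self):
        """dE=0.1, E_kin=0.05, alpha=0.1, dt=1 au -> damping exp(-1/30)."""
        a = np.array([1.0, 1.0], dtype=complex) / math.sqrt(2.0)
        out = apply_decoherence(
            a, active=1, energies=np.array([0.0, 0.1]),
            e_kin=0.05, dt=1.0, alpha=0.1,
        )
        assert abs(out[0]) / abs(a[0]) == pytest.approx(
            math.exp(-1.0 / 30.0), rel=1e-12
        )

    def test_alpha_zero_high_ekin_limit(self):
        a = np.array([1.0, 1.0], dtype=complex) / math.sqrt(2.0)
        de, dt = 0.2, 2.0
        out = apply_decoherence(
            a, active=1, energies=np.array([0.0, de]),
            e_kin=1e12, dt=dt, alpha=0.0,
        )
        assert abs(out[0]) / abs(a[0]) == pytest.approx(
            math.exp(-dt * de), rel=1e-9
        )

    def test_renormalization(self, rng):
        a = rng.standard_normal(4) + 1j * rng.standard_normal(4)
        a /= np.linalg.norm(a)
        out = apply_decoherence(
            a, active=2, energies=np.array([0.0, 0.05, 0.08, 0.2]),
            e_kin=0.01, dt=10.0, alpha=0.1,
        )
        assert np.sum(np.abs(out) ** 2) == pytest.approx(1.0, abs=1e-12)

    def test_zero_kinetic_energy_noop(self):
        a = np.array([0.6, 0.8], dtype=complex)
        out = apply_decoherence(
            a, active=1, energies=np.array([0.0, 0.1]),
            e_kin=0.0, dt=1.0, alpha=0.1,
        )
        np.testing.assert_array_equal(out, a)


class TestRunTrajectory:
    def test_landau_zener(self):
        """High-velocity passage through an avoided crossing: ensemble
        diabatic survival within 0.05 of the closed form."""
        slope, coupling, mass = 0.03, 0.004, 2000.0
        model = make_lz_model(slope, coupling, mass)
        surf = BareElectronicSurface(model)
        p0 = 30.0
        v = p0 / mass
        p_lz = lz_diabatic_survival(slope, coupling, v)
        settings = SimulationSettings(
            dt_fs=0.1, n_steps=220, decoherence="none", rng_seed=42,
        )
        # diabat 2 is the upper adiabat at x << 0 (h22 = +slope*|x|)
        n_traj, stay = 400, 0
        inits = [
            initial_state(surf, [-5.0], [p0], model.inertias, 1)
            for _ in range(n_traj)
        ]
        ens = run_ensemble(surf, inits, settings)
        for t in ens.trajectories:
            assert t.coords[-1, 0] > 3.0  # passed the crossing
            # diabat 2 on the right is the *lower* adiabat
            if t.active[-1] == 0:
                stay += 1
        assert stay / n_traj == pytest.approx(p_lz, abs=0.05)

    def test_microcanonical_conservation(self, azo, cavity_13):
        """Hop-free segment: |E(t) - E(0)| <= 1e-3 eV over 500 fs."""
        surf = PolaritonicSurface(azo, cavity_13)
        st = initial_state(
            surf, [math.pi - 0.12, azo.alpha0 + 0.05], [0.0, 0.0],
            azo.inertias, 0,
        )
        settings = SimulationSettings(
            dt_fs=0.1, n_steps=5000, decoherence="none", rng_seed=0,
        )
        traj = run_trajectory(surf, st, settings)
        assert not traj.failed
        assert not any(h.accepted for h in traj.hops)
        e_tot = (
            0.5 * np.sum(traj.momenta**2 / azo.inertias, axis=1)
            + traj.energies[np.arange(traj.t_fs.size), traj.active]
        )
        drift = np.max(np.abs(e_tot - e_tot[0])) * EV_PER_HARTREE
        assert drift <= 1e-3

    def test_norm_conservation(self, azo, cavity_13):
        surf = PolaritonicSurface(azo, cavity_13)
        st = initial_state(surf, [2.6, 2.1], [-20.0, 10.0], azo.inertias, 2)
        settings = SimulationSettings(dt_fs=0.1, n_steps=1000, rng_seed=1)
        traj = run_trajectory(surf, st, settings)
        norms = np.sum(np.abs(traj.A) ** 2, axis=1)
        assert np.max(np.abs(norms - 1.0)) < 1e-8

    def test_hop_bookkeeping_consistent(self, azo, cavity_13):
        """Active-state changes occur exactly at accepted hops."""
        surf = PolaritonicSurface(azo, cavity_13)
        st = initial_state(surf, [2.4, 2.0], [-30.0, 0.0], azo.inertias, 2)
        settings = SimulationSettings(dt_fs=0.1, n_steps=2000, rng_seed=7)
        traj = run_trajectory(surf, st, settings)
        changes = {
            i: (int(traj.active[i - 1]), int(traj.active[i]))
            for i in np.nonzero(np.diff(traj.active))[0] + 1
        }
        accepted = {
            h.step: (h.source, h.target) for h in traj.hops if h.accepted
        }
        assert changes == accepted

    def test_failed_trajectory_flagged(self, azo, cavity_13):
        surf = PolaritonicSurface(azo, cavity_13)
        st = initial_state(surf, [2.4, 2.0], [0.0, 0.0], azo.inertias, 2)
        settings = SimulationSettings(dt_fs=8.0, n_steps=200, rng_seed=0)
        traj = run_trajectory(surf, st, settings)
        assert traj.failed
        assert traj.t_fs.size < settings.n_steps + 1


class TestRunEnsemble:
    def _inits(self, surf, model, n):
        return [
            initial_state(surf, [2.5 + 0.01 * i, 2.0], [-10.0, 5.0],
                          model.inertias, 2)
            for i in range(n)
        ]

    def test_single_trajectory_ensemble(self, azo, cavity_13):
        surf = PolaritonicSurface(azo, cavity_13)
        settings = SimulationSettings(dt_fs=0.2, n_steps=100, rng_seed=9)
        inits = self._inits(surf, azo, 1)
        ens = run_ensemble(surf, inits, settings)
        solo = run_trajectory(
            surf, inits[0], settings, rng=trajectory_rng(9, 0), traj_id=0
        )
        np.testing.assert_array_equal(
            ens.trajectories[0].coords, solo.coords
        )
        np.testing.assert_array_equal(
            ens.trajectories[0].active, solo.active
        )

    def test_determinism(self, azo, cavity_13):
        surf = PolaritonicSurface(azo, cavity_13)
        settings = SimulationSettings(dt_fs=0.2, n_steps=150, rng_seed=3)
        a = run_ensemble(surf, self._inits(surf, azo, 4), settings)
        b = run_ensemble(surf, self._inits(surf, azo, 4), settings)
        for ta, tb in zip(a.trajectories, b.trajectories):
            np.testing.assert_array_equal(ta.coords, tb.coords)
            np.testing.assert_array_equal(ta.A, tb.A)

    def test_order_independence(self, azo, cavity_13, rng):
        surf = PolaritonicSurface(azo, cavity_13)
        settings = SimulationSettings(dt_fs=0.2, n_steps=150, rng_seed=3)
        inits = self._inits(surf, azo, 5)
        ref = run_ensemble(surf, inits, settings)
        perm = rng.permutation(5)
        shuffled = run_ensemble(
            surf, [inits[i] for i in perm], settings, ids=perm.tolist()
        )
        by_id = {t.traj_id: t for t in shuffled.trajectories}
        for t in ref.trajectories:
            np.testing.assert_array_equal(t.coords, by_id[t.traj_id].coords)
            np.testing.assert_array_equal(t.active, by_id[t.traj_id].active)

    def test_empty_inits_rejected(self, azo, cavity_13):
        surf = PolaritonicSurface(azo, cavity_13)
        with pytest.raises(ValueError):
            run_ensemble(surf, [], SimulationSettings(n_steps=1))
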