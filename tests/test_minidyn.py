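"""Toy dynamics engine: integrators, thermostat, virial consistency,
tensile protocol."""

import numpy as np
import pytest

from bonefiber.mechanics import StrainSchedule, VirialState, fit_young_modulus, virial_pressure
from bonefiber.minidyn import (
    SimState,
    ToyForceField,
    dump_frame,
    maxwell_boltzmann,
    pressure_tensor,
    run,
    run_tensile,
    step_langevin,
    step_nve,
    total_energy,
)
from bonefiber.testsystems import composite_modulus, spring_fiber
from bonefiber.units import AMU_A2_FS2_TO_KCAL_MOL


def lj_gas(n_side=4, spacing=5.0, temperature=100.0, seed=2):
    n = n_side**3
    grid = (
        np.stack(np.meshgrid(*[np.arange(n_side)] * 3, indexing="ij"), -1).reshape(-1, 3)
        * spacing
        + spacing / 2
    )
    masses = np.full(n, 40.0)
    rng = np.random.default_rng(seed)
    state = SimState(
        positions=grid.astype(float),
        velocities=maxwell_boltzmann(masses, temperature, rng),
        masses=masses,
        box=np.full(3, n_side * spacing),
        dt=1.0,
        friction=0.0,
    )
    ff = ToyForceField(
        bonds=np.empty((0, 2)),
        bond_k=[],
        bond_r0=[],
        lj_epsilon=np.full(n, 0.238),
        lj_sigma=np.full(n, 3.4),
        lj_cutoff=8.0,
    )
    return state, ff


class TestNVE:
    def test_free_particle_linear_motion(self):
        state = SimState(
            positions=[[0.0, 0, 0]], velocities=[[0.01, 0, 0]], masses=[10.0],
            box=[50.0, 50, 50], dt=1.0, friction=0.0,
        )
        ff = ToyForceField(bonds=np.empty((0, 2)), bond_k=[], bond_r0=[])
        for _ in range(100):
            step_nve(state, ff)
        np.testing.assert_allclose(state.positions[0], [1.0, 0, 0], atol=1e-12)

    def test_harmonic_dimer_period(self):
        k, m = 100.0, 1.0
        mu = m / 2
        omega = np.sqrt(k / AMU_A2_FS2_TO_KCAL_MOL / mu)
        period = 2 * np.pi / omega
        state = SimState(
            positions=[[0.0, 0, 0], [0.0, 0, 1.2]], velocities=np.zeros((2, 3)),
            masses=[m, m], box=[50.0, 50, 50], dt=period / 1000, friction=0.0,
        )
        ff = ToyForceField(bonds=[[0, 1]], bond_k=k, bond_r0=1.0)
        seps = []
        for _ in range(2500):
            step_nve(state, ff)
            seps.append(state.positions[1, 2] - state.positions[0, 2])
        seps = np.array(seps)
        maxima = np.flatnonzero((seps[1:-1] > seps[:-2]) & (seps[1:-1] > seps[2:])) + 1
        measured = np.diff(maxima).mean() * state.dt
        assert measured == pytest.approx(period, rel=1e-3)

    def test_lj_gas_energy_conservation(self):
        state, ff = lj_gas()
        e0 = total_energy(state, ff)
        for _ in range(100):
            step_nve(state, ff)
        assert abs(total_energy(state, ff) - e0) / abs(e0) < 1e-4

    def test_momentum_conserved(self):
        state, ff = lj_gas()
        p0 = (state.masses[:, None] * state.velocities).sum(axis=0)
        for _ in range(50):
            step_nve(state, ff)
        p1 = (state.masses[:, None] * state.velocities).sum(axis=0)
        np.testing.assert_allclose(p1, p0, atol=1e-10)


class TestLangevin:
    def test_equipartition_temperature(self):
        n = 200
        masses = np.full(n, 40.0)
        state = SimState(
            positions=np.random.default_rng(3).random((n, 3)) * 30,
            velocities=np.zeros((n, 3)),
            masses=masses, box=[30.0, 30, 30], dt=2.0,
            temperature=310.0, friction=0.02, rng=np.random.default_rng(7),
        )
        ff = ToyForceField(bonds=np.empty((0, 2)), bond_k=[], bond_r0=[])
        temps = []
        for i in range(5000):
            step_langevin(state, ff)
            if i > 1000 and i % 10 == 0:
                temps.append(state.kinetic_temperature())
        mean_t = np.mean(temps)
        # instantaneous T fluctuates with sd T·√(2/3N); samples correlate over
        # ~1/friction, leaving ~n_eff independent draws
        n_eff = len(temps) / 5
        se = 310.0 * np.sqrt(2.0 / (3 * n)) / np.sqrt(n_eff)
        assert abs(mean_t - 310.0) < 4 * se

    def test_zero_friction_reduces_to_nve(self):
        s1, ff = lj_gas()
        s2, _ = lj_gas()
        s2.friction = 0.0
        for _ in range(20):
            step_nve(s1, ff)
            step_langevin(s2, ff)
        np.testing.assert_allclose(s1.positions, s2.positions, atol=1e-12)

    def test_same_seed_identical_trajectory(self):
        def traj(seed):
            state, ff = lj_gas()
            state.friction = 0.02
            state.temperature = 100.0
            state.rng = np.random.default_rng(seed)
            for _ in range(30):
                step_langevin(state, ff)
            return state.positions.copy()

        np.testing.assert_array_equal(traj(9), traj(9))
        assert not np.array_equal(traj(9), traj(10))


class TestVirialConsistency:
    def test_internal_pressure_equals_mechanics_on_dumped_frame(self):
        state, ff = lj_gas()
        run(state, ff, 20, integrator="nve")
        frame = dump_frame(state, ff)
        vs = VirialState(
            masses=state.masses,
            velocities=frame.velocities,
            volume=state.volume,
            virial=frame.virial,
        )
        np.testing.assert_array_equal(
            pressure_tensor(state, ff), virial_pressure(vs)
        )

    def test_pressure_tensor_symmetric(self):
        state, ff = lj_gas()
        run(state, ff, 20, integrator="nve")
        P = pressure_tensor(state, ff)
        np.testing.assert_allclose(P, P.T, atol=1e-10)


class TestRunTensile:
    def test_spring_network_matches_closed_form(self):
        state, ff, e_closed = spring_fiber()
        schedule = StrainSchedule(L_z0=float(state.box[2]), rate=1e-4, duration=1500.0)
        series = run_tensile(state, ff, schedule, integrator="nve", output_every=5)
        fit = fit_young_modulus(series)
        assert fit.modulus == pytest.approx(e_closed, rel=0.02)

    def test_zero_rate_gives_zero_strains(self):
        state, ff, _ = spring_fiber(n_chains=4, n_beads=10)
        schedule = StrainSchedule(L_z0=float(state.box[2]), rate=0.0, duration=100.0)
        series = run_tensile(state, ff, schedule, integrator="nve", output_every=10)
        np.testing.assert_allclose(series.strain, 0.0, atol=1e-15)

    def test_zero_duration_rejected(self):
        state, ff, _ = spring_fiber(n_chains=4, n_beads=10)
        schedule = StrainSchedule(L_z0=float(state.box[2]), rate=1e-4, duration=0.0)
        with pytest.raises(ValueError, match="duration"):
            run_tensile(state, ff, schedule)

    def test_mineral_stiffens_fiber(self):
        # desk-scale analogue of mineral stiffening: one seed here, the
        # 5-seed comparison runs in the acceptance suite
        e_bare = composite_modulus(0.0, seed=0)
        e_mineral = composite_modulus(0.3, seed=0)
        assert e_mineral > e_bare

    def test_lateral_barostat_keeps_box_near_start(self):
        state, ff, _ = spring_fiber(n_chains=4, n_beads=10)
        schedule = StrainSchedule(L_z0=float(state.box[2]), rate=1e-4, duration=200.0)
        series = run_tensile(
            state, ff, schedule, integrator="nve", lateral_barostat=True,
            output_every=10,
        )
        assert len(series) == 20
        # weak coupling must not collapse the lateral box
        assert state.box[0] == pytest.approx(10.0, rel=0.05)
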