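"""Excitation directions, velocity kicks, Langevin relaxation and the
protocol schedulers."""

import numpy as np
import pytest

from mdenm import (
    DirectionBudgetError,
    ExcitationDirection,
    KB_KCAL,
    MDState,
    ProtocolConfig,
    displacement_rmsd,
    excite,
    generate_directions,
    kinetic_temperature,
    maxwell_boltzmann_velocities,
    relax,
    run_md,
    run_mdenm,
)
from mdenm.engine import _ca_indices

from conftest import make_diatomic


def scaled_config(**overrides):
    base = dict(
        n_replicas=4, n_excitations=4, relaxation_ps=1.0,
        md_replicas=2, md_length_ns=0.002, md_sample_every_ps=0.5,
        equilibration_ps=0.5, seed=0,
    )
    base.update(overrides)
    return ProtocolConfig(**base)


class TestProtocolArithmetic:
    def test_scaled_schedule_total(self):
        cfg = ProtocolConfig(n_replicas=2, n_excitations=3, relaxation_ps=4.0)
        assert cfg.total_excitation_time_ns == pytest.approx(0.024)

    def test_default_mdenm_total_is_48_ns(self):
        assert ProtocolConfig().total_excitation_time_ns == pytest.approx(48.0)

    def test_default_md_aggregate_is_600_ns(self):
        assert ProtocolConfig().md_aggregate_time_ns == pytest.approx(600.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ProtocolConfig(relaxation_ps=-1.0)


class TestGenerateDirections:
    def test_normalization_and_pairwise_filter(self, toy_receptor, toy_selected_modes):
        structure, _, _ = toy_receptor
        cfg = ProtocolConfig(seed=5, min_pairwise_rmsd=0.3)
        dirs = generate_directions(toy_selected_modes, structure, cfg, n=25)
        ca = _ca_indices(structure)
        assert len(dirs) == 25
        for d in dirs:
            assert displacement_rmsd(d.vector, ca) == pytest.approx(1.0, abs=1e-6)
        for i in range(len(dirs)):
            for j in range(i + 1, len(dirs)):
                sep = displacement_rmsd(dirs[i].vector - dirs[j].vector, ca)
                assert sep > 0.3

    def test_orthogonal_unit_rmsd_displacements_separate_by_sqrt2(self):
        """Two directions from orthogonal equal-mass modes at angle 90°:
        displaced-structure RMSD is sqrt(2 - 2 cos 90°) = sqrt(2)."""
        n = 8
        rng = np.random.default_rng(0)
        q = np.linalg.qr(rng.normal(size=(3 * n, 2)))[0]
        ca = np.arange(n)
        u = q[:, 0] / displacement_rmsd(q[:, 0], ca)
        v = q[:, 1] / displacement_rmsd(q[:, 1], ca)
        assert displacement_rmsd(u - v, ca) == pytest.approx(np.sqrt(2.0), abs=1e-9)

    def test_antiparallel_displacements_separate_by_two(self):
        n = 8
        rng = np.random.default_rng(1)
        u = rng.normal(size=3 * n)
        ca = np.arange(n)
        u /= displacement_rmsd(u, ca)
        assert displacement_rmsd(u - (-u), ca) == pytest.approx(2.0, abs=1e-9)

    def test_duplicate_direction_rejected_budget_error(self, toy_receptor, toy_selected_modes):
        structure, _, _ = toy_receptor
        # an impossible request in a 3-mode space exhausts the budget and
        # reports the achievable count
        cfg = ProtocolConfig(seed=2, min_pairwise_rmsd=1.9,
                             max_direction_attempts=500)
        with pytest.raises(DirectionBudgetError) as err:
            generate_directions(toy_selected_modes, structure, cfg, n=50)
        assert 0 < err.value.achieved < 50

    def test_deterministic_under_seed(self, toy_receptor, toy_selected_modes):
        structure, _, _ = toy_receptor
        cfg = ProtocolConfig(seed=11)
        a = generate_directions(toy_selected_modes, structure, cfg, n=5)
        b = generate_directions(toy_selected_modes, structure, cfg, n=5)
        for da, db in zip(a, b):
            assert np.array_equal(da.vector, db.vector)


class TestKineticTemperature:
    def test_zero_velocities(self):
        state = MDState(np.zeros(30), np.zeros(30))
        assert kinetic_temperature(state, np.full(10, 12.0)) == 0.0

    def test_maxwell_boltzmann_sampling(self):
        """Estimator applied to Maxwell-Boltzmann draws at 300 K: single
        draws land within the ~1-sigma sampling band, the mean much closer."""
        rng = np.random.default_rng(3)
        masses = np.full(500, 12.0)
        temps = []
        for _ in range(20):
            v = maxwell_boltzmann_velocities(masses, 300.0, rng)
            temps.append(kinetic_temperature(MDState(np.zeros(1500), v), masses))
        sigma = 300.0 * np.sqrt(2.0 / 1500.0)  # ~11 K for 1500 dof
        assert np.all(np.abs(np.array(temps) - 300.0) < 4 * sigma)
        assert np.mean(temps) == pytest.approx(300.0, abs=10.0)

    def test_doubling_speeds_quadruples_temperature(self):
        rng = np.random.default_rng(4)
        masses = np.full(50, 12.0)
        v = maxwell_boltzmann_velocities(masses, 250.0, rng)
        t1 = kinetic_temperature(MDState(np.zeros(150), v), masses)
        t2 = kinetic_temperature(MDState(np.zeros(150), 2 * v), masses)
        assert t2 == pytest.approx(4 * t1, rel=1e-12)


class TestExcite:
    def _direction(self, n_atoms, seed=0):
        rng = np.random.default_rng(seed)
        u = rng.normal(size=3 * n_atoms)
        u /= np.sqrt(np.mean(np.sum(u.reshape(-1, 3) ** 2, axis=1)))
        return ExcitationDirection(u, np.array([1.0]))

    def test_kick_from_rest_reaches_exactly_delta(self):
        masses = np.full(20, 12.0)
        state = MDState(np.zeros(60), np.zeros(60))
        out = excite(state, self._direction(20), 2.0, masses)
        assert kinetic_temperature(out, masses) == pytest.approx(2.0, abs=1e-12)

    def test_contract_plus_two_kelvin(self):
        rng = np.random.default_rng(5)
        masses = np.full(20, 12.0)
        v = maxwell_boltzmann_velocities(masses, 300.0, rng)
        state = MDState(np.zeros(60), v)
        pre = kinetic_temperature(state, masses)
        out = excite(state, self._direction(20, seed=1), 2.0, masses)
        assert kinetic_temperature(out, masses) == pytest.approx(pre + 2.0, abs=1e-9)

    def test_antiparallel_initial_velocity_single_particle(self):
        """One particle moving against the kick direction: the larger
        quadratic root still raises the temperature by delta."""
        m = np.array([12.0])
        u = np.zeros(3)
        u[0] = 1.0  # unit displacement-RMSD for a single atom
        d = ExcitationDirection(u, np.array([1.0]))
        v = np.array([-3.0, 0.0, 0.0])
        state = MDState(np.zeros(3), v)
        pre = kinetic_temperature(state, m)
        out = excite(state, d, 2.0, m)
        assert kinetic_temperature(out, m) == pytest.approx(pre + 2.0, abs=1e-9)
        # hand-solved quadratic: 0.5*m*l^2 + m*v*l - dKE = 0
        dke = 0.5 * 3 * KB_KCAL * 2.0 * 418.4
        lam = (-m[0] * v[0] + np.sqrt((m[0] * v[0]) ** 2 + 2 * m[0] * dke)) / m[0]
        assert out.velocities[0] == pytest.approx(v[0] + lam, rel=1e-12)

    def test_hundred_random_states_reproduce_delta(self, toy_receptor):
        structure, _, _ = toy_receptor
        masses = structure.masses
        rng = np.random.default_rng(6)
        d = self._direction(structure.n_atoms, seed=2)
        for _ in range(100):
            t_target = rng.uniform(10.0, 600.0)
            v = maxwell_boltzmann_velocities(masses, t_target, rng)
            state = MDState(structure.coords.copy(), v)
            pre = kinetic_temperature(state, masses)
            out = excite(state, d, 2.0, masses)
            assert kinetic_temperature(out, masses) == pytest.approx(
                pre + 2.0, abs=1e-9
            )

    def test_non_positive_delta_rejected(self):
        state = MDState(np.zeros(3), np.zeros(3))
        with pytest.raises(ValueError):
            excite(state, self._direction(1), 0.0, np.array([12.0]))


class TestRelax:
    def test_zero_temperature_stays_at_minimum(self, diatomic):
        s, pot = diatomic
        cfg = ProtocolConfig(bath_temperature=1e-12, seed=0)
        state = MDState(s.coords.copy(), np.zeros(6))
        rng = np.random.default_rng(0)
        out, _ = relax(state, pot, s.masses, 10.0, cfg, rng)
        assert np.allclose(out.coords, s.coords, atol=1e-6)

    def test_oscillator_equipartition(self, diatomic):
        """Time-averaged kinetic temperature of a harmonic oscillator under
        the thermostat matches the bath within 5%."""
        s, pot = diatomic
        cfg = ProtocolConfig(bath_temperature=300.0, seed=0)
        rng = np.random.default_rng(1)
        state = MDState(
            s.coords.copy(),
            maxwell_boltzmann_velocities(s.masses, 300.0, rng),
        )
        temps = []
        for _ in range(400):
            state, _ = relax(state, pot, s.masses, 1.0, cfg, rng)
            temps.append(kinetic_temperature(state, s.masses))
        assert np.mean(temps) == pytest.approx(300.0, rel=0.05)

    def test_energy_bounded_over_long_run(self, diatomic):
        s, pot = diatomic
        cfg = ProtocolConfig(bath_temperature=300.0, seed=0)
        rng = np.random.default_rng(2)
        state = MDState(s.coords.copy(), np.zeros(6))
        state, _ = relax(state, pot, s.masses, 2000.0, cfg, rng)  # 1e6 steps
        ke = kinetic_temperature(state, s.masses)
        assert np.all(np.isfinite(state.coords))
        assert pot.energy(state.coords) < 100.0
        assert ke < 1e4

    def test_dt_must_divide_duration(self, diatomic):
        s, pot = diatomic
        cfg = ProtocolConfig(dt_ps=0.002)
        with pytest.raises(ValueError, match="integer steps"):
            relax(MDState(s.coords, np.zeros(6)), pot, s.masses, 0.003,
                  cfg, np.random.default_rng(0))


class TestRunMD:
    def test_same_seed_reproduces_bitwise(self, small_receptor):
        s, _, pot = small_receptor
        cfg = scaled_config(seed=9)
        a = run_md(s, pot, cfg)
        b = run_md(s, pot, cfg)
        assert np.array_equal(a.frames, b.frames)

    def test_different_seeds_differ(self, small_receptor):
        s, _, pot = small_receptor
        a = run_md(s, pot, scaled_config(seed=1))
        b = run_md(s, pot, scaled_config(seed=2))
        assert not np.allclose(a.frames, b.frames)

    def test_frame_count_and_provenance(self, small_receptor):
        s, _, pot = small_receptor
        cfg = scaled_config(md_replicas=2, md_length_ns=0.002,
                            md_sample_every_ps=0.5)
        ens = run_md(s, pot, cfg)
        assert ens.n_frames == 2 * 4  # 2 ps per replica, every 0.5 ps
        assert set(ens.source) == {"MD"}
        assert set(ens.replica.tolist()) == {0, 1}


class TestRunMDeNM:
    def test_frames_per_replica_every_second_relaxation(self, small_receptor):
        s, _, pot = small_receptor
        from mdenm import compute_modes, select_modes
        from mdenm.enm import hessian

        modes = compute_modes(hessian(pot, s), s.masses)
        chosen = select_modes(modes, 300.0, 3)
        cfg = scaled_config(n_replicas=2, n_excitations=6, relaxation_ps=1.0)
        log = []
        ens = run_mdenm(s, pot, chosen, cfg, log=log)
        assert ens.n_frames == 2 * 3  # 6 excitations sampled every 2nd
        assert set(ens.source) == {"MDeNM"}
        assert len(log) == 2 * 6
        # every logged kick raised the kinetic temperature by delta_T
        for _, _, pre, post in log:
            assert post - pre == pytest.approx(cfg.delta_T, abs=1e-9)

    def test_reproducible_under_seed(self, small_receptor):
        s, _, pot = small_receptor
        from mdenm import compute_modes, select_modes
        from mdenm.enm import hessian

        modes = compute_modes(hessian(pot, s), s.masses)
        chosen = select_modes(modes, 300.0, 3)
        cfg = scaled_config(n_replicas=2, n_excitations=2)
        a = run_mdenm(s, pot, chosen, cfg)
        b = run_mdenm(s, pot, chosen, cfg)
        assert np.array_equal(a.frames, b.frames)
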