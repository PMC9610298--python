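"""MD engine: Maxwell initialisation, Verlet integration, thermostat,
energy fingerprints and force-field gradient checks."""

import numpy as np
import pytest
from scipy import stats

from chesar.forcefields import (
    DoubleWell2D,
    HarmonicWell,
    LennardJones,
    ShiftedField,
    ZeroField,
    numerical_gradient,
)
from chesar.md import (
    MDConfig,
    MDState,
    MolecularSystem,
    REDUCED,
    energy_fingerprint,
    instantaneous_temperature,
    maxwell_velocities,
    read_xyz,
    run_md,
    velocity_scaling,
    velocity_verlet_step,
    write_trajectory_xyz,
)


class TestMaxwellVelocities:
    def test_zero_temperature_is_at_rest(self):
        v = maxwell_velocities(np.ones(5), 0.0, rng=1)
        assert np.all(v == 0)

    def test_equipartition(self):
        masses = np.ones(1000)
        v = maxwell_velocities(masses, temperature=2.0, rng=42)
        ke_per_dof = 0.5 * np.sum(v**2) / (3 * 1000 - 3)
        assert ke_per_dof == pytest.approx(1.0, abs=0.05)  # k_B T / 2 with T=2

    def test_momentum_removed(self, rng):
        masses = rng.uniform(1, 20, size=30)
        v = maxwell_velocities(masses, temperature=5.0, rng=rng)
        momentum = (masses[:, None] * v).sum(axis=0)
        assert np.all(np.abs(momentum) < 1e-10)


class TestTemperature:
    def test_forced_arithmetic_two_particles(self):
        v = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        # KE = 1, N_dof = 3 -> T = 2/3
        assert instantaneous_temperature(v, np.ones(2)) == pytest.approx(2 / 3)

    def test_zero_velocities(self):
        assert instantaneous_temperature(np.zeros((4, 3)), np.ones(4)) == 0.0

    def test_single_particle_undefined(self):
        with pytest.raises(ValueError):
            instantaneous_temperature(np.ones((1, 3)), np.ones(1))

    def test_maxwell_draws_recover_target_temperature(self):
        masses = np.ones(500)
        t_star, temps = 3.0, []
        for seed in range(20):
            v = maxwell_velocities(masses, t_star, rng=seed)
            temps.append(instantaneous_temperature(v, masses))
        se = np.std(temps, ddof=1) / np.sqrt(len(temps))
        assert abs(np.mean(temps) - t_star) < 3 * se + 1e-12


class TestVelocityScaling:
    def test_factor_of_half_when_four_times_hotter(self):
        v = np.array([[2.0, 0, 0], [-2.0, 0, 0]])
        target = instantaneous_temperature(v, np.ones(2)) / 4
        scaled = velocity_scaling(v, np.ones(2), target)
        np.testing.assert_allclose(scaled, v * 0.5)

    def test_identity_and_exact_postcondition(self, rng):
        masses = rng.uniform(1, 5, size=8)
        v = rng.normal(size=(8, 3))
        t_now = instantaneous_temperature(v, masses)
        np.testing.assert_allclose(velocity_scaling(v, masses, t_now), v)
        scaled = velocity_scaling(v, masses, 7.3)
        assert instantaneous_temperature(scaled, masses) == pytest.approx(7.3, abs=1e-12)

    def test_cannot_heat_a_frozen_system(self):
        with pytest.raises(ValueError):
            velocity_scaling(np.zeros((3, 3)), np.ones(3), 1.0)


def harmonic_oscillator_state(x0=1.0):
    coords = np.array([[x0, 0.0, 0.0]])
    field = HarmonicWell(k=1.0)
    e, g = field.evaluate(coords)
    return MDState(coords, np.zeros((1, 3)), -g, e), field


class TestVelocityVerlet:
    def test_zero_force_gives_uniform_linear_motion(self):
        coords = np.zeros((2, 3))
        v = np.array([[1.0, 0, 0], [0, -2.0, 0]])
        state = MDState(coords, v, np.zeros((2, 3)), 0.0)
        field = ZeroField()
        dt = 0.1
        for _ in range(50):
            state = velocity_verlet_step(state, field, dt, np.ones(2))
        np.testing.assert_allclose(state.coordinates, v * 50 * dt, atol=1e-12)

    def test_harmonic_period_and_return_to_start(self):
        # analytic period 2*pi*sqrt(m/k) = 2*pi; integrate exactly one period
        state, field = harmonic_oscillator_state()
        dt = 2 * np.pi / 1000
        xs = [state.coordinates[0, 0]]
        for _ in range(1000):
            state = velocity_verlet_step(state, field, dt, np.ones(1))
            xs.append(state.coordinates[0, 0])
        assert state.coordinates[0, 0] == pytest.approx(1.0, abs=1e-3)
        assert abs(state.velocities[0, 0]) < 1e-2
        # measured period from the zero crossings of x(t)
        xs = np.array(xs)
        crossings = np.where(np.diff(np.sign(xs)) != 0)[0]
        half_period = (crossings[1] - crossings[0]) * dt
        assert 2 * half_period == pytest.approx(2 * np.pi, rel=1e-3)

    def test_energy_drift_is_second_order(self):
        def max_drift(dt, n_steps):
            state, field = harmonic_oscillator_state()
            e0 = state.potential_energy + 0.5 * np.sum(state.velocities**2)
            worst = 0.0
            for _ in range(n_steps):
                state = velocity_verlet_step(state, field, dt, np.ones(1))
                e = state.potential_energy + 0.5 * np.sum(state.velocities**2)
                worst = max(worst, abs(e - e0) / e0)
            return worst

        drift = max_drift(2 * np.pi / 1000, 10_000)
        assert drift < 1e-4
        assert max_drift(2 * np.pi / 2000, 10_000) < drift / 3  # ~4x for O(dt^2)

    def test_blowup_detection(self):
        state = MDState(
            np.array([[0.0, 0, 0], [1e-30, 0, 0]]),
            np.zeros((2, 3)),
            np.zeros((2, 3)),
            0.0,
        )
        overlapping = LennardJones()
        with pytest.raises(Exception, match="step"):
            s = state
            for _ in range(10):
                s = velocity_verlet_step(s, overlapping, 1.0, np.ones(2))


class TestRunMD:
    def trimer(self):
        return MolecularSystem(
            masses=np.ones(3),
            coordinates=np.array([[0.5, 0, 0], [-0.4, 0.3, 0], [0, -0.2, 0.4]]),
        )

    def config(self, **kw):
        defaults = dict(dt=0.01, n_steps=2000, t_init=0.8, thermostat_interval=1,
                        record_interval=10, seed=5, units=REDUCED)
        defaults.update(kw)
        return MDConfig(**defaults)

    def test_thermostat_holds_target_temperature(self):
        traj = run_md(self.trimer(), HarmonicWell(k=4.0), self.config(n_steps=10_000))
        last_half = traj.temperature[traj.n_frames // 2:]
        assert np.mean(last_half) == pytest.approx(0.8, rel=0.05)

    def test_same_seed_bit_identical(self):
        t1 = run_md(self.trimer(), HarmonicWell(), self.config())
        t2 = run_md(self.trimer(), HarmonicWell(), self.config())
        np.testing.assert_array_equal(t1.coordinates, t2.coordinates)
        np.testing.assert_array_equal(t1.potential_energy, t2.potential_energy)

    def test_frame_count_contract(self):
        traj = run_md(self.trimer(), HarmonicWell(), self.config(n_steps=100, record_interval=100))
        assert traj.n_frames == 2
        traj = run_md(self.trimer(), HarmonicWell(), self.config(n_steps=105, record_interval=10))
        assert traj.n_frames == 105 // 10 + 1

    def test_nve_conserves_energy(self):
        config = self.config(thermostat_interval=None, n_steps=5000, t_init=0.3, dt=0.005)
        traj = run_md(self.trimer(), HarmonicWell(), config)
        total = traj.potential_energy + traj.kinetic_energy
        assert np.max(np.abs(total - total[0])) / abs(total[0]) < 1e-4


class TestEnergyFingerprint:
    def test_constant_energies_give_zero_vector(self):
        fp = energy_fingerprint(np.full(100, 3.7), q=8)
        np.testing.assert_array_equal(fp.values, np.zeros(8))

    def test_uniform_grid_forced_quantiles(self):
        fp = energy_fingerprint(np.linspace(0.0, 100.0, 101), q=5)
        np.testing.assert_allclose(fp.values, [0, 25, 50, 75, 100])

    def test_exponential_sample_matches_inverse_cdf(self, rng):
        n, scale = 10_000, 2.0
        sample = rng.exponential(scale, size=n)
        fp = energy_fingerprint(sample, q=64)
        # interior quantiles against the exponential inverse CDF, within the
        # Kolmogorov-Smirnov band at n = 1e4
        ks_band = 1.36 / np.sqrt(n)
        ps = np.linspace(0, 1, 64)[1:-1]
        expected = stats.expon.ppf(ps, scale=scale) - sample.min()
        empirical_ps = stats.expon.cdf(fp.values[1:-1] + sample.min(), scale=scale)
        assert np.max(np.abs(empirical_ps - ps)) < ks_band

    def test_offset_invariance(self):
        system = MolecularSystem(masses=np.ones(2),
                                 coordinates=np.array([[0.3, 0, 0], [-0.3, 0.1, 0]]))
        config = MDConfig(dt=0.01, n_steps=500, t_init=0.5, seed=9, units=REDUCED)
        base = HarmonicWell()
        fp1 = energy_fingerprint(run_md(system, base, config), q=16)
        fp2 = energy_fingerprint(run_md(system, ShiftedField(base, 123.4), config), q=16)
        np.testing.assert_allclose(fp1.values, fp2.values, atol=1e-9)
        assert fp1.values[0] == 0.0
        assert np.all(np.diff(fp1.values) >= 0)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            energy_fingerprint(np.arange(5.0), q=10)


class TestForceFields:
    @pytest.mark.parametrize(
        "field,n",
        [
            (HarmonicWell(k=2.3, center=0.1), 4),
            (LennardJones(epsilon=0.7, sigma=1.2), 2),
            (LennardJones(), 5),
            (DoubleWell2D(a=1.5, b=0.8), 3),
        ],
        ids=["harmonic", "lj-dimer", "lj-cluster", "double-well"],
    )
    def test_analytic_gradients_match_finite_differences(self, field, n, rng):
        for _ in range(20):
            coords = rng.uniform(-1.5, 1.5, size=(n, 3))
            if isinstance(field, LennardJones):
                # keep particles separated so the finite difference is stable
                coords = coords * 0.3 + 1.5 * np.arange(n)[:, None] * np.array([1.0, 0, 0])
            _, grad = field.evaluate(coords)
            num = numerical_gradient(field, coords)
            scale = max(1.0, np.max(np.abs(num)))
            np.testing.assert_allclose(grad, num, atol=1e-6 * scale)

    def test_lj_dimer_minimum(self):
        field = LennardJones()
        coords = np.array([[0.0, 0, 0], [2 ** (1 / 6), 0, 0]])
        energy, grad = field.evaluate(coords)
        assert energy == pytest.approx(-1.0)
        assert np.all(np.abs(grad) < 1e-12)

    def test_harmonic_at_origin(self):
        energy, grad = HarmonicWell().evaluate(np.zeros((3, 3)))
        assert energy == 0.0
        assert np.all(grad == 0)


def test_xyz_roundtrip(tmp_path):
    path = tmp_path / "water.xyz"
    path.write_text("3\nwater\nO 0.0 0.0 0.0\nH 0.96 0.0 0.0\nH -0.24 0.93 0.0\n")
    system = read_xyz(path)
    assert system.labels == ("O", "H", "H")
    assert system.masses[0] == pytest.approx(15.999)
    config = MDConfig(dt=0.5, n_steps=10, t_init=300.0, seed=2, record_interval=5)
    traj = run_md(system, HarmonicWell(k=0.1), config)
    out = tmp_path / "traj.xyz"
    write_trajectory_xyz(traj, out)
    text = out.read_text()
    assert text.count("epot=") == traj.n_frames
    assert read_xyz(out).n_particles == 3  # first frame parses as plain XYZ
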