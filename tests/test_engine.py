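"""Boost closed forms, integrator physics, determinism, minimizer."""

import numpy as np
import pytest

from boostmd import engine, models
from boostmd.engine import (
    ACC,
    KB,
    BoostParams,
    SimulationConfig,
    boost_energy,
    boost_force_scale,
    dual_boost,
    evaluate_forces,
)

from conftest import finite_difference_gradient


class Harmonic1D(models.EnergyTerm):
    """V = k x^2 for a single 1-D particle (test-only convex system)."""

    name = "harmonic"

    def __init__(self, k):
        self.k = float(k)

    def energy_gradient(self, x):
        return self.k * x[0, 0] ** 2, np.array([[2.0 * self.k * x[0, 0]]])


def harmonic_system(k=10.0, mass=10.0):
    return models.ModelSystem(
        "harmonic", 1, np.array([mass]), 1, 1, (Harmonic1D(k),)
    )


class TestBoostClosedForms:
    def test_boundary_and_branches(self):
        assert boost_energy(100.0, 100.0, 20.0) == 0.0
        assert boost_energy(80.0, 100.0, 20.0) == pytest.approx(10.0)
        assert boost_energy(120.0, 100.0, 20.0) == 0.0

    def test_nonnegative_everywhere(self):
        v = np.linspace(-200, 200, 401)
        assert np.all(boost_energy(v, 50.0, 15.0) >= 0.0)

    def test_force_scale_values_and_bounds(self):
        assert boost_force_scale(100.0, 100.0, 20.0) == 1.0
        assert boost_force_scale(80.0, 100.0, 20.0) == pytest.approx(0.25)
        v = np.linspace(-500, 150, 600)
        s = boost_force_scale(v, 100.0, 20.0)
        assert np.all((s > 0) & (s <= 1.0))
        assert np.all(np.diff(s) >= 0)  # monotone non-decreasing in V

    def test_force_scale_matches_derivative_of_boosted_energy(self):
        # d(V + dV)/dV computed by central differences on a grid
        E, alpha, h = 100.0, 20.0, 1e-4
        v = np.linspace(-50.0, 99.0, 150)
        num = 1.0 + (boost_energy(v + h, E, alpha) - boost_energy(v - h, E, alpha)) / (
            2 * h
        )
        np.testing.assert_allclose(boost_force_scale(v, E, alpha), num, atol=1e-8)

    @pytest.mark.parametrize("alpha", [0.0, -1.0])
    def test_nonpositive_alpha_rejected(self, alpha):
        with pytest.raises(ValueError):
            boost_energy(0.0, 1.0, alpha)
        with pytest.raises(ValueError):
            boost_force_scale(0.0, 1.0, alpha)


class TestDualBoost:
    PARAMS = BoostParams(E_P=100.0, alpha_P=20.0, E_D=10.0, alpha_D=4.0)

    def test_mode_none_is_identity(self):
        dv, rule = dual_boost(50.0, 5.0, self.PARAMS, "none")
        assert dv == 0.0
        g = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_array_equal(rule.modified_gradient(g, 0 * g), g)

    def test_both_branches_inactive_above_thresholds(self):
        dv, rule = dual_boost(120.0, 12.0, self.PARAMS, "dual")
        assert dv == 0.0
        assert rule.total_scale == 1.0
        assert rule.dihedral_extra == 0.0

    def test_additive_example(self):
        dv, _ = dual_boost(80.0, 8.0, self.PARAMS, "dual")
        assert dv == pytest.approx(10.0 + 4.0 / 6.0)

    def test_missing_params_rejected(self):
        with pytest.raises(ValueError):
            dual_boost(0.0, 0.0, BoostParams(), "dual")

    def test_modified_force_is_gradient_of_boosted_potential(self, rng):
        system = models.make_cg_helix(8)
        # thresholds above typical energies so both branches are active
        x = system.reference + 0.3 * rng.standard_normal((8, 3))
        v, v_d, _, _ = system.evaluate(x)
        params = BoostParams(
            E_P=v + 5.0, alpha_P=4.0, E_D=v_d + 3.0, alpha_D=2.0
        )
        for mode, nested in [("dihedral", False), ("total", False),
                             ("dual", False), ("dual", True)]:
            force, V, _, dv = evaluate_forces(system, x, params, mode, nested)
            assert dv > 0.0

            def v_prime(y, _m=mode, _n=nested):
                _, V_, _, dv_ = evaluate_forces(system, y, params, _m, _n)
                return V_ + dv_

            g_fd = finite_difference_gradient(v_prime, x)
            denom = max(float(np.max(np.abs(g_fd))), 1e-6)
            assert np.max(np.abs(-force - g_fd)) / denom < 1e-5, (mode, nested)


class TestLangevin:
    def test_frictionless_step_is_velocity_verlet(self):
        system = harmonic_system()
        cfg = SimulationConfig(timestep=0.002, temperature=300.0, n_steps=1,
                               collision_frequency=0.0, seed=4)
        rng = np.random.default_rng(4)
        x0, v0 = np.array([[1.0]]), np.array([[3.0]])
        f0 = -system.gradient(x0)
        x1, v1, _, _ = engine.langevin_step(system, x0, v0, cfg, rng)
        # manual velocity-Verlet
        a0 = f0 * ACC / system.masses[:, None]
        x_vv = x0 + cfg.timestep * v0 + 0.5 * cfg.timestep**2 * a0
        a1 = -system.gradient(x_vv) * ACC / system.masses[:, None]
        v_vv = v0 + 0.5 * cfg.timestep * (a0 + a1)
        np.testing.assert_allclose(x1, x_vv, atol=1e-12)
        np.testing.assert_allclose(v1, v_vv, atol=1e-12)

    def test_energy_conservation_without_friction(self):
        system = harmonic_system(k=10.0, mass=10.0)
        omega = np.sqrt(2 * 10.0 * ACC / 10.0)
        dt = 2 * np.pi / omega / 100.0
        cfg = SimulationConfig(timestep=dt, temperature=0.0, n_steps=10_000,
                               collision_frequency=0.0, save_interval=10, seed=7)
        traj = engine.run_simulation(system, np.array([[1.0]]), cfg)
        ke = 0.5 * KB * traj.T_inst  # one degree of freedom
        total = traj.V + ke
        assert np.max(np.abs(total - total[0])) / total[0] < 0.01

    def test_equipartition_at_target_temperature(self):
        system = harmonic_system(k=10.0, mass=10.0)
        cfg = SimulationConfig(timestep=0.002, temperature=300.0, n_steps=200_000,
                               collision_frequency=1.0, save_interval=10, seed=21)
        traj = engine.run_simulation(system, np.array([[0.5]]), cfg)
        t = traj.T_inst[len(traj.T_inst) // 4:]
        blocks = np.array_split(t, 20)
        means = np.array([b.mean() for b in blocks])
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 300.0) < 3 * se + 1e-9

    def test_inactive_boost_is_bit_for_bit_identical(self):
        system = models.make_double_well(6.0, 2.0)
        below = BoostParams(E_P=-1e6, alpha_P=1.0, E_D=-1e6, alpha_D=1.0)
        kw = dict(timestep=0.01, temperature=300.0, n_steps=20_000,
                  save_interval=10, seed=13)
        t_plain = engine.run_simulation(
            system, np.array([[-2.0]]), SimulationConfig(boost_mode="none", **kw)
        )
        t_boost = engine.run_simulation(
            system, np.array([[-2.0]]), SimulationConfig(boost_mode="dual", **kw),
            boost=below,
        )
        np.testing.assert_array_equal(t_plain.coords, t_boost.coords)
        np.testing.assert_array_equal(t_plain.V, t_boost.V)
        assert np.all(t_boost.deltaV == 0.0)


class TestRunSimulation:
    def test_seed_determinism(self, double_well):
        cfg = SimulationConfig(timestep=0.01, temperature=300.0, n_steps=5_000,
                               save_interval=25, seed=99)
        a = engine.run_simulation(double_well, np.array([[2.0]]), cfg)
        b = engine.run_simulation(double_well, np.array([[2.0]]), cfg)
        np.testing.assert_array_equal(a.coords, b.coords)
        np.testing.assert_array_equal(a.T_inst, b.T_inst)

    def test_unboosted_run_has_zero_bias(self, double_well):
        cfg = SimulationConfig(timestep=0.01, temperature=300.0, n_steps=2_000, seed=3)
        traj = engine.run_simulation(double_well, np.array([[2.0]]), cfg)
        assert np.all(traj.deltaV == 0.0)
        assert np.all(np.diff(traj.times) > 0)

    def test_boost_required_for_boosted_mode(self, double_well):
        cfg = SimulationConfig(timestep=0.01, temperature=300.0, n_steps=10,
                               boost_mode="total", seed=0)
        with pytest.raises(ValueError):
            engine.run_simulation(double_well, np.array([[2.0]]), cfg)

    def test_divergence_is_reported_and_truncated(self, cg_helix10):
        cfg = SimulationConfig(timestep=5.0, temperature=300.0, n_steps=5_000,
                               save_interval=1, seed=5, energy_ceiling=1e6)
        traj = engine.run_simulation(cg_helix10, cg_helix10.reference, cfg)
        assert traj.status == "diverged"
        assert traj.error_step is not None
        assert traj.n_frames < 5_001

    def test_boosted_frames_report_positive_bias(self, cg_helix10):
        params = BoostParams(E_D=1e4, alpha_D=50.0)
        cfg = SimulationConfig(timestep=0.005, temperature=300.0, n_steps=2_000,
                               save_interval=20, boost_mode="dihedral", seed=8)
        traj = engine.run_simulation(cg_helix10, cg_helix10.reference, cfg, params)
        assert traj.status == "ok"
        assert np.all(traj.deltaV > 0.0)


class TestMinimize:
    def test_convex_system_reaches_analytic_minimum(self):
        system = harmonic_system(k=3.0)
        res = engine.minimize(system, np.array([[4.0]]), gtol=1e-8)
        assert res.converged
        assert abs(res.coords[0, 0]) < 1e-6

    @pytest.mark.parametrize("x0,basin", [(0.1, 2.0), (-0.1, -2.0)])
    def test_double_well_basin_assignment(self, double_well, x0, basin):
        res = engine.minimize(double_well, np.array([[x0]]), gtol=1e-8)
        assert res.coords[0, 0] == pytest.approx(basin, abs=1e-4)

    def test_energy_never_increases(self, cg_helix10, rng):
        x0 = cg_helix10.reference + 0.5 * rng.standard_normal((10, 3))
        e0 = cg_helix10.energy(x0)
        res = engine.minimize(cg_helix10, x0)
        assert res.energy <= e0


class TestFirstPassage:
    def test_fast_path_returns_crossing_step(self):
        system = models.make_double_well(2.0, 2.0)  # low barrier: quick crossing
        cfg = SimulationConfig(timestep=0.01, temperature=300.0, n_steps=1, seed=17)
        fpt = engine.first_passage_steps(system, -2.0, 2.0, cfg, max_steps=2_000_000)
        assert isinstance(fpt, int) and fpt > 0

    def test_step_cap_returns_none(self):
        system = models.make_double_well(30.0, 2.0)  # effectively uncrossable
        cfg = SimulationConfig(timestep=0.01, temperature=300.0, n_steps=1, seed=18)
        assert engine.first_passage_steps(system, -2.0, 2.0, cfg, max_steps=500) is None
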