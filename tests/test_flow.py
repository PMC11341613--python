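"""Finite-volume flow solver: kinematics, projection contract, cycles."""

import numpy as np
import pytest

from atriarom.case import build_channel_mesh
from atriarom.flow import (BoundaryConditions, FlowSolver, FlowState,
                           SolverConfig, run_cycles, snapshot_count,
                           snapshot_times, strain_invariant)
from atriarom.rheology import RheologyParams

from conftest import toy_case_config


@pytest.fixture(scope="module")
def channel():
    return build_channel_mesh(0.02, 0.01, 0.0005)


class TestStrainInvariant:
    def test_uniform_translation_has_no_strain(self, channel):
        u = np.tile([0.3, -0.1], (channel.n_cells, 1))
        bv = u[channel.bface_owner]
        assert np.abs(strain_invariant(u, channel, boundary_values=bv)).max() < 1e-20

    def test_simple_shear(self, channel):
        # u = (gamma*y, 0) with gamma = 2 /s gives J2 = 1 exactly
        gamma = 2.0
        u = np.column_stack([gamma * channel.cell_centers[:, 1],
                             np.zeros(channel.n_cells)])
        bv = np.column_stack([gamma * channel.bface_center[:, 1],
                              np.zeros(channel.n_bfaces)])
        j2 = strain_invariant(u, channel, boundary_values=bv)
        assert np.abs(j2 - 1.0).max() < 1e-10
        # with zero-gradient boundary extrapolation only interior cells are exact
        j2_free = strain_invariant(u, channel)
        interior = np.flatnonzero(
            (channel.cell_centers[:, 1] > 2 * channel.h)
            & (channel.cell_centers[:, 1] < 0.01 - 2 * channel.h)
            & (channel.cell_centers[:, 0] > 2 * channel.h)
            & (channel.cell_centers[:, 0] < 0.02 - 2 * channel.h))
        assert np.abs(j2_free[interior] - 1.0).max() < 1e-6

    def test_rigid_rotation_has_no_strain(self, channel):
        omega = 3.0
        c = channel.cell_centers
        u = np.column_stack([-omega * c[:, 1], omega * c[:, 0]])
        b = channel.bface_center
        bv = np.column_stack([-omega * b[:, 1], omega * b[:, 0]])
        j2 = strain_invariant(u, channel, boundary_values=bv)
        assert np.abs(j2).max() < 1e-12

    def test_non_negative(self, channel):
        rng = np.random.default_rng(7)
        u = rng.standard_normal((channel.n_cells, 2))
        assert strain_invariant(u, channel).min() >= 0.0


class TestProjectionStep:
    def test_rest_state_is_fixed_point(self, channel):
        bc = BoundaryConditions.steady_inlet(
            channel, lambda c: np.zeros((len(c), 2)))
        solver = FlowSolver(channel, RheologyParams(), bc, SolverConfig())
        state = FlowState.rest(channel)
        for _ in range(3):
            state = solver.step(state, 0.01)
        assert np.abs(state.velocity).max() == 0.0
        assert np.abs(state.pressure - state.pressure[0]).max() < 1e-12

    def test_divergence_bound_every_step(self, channel):
        U = 0.01
        bc = BoundaryConditions.steady_inlet(
            channel, lambda c: np.column_stack([np.full(len(c), U),
                                                np.zeros(len(c))]))
        cfg = SolverConfig(div_tol=1e-9)
        solver = FlowSolver(channel, RheologyParams(), bc, cfg)
        state = FlowState.rest(channel)
        for _ in range(10):
            state = solver.step(state, solver.suggest_dt(state, state.time + 0.01))
            assert solver.last_divergence <= cfg.div_tol

    def test_global_mass_balance(self, channel):
        U = 0.01
        bc = BoundaryConditions.steady_inlet(
            channel, lambda c: np.column_stack([np.full(len(c), U),
                                                np.zeros(len(c))]))
        solver = FlowSolver(channel, RheologyParams(), bc, SolverConfig())
        state = FlowState.rest(channel)
        for _ in range(5):
            state = solver.step(state, 0.01)
        assert abs(state.bflux.sum()) < 1e-15 * abs(state.bflux).sum()

    def test_missing_outlet_rejected(self, channel):
        bc = BoundaryConditions.steady_inlet(
            channel, lambda c: np.zeros((len(c), 2)))
        bc.outlet_mask = np.zeros(channel.n_bfaces, dtype=bool)
        bc.dirichlet_mask = ~bc.outlet_mask
        from atriarom.flow import SolverError
        with pytest.raises(SolverError):
            FlowSolver(channel, RheologyParams(), bc, SolverConfig())


class TestCycles:
    def test_snapshot_schedule(self):
        assert snapshot_count(1.07, 0.01) == 107
        times = snapshot_times(1.07, 0.01, n_cycles=2)
        assert times.size == 214
        assert times[0] == pytest.approx(0.01)
        assert times[-1] == pytest.approx(2.14)
        assert np.allclose(np.diff(times), 0.01)

    def test_single_cycle_equals_direct_integration(self, toy_mesh):
        case = toy_case_config(n_cycles=1)
        rheo = RheologyParams()
        final = run_cycles(case, rheo, mesh=toy_mesh)
        full = run_cycles(case, rheo, mesh=toy_mesh, return_all=True)
        assert len(final) == snapshot_count(case.period, case.dt_max)
        np.testing.assert_array_equal(final.velocity, full.velocity)

    def test_periodicity_drift_decreases_with_cycles(self, toy_mesh):
        rheo = RheologyParams()
        n = snapshot_count(1.07, 0.01)

        def drift(n_cycles):
            case = toy_case_config(n_cycles=n_cycles)
            s = run_cycles(case, rheo, mesh=toy_mesh, return_all=True)
            ke = s.kinetic_energy()
            return np.linalg.norm(ke[-n:] - ke[-2 * n:-n]) / np.linalg.norm(ke[-n:])

        assert drift(4) < drift(2)


class TestSolverConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(courant_max=0.0), dict(courant_max=1.5), dict(dt_max=-0.01),
        dict(convection="quick"),
    ])
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            SolverConfig(**kw)
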