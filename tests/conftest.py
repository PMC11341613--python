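import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from atriarom.case import CaseConfig, build_channel_mesh, build_mesh
from atriarom.flow import BoundaryConditions, FlowSolver, FlowState, \
    SolverConfig, run_cycles
from atriarom.rheology import RheologyParams

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def toy_case_config(**overrides) -> CaseConfig:
    """Small idealized atrium: 220 cells, fast enough for per-test FOM runs."""
    kw = dict(chamber_length=0.02, chamber_height=0.01, pocket_length=0.005,
              pocket_width=0.004, h=0.001, n_inlets=2, n_cycles=2,
              stroke_volume=8e-5)
    kw.update(overrides)
    return CaseConfig(**kw)


@pytest.fixture(scope="session")
def toy_case():
    return toy_case_config()


@pytest.fixture(scope="session")
def toy_mesh(toy_case):
    return build_mesh(toy_case)


@pytest.fixture(scope="session")
def toy_flow_series(toy_case, toy_mesh):
    """Two cardiac cycles of the Newtonian toy case, all snapshots kept."""
    return run_cycles(toy_case, RheologyParams(), mesh=toy_mesh, return_all=True)


# -- Poiseuille channel fixture ------------------------------------------------

POISEUILLE = dict(length=0.02, height=0.005, h=0.0002, mean_velocity=0.01)


@pytest.fixture(scope="session")
def poiseuille_steady():
    """Steady developed Poiseuille flow in a straight channel (Newtonian).

    Plug inflow at the left, reference pressure at the right outlet; marched
    to steady state.  Returns the mesh, final state and material parameters.
    """
    p = POISEUILLE
    mesh = build_channel_mesh(p["length"], p["height"], p["h"])
    rheo = RheologyParams(model="newtonian")
    U = p["mean_velocity"]
    bc = BoundaryConditions.steady_inlet(
        mesh, lambda c: np.column_stack([np.full(len(c), U), np.zeros(len(c))]))
    cfg = SolverConfig(dt_max=0.05, courant_max=1.0, div_tol=1e-6)
    solver = FlowSolver(mesh, rheo, bc, cfg)
    state = FlowState.rest(mesh)
    prev = state.velocity.copy()
    for _ in range(5000):
        dt = solver.suggest_dt(state, state.time + cfg.dt_max)
        state = solver.step(state, dt)
        if np.abs(state.velocity - prev).max() / dt < 1e-7 * U:
            break
        prev = state.velocity.copy()
    return {"mesh": mesh, "state": state, "rheology": rheo, "solver": solver,
            **p}
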