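"""Incompressible Navier-Stokes finite-volume solver (2-D, cell-centred).

Solves  rho dv/dt + rho div(v x v) - div(T) = 0,  div(v) = 0  with either a
constant (Newtonian) or Casson shear-thinning viscosity, using an incremental
pressure-correction (fractional-step) scheme:

1. implicit-Euler momentum predictor with implicit upwind convection
   (optionally corrected to second-order linear-upwind by deferred
   correction), implicit diffusion with lagged (Picard) viscosity, and the
   previous pressure gradient;
2. a pressure-correction Poisson solve on Rhie-Chow interpolated face fluxes;
3. flux and cell-velocity correction, making the discrete face-flux
   divergence zero to linear-solver tolerance.

Boundary conditions: Dirichlet velocity on inlets and walls, zero-gradient
velocity with a fixed reference pressure on the outlet.  Time steps satisfy
both a maximum step and a maximum Courant number, subcycling so that steps
land exactly on the uniform snapshot schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .case import CaseConfig, Waveform, inlet_split
from .mesh import Mesh
from .rheology import RheologyParams, effective_viscosity


class SolverError(RuntimeError):
    """Linear-solver breakdown or non-finite fields during time stepping."""


@dataclass
class SolverConfig:
    """Numerical settings for the flow solver."""

    dt_max: float = 0.01
    courant_max: float = 0.8
    convection: str = "linear_upwind"   # or "upwind" (first-order fallback)
    dt_snap: float | None = None        # snapshot spacing; defaults to dt_max
    div_tol: float = 1e-8               # max |div F| accepted per cell (m^2/s)

    def __post_init__(self):
        if not 0 < self.courant_max <= 1:
            raise ValueError("courant_max must lie in (0, 1]")
        if self.dt_max <= 0:
            raise ValueError("dt_max must be positive")
        if self.convection not in ("linear_upwind", "upwind"):
            raise ValueError(f"unknown convection scheme {self.convection!r}")
        if self.dt_snap is None:
            self.dt_snap = self.dt_max


@dataclass
class FlowState:
    """Cell-centred velocity/pressure plus divergence-free face fluxes."""

    velocity: np.ndarray          # (Nc, 2) m/s
    pressure: np.ndarray          # (Nc,)  Pa
    time: float                   # s
    flux: np.ndarray              # (Nf,)  m^2/s, owner -> neighbour
    bflux: np.ndarray             # (Nb,)  m^2/s, outward

    @classmethod
    def rest(cls, mesh: Mesh, t: float = 0.0) -> "FlowState":
        return cls(velocity=np.zeros((mesh.n_cells, 2)),
                   pressure=np.zeros(mesh.n_cells), time=t,
                   flux=np.zeros(mesh.n_faces), bflux=np.zeros(mesh.n_bfaces))


class BoundaryConditions:
    """Dirichlet velocity on inlets/walls, zero-gradient + p ref on the outlet.

    ``velocity_of(t)`` returns an (Nb, 2) array of boundary-face velocities;
    entries on outlet faces are ignored.
    """

    def __init__(self, mesh: Mesh, velocity_of, outlet_patch: str = "outlet"):
        self.mesh = mesh
        self.velocity_of = velocity_of
        self.outlet_mask = mesh.bface_patch == mesh.patch_id(outlet_patch)
        self.dirichlet_mask = ~self.outlet_mask

    @classmethod
    def for_case(cls, mesh: Mesh, waveform: Waveform, f: float = 1.0
                 ) -> "BoundaryConditions":
        """Pulsatile case: equal plug inflow on each inlet balancing Q(t;f)."""
        inlets = mesh.inlet_patch_names()
        areas = {name: mesh.patch_area(name) for name in inlets}
        patch_rows = {name: mesh.patch_faces(name) for name in inlets}
        normals = mesh.bface_normal

        def velocity_of(t):
            vb = np.zeros((mesh.n_bfaces, 2))
            rates = inlet_split(waveform.rate(t, f), mesh)
            for name in inlets:
                rows = patch_rows[name]
                speed = rates[name] / areas[name]
                vb[rows] = -normals[rows] * speed   # plug flow, inward
            return vb

        return cls(mesh, velocity_of)

    @classmethod
    def steady_inlet(cls, mesh: Mesh, profile) -> "BoundaryConditions":
        """Steady inlet velocity from ``profile(face_centers) -> (n, 2)``."""
        vb0 = np.zeros((mesh.n_bfaces, 2))
        for name in mesh.inlet_patch_names():
            rows = mesh.patch_faces(name)
            vb0[rows] = profile(mesh.bface_center[rows])
        return cls(mesh, lambda t: vb0)


class FlowSolver:
    """Stateful solver bound to one mesh / rheology / boundary setup."""

    def __init__(self, mesh: Mesh, rheology: RheologyParams,
                 bc: BoundaryConditions, config: SolverConfig | None = None):
        self.mesh = mesh
        self.rheology = rheology
        self.bc = bc
        self.config = config or SolverConfig()
        self._build_pressure_system()
        self._rows, self._cols = self._momentum_pattern()
        self.last_divergence = 0.0

    # -- setup ---------------------------------------------------------------

    def _build_pressure_system(self):
        m = self.mesh
        a = m.face_area / m.h
        rows = np.concatenate([m.face_owner, m.face_neigh, m.face_owner, m.face_neigh])
        cols = np.concatenate([m.face_owner, m.face_neigh, m.face_neigh, m.face_owner])
        data = np.concatenate([np.full(m.n_faces, a), np.full(m.n_faces, a),
                               np.full(m.n_faces, -a), np.full(m.n_faces, -a)])
        out = np.flatnonzero(self.bc.outlet_mask)
        ab = m.face_area / (m.h / 2.0)
        rows = np.concatenate([rows, m.bface_owner[out]])
        cols = np.concatenate([cols, m.bface_owner[out]])
        data = np.concatenate([data, np.full(out.size, ab)])
        L = sp.coo_matrix((data, (rows, cols)), shape=(m.n_cells, m.n_cells)).tocsc()
        if out.size == 0:
            raise SolverError("a well-posed case needs an outlet patch "
                              "(pressure reference)")
        self._plu = spla.splu(L)

    def _momentum_pattern(self):
        m = self.mesh
        diag = np.arange(m.n_cells)
        rows = np.concatenate([diag, m.face_owner, m.face_neigh])
        cols = np.concatenate([diag, m.face_neigh, m.face_owner])
        return rows, cols

    # -- helpers -------------------------------------------------------------

    def boundary_velocity(self, t: float) -> np.ndarray:
        return self.bc.velocity_of(t)

    def _face_values_for_gradient(self, u: np.ndarray, vb: np.ndarray) -> np.ndarray:
        bvals = u[self.mesh.bface_owner].copy()     # zero-gradient default
        d = self.bc.dirichlet_mask
        bvals[d] = vb[d]
        return bvals

    def cell_viscosity(self, u: np.ndarray, vb: np.ndarray) -> np.ndarray:
        if self.rheology.model == "newtonian":
            return np.full(self.mesh.n_cells, self.rheology.mu_newtonian)
        j2 = strain_invariant(u, self.mesh,
                              boundary_values=self._face_values_for_gradient(u, vb))
        return np.atleast_1d(effective_viscosity(j2, self.rheology))

    def suggest_dt(self, state: FlowState, t_target: float) -> float:
        cfg = self.config
        umax = float(np.abs(state.velocity).max(initial=0.0))
        dt = cfg.dt_max
        if umax > 0:
            dt = min(dt, cfg.courant_max * self.mesh.h / umax)
        return min(dt, max(t_target - state.time, 0.0))

    # -- one time step -------------------------------------------------------

    def step(self, state: FlowState, dt: float) -> FlowState:
        m, cfg, rho = self.mesh, self.config, self.rheology.density
        area, h, V = m.face_area, m.h, m.cell_volumes
        u, p = state.velocity, state.pressure
        t_new = state.time + dt
        vb = self.boundary_velocity(t_new)
        d_mask = self.bc.dirichlet_mask
        out_mask = self.bc.outlet_mask

        # lagged (Picard) viscosity
        mu_c = self.cell_viscosity(u, vb)
        mu_f = 0.5 * (mu_c[m.face_owner] + mu_c[m.face_neigh])
        mu_b = mu_c[m.bface_owner]

        F = state.flux
        Fb = state.bflux

        # -- momentum matrix (shared by both velocity components) ------------
        a_diff = mu_f * area / h
        up_pos = rho * np.maximum(F, 0.0)
        up_neg = rho * np.minimum(F, 0.0)
        diag = rho * V / dt
        np.add.at(diag, m.face_owner, up_pos + a_diff)
        np.add.at(diag, m.face_neigh, -up_neg + a_diff)
        off_on = up_neg - a_diff        # coefficient of u_N in owner row
        off_no = -up_pos - a_diff       # coefficient of u_O in neighbour row

        # boundary contributions
        bdiag = np.zeros(m.n_cells)
        # Dirichlet faces: diffusion to the face value; convection upwinds the
        # boundary value on inflow (goes to RHS) and the cell value on outflow
        ab = mu_b * area / (h / 2.0)
        np.add.at(bdiag, m.bface_owner[d_mask], ab[d_mask])
        np.add.at(bdiag, m.bface_owner, rho * np.maximum(Fb, 0.0))
        diag += bdiag

        A = sp.coo_matrix(
            (np.concatenate([diag, off_on, off_no]), (self._rows, self._cols)),
            shape=(m.n_cells, m.n_cells)).tocsc()
        alu = spla.splu(A)

        # -- right-hand sides -------------------------------------------------
        bgrad_vals = self._face_values_for_gradient(u, vb)
        grad_u = m.green_gauss_gradient(u, boundary_values=bgrad_vals)  # (Nc,2,2)

        rhs = rho * V[:, None] / dt * u

        # previous pressure force: -V grad(p) via Green-Gauss faces
        pb = p[m.bface_owner].copy()
        pb[out_mask] = 0.0
        gp = m.green_gauss_gradient(p, boundary_values=pb)
        rhs -= V[:, None] * gp

        # Dirichlet boundary terms (diffusion + inflow convection)
        inflow = rho * np.minimum(Fb, 0.0)
        w = (ab * d_mask - inflow * d_mask)[:, None] * vb
        np.add.at(rhs, m.bface_owner, w)

        # deferred second-order (linear-upwind) convection correction
        if cfg.convection == "linear_upwind":
            up_cell = np.where(F >= 0, m.face_owner, m.face_neigh)
            dx = m.cell_centers[m.face_neigh] - m.cell_centers[m.face_owner]
            sgn = np.where(F >= 0, 0.5, -0.5)[:, None]
            corr = np.einsum("fij,fj->fi", grad_u[up_cell], dx * sgn)
            flux_corr = rho * F[:, None] * corr
            np.add.at(rhs, m.face_owner, -flux_corr)
            np.add.at(rhs, m.face_neigh, flux_corr)

        # explicit transpose-stress term: (div(mu grad(u)^T))_i = d_j(mu d_i u_j)
        for i in range(2):
            s = mu_c[:, None] * grad_u[:, :, i]      # vector field s_j = mu d_i u_j
            gs = m.green_gauss_gradient(s)
            rhs[:, i] += (gs[:, 0, 0] + gs[:, 1, 1]) * V

        ustar = np.column_stack([alu.solve(rhs[:, 0]), alu.solve(rhs[:, 1])])
        if not np.all(np.isfinite(ustar)):
            raise SolverError(f"non-finite velocity predictor at t={t_new:.4f}")

        # -- face fluxes with Rhie-Chow pressure dissipation ------------------
        nvec = np.eye(2)[m.face_axis]                     # (Nf, 2) unit normals
        Fstar = 0.5 * ((ustar[m.face_owner] + ustar[m.face_neigh]) * nvec
                       ).sum(axis=1) * area
        # replace the interpolated old-pressure gradient by the compact one
        gp_f = 0.5 * (gp[m.face_owner] + gp[m.face_neigh])
        compact = (p[m.face_neigh] - p[m.face_owner]) / h
        Fstar += dt / rho * ((gp_f * nvec).sum(axis=1) - compact) * area

        Fb_star = np.zeros(m.n_bfaces)
        Fb_star[d_mask] = (vb[d_mask] * m.bface_normal[d_mask]).sum(axis=1) * area
        Fb_star[out_mask] = (ustar[m.bface_owner[out_mask]]
                             * m.bface_normal[out_mask]).sum(axis=1) * area
        # enforce global mass balance by an additive outlet correction
        imbalance = Fb_star[d_mask].sum() + Fb_star[out_mask].sum()
        n_out = int(out_mask.sum())
        Fb_star[out_mask] -= imbalance / n_out

        div = np.zeros(m.n_cells)
        np.add.at(div, m.face_owner, Fstar)
        np.add.at(div, m.face_neigh, -Fstar)
        np.add.at(div, m.bface_owner, Fb_star)

        # -- pressure correction ----------------------------------------------
        pc = self._plu.solve(-rho / dt * div)
        if not np.all(np.isfinite(pc)):
            raise SolverError(f"pressure-correction solve failed at t={t_new:.4f}")

        a = area / h
        Fnew = Fstar - dt / rho * a * (pc[m.face_neigh] - pc[m.face_owner])
        Fb_new = Fb_star.copy()
        ab_p = area / (h / 2.0)
        Fb_new[out_mask] -= dt / rho * ab_p * (0.0 - pc[m.bface_owner[out_mask]])

        pcb = pc[m.bface_owner].copy()
        pcb[out_mask] = 0.0
        gpc = m.green_gauss_gradient(pc, boundary_values=pcb)
        unew = ustar - dt / rho * gpc
        pnew = p + pc

        # divergence diagnostic (continuity residual per cell, m^2/s)
        div_new = np.zeros(m.n_cells)
        np.add.at(div_new, m.face_owner, Fnew)
        np.add.at(div_new, m.face_neigh, -Fnew)
        np.add.at(div_new, m.bface_owner, Fb_new)
        self.last_divergence = float(np.abs(div_new).max(initial=0.0))
        if self.last_divergence > self.config.div_tol:
            raise SolverError(
                f"continuity residual {self.last_divergence:.3e} exceeds "
                f"div_tol at t={t_new:.4f}")
        if not np.all(np.isfinite(unew)):
            raise SolverError(f"non-finite velocity at t={t_new:.4f}")

        return FlowState(velocity=unew, pressure=pnew, time=t_new,
                         flux=Fnew, bflux=Fb_new)

    def advance_to(self, state: FlowState, t_target: float) -> FlowState:
        """Subcycle (Courant-limited) until ``t_target`` is reached exactly."""
        while state.time < t_target - 1e-12:
            dt = self.suggest_dt(state, t_target)
            state = self.step(state, dt)
        return replace(state, time=t_target)


@dataclass
class FlowSeries:
    """Velocity snapshots on the uniform schedule, plus the face fluxes the
    transport solvers consume."""

    mesh: Mesh
    times: np.ndarray             # (Ns,)
    velocity: np.ndarray          # (Ns, Nc, 2)
    pressure: np.ndarray          # (Ns, Nc)
    flux: np.ndarray              # (Ns, Nf)
    bflux: np.ndarray             # (Ns, Nb)

    def __len__(self):
        return self.times.size

    def final_cycle(self, period: float, dt_snap: float) -> "FlowSeries":
        n = snapshot_count(period, dt_snap)
        return FlowSeries(self.mesh, self.times[-n:], self.velocity[-n:],
                          self.pressure[-n:], self.flux[-n:], self.bflux[-n:])

    def kinetic_energy(self, rho: float = 1050.0) -> np.ndarray:
        ke = 0.5 * rho * (self.velocity ** 2).sum(axis=2)
        return (ke * self.mesh.cell_volumes).sum(axis=1)


def snapshot_count(period: float, dt_snap: float) -> int:
    """Snapshots per cycle on the uniform schedule t_i = i * dt_snap."""
    return int(round(period / dt_snap))


def snapshot_times(period: float, dt_snap: float, n_cycles: int = 1) -> np.ndarray:
    """Uniform snapshot schedule over ``n_cycles`` periods, excluding t=0."""
    n = snapshot_count(period, dt_snap)
    return dt_snap * np.arange(1, n * n_cycles + 1)


def strain_invariant(velocity: np.ndarray, mesh: Mesh,
                     boundary_values: np.ndarray | None = None) -> np.ndarray:
    """Second invariant J2 = 1/2 (D : D) of the strain-rate tensor (s^-2).

    The velocity gradient is evaluated by Green-Gauss reconstruction; without
    ``boundary_values`` a zero-normal-gradient extrapolation is used at the
    boundary, so boundary-cell values are one-sided approximations.  The shear
    rate is gamma = 2 sqrt(J2); J2 >= 0 everywhere.
    """
    grad = mesh.green_gauss_gradient(np.asarray(velocity, dtype=float),
                                     boundary_values=boundary_values)
    D = 0.5 * (grad + np.swapaxes(grad, 1, 2))
    return 0.5 * np.einsum("cij,cij->c", D, D)


def advance_flow(state: FlowState, mesh: Mesh, rheology: RheologyParams,
                 bc: BoundaryConditions, config: SolverConfig | None = None,
                 dt: float | None = None) -> FlowState:
    """Single time step; convenience wrapper over :class:`FlowSolver`."""
    solver = FlowSolver(mesh, rheology, bc, config)
    if dt is None:
        dt = solver.suggest_dt(state, state.time + (config or SolverConfig()).dt_max)
    return solver.step(state, dt)


def run_cycles(case: CaseConfig, rheology: RheologyParams,
               config: SolverConfig | None = None, *,
               mesh: Mesh | None = None, f: float = 1.0,
               bc: BoundaryConditions | None = None,
               return_all: bool = False) -> FlowSeries:
    """Integrate ``case.n_cycles`` cardiac cycles from rest (v = 0).

    Returns the snapshots of the final cycle on the uniform schedule
    ``t_i = i * dt_snap`` (count = round(T / dt_snap)), or the whole run when
    ``return_all`` is set (the transport solvers integrate from t = 0).
    """
    from .case import build_mesh

    cfg = config or SolverConfig(dt_max=case.dt_max)
    if mesh is None:
        mesh = build_mesh(case)
    if bc is None:
        bc = BoundaryConditions.for_case(mesh, Waveform.from_config(case), f=f)
    solver = FlowSolver(mesh, rheology, bc, cfg)
    times = snapshot_times(case.period, cfg.dt_snap, case.n_cycles)

    state = FlowState.rest(mesh)
    vel = np.empty((times.size, mesh.n_cells, 2))
    pre = np.empty((times.size, mesh.n_cells))
    flx = np.empty((times.size, mesh.n_faces))
    bfl = np.empty((times.size, mesh.n_bfaces))
    for i, t in enumerate(times):
        state = solver.advance_to(state, t)
        vel[i], pre[i] = state.velocity, state.pressure
        flx[i], bfl[i] = state.flux, state.bflux

    series = FlowSeries(mesh, times, vel, pre, flx, bfl)
    return series if return_all else series.final_cycle(case.period, cfg.dt_snap)
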