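"""Passive-scalar transport: blood-age moments and washout.

The first and second moments of the blood-age distribution, m1 (s) and
m2 (s^2), obey

    rho dm_k/dt + rho div(v m_k) = div(mu_mk grad m_k) + rho k m_{k-1},

with m0 = 1, Dirichlet value 0 on the inlets, zero normal gradient on the
rest of the boundary and initial data m_k = 0.  The washout phi solves the
same equation without the source term, from initial data phi = 1; its
residual at cycle end marks poorly cleared (stasis-prone) regions.

Scalars are solved segregated, consuming velocity/flux snapshots stored by
the flow solver.  The default convection scheme is first-order upwind with
implicit Euler in time, which keeps m_k >= 0 and phi within [0, 1] by the
discrete maximum principle; a second-order (deferred-correction
linear-upwind) option is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .flow import FlowSeries
from .mesh import Mesh


@dataclass
class TransportConfig:
    """Diffusivities (kg m^-1 s^-1) and scheme for the passive scalars."""

    diffusivity_m1: float = 1e-10
    diffusivity_m2: float = 1e-10
    diffusivity_washout: float = 1e-10
    density: float = 1050.0
    convection: str = "upwind"   # "upwind" (bounded) or "linear_upwind"

    def __post_init__(self):
        for name in ("diffusivity_m1", "diffusivity_m2", "diffusivity_washout"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.convection not in ("upwind", "linear_upwind"):
            raise ValueError(f"unknown convection scheme {self.convection!r}")

    def diffusivity(self, tag: str) -> float:
        return {"m1": self.diffusivity_m1, "m2": self.diffusivity_m2,
                "washout": self.diffusivity_washout}[tag]


def _boundary_fluxes(mesh: Mesh, velocity: np.ndarray,
                     bflux: np.ndarray | None) -> np.ndarray:
    if bflux is not None:
        return bflux
    return (velocity[mesh.bface_owner] * mesh.bface_normal).sum(axis=1) * mesh.face_area


def _interior_fluxes(mesh: Mesh, velocity: np.ndarray,
                     flux: np.ndarray | None) -> np.ndarray:
    if flux is not None:
        return flux
    nvec = np.eye(2)[mesh.face_axis]
    vf = 0.5 * (velocity[mesh.face_owner] + velocity[mesh.face_neigh])
    return (vf * nvec).sum(axis=1) * mesh.face_area


def _inlet_mask(mesh: Mesh) -> np.ndarray:
    mask = np.zeros(mesh.n_bfaces, dtype=bool)
    for name in mesh.inlet_patch_names():
        mask |= mesh.bface_patch == mesh.patch_id(name)
    return mask


def _advance_scalar(c: np.ndarray, mesh: Mesh, config: TransportConfig,
                    dt: float, mu_d: float, source: np.ndarray,
                    velocity: np.ndarray, flux: np.ndarray | None,
                    bflux: np.ndarray | None) -> np.ndarray:
    """Implicit-Euler FV step of one scalar; Dirichlet 0 on inlets."""
    rho, V, h, area = config.density, mesh.cell_volumes, mesh.h, mesh.face_area
    F = _interior_fluxes(mesh, velocity, flux)
    Fb = _boundary_fluxes(mesh, velocity, bflux)
    inlet = _inlet_mask(mesh)

    a_diff = mu_d * area / h
    up_pos = rho * np.maximum(F, 0.0)
    up_neg = rho * np.minimum(F, 0.0)
    diag = rho * V / dt
    np.add.at(diag, mesh.face_owner, up_pos + a_diff)
    np.add.at(diag, mesh.face_neigh, -up_neg + a_diff)
    off_on = up_neg - a_diff
    off_no = -up_pos - a_diff

    # boundary: inlets are Dirichlet 0 (diffusion + inflow convection of 0,
    # i.e. nothing on the RHS); elsewhere zero-gradient, outflow upwinds the cell
    bdiag = np.zeros(mesh.n_cells)
    ab = mu_d * area / (h / 2.0)
    np.add.at(bdiag, mesh.bface_owner[inlet], ab)
    np.add.at(bdiag, mesh.bface_owner, rho * np.maximum(Fb, 0.0))
    diag_full = diag + bdiag

    rows = np.concatenate([np.arange(mesh.n_cells), mesh.face_owner, mesh.face_neigh])
    cols = np.concatenate([np.arange(mesh.n_cells), mesh.face_neigh, mesh.face_owner])
    data = np.concatenate([diag_full, off_on, off_no])
    A = sp.coo_matrix((data, (rows, cols)),
                      shape=(mesh.n_cells, mesh.n_cells)).tocsc()

    rhs = rho * V / dt * c + source
    if config.convection == "linear_upwind":
        bvals = c[mesh.bface_owner].copy()
        bvals[inlet] = 0.0
        grad = mesh.green_gauss_gradient(c, boundary_values=bvals)
        up_cell = np.where(F >= 0, mesh.face_owner, mesh.face_neigh)
        dx = mesh.cell_centers[mesh.face_neigh] - mesh.cell_centers[mesh.face_owner]
        sgn = np.where(F >= 0, 0.5, -0.5)[:, None]
        corr = (grad[up_cell] * (dx * sgn)).sum(axis=1)
        flux_corr = rho * F * corr
        np.add.at(rhs, mesh.face_owner, -flux_corr)
        np.add.at(rhs, mesh.face_neigh, flux_corr)

    out = spla.spsolve(A, rhs)
    if not np.all(np.isfinite(out)):
        raise RuntimeError("non-finite scalar field in transport step")
    return out


def advance_moment(k: int, m_k: np.ndarray, m_prev: np.ndarray | None,
                   velocity: np.ndarray, mesh: Mesh, config: TransportConfig,
                   dt: float, *, flux: np.ndarray | None = None,
                   bflux: np.ndarray | None = None) -> np.ndarray:
    """One implicit-Euler step of the age-moment equation (k = 1 or 2).

    ``m_prev`` is the lower moment m_{k-1} at the new time level; for k = 1 it
    may be omitted (m0 = 1 identically).
    """
    if k not in (1, 2):
        raise ValueError("moment order k must be 1 or 2")
    if k == 2 and m_prev is None:
        raise ValueError("advance_moment(k=2) requires the first moment m1")
    if m_prev is None:
        m_prev = np.ones(mesh.n_cells)
    source = config.density * k * m_prev * mesh.cell_volumes
    return _advance_scalar(m_k, mesh, config, dt, config.diffusivity(f"m{k}"),
                           source, velocity, flux, bflux)


def advance_washout(phi: np.ndarray, velocity: np.ndarray, mesh: Mesh,
                    config: TransportConfig, dt: float, *,
                    flux: np.ndarray | None = None,
                    bflux: np.ndarray | None = None) -> np.ndarray:
    """One implicit-Euler step of the washout equation (no source)."""
    source = np.zeros(mesh.n_cells)
    return _advance_scalar(phi, mesh, config, dt, config.diffusivity("washout"),
                           source, velocity, flux, bflux)


@dataclass
class ScalarFieldSeries:
    """Per-cell time series of one stasis scalar (m1, m2 or washout)."""

    tag: str                      # "m1" (s), "m2" (s^2), "washout" (-)
    times: np.ndarray             # (Nt,)
    values: np.ndarray            # (Nt, Nc)

    def mean_over(self, cells: np.ndarray, it: int = -1) -> float:
        return float(self.values[it, cells].mean())


def run_transport(series: FlowSeries, config: TransportConfig | None = None,
                  tags: tuple = ("m1", "m2", "washout"),
                  n_keep: int | None = None) -> dict:
    """March the stasis scalars over a stored velocity-snapshot series.

    The scalars start from their initial data (m_k = 0, phi = 1) at the first
    snapshot and are advanced snapshot-to-snapshot with the stored
    divergence-free face fluxes; m1 feeds the m2 source at the new time level.
    Returns ``{tag: ScalarFieldSeries}`` keeping the last ``n_keep`` snapshots
    (all by default).
    """
    cfg = config or TransportConfig()
    mesh = series.mesh
    nt = len(series)
    dt = float(np.diff(series.times).mean()) if nt > 1 else float(series.times[0])

    m1 = np.zeros(mesh.n_cells)
    m2 = np.zeros(mesh.n_cells)
    phi = np.ones(mesh.n_cells)
    hist = {tag: np.empty((nt, mesh.n_cells)) for tag in tags}
    for i in range(nt):
        v, F, Fb = series.velocity[i], series.flux[i], series.bflux[i]
        if "m1" in tags or "m2" in tags:
            m1 = advance_moment(1, m1, None, v, mesh, cfg, dt, flux=F, bflux=Fb)
        if "m2" in tags:
            m2 = advance_moment(2, m2, m1, v, mesh, cfg, dt, flux=F, bflux=Fb)
        if "washout" in tags:
            phi = advance_washout(phi, v, mesh, cfg, dt, flux=F, bflux=Fb)
        for tag, val in (("m1", m1), ("m2", m2), ("washout", phi)):
            if tag in tags:
                hist[tag][i] = val

    keep = slice(-n_keep, None) if n_keep else slice(None)
    return {tag: ScalarFieldSeries(tag, series.times[keep], hist[tag][keep])
            for tag in tags}
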