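"""Desk-scale idealized atrium case: geometry, mesh and pulsatile boundary data.

The patient left atrium is emulated by a 2-D rectangular chamber with a blind
rectangular side pocket standing in for the atrial appendage: several equal
flow inlets ("pulmonary veins") on the top wall, one pulsatile outlet ("mitral
valve") on the bottom wall, rigid no-slip walls everywhere else, and the
pocket attached to the left wall where stasis concentrates.  All units are SI;
2-D flow rates are per unit depth (m^2/s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .mesh import Mesh, MeshConfigError, _snap, mesh_from_mask


@dataclass
class CaseConfig:
    """Geometry, discretization and cardiac-cycle settings for a synthetic case.

    Lengths in metres.  ``period`` is the cardiac period T (1.07 s), ``dt_max``
    the maximum time step, ``n_cycles`` the number of cycles integrated from
    rest (statistics are collected on the final cycle).  ``stroke_volume`` is
    the per-unit-depth volume (m^2) expelled through the outlet per cycle at
    scaling factor f = 1.
    """

    chamber_length: float = 0.04
    chamber_height: float = 0.02
    pocket_length: float = 0.01
    pocket_width: float = 0.006
    h: float = 0.001
    n_inlets: int = 4
    period: float = 1.07
    dt_max: float = 0.01
    n_cycles: int = 4
    rheology: str = "newtonian"
    stroke_volume: float = 3.0e-4
    inlet_width: float | None = None      # default: chamber_length / (2 n_inlets)
    outlet_width: float | None = None     # default: chamber_length / 5
    mv_opening: float = 0.4               # outlet opens near t = mv_opening * T

    def __post_init__(self):
        for name in ("chamber_length", "chamber_height", "pocket_length",
                     "pocket_width", "h", "period", "dt_max", "stroke_volume"):
            if getattr(self, name) <= 0:
                raise MeshConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_inlets < 1:
            raise MeshConfigError("n_inlets must be >= 1")
        if self.n_cycles < 1:
            raise MeshConfigError("n_cycles must be >= 1")
        if self.dt_max > self.period:
            raise MeshConfigError("dt_max must not exceed the period")
        if self.pocket_width > self.chamber_height:
            raise MeshConfigError("pocket wider than the chamber")
        if self.pocket_length > self.chamber_length:
            raise MeshConfigError("pocket longer than the chamber")
        if self.rheology not in ("newtonian", "casson"):
            raise MeshConfigError(f"unknown rheology {self.rheology!r}")
        if self.inlet_width is None:
            self.inlet_width = self.chamber_length / (2 * self.n_inlets)
        if self.outlet_width is None:
            self.outlet_width = self.chamber_length / 5

    @classmethod
    def from_file(cls, path) -> "CaseConfig":
        """Read a plain-text key/value (YAML) config file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise MeshConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def build_mesh(config: CaseConfig) -> Mesh:
    """Mesh the chamber with the blind pocket attached to the left wall.

    The pocket occupies ``[-pocket_length, 0] x [yc - w/2, yc + w/2]`` with
    ``yc`` the chamber mid-height; pocket cells carry region tag 1.
    Inlet patches are ``n_inlets`` equal segments evenly spaced on the top
    wall; the outlet is a centred segment of the bottom wall.
    """
    h = config.h
    nxc = _snap(config.chamber_length, h, "chamber_length")
    nyc = _snap(config.chamber_height, h, "chamber_height")
    nxp = _snap(config.pocket_length, h, "pocket_length")
    nyp = _snap(config.pocket_width, h, "pocket_width")
    if nyp > nyc:
        raise MeshConfigError("pocket wider than the chamber after snapping")

    nx, ny = nxc + nxp, nyc
    active = np.zeros((nx, ny), dtype=bool)
    region = np.zeros((nx, ny), dtype=int)
    active[nxp:, :] = True                       # chamber
    j0 = (nyc - nyp) // 2
    active[:nxp, j0:j0 + nyp] = True             # pocket
    region[:nxp, :] = 1
    origin = (-config.pocket_length, 0.0)

    L, H = config.chamber_length, config.chamber_height
    # inlet segments on the top wall, centred at L*(k+1/2)/n_inlets
    wi = config.inlet_width
    inlet_lo = np.array([L * (k + 0.5) / config.n_inlets - wi / 2
                         for k in range(config.n_inlets)])
    inlet_hi = inlet_lo + wi
    out_lo = L / 2 - config.outlet_width / 2
    out_hi = L / 2 + config.outlet_width / 2
    tol = 1e-9 * h

    def patch_of(x, y, n):
        if n[1] > 0.5 and abs(y - H) < tol:      # top wall
            for k in range(config.n_inlets):
                if inlet_lo[k] - tol < x < inlet_hi[k] + tol:
                    return f"inlet_{k}"
        if n[1] < -0.5 and abs(y) < tol:         # bottom wall
            if out_lo - tol < x < out_hi + tol:
                return "outlet"
        return "wall"

    mesh = mesh_from_mask(active, origin, h, patch_of, region=region)
    for k in range(config.n_inlets):
        if mesh.patch_faces(f"inlet_{k}").size == 0:  # pragma: no cover
            raise MeshConfigError(f"inlet_{k} received no boundary faces")
    if mesh.patch_faces("outlet").size == 0:  # pragma: no cover
        raise MeshConfigError("outlet received no boundary faces")
    return mesh


def build_channel_mesh(length: float, height: float, h: float) -> Mesh:
    """Straight 2-D channel fixture: inlet at x=0, outlet at x=length, walls.

    Verification geometry (Poiseuille flow, plug-flow transport oracles);
    not part of the atrium case family, hence no pocket.
    """
    nx = _snap(length, h, "length")
    ny = _snap(height, h, "height")
    active = np.ones((nx, ny), dtype=bool)
    tol = 1e-9 * h

    def patch_of(x, y, n):
        if n[0] < -0.5 and abs(x) < tol:
            return "inlet_0"
        if n[0] > 0.5 and abs(x - length) < tol:
            return "outlet"
        return "wall"

    return mesh_from_mask(active, (0.0, 0.0), h, patch_of)


@dataclass
class Waveform:
    """Pulsatile outlet ("mitral valve") flow-rate waveform.

    Q(t; f) = f * stroke_volume * g(t) / integral(g), with g a smooth
    sin^2 pulse supported on the open phase [opening*T, T] and zero during
    the closed phase.  Exactly linear in the scaling factor f and periodic
    with period T.  Rates are per unit depth (m^2/s).
    """

    period: float = 1.07
    stroke_volume: float = 3.0e-4
    opening: float = 0.4

    def __call__(self, t, f: float = 1.0):
        return self.rate(t, f)

    def rate(self, t, f: float = 1.0):
        """Volumetric flow rate Q(t; f); t is wrapped modulo the period."""
        if not 0.5 <= f <= 1.5:
            warnings.warn(f"scaling factor f={f} outside the study range [0.5, 1.5]",
                          stacklevel=2)
        t = np.asarray(t, dtype=float)
        T = self.period
        tau = np.mod(t, T)
        t_open = self.opening * T
        width = T - t_open
        phase = (tau - t_open) / width
        g = np.where((tau >= t_open), np.sin(np.pi * np.clip(phase, 0.0, 1.0)) ** 2, 0.0)
        # integral of sin^2 over the open window is width/2
        q = f * self.stroke_volume * g / (width / 2)
        return float(q) if q.ndim == 0 else q

    @classmethod
    def from_config(cls, config: CaseConfig) -> "Waveform":
        return cls(period=config.period, stroke_volume=config.stroke_volume,
                   opening=config.mv_opening)


def mv_waveform(t, f: float = 1.0, *, period: float = 1.07,
                stroke_volume: float = 3.0e-4, opening: float = 0.4):
    """Outlet flow rate Q(t; f); thin wrapper over :class:`Waveform`."""
    return Waveform(period, stroke_volume, opening).rate(t, f)


def inlet_split(total_rate: float, mesh: Mesh) -> dict:
    """Split a total inflow rate equally over the inlet patches.

    Each pulmonary-vein inlet carries the same flow rate; returns
    ``{patch_name: rate}``.  The per-patch plug velocity is
    ``rate / patch_area`` directed inward.
    """
    inlets = mesh.inlet_patch_names()
    if not inlets:
        raise MeshConfigError("mesh has no inlet patches")
    for name in inlets:
        if mesh.patch_area(name) <= 0:
            raise MeshConfigError(f"inlet patch {name} has zero area")
    share = total_rate / len(inlets)
    return {name: share for name in inlets}
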