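"""Wall shear stress and its cycle-averaged indices (TAWSS, OSI).

WSS is the tangential traction of the deviatoric stress on the wall,
WSS = T_d . n = 2 mu D(v) . n.  At a no-slip wall the dominant term is
mu du_t/dn; the wall-normal gradient is evaluated with the same one-sided
two-point stencil the flow solver uses for wall diffusion, and the same
effective viscosity, so the reported stress is discretely consistent with
the momentum balance.

Cycle statistics:

    TAWSS = (1/T) int_0^T ||WSS|| dt
    OSI   = 1/2 [ 1 - ||int_0^T WSS dt|| / int_0^T ||WSS|| dt ]

OSI ranges from 0 (unidirectional shear) to 0.5 (fully reversing shear).
Time integrals use the cycle-periodic trapezoidal rule: the snapshots sample
one period uniformly without a duplicated endpoint, for which the trapezoidal
rule reduces to (sample mean) x T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import Mesh
from .rheology import RheologyParams, effective_viscosity


@dataclass
class WallStressSeries:
    """WSS vectors (Pa) on the wall-patch boundary faces over one cycle."""

    times: np.ndarray             # (Nt,)
    values: np.ndarray            # (Nt, Nw, 2)
    face_ids: np.ndarray          # (Nw,) indices into the mesh boundary faces

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.values, axis=2)


@dataclass
class SteadyIndexField:
    """One cycle-averaged wall index per wall face."""

    tag: str                      # "TAWSS" (Pa) or "OSI" (-)
    values: np.ndarray            # (Nw,)
    face_ids: np.ndarray


def wall_shear_stress(velocity: np.ndarray, rheology: RheologyParams,
                      mesh: Mesh, wall_patch: str = "wall") -> np.ndarray:
    """WSS vectors (Nw, 2) on the wall faces for one velocity snapshot.

    Zero velocity gives exactly zero stress.  The effective viscosity at the
    wall is evaluated from the wall shear rate itself (J2 = (du_t/dn)^2 / 4).
    """
    wall = mesh.patch_faces(wall_patch)
    owner = mesh.bface_owner[wall]
    n = mesh.bface_normal[wall]
    tangent = np.column_stack([-n[:, 1], n[:, 0]])
    u_t = (velocity[owner] * tangent).sum(axis=1)
    dudn = u_t / (mesh.h / 2.0)                 # one-sided, solver-consistent
    j2_wall = dudn ** 2 / 4.0
    mu = np.atleast_1d(effective_viscosity(j2_wall, rheology))
    return (mu * dudn)[:, None] * tangent


def wall_stress_series(velocity_series: np.ndarray, times: np.ndarray,
                       rheology: RheologyParams, mesh: Mesh,
                       wall_patch: str = "wall") -> WallStressSeries:
    """Evaluate the WSS on every snapshot of a velocity series."""
    wall = mesh.patch_faces(wall_patch)
    out = np.empty((len(times), wall.size, 2))
    for i, v in enumerate(velocity_series):
        out[i] = wall_shear_stress(v, rheology, mesh, wall_patch)
    return WallStressSeries(times=np.asarray(times), values=out, face_ids=wall)


def _cycle_integral(values: np.ndarray, period: float) -> np.ndarray:
    """Periodic trapezoidal integral over one cycle: mean(samples) * T."""
    return values.mean(axis=0) * period


def tawss(series: WallStressSeries, period: float) -> SteadyIndexField:
    """Time-averaged WSS magnitude per wall face (Pa)."""
    if series.values.shape[0] == 0:
        raise ValueError("empty WSS series")
    mean_mag = _cycle_integral(series.magnitudes(), period) / period
    return SteadyIndexField("TAWSS", mean_mag, series.face_ids)


def osi(series: WallStressSeries, period: float) -> SteadyIndexField:
    """Oscillatory shear index per wall face, in [0, 0.5].

    Faces whose shear is identically zero over the cycle get OSI = 0.
    """
    if series.values.shape[0] == 0:
        raise ValueError("empty WSS series")
    int_vec = _cycle_integral(series.values, period)       # (Nw, 2)
    int_mag = _cycle_integral(series.magnitudes(), period)  # (Nw,)
    num = np.linalg.norm(int_vec, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(int_mag > 0, num / np.maximum(int_mag, 1e-300), 1.0)
    vals = 0.5 * (1.0 - np.clip(ratio, 0.0, 1.0))
    return SteadyIndexField("OSI", vals, series.face_ids)


__all__ = ["WallStressSeries", "SteadyIndexField", "wall_shear_stress",
           "wall_stress_series", "tawss", "osi"]
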