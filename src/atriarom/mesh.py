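"""Structured 2-D finite-volume mesh with labelled boundary patches.

The mesh is a uniform Cartesian grid restricted to an "active" cell mask,
stored in the owner/neighbour face format used by cell-centred finite-volume
solvers.  All geometric quantities are per unit depth (2-D): cell "volumes"
are areas (m^2) and face "areas" are lengths (m).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: axis unit vectors for face normals (x, y)
_AXES = np.array([[1.0, 0.0], [0.0, 1.0]])


@dataclass
class Mesh:
    """Cell-centred finite-volume mesh on a uniform Cartesian grid.

    Attributes
    ----------
    h : float
        Uniform grid spacing (m).
    cell_centers : (Nc, 2) float array
    cell_volumes : (Nc,) float array
        Cell areas per unit depth (h**2).
    region : (Nc,) int array
        Region tag per cell (0 = main chamber, 1 = pocket).
    face_owner, face_neigh : (Nf,) int arrays
        Interior faces; the face normal points from owner to neighbour
        along axis ``face_axis``.
    face_axis : (Nf,) int array in {0, 1}
    bface_owner : (Nb,) int array
    bface_normal : (Nb, 2) float array
        Unit outward normals of boundary faces.
    bface_center : (Nb, 2) float array
    bface_patch : (Nb,) int array
        Index into ``patch_names``.
    patch_names : list of str
        e.g. ``["inlet_0", ..., "outlet", "wall"]``.
    """

    h: float
    cell_centers: np.ndarray
    cell_volumes: np.ndarray
    region: np.ndarray
    face_owner: np.ndarray
    face_neigh: np.ndarray
    face_axis: np.ndarray
    bface_owner: np.ndarray
    bface_normal: np.ndarray
    bface_center: np.ndarray
    bface_patch: np.ndarray
    patch_names: list = field(default_factory=list)
    # grid bookkeeping (index coordinates of active cells), used by builders
    cell_ij: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.cell_centers.shape[0]

    @property
    def n_faces(self) -> int:
        return self.face_owner.shape[0]

    @property
    def n_bfaces(self) -> int:
        return self.bface_owner.shape[0]

    @property
    def face_area(self) -> float:
        """Face length per unit depth; uniform grid, so a scalar."""
        return self.h

    def patch_id(self, name: str) -> int:
        try:
            return self.patch_names.index(name)
        except ValueError:
            raise KeyError(f"no boundary patch named {name!r}; have {self.patch_names}")

    def patch_faces(self, name: str) -> np.ndarray:
        """Indices (into boundary-face arrays) of the faces of one patch."""
        return np.flatnonzero(self.bface_patch == self.patch_id(name))

    def patch_area(self, name: str) -> float:
        return self.patch_faces(name).size * self.face_area

    def inlet_patch_names(self) -> list:
        return [p for p in self.patch_names if p.startswith("inlet")]

    def boundary_closure(self) -> np.ndarray:
        """Sum of outward area vectors over the boundary (zero for a closed mesh)."""
        return (self.bface_normal * self.face_area).sum(axis=0)

    def pocket_cells(self) -> np.ndarray:
        return np.flatnonzero(self.region == 1)

    def chamber_cells(self) -> np.ndarray:
        return np.flatnonzero(self.region == 0)

    # -- discrete operators shared by the flow and transport solvers ---------

    def green_gauss_gradient(self, values: np.ndarray,
                             boundary_values: np.ndarray | None = None) -> np.ndarray:
        """Green–Gauss cell gradient of a cell field.

        ``boundary_values`` are face values on boundary faces; when omitted a
        zero-normal-gradient extrapolation (face value = owner value) is used.
        Returns an array of shape ``values.shape + (2,)``.
        """
        values = np.asarray(values, dtype=float)
        scalar = values.ndim == 1
        vals = values[:, None] if scalar else values
        ncomp = vals.shape[1]
        grad = np.zeros((self.n_cells, ncomp, 2))
        area = self.face_area

        fv = 0.5 * (vals[self.face_owner] + vals[self.face_neigh])  # (Nf, ncomp)
        for ax in (0, 1):
            sel = self.face_axis == ax
            contrib = fv[sel] * area
            np.add.at(grad[:, :, ax], self.face_owner[sel], contrib)
            np.add.at(grad[:, :, ax], self.face_neigh[sel], -contrib)

        if boundary_values is None:
            bv = vals[self.bface_owner]
        else:
            bv = np.asarray(boundary_values, dtype=float)
            if bv.ndim == 1:
                bv = bv[:, None]
        bcontrib = bv[:, :, None] * (self.bface_normal * area)[:, None, :]
        np.add.at(grad, self.bface_owner, bcontrib)

        grad /= self.cell_volumes[:, None, None]
        return grad[:, 0, :] if scalar else grad


class MeshConfigError(ValueError):
    """Raised when the case geometry cannot produce a valid mesh."""


def _snap(length: float, h: float, name: str) -> int:
    """Number of cells along a dimension; h must divide it to within one cell."""
    n = int(round(length / h))
    if n < 1:
        raise MeshConfigError(f"{name}={length} smaller than one cell (h={h})")
    if abs(n * h - length) > h:
        raise MeshConfigError(
            f"spacing h={h} does not divide {name}={length} to within one cell")
    return n


def mesh_from_mask(active: np.ndarray, origin: tuple, h: float,
                   patch_of_bface, region: np.ndarray | None = None) -> Mesh:
    """Build the owner/neighbour face structure from an active-cell mask.

    ``active`` is an (nx, ny) boolean array; ``patch_of_bface(x, y, n)`` maps a
    boundary-face center and outward normal to a patch name.
    """
    nx, ny = active.shape
    cid = -np.ones((nx, ny), dtype=int)
    ii, jj = np.nonzero(active)
    cid[ii, jj] = np.arange(ii.size)
    x0, y0 = origin
    centers = np.column_stack([x0 + (ii + 0.5) * h, y0 + (jj + 0.5) * h])
    volumes = np.full(ii.size, h * h)
    reg = np.zeros(ii.size, dtype=int) if region is None else region[ii, jj].astype(int)

    f_owner, f_neigh, f_axis = [], [], []
    # interior faces along x then y
    both = active[:-1, :] & active[1:, :]
    a, b = np.nonzero(both)
    f_owner.append(cid[a, b]); f_neigh.append(cid[a + 1, b])
    f_axis.append(np.zeros(a.size, dtype=int))
    both = active[:, :-1] & active[:, 1:]
    a, b = np.nonzero(both)
    f_owner.append(cid[a, b]); f_neigh.append(cid[a, b + 1])
    f_axis.append(np.ones(a.size, dtype=int))

    face_owner = np.concatenate(f_owner)
    face_neigh = np.concatenate(f_neigh)
    face_axis = np.concatenate(f_axis)

    # boundary faces: active cell next to inactive / outside
    b_owner, b_normal, b_center = [], [], []
    pad = np.zeros((nx + 2, ny + 2), dtype=bool)
    pad[1:-1, 1:-1] = active
    for (di, dj) in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nbr = pad[1 + di:nx + 1 + di, 1 + dj:ny + 1 + dj]
        edge = active & ~nbr
        a, b = np.nonzero(edge)
        b_owner.append(cid[a, b])
        n = np.array([di, dj], dtype=float)
        b_normal.append(np.tile(n, (a.size, 1)))
        cx = x0 + (a + 0.5) * h + di * h / 2
        cy = y0 + (b + 0.5) * h + dj * h / 2
        b_center.append(np.column_stack([cx, cy]))

    bface_owner = np.concatenate(b_owner)
    bface_normal = np.vstack(b_normal)
    bface_center = np.vstack(b_center)

    names: list = []
    patch_idx = np.empty(bface_owner.size, dtype=int)
    for k in range(bface_owner.size):
        name = patch_of_bface(bface_center[k, 0], bface_center[k, 1], bface_normal[k])
        if name not in names:
            names.append(name)
        patch_idx[k] = names.index(name)
    # canonical patch order: inlets (sorted), outlet, wall
    order = sorted(names, key=lambda s: (not s.startswith("inlet"), s != "outlet", s))
    remap = np.array([order.index(n) for n in names])
    patch_idx = remap[patch_idx]

    mesh = Mesh(h=h, cell_centers=centers, cell_volumes=volumes, region=reg,
                face_owner=face_owner, face_neigh=face_neigh, face_axis=face_axis,
                bface_owner=bface_owner, bface_normal=bface_normal,
                bface_center=bface_center, bface_patch=patch_idx,
                patch_names=order, cell_ij=np.column_stack([ii, jj]))
    return mesh
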