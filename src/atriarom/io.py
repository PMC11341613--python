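"""Field export (legacy ASCII VTK), wall-index tables and offline artifacts.

Cell fields are written as VTK UNSTRUCTURED_GRID files with one quad per
finite-volume cell, readable by ParaView and friends.  A minimal reader for
the same dialect supports write/read roundtrips.  Offline ROM artifacts go
into a compressed .npz plus a JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .mesh import Mesh


def _mesh_points_cells(mesh: Mesh):
    """Unique corner points and per-cell quad connectivity."""
    h = mesh.h
    corners = mesh.cell_centers[:, None, :] + 0.5 * h * np.array(
        [[-1, -1], [1, -1], [1, 1], [-1, 1]])        # (Nc, 4, 2), CCW
    flat = corners.reshape(-1, 2)
    keys = np.round(flat / h * 2).astype(np.int64)   # corners sit on the h/2 lattice
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    points = uniq * (h / 2)
    conn = inverse.reshape(-1, 4)
    return points, conn


def write_vtk(path, mesh: Mesh, cell_data: dict | None = None) -> Path:
    """Write the mesh and optional cell fields to a legacy ASCII VTK file.

    ``cell_data`` maps names to (Nc,) scalar or (Nc, 2) vector arrays.
    """
    path = Path(path)
    points, conn = _mesh_points_cells(mesh)
    nc = mesh.n_cells
    lines = ["# vtk DataFile Version 3.0", "atriarom fields", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {len(points)} double"]
    lines += [f"{x:.10g} {y:.10g} 0" for x, y in points]
    lines.append(f"CELLS {nc} {nc * 5}")
    lines += ["4 " + " ".join(map(str, row)) for row in conn]
    lines.append(f"CELL_TYPES {nc}")
    lines += ["9"] * nc                               # VTK_QUAD
    if cell_data:
        lines.append(f"CELL_DATA {nc}")
        for name, arr in cell_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape[0] != nc:
                raise ValueError(f"field {name!r} has {arr.shape[0]} values "
                                 f"for {nc} cells")
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.10g}" for v in arr]
            elif arr.ndim == 2 and arr.shape[1] == 2:
                lines.append(f"VECTORS {name} double")
                lines += [f"{v[0]:.10g} {v[1]:.10g} 0" for v in arr]
            else:
                raise ValueError(f"field {name!r} has unsupported shape {arr.shape}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vtk_cell_data(path) -> dict:
    """Read back cell fields from a legacy ASCII VTK file written by write_vtk."""
    tokens = Path(path).read_text().split("\n")
    data: dict = {}
    i = 0
    ncells = None
    while i < len(tokens):
        line = tokens[i].split()
        if line[:1] == ["CELL_DATA"]:
            ncells = int(line[1])
        elif line[:1] == ["SCALARS"] and ncells is not None:
            name = line[1]
            i += 1                                    # skip LOOKUP_TABLE
            vals = [float(tokens[i + 1 + k]) for k in range(ncells)]
            data[name] = np.array(vals)
            i += ncells
        elif line[:1] == ["VECTORS"] and ncells is not None:
            name = line[1]
            rows = [tokens[i + 1 + k].split() for k in range(ncells)]
            data[name] = np.array([[float(r[0]), float(r[1])] for r in rows])
            i += ncells
        i += 1
    return data


def export_fields(fields: dict, mesh: Mesh, path) -> Path:
    """Export cell fields to one VTK file; shape-checked wrapper."""
    return write_vtk(path, mesh, cell_data=fields)


def snapshot_filename(tag: str, sample: int, time_index: int | None = None,
                      suffix: str = "vtk") -> str:
    """Canonical snapshot file name encoding variable, sample and time index."""
    if time_index is None:
        return f"{tag}_s{sample:03d}.{suffix}"
    return f"{tag}_s{sample:03d}_t{time_index:03d}.{suffix}"


def write_wall_table(path, mesh: Mesh, face_ids: np.ndarray,
                     columns: dict) -> Path:
    """Per-wall-face index table as tab-delimited text (x, y, then columns)."""
    import pandas as pd

    centers = mesh.bface_center[face_ids]
    table = {"x": centers[:, 0], "y": centers[:, 1]}
    for name, arr in columns.items():
        arr = np.asarray(arr)
        if arr.shape[0] != face_ids.size:
            raise ValueError(f"column {name!r} has {arr.shape[0]} rows for "
                             f"{face_ids.size} wall faces")
        table[name] = arr
    path = Path(path)
    pd.DataFrame(table).to_csv(path, sep="\t", index=False)
    return path


def save_artifacts(directory, arrays: dict, manifest: dict) -> Path:
    """Persist offline ROM artifacts: arrays.npz + manifest.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(directory / "arrays.npz", **arrays)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return directory


def load_artifacts(directory):
    """Load arrays and manifest written by :func:`save_artifacts`."""
    directory = Path(directory)
    npz = directory / "arrays.npz"
    man = directory / "manifest.json"
    if not npz.exists() or not man.exists():
        raise FileNotFoundError(f"no offline artifacts under {directory}")
    arrays = dict(np.load(npz, allow_pickle=False))
    with open(man) as fh:
        manifest = json.load(fh)
    return arrays, manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
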