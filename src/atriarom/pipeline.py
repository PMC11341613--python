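"""Offline/online orchestration of the full stasis-index ROM workflow.

Offline: for every training design point, run the full-order flow solver over
``n_cycles`` cardiac cycles from rest, transport the stasis scalars
(m1, m2, washout) along the stored velocity snapshots, evaluate the wall
indices (TAWSS, OSI) on the final cycle, assemble the five snapshot matrices
and fit one POD-RBF surrogate per variable.  Everything, including the random
seeds and retained mode counts, is persisted with a JSON run manifest.

Online: load the artifacts and evaluate the surrogates at new parameter
values (and times, for the unsteady scalars); when matching full-order truth
fields are supplied, relative-error reports are emitted.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .case import CaseConfig, build_mesh
from .flow import SolverConfig, run_cycles, snapshot_count
from .io import load_artifacts, save_artifacts
from .mesh import Mesh
from .rheology import RheologyParams
from .rom import POD, PODRBFROM, RBFInterpolant, SnapshotMatrix, \
    assemble_snapshots, relative_error, sample_lhs, sample_uniform
from .transport import TransportConfig, run_transport
from .wallstress import osi, tawss, wall_stress_series

UNSTEADY_VARIABLES = ("m1", "m2", "washout")
STEADY_VARIABLES = ("TAWSS", "OSI")
ALL_VARIABLES = UNSTEADY_VARIABLES + STEADY_VARIABLES

#: study parameter ranges: scaling factor f, plasma viscosity (Pa s),
#: hematocrit (percent)
F_RANGE = (0.5, 1.5)
ETA_RANGE = (1.5e-3, 1.7e-3)
H_RANGE = (35.0, 50.0)


@dataclass
class DesignConfig:
    """Parameter-space sampling design for the offline phase."""

    n_samples: int = 20
    method: str = "uniform"          # "uniform" (1-D, Newtonian) or "lhs" (Casson)
    f_range: tuple = F_RANGE
    eta_range: tuple = ETA_RANGE
    h_range: tuple = H_RANGE
    test_indices: tuple = ()         # held-out sample indices (0-based)
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("uniform", "lhs"):
            raise ValueError(f"unknown sampling method {self.method!r}")


@dataclass
class ROMSettings:
    energy: float = 0.99
    kernel: str = "thin_plate_spline"
    shape: float = 1.0


@dataclass
class OfflineConfig:
    case: CaseConfig = field(default_factory=CaseConfig)
    design: DesignConfig = field(default_factory=DesignConfig)
    rom: ROMSettings = field(default_factory=ROMSettings)

    @classmethod
    def from_file(cls, path) -> "OfflineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(case=CaseConfig(**data.get("case", {})),
                   design=DesignConfig(**{k: tuple(v) if isinstance(v, list) else v
                                          for k, v in data.get("design", {}).items()}),
                   rom=ROMSettings(**data.get("rom", {})))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"case": asdict(self.case),
                            "design": asdict(self.design),
                            "rom": asdict(self.rom)}, fh, sort_keys=False)


def build_design(config: DesignConfig) -> np.ndarray:
    """Training/validation parameter samples, one row per design point.

    Newtonian (uniform): (n, 1) equispaced scaling factors.  Casson (LHS):
    (n, 3) Latin-hypercube points over (f, eta, H) with the design seed.
    """
    if config.method == "uniform":
        return sample_uniform(*config.f_range, config.n_samples)[:, None]
    ranges = [config.f_range, config.eta_range, config.h_range]
    return sample_lhs(ranges, config.n_samples, seed=config.seed)


def rheology_for_sample(case: CaseConfig, sample: np.ndarray) -> RheologyParams:
    sample = np.atleast_1d(sample)
    if case.rheology == "newtonian":
        return RheologyParams(model="newtonian")
    return RheologyParams(model="casson", plasma_viscosity=float(sample[1]),
                          hematocrit=float(sample[2]))


def compute_sample_fields(case: CaseConfig, sample: np.ndarray, *,
                          mesh: Mesh | None = None,
                          transport: TransportConfig | None = None) -> dict:
    """Full-order pipeline for one design point.

    Runs the flow for ``case.n_cycles`` cycles from rest, transports the
    scalars from t = 0 and keeps the final cycle, and reduces the final-cycle
    WSS series to TAWSS/OSI.  Returns ``{variable: array}`` with (N_t, N_h)
    series for the unsteady scalars and (N_w,) fields for the wall indices,
    plus the relative final-cycle times under ``"times"``.
    """
    sample = np.atleast_1d(sample)
    f = float(sample[0])
    if mesh is None:
        mesh = build_mesh(case)
    rheo = rheology_for_sample(case, sample)
    cfg = SolverConfig(dt_max=case.dt_max)
    series_all = run_cycles(case, rheo, cfg, mesh=mesh, f=f, return_all=True)

    n_keep = snapshot_count(case.period, cfg.dt_snap)
    scalars = run_transport(series_all, transport, n_keep=n_keep)

    final = series_all.final_cycle(case.period, cfg.dt_snap)
    wss = wall_stress_series(final.velocity, final.times, rheo, mesh)
    out = {tag: scalars[tag].values for tag in UNSTEADY_VARIABLES}
    out["TAWSS"] = tawss(wss, case.period).values
    out["OSI"] = osi(wss, case.period).values
    out["times"] = final.times - (case.n_cycles - 1) * case.period
    out["wall_faces"] = wss.face_ids
    return out


@dataclass
class RunManifest:
    """Reproducibility record of one offline run."""

    config: dict
    seed: int
    samples: list
    train_indices: list
    test_indices: list
    n_cells: int
    n_time: int
    n_columns: dict
    n_modes: dict
    timings: dict

    def to_dict(self) -> dict:
        return asdict(self)


def run_offline(config: OfflineConfig, outdir, *,
                transport: TransportConfig | None = None) -> RunManifest:
    """Execute the offline phase and persist all artifacts under ``outdir``."""
    outdir = Path(outdir)
    t_start = time.perf_counter()
    mesh = build_mesh(config.case)
    design = build_design(config.design)
    test_idx = sorted(set(int(i) for i in config.design.test_indices))
    train_idx = [j for j in range(design.shape[0]) if j not in test_idx]
    if not train_idx:
        raise ValueError("the training design is empty after the held-out split")

    per_sample = []
    for j in train_idx:
        try:
            per_sample.append(compute_sample_fields(
                config.case, design[j], mesh=mesh, transport=transport))
        except Exception as err:
            raise RuntimeError(f"offline stage failed at design point {j} "
                               f"(mu={design[j]}): {err}") from err
    t_fom = time.perf_counter()

    times = per_sample[0]["times"]
    train_samples = design[train_idx]
    snaps = {}
    for var in UNSTEADY_VARIABLES:
        snaps[var] = assemble_snapshots([s[var] for s in per_sample],
                                        train_samples, times, tag=var)
    for var in STEADY_VARIABLES:
        snaps[var] = assemble_snapshots([s[var] for s in per_sample],
                                        train_samples, tag=var)

    arrays, n_modes, n_columns = {}, {}, {}
    rs = config.rom
    t_pod = t_rbf = 0.0
    for var, snap in snaps.items():
        t0 = time.perf_counter()
        model = PODRBFROM(energy=rs.energy, kernel=rs.kernel, shape=rs.shape)
        model.pod_ = POD(energy=rs.energy).fit(snap.matrix.T)
        t1 = time.perf_counter()
        alpha = model.pod_.transform(snap.matrix.T)
        model.rbf_ = RBFInterpolant(kernel=rs.kernel, shape=rs.shape).fit(
            snap.coordinates(), alpha)
        t2 = time.perf_counter()
        t_pod += t1 - t0
        t_rbf += t2 - t1
        n_modes[var] = int(model.pod_.n_modes_)
        n_columns[var] = int(snap.n_columns)
        arrays.update(_pack_model(var, model, snap))
    arrays["wall_faces"] = per_sample[0]["wall_faces"]

    manifest = RunManifest(
        config={"case": asdict(config.case), "design": asdict(config.design),
                "rom": asdict(rs)},
        seed=config.design.seed,
        samples=design.tolist(),
        train_indices=train_idx,
        test_indices=test_idx,
        n_cells=mesh.n_cells,
        n_time=int(times.size),
        n_columns=n_columns,
        n_modes=n_modes,
        timings={"fom_s": t_fom - t_start, "pod_s": t_pod, "rbf_s": t_rbf},
    )
    save_artifacts(outdir, arrays, manifest.to_dict())
    _check_consistency(arrays, manifest.to_dict())
    return manifest


def _pack_model(var: str, model: PODRBFROM, snap: SnapshotMatrix) -> dict:
    pre = f"{var}__"
    return {
        pre + "components": model.pod_.components_,
        pre + "singular_values": model.pod_.singular_values_,
        pre + "nodes": model.rbf_.nodes_,
        pre + "weights": model.rbf_.weights_,
        pre + "poly": model.rbf_.poly_coeffs_,
        pre + "lower": model.rbf_.lower_,
        pre + "span": model.rbf_.span_,
        pre + "active_dims": model.rbf_.active_dims_,
        pre + "times": snap.times,
        pre + "samples": snap.samples,
        pre + "matrix": snap.matrix,
    }


def _unpack_model(var: str, arrays: dict, rom: dict) -> tuple:
    pre = f"{var}__"
    podm = POD(energy=rom.get("energy", 0.99))
    podm.components_ = arrays[pre + "components"]
    podm.singular_values_ = arrays[pre + "singular_values"]
    podm.n_modes_ = podm.components_.shape[0]
    podm.rank_ = podm.singular_values_.size
    rbf = RBFInterpolant(kernel=rom.get("kernel", "thin_plate_spline"),
                         shape=rom.get("shape", 1.0))
    rbf.nodes_ = arrays[pre + "nodes"]
    rbf.weights_ = arrays[pre + "weights"]
    rbf.poly_coeffs_ = arrays[pre + "poly"]
    rbf.lower_ = arrays[pre + "lower"]
    rbf.span_ = arrays[pre + "span"]
    rbf.active_dims_ = arrays[pre + "active_dims"]
    rbf.n_outputs_ = rbf.weights_.shape[1]
    model = PODRBFROM(energy=rom.get("energy", 0.99),
                      kernel=rbf.kernel, shape=rbf.shape)
    model.pod_, model.rbf_ = podm, rbf
    return model, arrays[pre + "times"]


def _check_consistency(arrays: dict, manifest: dict) -> None:
    for var, ncol in manifest["n_columns"].items():
        if arrays[f"{var}__matrix"].shape[1] != ncol:
            raise RuntimeError(f"manifest/artifact mismatch for {var}")
        if arrays[f"{var}__components"].shape[0] != manifest["n_modes"][var]:
            raise RuntimeError(f"manifest mode count mismatch for {var}")


def run_online(artifact_dir, query, times=None, variables=None,
               truth: dict | None = None) -> dict:
    """Evaluate the persisted surrogates at new parameters.

    ``query`` is one parameter vector (f,) or (f, eta, H).  For the unsteady
    scalars, ``times`` defaults to the training snapshot schedule.  Steady
    variables reject an explicit ``times`` argument.  When ``truth`` supplies
    matching full-order fields, an :class:`ErrorReport` is added per variable.
    """
    arrays, manifest = load_artifacts(artifact_dir)
    variables = list(variables or ALL_VARIABLES)
    query = np.atleast_1d(np.asarray(query, dtype=float))
    results: dict = {}
    for var in variables:
        model, train_times = _unpack_model(var, arrays, manifest["config"]["rom"])
        steady = train_times.size == 0
        if steady:
            if times is not None:
                raise ValueError(f"{var} is a steady variable and takes no times")
            pred = model.predict(query[None, :])[0]
        else:
            tq = np.asarray(train_times if times is None else times, dtype=float)
            X = np.hstack([tq[:, None], np.tile(query, (tq.size, 1))])
            pred = model.predict(X)
        results[var] = pred
        if truth is not None and var in truth:
            tkw = {} if steady else {"times": tq}
            results[f"{var}_error"] = relative_error(truth[var], pred, tag=var, **tkw)
    return results
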