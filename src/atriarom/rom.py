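"""Non-intrusive POD-RBF reduced-order model.

Offline: full-order snapshots of a field Phi(x, t; mu) are collected column
by column into a snapshot matrix S (cells x snapshots); a thin SVD extracts
orthonormal spatial modes, truncated at the smallest L whose cumulative
squared singular values reach an energy threshold eps; the modal coefficients
alpha = B^T S are interpolated over (t, mu) — or mu alone for steady fields —
by radial basis functions with a degree-1 polynomial tail and the two moment
constraints (sum w_j = 0, sum w_j x_j = 0) that make the interpolant unique.

Online: for a new (t, mu) the RBF returns the modal coefficients and the
field is reconstructed as Phi_rb = sum_l alpha_l ell_l, at a cost independent
of the full-order solve.

The estimators follow the scikit-learn protocol (get_params/set_params,
fitted attributes with trailing underscores) so they compose with sklearn
pipelines and model selection; module-level functions are thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

__all__ = [
    "POD", "RBFInterpolant", "PODRBFROM", "SnapshotMatrix",
    "sample_uniform", "sample_lhs", "assemble_snapshots", "pod",
    "project_coefficients", "fit_rbf", "relative_error", "mode_energy_sweep",
]


# ---------------------------------------------------------------------------
# sampling designs
# ---------------------------------------------------------------------------

def sample_uniform(low: float, high: float, n: int) -> np.ndarray:
    """``n`` equispaced samples covering [low, high], endpoints included."""
    if n < 2:
        raise ValueError("uniform sampling needs n >= 2")
    return np.linspace(low, high, n)


def sample_lhs(ranges, n: int, seed: int | None = None) -> np.ndarray:
    """Latin hypercube design: ``n`` points over the given (low, high) ranges.

    Every coordinate takes exactly one value in each of the ``n``
    equal-probability strata; the design is reproducible for a fixed seed.
    Returns an (n, d) array.
    """
    ranges = np.atleast_2d(np.asarray(ranges, dtype=float))
    d = ranges.shape[0]
    sampler = qmc.LatinHypercube(d=d, seed=seed)
    unit = sampler.random(n)
    return qmc.scale(unit, ranges[:, 0], ranges[:, 1])


# ---------------------------------------------------------------------------
# snapshot bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class SnapshotMatrix:
    """Field snapshots as columns, with their (t, mu) column coordinates.

    ``matrix`` is (N_h, N_s).  For a time-dependent variable the columns are
    ordered parameter-outer / time-inner: (mu_1: t_1..t_Nt), (mu_2: ...), and
    N_s = N_t * N_p; steady variables have one column per parameter
    (N_s = N_p) and an empty time grid.
    """

    tag: str
    matrix: np.ndarray
    samples: np.ndarray           # (N_p, d) parameter list
    times: np.ndarray             # (N_t,) or empty for steady variables

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        self.times = np.asarray(self.times, dtype=float).ravel()
        expected = self.n_param * max(self.n_time, 1)
        if self.matrix.shape[1] != expected:
            raise ValueError(
                f"snapshot matrix has {self.matrix.shape[1]} columns, "
                f"expected N_t*N_p = {expected}")

    @property
    def n_time(self) -> int:
        return int(self.times.size)

    @property
    def n_param(self) -> int:
        return int(self.samples.shape[0])

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def column(self, j_param: int, i_time: int | None = None) -> np.ndarray:
        if self.n_time == 0:
            return self.matrix[:, j_param]
        if i_time is None:
            raise ValueError("time-dependent variable needs a time index")
        return self.matrix[:, j_param * self.n_time + i_time]

    def coordinates(self) -> np.ndarray:
        """(N_s, d+1) array of (t, mu) per column; (N_s, d) when steady."""
        if self.n_time == 0:
            return self.samples
        t = np.tile(self.times, self.n_param)[:, None]
        p = np.repeat(self.samples, self.n_time, axis=0)
        return np.hstack([t, p])


def assemble_snapshots(fields, samples, times=None, tag: str = "field"
                       ) -> SnapshotMatrix:
    """Stack per-sample field series into a snapshot matrix.

    ``fields`` is a sequence with one entry per parameter sample: an
    (N_t, N_h) array for a time-dependent variable (``times`` given) or an
    (N_h,) array for a steady one.  Columns follow the parameter-outer /
    time-inner ordering.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    if len(fields) != samples.shape[0]:
        raise ValueError(f"{len(fields)} field series for {samples.shape[0]} samples")

    cols = []
    times = np.asarray([] if times is None else times, dtype=float)
    for j, fj in enumerate(fields):
        fj = np.asarray(fj, dtype=float)
        if times.size:
            if fj.ndim != 2 or fj.shape[0] != times.size:
                raise ValueError(
                    f"sample {j}: expected ({times.size}, N_h) series, got {fj.shape}")
            cols.append(fj.T)
        else:
            if fj.ndim != 1:
                raise ValueError(f"sample {j}: steady variable must be 1-D, got {fj.shape}")
            cols.append(fj[:, None])
        if cols[-1].shape[0] != cols[0].shape[0]:
            raise ValueError(f"sample {j}: inconsistent field size")
    S = np.hstack(cols)
    if not np.all(np.isfinite(S)):
        raise ValueError("snapshot matrix contains non-finite entries")
    return SnapshotMatrix(tag=tag, matrix=S, samples=samples, times=times)


# ---------------------------------------------------------------------------
# POD (sklearn-style transformer)
# ---------------------------------------------------------------------------

class POD:
    """Proper orthogonal decomposition of uncentred snapshots.

    Follows the scikit-learn transformer protocol: ``fit(X)`` with X of shape
    (n_snapshots, n_cells) computes a thin SVD (no mean subtraction) and
    retains the smallest L modes whose cumulative squared singular values
    reach the ``energy`` fraction of the total; ``transform`` projects
    snapshots onto the modes, ``inverse_transform`` reconstructs them.

    Parameters
    ----------
    energy : float in (0, 1], default 0.99
        Cumulative-energy threshold eps.
    n_modes : int, optional
        Fixed truncation rank overriding the energy criterion.

    Attributes
    ----------
    components_ : (L, n_cells) orthonormal modes (rows).
    singular_values_ : (R,) all nonzero singular values, non-increasing.
    n_modes_ : int, retained count L.
    """

    def __init__(self, energy: float = 0.99, n_modes: int | None = None):
        self.energy = energy
        self.n_modes = n_modes

    def get_params(self, deep: bool = True) -> dict:
        return {"energy": self.energy, "n_modes": self.n_modes}

    def set_params(self, **params) -> "POD":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "POD":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.size == 0:
            raise ValueError("expected a non-empty 2-D snapshot array")
        if not np.all(np.isfinite(X)):
            raise ValueError("snapshots contain non-finite entries")
        if not 0 < self.energy <= 1:
            raise ValueError("energy threshold must lie in (0, 1]")
        # snapshots are rows here; modes are left singular vectors of S = X.T
        u, s, vt = np.linalg.svd(X.T, full_matrices=False)
        tol = s[0] * max(X.shape) * np.finfo(float).eps if s.size else 0.0
        rank = int(np.sum(s > tol))
        if rank == 0:
            raise ValueError("all-zero snapshot matrix has no POD basis")
        s = s[:rank]
        energy = np.cumsum(s ** 2) / np.sum(s ** 2)
        if self.n_modes is not None:
            L = min(self.n_modes, rank)
        else:
            L = int(np.searchsorted(energy, self.energy - 1e-14) + 1)
            L = min(L, rank)
        self.components_ = u[:, :L].T
        self.singular_values_ = s
        self.n_modes_ = L
        self.rank_ = rank
        return self

    def transform(self, X) -> np.ndarray:
        """Modal coefficients alpha = B^T Phi for each snapshot row."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.components_.shape[1]:
            raise ValueError("snapshot size does not match the fitted basis")
        return X @ self.components_.T

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, alpha) -> np.ndarray:
        self._check_fitted()
        alpha = np.asarray(alpha, dtype=float)
        if alpha.shape[-1] != self.n_modes_:
            raise ValueError(f"expected {self.n_modes_} modal coefficients")
        return alpha @ self.components_

    def retained_energy(self) -> float:
        self._check_fitted()
        s2 = self.singular_values_ ** 2
        return float(s2[: self.n_modes_].sum() / s2.sum())

    def _check_fitted(self):
        if not hasattr(self, "components_"):
            raise RuntimeError("POD instance is not fitted")


# ---------------------------------------------------------------------------
# RBF interpolation with degree-1 polynomial tail
# ---------------------------------------------------------------------------

def _kernel(r: np.ndarray, name: str, shape: float) -> np.ndarray:
    if name == "thin_plate_spline":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(r > 0, r ** 2 * np.log(r), 0.0)
        return out
    if name == "gaussian":
        return np.exp(-(shape * r) ** 2)
    if name == "multiquadric":
        return np.sqrt(1.0 + (shape * r) ** 2)
    raise ValueError(f"unknown RBF kernel {name!r}")


class RBFInterpolant:
    """Exact RBF interpolation with a degree-1 polynomial tail.

    Solves the augmented symmetric system

        [ K   P ] [ w ]   [ Y ]
        [ P^T 0 ] [ c ] = [ 0 ]

    with K_ij = psi(||x_i - x_j||), P = [1 | x], which enforces exact
    interpolation plus the moment constraints sum_j w_j = 0 and
    sum_j w_j x_j = 0.  Inputs are affinely normalized to [0, 1] per
    coordinate before kernel evaluation (the raw coordinates mix units).

    Parameters: ``kernel`` in {thin_plate_spline, gaussian, multiquadric}
    and ``shape`` (ignored by the thin-plate spline).
    """

    def __init__(self, kernel: str = "thin_plate_spline", shape: float = 1.0):
        self.kernel = kernel
        self.shape = shape

    def get_params(self, deep: bool = True) -> dict:
        return {"kernel": self.kernel, "shape": self.shape}

    def set_params(self, **params) -> "RBFInterpolant":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.span_ > 0, self.span_, 1.0)
        return (X - self.lower_) / span

    def fit(self, X, Y) -> "RBFInterpolant":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, d = X.shape
        if Y.shape[0] != n:
            raise ValueError("X and Y disagree on the number of nodes")
        self.lower_ = X.min(axis=0)
        self.span_ = X.max(axis=0) - self.lower_
        # coordinates that do not vary across the nodes cannot enter the
        # degree-1 tail (their column would duplicate the constant one)
        self.active_dims_ = np.flatnonzero(self.span_ > 0)
        da = self.active_dims_.size
        if n < da + 2:
            raise ValueError(f"need at least {da + 2} nodes for a degree-1 "
                             f"tail over {da} varying coordinate(s)")
        Xn = self._normalize(X)
        dist = np.linalg.norm(Xn[:, None, :] - Xn[None, :, :], axis=2)
        if np.any(dist[~np.eye(n, dtype=bool)] == 0):
            raise ValueError("duplicate interpolation nodes")
        K = _kernel(dist, self.kernel, self.shape)
        P = np.hstack([np.ones((n, 1)), Xn[:, self.active_dims_]])
        A = np.zeros((n + da + 1, n + da + 1))
        A[:n, :n] = K
        A[:n, n:] = P
        A[n:, :n] = P.T
        rhs = np.vstack([Y, np.zeros((da + 1, Y.shape[1]))])
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular RBF system (kernel={self.kernel}, shape={self.shape}): {err}")
        self.nodes_ = Xn
        self.weights_ = sol[:n]
        self.poly_coeffs_ = sol[n:]
        self.n_outputs_ = Y.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "weights_"):
            raise RuntimeError("RBFInterpolant is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None] if self.nodes_.shape[1] == 1 else X[None, :]
        if X.shape[1] != self.nodes_.shape[1]:
            raise ValueError("query dimension does not match the fitted nodes")
        Xn = self._normalize(X)
        if np.any(Xn < -1e-9) or np.any(Xn > 1 + 1e-9):
            warnings.warn("RBF query outside the training box (extrapolation)",
                          stacklevel=2)
        dist = np.linalg.norm(Xn[:, None, :] - self.nodes_[None, :, :], axis=2)
        K = _kernel(dist, self.kernel, self.shape)
        P = np.hstack([np.ones((X.shape[0], 1)), Xn[:, self.active_dims_]])
        return K @ self.weights_ + P @ self.poly_coeffs_


# ---------------------------------------------------------------------------
# combined surrogate
# ---------------------------------------------------------------------------

class PODRBFROM:
    """POD-RBF surrogate: modes from snapshots, coefficients by RBF over (t, mu).

    ``fit(X, Y)`` takes the column coordinates X of shape (N_s, d) — time
    first for unsteady variables — and the snapshots Y of shape (N_s, N_h);
    ``predict(Xq)`` returns reconstructed fields of shape (nq, N_h).
    """

    def __init__(self, energy: float = 0.99, n_modes: int | None = None,
                 kernel: str = "thin_plate_spline", shape: float = 1.0):
        self.energy = energy
        self.n_modes = n_modes
        self.kernel = kernel
        self.shape = shape

    def get_params(self, deep: bool = True) -> dict:
        return {"energy": self.energy, "n_modes": self.n_modes,
                "kernel": self.kernel, "shape": self.shape}

    def set_params(self, **params) -> "PODRBFROM":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, Y) -> "PODRBFROM":
        self.pod_ = POD(energy=self.energy, n_modes=self.n_modes).fit(Y)
        alpha = self.pod_.transform(Y)
        self.rbf_ = RBFInterpolant(kernel=self.kernel, shape=self.shape).fit(X, alpha)
        return self

    @classmethod
    def from_snapshots(cls, snap: SnapshotMatrix, **params) -> "PODRBFROM":
        model = cls(**params)
        model.fit(snap.coordinates(), snap.matrix.T)
        return model

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "pod_"):
            raise RuntimeError("PODRBFROM is not fitted")
        return self.pod_.inverse_transform(self.rbf_.predict(X))


# ---------------------------------------------------------------------------
# error metrics and diagnostics
# ---------------------------------------------------------------------------

@dataclass
class ErrorReport:
    """Relative FOM-ROM errors: per-time series and/or scalar summaries."""

    tag: str
    times: np.ndarray = field(default_factory=lambda: np.array([]))
    series: np.ndarray = field(default_factory=lambda: np.array([]))
    scalar: float | None = None

    @property
    def time_average(self) -> float:
        if self.series.size:
            return float(self.series.mean())
        return float(self.scalar)


def relative_error(truth: np.ndarray, rom: np.ndarray,
                   times: np.ndarray | None = None, tag: str = "field"
                   ) -> ErrorReport:
    """Relative Frobenius-norm error between full-order and ROM fields.

    ``truth``/``rom`` are (N_t, N_h) series (per-time errors plus the time
    average) or flat (N_h,) steady fields (a single scalar).
    """
    truth = np.asarray(truth, dtype=float)
    rom = np.asarray(rom, dtype=float)
    if truth.shape != rom.shape:
        raise ValueError(f"shape mismatch {truth.shape} vs {rom.shape}")
    if truth.ndim == 1:
        denom = np.linalg.norm(truth)
        if denom == 0:
            raise ValueError("zero-norm truth field")
        return ErrorReport(tag=tag, scalar=float(np.linalg.norm(truth - rom) / denom))
    denom = np.linalg.norm(truth, axis=1)
    if np.any(denom == 0):
        raise ValueError("zero-norm truth field at some time instant")
    series = np.linalg.norm(truth - rom, axis=1) / denom
    t = np.arange(len(series), dtype=float) if times is None else np.asarray(times)
    return ErrorReport(tag=tag, times=t, series=series)


def mode_energy_sweep(snap: SnapshotMatrix, epsilons=(0.90, 0.95, 0.99, 0.999),
                      test_snapshots: SnapshotMatrix | None = None,
                      kernel: str = "thin_plate_spline", shape: float = 1.0):
    """Retained modes and train/test errors across energy thresholds.

    Returns a pandas DataFrame with columns (epsilon, n_modes, train_error,
    test_error); the test error is the mean relative error over the held-out
    snapshot columns when ``test_snapshots`` is given.
    """
    import pandas as pd

    rows = []
    X, Y = snap.coordinates(), snap.matrix.T
    for eps in epsilons:
        model = PODRBFROM(energy=eps, kernel=kernel, shape=shape).fit(X, Y)
        recon = model.pod_.inverse_transform(model.pod_.transform(Y))
        train = float(np.linalg.norm(Y - recon) / np.linalg.norm(Y))
        test = np.nan
        if test_snapshots is not None:
            Xt = test_snapshots.coordinates()
            Yt = test_snapshots.matrix.T
            pred = model.predict(Xt)
            err = np.linalg.norm(Yt - pred, axis=1) / np.linalg.norm(Yt, axis=1)
            test = float(err.mean())
        rows.append({"epsilon": eps, "n_modes": model.pod_.n_modes_,
                     "train_error": train, "test_error": test})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# thin functional wrappers (matrix-column convention: fields as columns)
# ---------------------------------------------------------------------------

def pod(S: np.ndarray | SnapshotMatrix, energy: float = 0.99) -> POD:
    """POD of a snapshot matrix with fields as columns (N_h, N_s)."""
    M = S.matrix if isinstance(S, SnapshotMatrix) else np.asarray(S, dtype=float)
    return POD(energy=energy).fit(M.T)


def project_coefficients(S: np.ndarray | SnapshotMatrix, basis: POD) -> np.ndarray:
    """Modal coefficients alpha = B^T S, one column per snapshot (L, N_s)."""
    M = S.matrix if isinstance(S, SnapshotMatrix) else np.asarray(S, dtype=float)
    return basis.transform(M.T).T


def fit_rbf(nodes: np.ndarray, alpha: np.ndarray, kernel: str = "thin_plate_spline",
            shape: float = 1.0) -> RBFInterpolant:
    """Fit the constrained RBF map nodes -> modal coefficients (rows)."""
    return RBFInterpolant(kernel=kernel, shape=shape).fit(nodes, alpha)


def predict(model: RBFInterpolant, basis: POD, query: np.ndarray) -> np.ndarray:
    """Reconstruct fields at query coordinates: Phi_rb = B (F(query))."""
    alpha = model.predict(np.atleast_2d(np.asarray(query, dtype=float)))
    if alpha.shape[1] != basis.n_modes_:
        raise ValueError("RBF output size does not match the POD basis rank")
    return basis.inverse_transform(alpha)
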