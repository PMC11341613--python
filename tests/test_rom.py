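"""POD, constrained RBF interpolation and the combined surrogate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import RBFInterpolator as ScipyRBF

from atriarom.rom import (POD, PODRBFROM, RBFInterpolant, SnapshotMatrix,
                          assemble_snapshots, fit_rbf, mode_energy_sweep, pod,
                          predict, project_coefficients, relative_error,
                          sample_lhs, sample_uniform)


class TestSampling:
    def test_uniform_design(self):
        pts = sample_uniform(0.5, 1.5, 20)
        assert pts.size == 20
        assert pts[0] == 0.5 and pts[-1] == 1.5
        assert np.allclose(np.diff(pts), 1.0 / 19)
        assert np.all((pts >= 0.5) & (pts <= 1.5))

    def test_uniform_two_points(self):
        np.testing.assert_array_equal(sample_uniform(0.0, 2.0, 2), [0.0, 2.0])
        with pytest.raises(ValueError):
            sample_uniform(0.0, 1.0, 1)

    def test_lhs_stratification(self):
        ranges = [(0.5, 1.5), (1.5e-3, 1.7e-3), (35.0, 50.0)]
        pts = sample_lhs(ranges, 30, seed=4)
        assert pts.shape == (30, 3)
        for d, (lo, hi) in enumerate(ranges):
            strata = np.floor((pts[:, d] - lo) / (hi - lo) * 30).astype(int)
            strata = np.clip(strata, 0, 29)
            assert sorted(strata) == list(range(30))

    def test_lhs_seed_determinism(self):
        r = [(0.0, 1.0)] * 2
        np.testing.assert_array_equal(sample_lhs(r, 10, seed=1),
                                      sample_lhs(r, 10, seed=1))
        assert not np.array_equal(sample_lhs(r, 10, seed=1),
                                  sample_lhs(r, 10, seed=2))


class TestAssembleSnapshots:
    def test_column_ordering_and_roundtrip(self):
        rng = np.random.default_rng(0)
        nt, nh = 4, 7
        times = np.linspace(0.1, 1.0, nt)
        samples = np.array([0.5, 1.0, 1.5])
        fields = [rng.standard_normal((nt, nh)) for _ in samples]
        snap = assemble_snapshots(fields, samples, times)
        assert snap.matrix.shape == (nh, nt * 3)
        for j in range(3):
            for i in range(nt):
                np.testing.assert_array_equal(snap.column(j, i), fields[j][i])
        coords = snap.coordinates()
        assert coords.shape == (nt * 3, 2)
        # parameter-outer, time-inner ordering
        np.testing.assert_array_equal(coords[:nt, 0], times)
        assert np.all(coords[:nt, 1] == 0.5)
        assert np.all(coords[nt:2 * nt, 1] == 1.0)

    def test_steady_variables_one_column_per_sample(self):
        fields = [np.arange(5.0), np.arange(5.0) + 1]
        snap = assemble_snapshots(fields, np.array([0.5, 1.5]), tag="TAWSS")
        assert snap.matrix.shape == (5, 2)
        assert snap.n_time == 0
        assert snap.coordinates().shape == (2, 1)

    def test_ragged_input_names_sample(self):
        times = np.linspace(0.1, 1.0, 4)
        good = np.zeros((4, 7))
        bad = np.zeros((3, 7))
        with pytest.raises(ValueError, match="sample 1"):
            assemble_snapshots([good, bad], np.array([1.0, 2.0]), times)

    def test_non_finite_rejected(self):
        f = np.zeros((2, 3))
        f[0, 0] = np.nan
        with pytest.raises(ValueError):
            assemble_snapshots([f], np.array([1.0]), np.array([0.1, 0.2]))


class TestPOD:
    def test_rank_one_needs_single_mode(self):
        S = np.outer(np.arange(1.0, 6.0), np.ones(4))        # (Nh, Ns) rank 1
        basis = pod(S, energy=0.5)
        assert basis.n_modes_ == 1
        recon = basis.inverse_transform(basis.transform(S.T))
        np.testing.assert_allclose(recon, S.T, atol=1e-12)

    def test_orthonormal_modes(self):
        rng = np.random.default_rng(1)
        basis = pod(rng.standard_normal((40, 12)), energy=0.99)
        B = basis.components_.T
        gram = B.T @ B
        assert np.abs(gram - np.eye(basis.n_modes_)).max() < 1e-10

    @given(seed=st.integers(0, 500))
    @settings(max_examples=25)
    def test_eckart_young_identity(self, seed):
        rng = np.random.default_rng(seed)
        S = rng.standard_normal((15, 9)) @ np.diag(2.0 ** -np.arange(9.0))
        basis = pod(S, energy=0.95)
        alpha = project_coefficients(S, basis)
        err2 = np.linalg.norm(S - basis.components_.T @ alpha, "fro") ** 2
        tail = (basis.singular_values_[basis.n_modes_:] ** 2).sum()
        assert err2 == pytest.approx(tail, rel=1e-8, abs=1e-12)

    def test_threshold_is_smallest_integer(self):
        # singular values 2, 1, 1e-8: energies 0.8, 1.0 (up to eps)
        u = np.linalg.qr(np.random.default_rng(0).standard_normal((6, 3)))[0]
        S = u @ np.diag([2.0, 1.0, 1e-8]) @ np.eye(3)
        assert pod(S, energy=0.79).n_modes_ == 1
        assert pod(S, energy=0.81).n_modes_ == 2

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            pod(np.zeros((5, 3)))

    def test_modes_monotone_in_energy(self):
        rng = np.random.default_rng(2)
        S = rng.standard_normal((30, 20)) @ np.diag(0.7 ** np.arange(20))
        Ls = [pod(S, energy=e).n_modes_ for e in (0.90, 0.95, 0.99, 0.999)]
        assert Ls == sorted(Ls)

    def test_sklearn_params_protocol(self):
        p = POD(energy=0.9)
        assert p.get_params() == {"energy": 0.9, "n_modes": None}
        p.set_params(energy=0.99, n_modes=3)
        assert p.energy == 0.99 and p.n_modes == 3
        with pytest.raises(ValueError):
            p.set_params(bogus=1)


class TestProjection:
    def test_single_mode_coefficient(self):
        rng = np.random.default_rng(3)
        basis = pod(rng.standard_normal((10, 4)), energy=0.999)
        c = 3.7
        col = c * basis.components_[0]           # snapshot = c * first mode
        alpha = basis.transform(col[None, :])[0]
        assert alpha[0] == pytest.approx(c, rel=1e-12)
        assert np.abs(alpha[1:]).max() < 1e-12

    def test_projection_is_optimal(self):
        rng = np.random.default_rng(4)
        S = rng.standard_normal((12, 8))
        basis = pod(S, energy=0.9)
        alpha = project_coefficients(S, basis)
        best = np.linalg.norm(S - basis.components_.T @ alpha)
        for _ in range(20):
            beta = alpha + 0.1 * rng.standard_normal(alpha.shape)
            assert np.linalg.norm(S - basis.components_.T @ beta) >= best

    def test_zero_column_zero_coefficients(self):
        S = np.column_stack([np.arange(6.0), np.zeros(6)])
        basis = pod(S)
        alpha = project_coefficients(S, basis)
        assert np.abs(alpha[:, 1]).max() == 0.0


class TestRBF:
    def nodes_and_values(self, n=25, d=2, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, (n, d))
        Y = np.column_stack([np.sin(3 * X[:, 0]) + X[:, 1] ** 2,
                             np.cos(X @ np.arange(1, d + 1.0))])
        return X, Y

    @pytest.mark.parametrize("kernel", ["thin_plate_spline", "gaussian",
                                        "multiquadric"])
    def test_interpolates_exactly_at_nodes(self, kernel):
        X, Y = self.nodes_and_values()
        model = RBFInterpolant(kernel=kernel, shape=2.0).fit(X, Y)
        pred = model.predict(X)
        assert np.abs(pred - Y).max() < 1e-8 * max(1.0, np.abs(Y).max())

    def test_moment_constraints(self):
        X, Y = self.nodes_and_values()
        model = fit_rbf(X, Y)
        w = model.weights_
        assert np.abs(w.sum(axis=0)).max() < 1e-8
        assert np.abs(model.nodes_.T @ w).max() < 1e-8

    def test_linear_data_absorbed_by_polynomial(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (20, 2))
        A = np.array([[2.0, -1.0], [0.5, 3.0]])
        b = np.array([1.0, -2.0])
        Y = X @ A + b
        model = fit_rbf(X, Y)
        assert np.abs(model.weights_).max() < 1e-8
        Xq = np.column_stack([rng.uniform(X[:, d].min(), X[:, d].max(), 30)
                              for d in range(2)])
        np.testing.assert_allclose(model.predict(Xq), Xq @ A + b, atol=1e-8)

    def test_duplicate_nodes_rejected(self):
        X = np.array([[0.0, 0.0], [0.5, 0.5], [0.5, 0.5], [1.0, 0.0], [0, 1.0]])
        with pytest.raises(ValueError, match="duplicate"):
            fit_rbf(X, np.arange(5.0))

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            fit_rbf(np.array([[0.0, 0.0], [1.0, 1.0]]), np.arange(2.0))

    def test_matches_scipy_reference(self):
        # independent oracle: scipy's RBF interpolator with the same kernel
        # and degree-1 polynomial tail.  The thin-plate spline is not
        # scale-invariant, so pin the nodes to the exact unit box to make the
        # internal normalization the identity map.
        X, Y = self.nodes_and_values(n=30)
        X[0], X[1] = [0.0, 0.0], [1.0, 1.0]
        ours = RBFInterpolant(kernel="thin_plate_spline").fit(X, Y)
        ref = ScipyRBF(X, Y, kernel="thin_plate_spline", degree=1)
        Xq = np.random.default_rng(6).uniform(0.05, 0.95, (40, 2))
        np.testing.assert_allclose(ours.predict(Xq), ref(Xq),
                                   rtol=1e-6, atol=1e-8)


class TestSurrogate:
    def make_snap(self, nt=6, nh=50, fs=(0.5, 0.75, 1.0, 1.25, 1.5)):
        x = np.linspace(0, 1, nh)
        times = np.linspace(0.1, 1.0, nt)
        fields = [np.array([(1 + f * t) * np.sin(np.pi * x)
                            + 0.3 * f * np.cos(np.pi * x) for t in times])
                  for f in fs]
        return assemble_snapshots(fields, np.asarray(fs), times)

    def test_training_point_reproduces_projection(self):
        snap = self.make_snap()
        model = PODRBFROM(energy=0.99).fit(snap.coordinates(), snap.matrix.T)
        X = snap.coordinates()
        proj = model.pod_.inverse_transform(model.pod_.transform(snap.matrix.T))
        np.testing.assert_allclose(model.predict(X), proj, rtol=1e-8, atol=1e-10)

    def test_full_basis_reproduces_snapshots(self):
        snap = self.make_snap()
        model = PODRBFROM(energy=1.0).fit(snap.coordinates(), snap.matrix.T)
        np.testing.assert_allclose(model.predict(snap.coordinates()),
                                   snap.matrix.T, rtol=1e-7, atol=1e-9)

    def test_predict_wrapper_checks_rank(self):
        snap = self.make_snap()
        basis = pod(snap.matrix, energy=1.0)
        other = pod(snap.matrix[:, :4], energy=0.5)
        alpha = project_coefficients(snap.matrix, basis)
        rbf = fit_rbf(snap.coordinates(), alpha.T)
        out = predict(rbf, basis, snap.coordinates()[:3])
        assert out.shape == (3, snap.matrix.shape[0])
        if other.n_modes_ != basis.n_modes_:
            with pytest.raises(ValueError):
                predict(rbf, other, snap.coordinates()[:3])

    def test_heldout_error_halves_with_design_refinement(self):
        # smooth manufactured family over (t, f): doubling the training design
        # at least halves the held-out relative error until the floor
        nh, nt = 300, 15
        x = np.linspace(0, 1, nh)
        times = np.linspace(0.05, 1.0, nt)
        rng = np.random.default_rng(42)
        K = 8
        gx = np.array([np.sin((k + 1) * np.pi * x) for k in range(K)])
        phase = rng.uniform(0, 2 * np.pi, K)

        def field(t, f):
            return sum(0.45 ** k * (1 + 0.6 * np.sin(2 * np.pi * t + phase[k]) * f
                                    + 0.3 * np.cos((k + 1) * f)) * gx[k]
                       for k in range(K))

        def err(n_train):
            fs = np.linspace(0.5, 1.5, n_train)
            snap = assemble_snapshots(
                [np.array([field(t, f) for t in times]) for f in fs],
                fs, times)
            model = PODRBFROM(energy=1.0).fit(snap.coordinates(), snap.matrix.T)
            f_test = 0.77
            Xq = np.column_stack([times, np.full(nt, f_test)])
            truth = np.array([field(t, f_test) for t in times])
            return np.linalg.norm(truth - model.predict(Xq)) / np.linalg.norm(truth)

        e4, e8, e16 = err(4), err(8), err(16)
        assert e8 <= 0.5 * e4
        assert e16 <= 0.5 * e8


class TestErrors:
    def test_identical_fields_zero(self):
        f = np.random.default_rng(7).standard_normal((4, 9))
        rep = relative_error(f, f)
        assert np.abs(rep.series).max() == 0.0

    def test_zero_rom_gives_unity(self):
        f = np.ones((3, 5))
        rep = relative_error(f, np.zeros_like(f))
        np.testing.assert_allclose(rep.series, 1.0)

    def test_hand_computed_values(self):
        truth = np.array([[3.0, 4.0]])
        assert relative_error(truth, np.array([[0.0, 0.0]])).series[0] == 1.0
        assert relative_error(truth, np.array([[3.0, 0.0]])).series[0] \
            == pytest.approx(4.0 / 5.0)

    def test_steady_scalar(self):
        rep = relative_error(np.array([3.0, 4.0]), np.array([3.0, 4.0]))
        assert rep.scalar == 0.0 and rep.time_average == 0.0

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            relative_error(np.zeros((2, 3)), np.ones((2, 3)))
        with pytest.raises(ValueError):
            relative_error(np.zeros(3), np.ones(3))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            relative_error(np.ones((2, 3)), np.ones((3, 2)))


class TestEnergySweep:
    def test_modes_grow_and_training_error_shrinks(self):
        rng = np.random.default_rng(8)
        nh, nt = 80, 10
        times = np.linspace(0.1, 1.0, nt)
        fs = np.linspace(0.5, 1.5, 6)
        basis_x = rng.standard_normal((6, nh))
        fields = [np.array([sum(0.5 ** k * np.sin((k + 1) * t + f) * basis_x[k]
                                for k in range(6)) for t in times]) for f in fs]
        snap = assemble_snapshots(fields, fs, times)
        table = mode_energy_sweep(snap, (0.90, 0.95, 0.99, 0.999))
        L = table["n_modes"].to_numpy()
        tr = table["train_error"].to_numpy()
        assert np.all(np.diff(L) >= 0)
        assert np.all(np.diff(tr) <= 1e-12)
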