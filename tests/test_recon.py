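import numpy as np
import pytest

from swigpc.gating import assign_frames, discard_steady_state
from swigpc.nufft import NufftOperator2D, nudft2, radial_dcf
from swigpc.protocol import ProtocolParams, RRSeries
from swigpc.recon import (
    cg_sense,
    estimate_coil_maps,
    grid_recon,
    phase_subtract,
    prewhiten,
    reconstruct_series,
    to_velocity,
    undersampling_factor,
)
from swigpc.simulator import (
    PhantomSpec,
    Region,
    RawKSpace,
    make_coil_model,
    sample_spokes,
)
from swigpc.trajectory import spoke_coordinates, swig_angles


class TestPrewhiten:
    def _raw_with_psi(self, psi, n_coils, rng):
        nsp, ro = 40, 16
        proto = ProtocolParams(matrix=16, readout_samples=ro, n_heartbeats=2)
        rr = RRSeries(np.full(2, 20 * 6.8 + 1))
        sched = swig_angles(2, rr, 6.8)
        data = rng.standard_normal((sched.n_spokes, ro, n_coils)) + 1j * (
            rng.standard_normal((sched.n_spokes, ro, n_coils))
        )
        return RawKSpace(data=data, schedule=sched, rr=rr, protocol=proto, psi=psi)

    def test_identity_psi_is_noop(self):
        rng = np.random.default_rng(0)
        raw = self._raw_with_psi(np.eye(3, dtype=complex), 3, rng)
        np.testing.assert_allclose(prewhiten(raw).data, raw.data)

    def test_diagonal_psi_scales(self):
        rng = np.random.default_rng(1)
        raw = self._raw_with_psi(4.0 * np.eye(1, dtype=complex), 1, rng)
        np.testing.assert_allclose(prewhiten(raw).data, raw.data / 2.0)

    def test_whitened_noise_covariance_near_identity(self):
        # correlated noise through the simulator, rho = 0.3, 8 coils
        rng = np.random.default_rng(2)
        n_coils, n = 8, 40000
        psi = 0.7 * np.eye(n_coils) + 0.3 * np.ones((n_coils, n_coils))
        L = np.linalg.cholesky(psi)
        e = (rng.standard_normal((n, n_coils)) + 1j * rng.standard_normal((n, n_coils))) / np.sqrt(2)
        data = (e @ L.T).reshape(100, -1, n_coils)
        proto = ProtocolParams(matrix=data.shape[1], n_heartbeats=2,
                               readout_samples=data.shape[1])
        rr = RRSeries(np.full(2, 50 * 6.8 + 1))
        sched = swig_angles(2, rr, 6.8)
        raw = RawKSpace(data=data, schedule=sched, rr=rr, protocol=proto,
                        psi=psi.astype(complex))
        white = prewhiten(raw).data.reshape(-1, n_coils)
        cov = white.T.conj() @ white / white.shape[0]
        assert np.linalg.norm(cov - np.eye(n_coils)) / np.sqrt(n_coils) < 0.05


class TestEstimateCoilMaps:
    def test_single_coil_uniform_support(self):
        img = np.zeros((32, 32), complex)
        img[8:24, 8:24] = 1.0
        maps, valid = estimate_coil_maps(img[None])
        np.testing.assert_allclose(np.abs(maps[0][valid]), 1.0, atol=1e-9)

    def test_recovers_simulated_maps(self):
        cm = make_coil_model(4, 32, seed=0)
        obj = np.zeros((32, 32))
        x = np.arange(32) - 16
        X, Y = np.meshgrid(x, x, indexing="ij")
        obj[(X**2 + Y**2) < 12**2] = 1.0
        imgs = cm.maps * obj[None]
        maps, valid = estimate_coil_maps(imgs)
        # ground truth normalized per pixel; compare up to global phase
        truth = cm.maps / np.linalg.norm(cm.maps, axis=0, keepdims=True)
        core = obj > 0
        core[2:] &= core[:-2]; core[:-2] &= core[2:]  # erode edges (block smoothing)
        core[:, 2:] &= core[:, :-2]; core[:, :-2] &= core[:, 2:]
        inner = valid & core
        dots = np.abs(np.sum(np.conj(truth[:, inner]) * maps[:, inner], axis=0))
        assert dots.min() > 0.98  # unit vectors: |<est, truth>| ~ 1

    def test_coil_permutation_keeps_magnitude(self):
        cm = make_coil_model(3, 24, seed=1)
        obj = np.ones((24, 24))
        maps1, _ = estimate_coil_maps(cm.maps * obj)
        maps2, _ = estimate_coil_maps(cm.maps[::-1] * obj)
        np.testing.assert_allclose(
            np.abs(maps1), np.abs(maps2[::-1]), atol=1e-6
        )


class TestGridRecon:
    def test_zero_data_zero_image(self):
        coords = spoke_coordinates(np.array([0.1, 0.7]), 16, 16).reshape(-1, 2)
        op = NufftOperator2D(coords, 16)
        img = grid_recon(np.zeros(32, complex), op, radial_dcf(coords, 2, 16))
        np.testing.assert_array_equal(img, 0)

    def test_single_spoke_backprojection(self):
        """One spoke at angle 0 -> the adjoint image is constant along the
        perpendicular (y) direction."""
        m = 16
        coords = spoke_coordinates(0.0, m, m).reshape(-1, 2)
        op = NufftOperator2D(coords, m)
        rng = np.random.default_rng(0)
        y = rng.standard_normal(m) + 1j * rng.standard_normal(m)
        img = op.adjoint(y)
        # angle 0 spoke lies along kx -> image varies only along x (up to
        # gridding-kernel accuracy)
        dev = np.abs(img - img[:, :1]).max() / np.abs(img).max()
        assert dev < 5e-3


class TestCgSense:
    def test_matches_dense_least_squares(self):
        """CG-SENSE converges to the weighted least-squares solution of the
        dense forward matrix (same operator, explicit columns) on a tiny
        problem."""
        m = 12
        rng = np.random.default_rng(0)
        ang = np.arange(24) * np.pi / 24
        coords = spoke_coordinates(ang, 2 * m, m).reshape(-1, 2)
        op = NufftOperator2D(coords, m)
        maps = np.ones((1, m, m), complex)
        A = op.forward(np.eye(m * m).reshape(-1, m, m)).reshape(m * m, -1).T
        truth = rng.standard_normal((m, m)) + 1j * rng.standard_normal((m, m))
        y = op.forward(truth)[None]
        w = radial_dcf(coords, 24, 2 * m)
        sw = np.sqrt(w)
        x_ls, *_ = np.linalg.lstsq(A * sw[:, None], y[0] * sw, rcond=None)
        img, info = cg_sense(y, op, maps, dcf=w, n_iter=300, tol=1e-14)
        rel = np.linalg.norm(img.ravel() - x_ls) / np.linalg.norm(x_ls)
        assert rel < 1e-3
        assert not info["diverged"]

    def test_zero_iterations_returns_adjoint(self):
        m = 12
        coords = spoke_coordinates(np.array([0.3]), m, m).reshape(-1, 2)
        op = NufftOperator2D(coords, m)
        maps = np.ones((1, m, m), complex)
        y = (np.arange(m) + 1j)[None]
        img, info = cg_sense(y, op, maps, n_iter=0)
        np.testing.assert_allclose(img, op.adjoint(y)[0])
        assert info["iterations"] == 0

    def test_error_energy_norm_monotone(self):
        """CG guarantee: the error in the normal-operator energy norm
        decreases at every iteration (the residual 2-norm may oscillate)."""
        m = 12
        rng = np.random.default_rng(1)
        coords = spoke_coordinates(np.arange(24) * np.pi / 24, 2 * m, m).reshape(-1, 2)
        op = NufftOperator2D(coords, m)
        maps = np.ones((1, m, m), complex)
        y = op.forward(rng.standard_normal((m, m)) + 0j)[None]
        w = radial_dcf(coords, 24, 2 * m)
        x_star, _ = cg_sense(y, op, maps, dcf=w, n_iter=400, tol=1e-14)

        def energy(e):
            z = op.forward(e[None])[0]
            return np.sum(w * np.abs(z) ** 2).real

        errs = []
        for k in range(1, 12):
            xk, _ = cg_sense(y, op, maps, dcf=w, n_iter=k, tol=0.0)
            errs.append(energy(xk - x_star))
        assert all(errs[i + 1] < errs[i] for i in range(len(errs) - 1))


class TestPhaseSubtraction:
    def test_identical_inputs_zero(self):
        z = np.ones((4, 4), complex)
        dphi, valid = phase_subtract(z, z)
        np.testing.assert_array_equal(dphi, 0)
        assert valid.all()

    def test_wrap_handled_by_product(self):
        dphi, _ = phase_subtract(np.exp(1j * 0.9 * np.pi), np.exp(-1j * 0.9 * np.pi))
        assert dphi == pytest.approx(-0.2 * np.pi, abs=1e-12)

    def test_random_pairs_match_wrapped_difference_oracle(self):
        rng = np.random.default_rng(0)
        z1 = np.exp(1j * rng.uniform(-np.pi, np.pi, 1000))
        z2 = np.exp(1j * rng.uniform(-np.pi, np.pi, 1000))
        dphi, _ = phase_subtract(z1, z2)
        oracle = np.angle(z1) - np.angle(z2)
        oracle = np.mod(oracle + np.pi, 2 * np.pi) - np.pi
        # oracle maps the boundary to -pi; fold both to the same convention
        fold = lambda a: np.where(np.isclose(a, -np.pi), np.pi, a)
        np.testing.assert_allclose(fold(dphi), fold(oracle), atol=1e-12)

    def test_zero_pixels_flagged(self):
        dphi, valid = phase_subtract(np.zeros(3, complex), np.zeros(3, complex))
        np.testing.assert_array_equal(dphi, 0)
        assert not valid.any()

    @pytest.mark.parametrize("dphi,venc,v", [(np.pi, 30, 30), (0, 30, 0),
                                             (np.pi / 2, 150, 75)])
    def test_venc_scaling(self, dphi, venc, v):
        assert to_velocity(dphi, venc) == pytest.approx(v)


class TestUndersampling:
    def test_radial_nyquist_bookkeeping(self):
        assert round(undersampling_factor(64, 36), 1) == 2.8


class TestReconstructSeries:
    def test_static_phantom_velocity_null(self, tissue_protocol):
        """A static phantom reconstructs to near-zero velocity everywhere:
        the +/- encodings see the identical object."""
        rr = RRSeries(np.full(13, 900.0))
        sched = swig_angles(13, rr, 6.8)
        ph = PhantomSpec(regions=(
            Region("bg", "ellipse", (0.0, 0.0), (130.0, 100.0), 1.0),
        ))
        coil = make_coil_model(2, 64, 0.0, seed=1)
        raw = sample_spokes(ph, sched, rr, tissue_protocol, coil)
        ret = discard_steady_state(raw)
        frames = assign_frames(ret, 6)
        series = reconstruct_series(ret, frames, method="gridding")
        support = ph.rasterize(64, 320.0)[0] > 0.99
        assert np.abs(series.velocity[:, support]).max() < 0.5

    def test_velocity_null_identical_windows(self):
        dphi, _ = phase_subtract(np.ones((3, 3)) + 1j, np.ones((3, 3)) + 1j)
        np.testing.assert_array_equal(dphi, 0)
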