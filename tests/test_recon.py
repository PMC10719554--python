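"""Regularizers, preconditioner, SART, and the alternating MDR solver."""

import numpy as np
import pytest

from tomomdr.denoiser import DenoiserSpec, apply_denoiser
from tomomdr.geometry import (ScanGeometry, SystemProjector, VolumeSpec,
                              apply_blur, gaussian_blur_kernel)
from tomomdr.noise import (NoiseModel, SinogramStack, WhitenedProjector,
                           whitened_filters)
from tomomdr.recon import (ReconConfig, ep_regularizer, mdr_reconstruct,
                           potential, preconditioner, red_regularizer,
                           sart_reconstruct, select_denoiser,
                           spaced_view_order)


class TestPotential:
    def test_zero(self):
        eta, deta = potential(0.0, 1.7)
        assert eta == 0.0 and deta == 0.0

    def test_closed_form_at_delta(self):
        eta, _ = potential(1.0, 1.0)
        assert eta == pytest.approx(np.sqrt(2.0) - 1.0, abs=1e-12)

    def test_derivative_asymptote(self):
        """eta'(t) approaches delta as t -> +-inf."""
        delta = 0.7
        for t in (1e6 * delta, -1e6 * delta):
            _, deta = potential(t, delta)
            assert abs(deta) == pytest.approx(delta, rel=1e-6)

    def test_even_function(self, rng):
        t = rng.normal(size=20)
        ep, dp = potential(t, 2.0)
        em, dm = potential(-t, 2.0)
        np.testing.assert_allclose(ep, em)
        np.testing.assert_allclose(dp, -dm)

    def test_invalid_delta(self):
        with pytest.raises(ValueError):
            potential(1.0, 0.0)


class TestEPRegularizer:
    def test_constant_volume_zero(self):
        val, grad = ep_regularizer(np.full((8, 8, 3), 2.5), delta=1.0,
                                   gamma=0.5)
        assert val == 0.0
        assert np.all(grad == 0)

    def test_gradient_matches_central_differences(self, rng):
        x = rng.normal(size=(6, 6, 2))
        _, grad = ep_regularizer(x, delta=1.3, gamma=0.7)
        h = 1e-6
        num = np.zeros_like(x)
        for idx in np.ndindex(x.shape):
            xp, xm = x.copy(), x.copy()
            xp[idx] += h
            xm[idx] -= h
            num[idx] = (ep_regularizer(xp, 1.3, 0.7)[0]
                        - ep_regularizer(xm, 1.3, 0.7)[0]) / (2 * h)
        assert np.abs(grad - num).max() < 1e-5

    def test_gamma_zero_drops_diagonals(self, rng):
        """With gamma = 0 only the axis-aligned differences contribute."""
        x = rng.normal(size=(7, 7, 2))
        val, grad = ep_regularizer(x, delta=1.0, gamma=0.0)
        h = potential(x[1:, :, :] - x[:-1, :, :], 1.0)[0].sum()
        v = potential(x[:, 1:, :] - x[:, :-1, :], 1.0)[0].sum()
        assert val == pytest.approx(h + v, rel=1e-12)

    def test_differences_stay_within_slices(self):
        """A volume constant within each slice has zero penalty even when
        slices differ."""
        x = np.zeros((6, 6, 3))
        x[:, :, 1] = 5.0
        x[:, :, 2] = -3.0
        val, grad = ep_regularizer(x, delta=1.0, gamma=1.0)
        assert val == 0.0
        assert np.all(grad == 0)


class TestREDRegularizer:
    def test_identity_denoiser_zero(self, rng):
        x = rng.normal(size=(5, 5, 2))
        val, resid = red_regularizer(x, lambda v: v.copy())
        assert val == 0.0
        assert np.all(resid == 0)

    def test_zero_denoiser_half_norm(self, rng):
        x = rng.normal(size=(5, 5, 2))
        val, _ = red_regularizer(x, lambda v: np.zeros_like(v))
        assert val == pytest.approx(0.5 * np.sum(x**2), rel=1e-12)

    def test_matches_dense_linear_smoother(self, rng):
        """For a symmetric linear smoother W, the penalty equals
        1/2 x'(I - W)x computed densely."""
        n = 12
        W = rng.random((n, n))
        W = (W + W.T) / 2
        W /= np.abs(np.linalg.eigvalsh(W)).max() * 1.5   # contraction
        x = rng.normal(size=(n, 1, 1))

        def G(v):
            return (W @ v[:, 0, 0])[:, None, None]

        val, _ = red_regularizer(x, G)
        xf = x[:, 0, 0]
        dense = 0.5 * xf @ (np.eye(n) - W) @ xf
        assert val == pytest.approx(dense, abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            red_regularizer(rng.normal(size=(4, 4, 1)),
                            lambda v: v[:2, :2, :])


class TestPreconditioner:
    def test_identity_system_unit_variance(self, identity_projector):
        """A = I, one view, sigma_q^2 + sigma_r^2 = 1, no regularization
        gives P = I."""
        m = NoiseModel(sigma_q=0.6, sigma_r=0.8)
        P = preconditioner(identity_projector, [m], beta_ep=0.0,
                           beta_red=0.0)
        np.testing.assert_allclose(P, 1.0)

    def test_majorizes_hessian_on_dense_toy(self):
        """Smallest eigenvalue of P^{-1} - H is nonnegative, where H is the
        dense Hessian of the inner cost (whitened data-fit + quadratic
        upper bound on the edge-preserving curvature + proximity term)."""
        vol = VolumeSpec(shape=(5, 5, 1))
        geom = ScanGeometry(angles=(-12.5, 0.0, 12.5),
                            detector_shape=(9, 12))
        proj = SystemProjector(geom, vol)
        m = NoiseModel(sigma_q=0.3, sigma_r=0.1,
                       blur=gaussian_blur_kernel(2.0))
        beta_ep, beta_red = 0.7, 1.3
        P = preconditioner(proj, [m] * 3, beta_ep, beta_red)
        n = vol.n_voxels
        filters = whitened_filters(geom, m)
        w = WhitenedProjector(proj, m.blur, filters)
        H = np.zeros((n, n))
        for i in range(3):
            Ai = np.zeros((np.prod(geom.detector_shape), n))
            for j in range(n):
                e = np.zeros(n)
                e[j] = 1.0
                Ai[:, j] = w.project(e.reshape(vol.shape), i).ravel()
            H += Ai.T @ Ai
        Hep = _dense_ep_hessian(vol, gamma=1.0 / np.sqrt(2.0))
        H_tot = H + beta_ep * Hep + beta_red * np.eye(n)
        pinv_diag = 1.0 / P.ravel()
        M = np.diag(pinv_diag) - H_tot
        assert np.linalg.eigvalsh((M + M.T) / 2).min() >= -1e-8

    def test_ep_hessian_eigenvalue_bound(self):
        """Power iteration on the edge-preserving Hessian stays below 8,
        validating the 8*beta_EP preconditioner term."""
        rng = np.random.default_rng(3)
        for shape in [(6, 6, 1), (10, 8, 2)]:
            H = _dense_ep_hessian(VolumeSpec(shape=shape),
                                  gamma=1.0 / np.sqrt(2.0))
            v = rng.normal(size=H.shape[0])
            for _ in range(200):
                v = H @ v
                v /= np.linalg.norm(v)
            lam = v @ H @ v
            assert lam <= 8.0 + 1e-9

    def test_out_of_field_voxels_frozen(self):
        """Voxels never crossed by a ray get P = 0 (excluded from
        updates) instead of dividing by zero."""
        vol = VolumeSpec(shape=(40, 40, 2),
                         origin=(-10.0, -10.0, -19.5))
        geom = ScanGeometry(angles=(0.0,), detector_shape=(12, 12))
        proj = SystemProjector(geom, vol)
        mask = proj.in_field_mask()
        assert not mask.all()            # small detector misses some voxels
        P = preconditioner(proj, [NoiseModel(sigma_q=1.0, sigma_r=0.0)],
                           beta_ep=0.0, beta_red=0.0)
        assert np.all(P[~mask] == 0)
        assert np.all(P[mask] > 0)


def _dense_ep_hessian(vol, gamma):
    """Edge-preserving Hessian at x = 0 in the quadratic (delta -> inf)
    regime, where the curvature bound is attained."""
    n = vol.n_voxels

    def grad(v):
        return ep_regularizer(v.reshape(vol.shape), delta=1e9,
                              gamma=gamma)[1].ravel()

    H = np.zeros((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1e-3
        H[:, j] = (grad(e) - grad(-e)) / 2e-3
    return (H + H.T) / 2


class TestSART:
    def test_identity_system_one_step(self, identity_projector, rng):
        y = rng.normal(size=(4, 4))
        geom = ScanGeometry(angles=(0.0,), detector_shape=(4, 4))
        sino = SinogramStack(views=y[None], geom=geom, noise=None)
        x = sart_reconstruct(sino, projector=identity_projector,
                             n_iterations=1, relaxation=1.0)
        np.testing.assert_allclose(x[:, :, 0], y, rtol=1e-12)

    def test_residual_decreases_on_consistent_data(self, toy_scene):
        """Projection residual norm is monotone decreasing on noise-free
        consistent data."""
        vol, geom, proj = (toy_scene["vol"], toy_scene["geom"],
                           toy_scene["proj"])
        x_true = toy_scene["x_true"]
        views = np.stack([proj.project(x_true, i)
                          for i in range(geom.n_views)])
        sino = SinogramStack(views=views, geom=geom, noise=None)
        resid = []
        for n_it in (1, 5, 15, 50):
            x = sart_reconstruct(sino, vol, n_iterations=n_it,
                                 relaxation=0.5)
            r = sum(np.sum((proj.project(x, i) - views[i])**2)
                    for i in range(geom.n_views))
            resid.append(r)
        assert all(b < a for a, b in zip(resid, resid[1:]))

    def test_deterministic(self, toy_scene):
        a = sart_reconstruct(toy_scene["sino"], toy_scene["vol"],
                             n_iterations=2)
        b = sart_reconstruct(toy_scene["sino"], toy_scene["vol"],
                             n_iterations=2)
        np.testing.assert_array_equal(a, b)

    def test_invalid_args(self, toy_scene):
        with pytest.raises(ValueError):
            sart_reconstruct(toy_scene["sino"], toy_scene["vol"],
                             n_iterations=0)


class TestMDR:
    def _desk_config(self, **kw):
        base = dict(beta_ep=0.5, beta_red=5.0, alpha=0.25, n_iter=3,
                    n_inner=2)
        base.update(kw)
        return ReconConfig(**base)

    def test_reduces_to_preconditioned_os_descent(self, toy_scene):
        """beta_EP = beta_RED = 0 makes the solver identical (bitwise) to a
        bare preconditioned ordered-subsets gradient loop."""
        sino, vol = toy_scene["sino"], toy_scene["vol"]
        proj = toy_scene["proj"]
        cfg = self._desk_config(beta_ep=0.0, beta_red=0.0)
        state = mdr_reconstruct(sino, vol, cfg, projector=proj)

        noise = sino.noise
        filters = whitened_filters(sino.geom, noise)
        w = WhitenedProjector(proj, noise.blur, filters)
        y = np.stack([filters[i].apply(sino.views[i])
                      for i in range(sino.n_views)])
        P = preconditioner(proj, [noise] * sino.n_views, 0.0, 0.0)
        x = np.zeros(vol.shape)
        order = cfg.view_order(sino.n_views)
        for _ in range(cfg.n_iter):
            for _ in range(cfg.n_inner):
                for i in order:
                    g = sino.n_views * w.backproject(
                        w.project(x, i) - y[i], i)
                    x = x - cfg.alpha * P * g
        np.testing.assert_array_equal(state.x, x)
        np.testing.assert_array_equal(state.z, x)

    def test_fixed_point_of_consistent_data(self, toy_scene):
        """With consistent data, a denoiser fixing x*, and beta terms on,
        the iterates stay at x* once started there."""
        vol, geom, proj = (toy_scene["vol"], toy_scene["geom"],
                           toy_scene["proj"])
        noise = toy_scene["sino"].noise
        x_star = np.full(vol.shape, 0.05)    # constant: EP gradient is zero
        views = np.stack([apply_blur(proj.project(x_star, i), noise.blur)
                          for i in range(geom.n_views)])
        sino = SinogramStack(views=views, geom=geom, noise=noise)

        cfg = self._desk_config(n_iter=2)
        state = mdr_reconstruct(sino, vol, cfg,
                                denoiser=lambda v: x_star.copy(),
                                x0=x_star, z0=x_star)
        assert np.abs(state.x - x_star).max() < 1e-10
        assert np.abs(state.z - x_star).max() < 1e-10

    def test_cost_nonincreasing_with_linear_contraction(self, toy_scene):
        """With a symmetric linear contraction as the denoiser, the overall
        cost trace is monotone non-increasing."""
        g = DenoiserSpec(kind="gaussian", params=dict(sigma=1.0))
        cfg = self._desk_config(alpha=0.1, n_iter=5, n_inner=2)
        state = mdr_reconstruct(toy_scene["sino"], toy_scene["vol"], cfg,
                                denoiser=lambda v: apply_denoiser(v, g))
        trace = np.array(state.cost_trace)
        assert np.all(np.diff(trace) <= 1e-9 * abs(trace[0]))

    def test_limit_point_is_stationary(self):
        """With a fixed symmetric linear denoiser and full-gradient steps,
        the solver's limit point satisfies the stationarity of the full
        cost (data-fit + EP + denoising penalty)."""
        from tomomdr.geometry import pristina_like
        from tomomdr.noise import data_fit_dbcn, simulate_measurement
        vol = VolumeSpec(shape=(12, 12, 1))
        geom = pristina_like(detector_shape=(20, 28))
        proj = SystemProjector(geom, vol)
        noise = NoiseModel(sigma_q=0.4, sigma_r=0.3,
                           blur=gaussian_blur_kernel(2.0))
        g0 = np.random.default_rng(5)
        x_true = g0.normal(size=vol.shape) * 0.3 + 1.0
        views = np.stack([simulate_measurement(proj.project(x_true, i),
                                               noise, 300 + i)
                          for i in range(geom.n_views)])
        sino = SinogramStack(views=views, geom=geom, noise=noise)

        g = DenoiserSpec(kind="gaussian", params=dict(sigma=1.0))
        G = lambda v: apply_denoiser(v, g)   # noqa: E731
        cfg = ReconConfig(beta_ep=0.5, beta_red=5.0, alpha=1.0,
                          n_iter=400, n_inner=2, subset_order="full")
        state = mdr_reconstruct(sino, vol, cfg, denoiser=G, projector=proj)
        x = state.x
        _, grad = data_fit_dbcn(x, sino, vol, projector=proj)
        grad = (grad + cfg.beta_ep * ep_regularizer(x, cfg.delta,
                                                    cfg.gamma)[1]
                + cfg.beta_red * (x - G(x)))
        assert np.linalg.norm(grad) < 1e-6 * max(1.0, np.linalg.norm(x))

    def test_divergence_guard(self, toy_scene):
        cfg = self._desk_config(alpha=500.0)
        with pytest.raises(RuntimeError, match="divergence"):
            mdr_reconstruct(toy_scene["sino"], toy_scene["vol"], cfg,
                            denoiser=lambda v: v.copy())

    def test_output_is_z_and_clamped(self, toy_scene):
        g = DenoiserSpec(kind="gaussian", params=dict(sigma=1.0))
        state = mdr_reconstruct(toy_scene["sino"], toy_scene["vol"],
                                self._desk_config(),
                                denoiser=lambda v: apply_denoiser(v, g))
        np.testing.assert_array_equal(state.image,
                                      np.maximum(state.z, 0.0))

    def test_suite_selection_inside_solver(self, toy_scene):
        """With a denoiser suite, the solver estimates the volume noise
        each outer iteration and applies the closest-matched entry."""
        suite = [DenoiserSpec(kind="gaussian", noise_center=0.0,
                              params=dict(sigma=1.0)),
                 DenoiserSpec(kind="identity", noise_center=1e6)]
        cfg = self._desk_config(n_iter=2)
        state = mdr_reconstruct(toy_scene["sino"], toy_scene["vol"], cfg,
                                suite=suite)
        # the low-noise-center gaussian must have been chosen: z is the
        # smoothed x, not a copy of it
        assert not np.array_equal(state.z, state.x)
        g = DenoiserSpec(kind="gaussian", params=dict(sigma=1.0))
        np.testing.assert_allclose(state.z, apply_denoiser(state.x, g),
                                   rtol=1e-12)

    def test_requires_denoiser_when_red_active(self, toy_scene):
        with pytest.raises(ValueError):
            mdr_reconstruct(toy_scene["sino"], toy_scene["vol"],
                            self._desk_config())


class TestSelectDenoiser:
    def _suite(self, centers):
        return [DenoiserSpec(kind="gaussian", noise_center=c,
                             params=dict(sigma=1.0)) for c in centers]

    def test_closest_center_wins(self, rng):
        vol = rng.normal(size=(48, 48, 2)) * 12.3
        chosen = select_denoiser(vol, self._suite([5.0, 10.0, 15.0]))
        assert chosen.noise_center == 10.0

    def test_tie_goes_to_lower_center(self, monkeypatch):
        # pin the estimate exactly midway between the two centers
        import tomomdr.assessment as am
        vol = np.zeros((48, 48, 2))
        monkeypatch.setattr(am, "estimate_volume_rms",
                            lambda *a, **k: 12.5)
        chosen = select_denoiser(vol, self._suite([15.0, 10.0]))
        assert chosen.noise_center == 10.0

    def test_single_entry_suite(self, rng):
        suite = self._suite([3.0])
        assert select_denoiser(rng.normal(size=(40, 40, 1)),
                               suite) is suite[0]

    def test_empty_suite_rejected(self, rng):
        with pytest.raises(ValueError):
            select_denoiser(rng.normal(size=(40, 40, 1)), [])


def test_spaced_order_is_permutation():
    for n in (1, 2, 5, 9):
        order = spaced_view_order(n)
        assert sorted(order) == list(range(n))
    assert spaced_view_order(9)[0] == 0
    assert spaced_view_order(9)[1] == 8     # farthest from 0
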