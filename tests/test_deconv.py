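"""Richardson-Lucy core: convolution, projectors, fixed points, fusion."""

import numpy as np
import pytest

from mvdecon import (
    FusionConfig,
    GaussianPSFModel,
    convolve,
    deconv1d,
    fuse,
    init_estimate,
    make_backprojectors,
    make_gaussian_psf,
    mse,
    mvd,
    mvd2d_slicewise,
    pcc,
    rl_step,
)
from conftest import convolve_direct, rl_step_direct


def gaussian_1d(sigma, radius):
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    return g / g.sum()


class TestConvolve:
    def test_impulse_kernel_identity(self):
        a = np.random.default_rng(0).uniform(0, 1, (6, 7, 8))
        k = np.zeros((3, 3, 3))
        k[1, 1, 1] = 1.0
        np.testing.assert_allclose(convolve(a, k), a, atol=1e-12)

    def test_impulse_input_copies_kernel(self):
        a = np.zeros((9, 9))
        a[4, 4] = 1.0
        k = np.random.default_rng(1).uniform(0, 1, (3, 3))
        np.testing.assert_allclose(convolve(a, k)[3:6, 3:6], k, atol=1e-12)

    @pytest.mark.parametrize("shape,kshape", [((9, 9, 9), (3, 3, 3)), ((16, 5), (5, 3)), ((30,), (7,))])
    def test_matches_spatial_oracle(self, shape, kshape):
        rng = np.random.default_rng(hash(shape) % 2**31)
        a = rng.uniform(0, 1, shape)
        k = rng.uniform(0, 1, kshape)
        got = convolve(a, k)
        want = convolve_direct(a, k)
        np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12)

    def test_dimensionality_mismatch(self):
        with pytest.raises(ValueError, match="dimensionality"):
            convolve(np.zeros((4, 4)), np.zeros((3, 3, 3)))


class TestRLStep:
    def test_delta_projectors_return_view(self):
        rng = np.random.default_rng(2)
        view = rng.uniform(0.1, 1, (8, 8))
        est = rng.uniform(0.1, 1, (8, 8))
        delta = np.zeros((3, 3))
        delta[1, 1] = 1.0
        np.testing.assert_allclose(rl_step(est, view, delta, delta), view, atol=1e-10)

    def test_consistent_data_fixed_point(self):
        # interior-supported estimate; view produced by the forward model
        est = np.zeros((16, 16, 16))
        est[5:11, 5:11, 5:11] = np.random.default_rng(3).uniform(0.5, 1, (6, 6, 6))
        f = make_gaussian_psf(GaussianPSFModel(0.6, 0.6, 0.6, radius=2))
        view = np.clip(convolve(est, f), 0, None)
        b = f[::-1, ::-1, ::-1].copy()
        out = rl_step(est, view, f, b)
        assert np.max(np.abs(out - est)) <= 1e-8 * est.max()

    def test_hand_computed_1d_example(self):
        est = np.ones(5)
        view = np.array([0.0, 0.0, 3.0, 0.0, 0.0])
        f = np.full(3, 1.0 / 3.0)
        out = rl_step(est, view, f, f)
        np.testing.assert_allclose(out, [0.0, 1.0, 1.0, 1.0, 0.0], atol=1e-12)

    def test_matches_direct_oracle_on_random_volumes(self):
        rng = np.random.default_rng(4)
        est = rng.uniform(0, 1, (12, 13, 11))
        view = rng.uniform(0, 1, (12, 13, 11))
        f = rng.uniform(0, 1, (3, 3, 3))
        f /= f.sum()
        b = f[::-1, ::-1, ::-1].copy()
        got = rl_step(est, view, f, b)
        want = rl_step_direct(est, view, f, b)
        np.testing.assert_allclose(got, want, rtol=1e-8, atol=1e-12)

    def test_rejects_negative_input(self):
        k = np.ones((3,)) / 3
        with pytest.raises(ValueError, match="nonnegative"):
            rl_step(np.array([-1.0, 0, 0]), np.zeros(3), k, k)


class TestBackprojectors:
    def test_impulse_psfs_all_optimizations(self):
        delta = np.zeros((3, 3, 3))
        delta[1, 1, 1] = 1.0
        for opt in ("matched", "opt1", "opt2"):
            ps = make_backprojectors([delta, delta], opt)
            for b in ps.backward:
                np.testing.assert_allclose(b, delta, atol=1e-12)

    def test_opt2_gaussian_composition(self):
        s1, s2, r = 1.0, 1.5, 10
        ps = make_backprojectors([gaussian_1d(s1, r), gaussian_1d(s2, r)], "opt2")
        expected = gaussian_1d(np.sqrt(s1**2 + s2**2), r)
        expected /= expected.sum()
        np.testing.assert_allclose(ps.backward[0], expected, atol=1e-5)
        assert ps.backward[0] is ps.backward[1]

    def test_matched_symmetric_is_identity(self):
        f = gaussian_1d(2.0, 8)
        ps = make_backprojectors([f], "matched")
        np.testing.assert_allclose(ps.backward[0], f, atol=1e-15)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            make_backprojectors([], "matched")

    def test_backward_normalized(self):
        rng = np.random.default_rng(5)
        psfs = [rng.uniform(0, 1, (5, 5)) for _ in range(3)]
        for opt in ("matched", "opt1", "opt2"):
            ps = make_backprojectors(psfs, opt)
            for b in ps.backward:
                assert b.sum() == pytest.approx(1.0, abs=1e-9)


class TestInitEstimate:
    def test_average(self):
        a, b = np.full((4, 4), 2.0), np.full((4, 4), 4.0)
        np.testing.assert_allclose(init_estimate([a, b]), 3.0)
        np.testing.assert_allclose(init_estimate([a]), a)


class TestMVD:
    def test_single_view_impulse_projectors(self):
        rng = np.random.default_rng(6)
        view = rng.uniform(0.1, 1, (10, 10))
        delta = np.zeros((3, 3))
        delta[1, 1] = 1.0
        ps = make_backprojectors([delta], "matched")
        out = mvd([view], ps, n_iter=1)
        np.testing.assert_allclose(out, view, atol=1e-10)

    def test_multiview_consistent_fixed_point(self):
        est = np.zeros((20, 20, 20))
        est[7:13, 7:13, 7:13] = np.random.default_rng(7).uniform(0.5, 1, (6, 6, 6))
        psf0 = make_gaussian_psf(GaussianPSFModel(0.6, 0.6, 0.9, radius=3))
        psf1 = make_gaussian_psf(GaussianPSFModel(0.9, 0.6, 0.6, radius=3))
        views = [np.clip(convolve(est, p), 0, None) for p in (psf0, psf1)]
        ps = make_backprojectors([psf0, psf1], "matched")
        out = mvd(views, ps, n_iter=1, init=est)
        assert np.max(np.abs(out - est)) <= 1e-8 * est.max()

    def test_single_view_reduces_to_rl(self):
        rng = np.random.default_rng(8)
        view = rng.uniform(0, 1, (16, 16))
        f = np.outer(gaussian_1d(1.0, 3), gaussian_1d(1.0, 3))
        ps = make_backprojectors([f], "matched")
        out = mvd([view], ps, n_iter=3)
        ref = init_estimate([view])
        for _ in range(3):
            ref = rl_step(ref, view, ps.forward[0], ps.backward[0])
        np.testing.assert_allclose(out, ref, rtol=1e-12)

    def test_zero_weight_is_noop(self):
        rng = np.random.default_rng(9)
        view = rng.uniform(0.1, 1, (12, 12))
        f = np.outer(gaussian_1d(1.0, 3), gaussian_1d(1.0, 3))
        ps = make_backprojectors([f, f], "matched")
        weights = np.stack([np.ones_like(view), np.zeros_like(view)])
        out = mvd([view, view], ps, weights=weights, n_iter=2)
        # second view never applied: equals single-view RL from the average
        ref = init_estimate([view, view])
        for _ in range(2):
            ref = rl_step(ref, view, ps.forward[0], ps.backward[0])
        np.testing.assert_allclose(out, ref, rtol=1e-10)

    def test_nonnegativity_with_noise(self, small_multiview):
        gt, views, psfs = small_multiview
        ps = make_backprojectors(psfs, "matched")
        out = mvd(views, ps, n_iter=2)
        assert out.min() >= 0

    def test_mse_decreases_over_first_iterations(self, small_multiview):
        gt, views, psfs = small_multiview
        ps = make_backprojectors(psfs, "matched")
        errs = []
        mvd(views, ps, n_iter=5, callback=lambda it, e: errs.append(mse(e, gt.data, fit_gain=True)))
        assert all(b < a for a, b in zip(errs, errs[1:]))


class TestSlicewise:
    def test_blocking_is_scheduling_only(self, small_multiview, default_psf):
        from mvdecon import extract_psf2d

        gt, views, psfs = small_multiview
        psf2ds = [extract_psf2d(p) for p in psfs]
        out_all = mvd2d_slicewise(views, psf2ds, FusionConfig(iters_mvd=2))
        out_one = mvd2d_slicewise(views, psf2ds, FusionConfig(iters_mvd=2, block_slices=1))
        scale = out_all.max()
        np.testing.assert_allclose(out_one / scale, out_all / scale, atol=1e-6)

    def test_slices_are_independent(self, small_multiview):
        from mvdecon import extract_psf2d

        gt, views, psfs = small_multiview
        psf2ds = [extract_psf2d(p) for p in psfs]
        cfg = FusionConfig(iters_mvd=1)
        base = mvd2d_slicewise(views, psf2ds, cfg)
        modified = [v.copy() for v in views]
        for v in modified:
            v[:, 10, :] *= 2.0  # perturb a single y-slice in every view
        out = mvd2d_slicewise(modified, psf2ds, cfg)
        assert not np.allclose(out[:, 10, :], base[:, 10, :])
        untouched = [y for y in range(base.shape[1]) if y != 10]
        np.testing.assert_allclose(out[:, untouched, :], base[:, untouched, :], rtol=1e-12)


class TestDeconv1D:
    def test_zero_iterations_identity(self):
        vol = np.random.default_rng(10).uniform(0, 1, (8, 16, 8))
        np.testing.assert_array_equal(deconv1d(vol, gaussian_1d(2.0, 6), n_iter=0), vol)

    def test_improves_axially_blurred_volume(self):
        rng = np.random.default_rng(11)
        truth = np.zeros((16, 48, 16))
        idx = rng.integers(4, 12, (40, 2))
        ys = rng.integers(12, 36, 40)
        truth[idx[:, 0], ys, idx[:, 1]] = rng.uniform(0.5, 1, 40)
        k = gaussian_1d(2.0, 6)
        blurred = np.clip(
            np.apply_along_axis(lambda col: np.convolve(col, k, mode="same"), 1, truth), 0, None
        )
        out = deconv1d(blurred, k, n_iter=10)
        assert mse(out, truth, fit_gain=True) < mse(blurred, truth, fit_gain=True)

    def test_flux_roughly_conserved_per_iteration(self):
        # matched 1D projectors on an interior-supported object
        rng = np.random.default_rng(12)
        vol = np.zeros((8, 64, 8))
        vol[2:6, 24:40, 2:6] = rng.uniform(0.5, 1, (4, 16, 4))
        k = gaussian_1d(1.5, 5)
        prev = deconv1d(vol, k, n_iter=1, blend_sigma=0.0)
        for n in (2, 3):
            cur = deconv1d(vol, k, n_iter=n, blend_sigma=0.0)
            assert abs(cur.sum() - prev.sum()) / prev.sum() < 0.005
            prev = cur


class TestFuse:
    def test_2d1d_with_zero_1d_iters_equals_2d(self, small_multiview):
        gt, views, psfs = small_multiview
        out_a, _ = fuse(views, psfs, FusionConfig(method="2d1d", iters_mvd=2, iters_1d=0))
        out_b, _ = fuse(views, psfs, FusionConfig(method="2d", iters_mvd=2))
        np.testing.assert_array_equal(out_a, out_b)

    def test_all_methods_nonnegative_and_finite(self, small_multiview):
        gt, views, psfs = small_multiview
        for method in ("2d", "2d1d", "3d"):
            cfg = FusionConfig(method=method, iters_mvd=2, iters_1d=1, iters_3d=2)
            out, _ = fuse(views, psfs, cfg)
            assert out.min() >= 0 and np.all(np.isfinite(out))

    def test_diagnostics_recorded_with_ground_truth(self, small_multiview):
        gt, views, psfs = small_multiview
        cfg = FusionConfig(method="2d1d", iters_mvd=2, iters_1d=1)
        out, records = fuse(views, psfs, cfg, ground_truth=gt.data)
        assert len(records) == 3  # two 2D sweeps + one 1D block
        assert all({"phase", "iteration", "mse", "pcc"} <= set(r) for r in records)
        assert all(-1 <= r["pcc"] <= 1 for r in records)

    def test_single_shared_psf_broadcast(self, small_multiview, default_psf):
        gt, views, psfs = small_multiview
        out, _ = fuse(views, [default_psf], FusionConfig(method="2d", iters_mvd=1))
        assert out.shape == views[0].shape
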