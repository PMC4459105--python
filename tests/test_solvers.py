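import numpy as np
import pytest

from mapdeconv import (
    DeconvParams,
    ImageStack,
    KernelConfig,
    adjoint_psf,
    apply_psf,
    deconvolve,
    estimate_expectation,
    forward_model,
    gaussian_psf,
    lr_step,
    mapd_step,
    maphunt_step,
    normalize_psf,
    objective,
)
from mapdeconv.psf import PSFKernel

from test_expectation import brute_force_expectation
from test_psf import naive_convolve_periodic


def delta_kernel(size=3):
    raw = np.zeros((size, size))
    raw[size // 2, size // 2] = 1.0
    return PSFKernel(raw)


@pytest.fixture
def blur_problem(rng):
    """A small synthetic blur: truth, PSF, and exact blurred measurement."""
    truth = rng.uniform(0.1, 1.0, size=(16, 16))
    H = gaussian_psf(1.0, radius=2)
    g = apply_psf(truth, H, boundary="wrap")
    return truth, H, g


class TestForwardModel:
    def test_delta_kernel_is_identity(self, rng):
        f = rng.uniform(0, 1, size=(8, 8))
        np.testing.assert_allclose(forward_model(f, delta_kernel()), f, atol=1e-12)

    def test_constant_preserved(self):
        H = gaussian_psf(1.5)
        out = forward_model(np.full((32, 32), 0.4), H)
        np.testing.assert_allclose(out, 0.4, atol=1e-12)

    def test_matches_naive_convolution(self, rng):
        f = rng.uniform(0, 1, size=(8, 8))
        H = normalize_psf(rng.uniform(0, 1, size=(3, 3)))
        np.testing.assert_allclose(
            forward_model(f, H, boundary="wrap"),
            naive_convolve_periodic(f, H.values),
            atol=1e-12,
        )


class TestLRStep:
    def test_delta_psf_recovers_g_in_one_step(self, rng):
        H = delta_kernel()
        g = rng.uniform(0.1, 1.0, size=(8, 8))
        f0 = rng.uniform(0.1, 1.0, size=(8, 8))
        np.testing.assert_allclose(
            lr_step(f0, g, H, adjoint_psf(H)), g, atol=1e-12
        )

    def test_exact_blur_is_fixed_point(self, blur_problem):
        truth, H, g = blur_problem
        out = lr_step(truth, g, H, adjoint_psf(H), boundary="wrap")
        np.testing.assert_allclose(out, truth, atol=1e-10)

    def test_flux_conserved_under_periodic_boundary(self, rng):
        f = rng.uniform(0.2, 1.0, size=(16, 16))
        H = gaussian_psf(1.5, radius=4)
        g = apply_psf(rng.uniform(0.2, 1.0, size=(16, 16)), H, boundary="wrap")
        cur = f
        for _ in range(5):
            nxt = lr_step(cur, g, H, adjoint_psf(H), boundary="wrap")
            cur = nxt
        # after one step the total flux locks onto sum(g)
        assert abs(cur.sum() - g.sum()) / g.sum() < 1e-9

    def test_kl_data_fit_nonincreasing(self, rng):
        truth = rng.uniform(0.1, 1.0, size=(16, 16))
        H = gaussian_psf(1.5, radius=4)
        g = np.clip(
            apply_psf(truth, H, boundary="wrap")
            + rng.normal(0, 0.02, size=(16, 16)),
            1e-3,
            None,
        )
        f = g.copy()
        H_adj = adjoint_psf(H)
        objs = []
        for _ in range(25):
            f = lr_step(f, g, H, H_adj, boundary="wrap")
            objs.append(objective(f, g, H, 0.0, None, boundary="wrap"))
        diffs = np.diff(objs)
        assert np.all(diffs <= 1e-9 * abs(objs[0]))


class TestMapHuntStep:
    def test_lam_zero_is_bit_identical_to_lr(self, rng):
        f = rng.uniform(0.1, 1.0, size=(10, 10))
        g = rng.uniform(0.1, 1.0, size=(10, 10))
        H = gaussian_psf(1.0, radius=2)
        H_adj = adjoint_psf(H)
        np.testing.assert_array_equal(
            maphunt_step(f, g, H, H_adj, lam=0.0), lr_step(f, g, H, H_adj)
        )

    def test_fixed_point_at_f_equals_g_with_delta_psf(self, rng):
        g = rng.uniform(0.1, 1.0, size=(8, 8))
        H = delta_kernel()
        out = maphunt_step(g, g, H, adjoint_psf(H), lam=0.2)
        np.testing.assert_allclose(out, g, atol=1e-12)

    def test_scalar_update_formula_with_delta_psf(self):
        # delta PSF decouples pixels: update is g/(1 + lam (f - g)) * f/g * ...
        # i.e. f_{j+1} = f * (g/f) / (1 + lam (f - g))
        f = np.full((3, 3), 0.6)
        g = np.full((3, 3), 0.3)
        H = delta_kernel()
        out = maphunt_step(f, g, H, adjoint_psf(H), lam=0.2)
        expected = 0.6 * (0.3 / 0.6) / (1 + 0.2 * (0.6 - 0.3))
        np.testing.assert_allclose(out, expected, atol=1e-12)


class TestMapDStep:
    def test_lam_zero_matches_lr_regardless_of_kernel(self, rng):
        f = rng.uniform(0.1, 1.0, size=(12, 12))
        g = rng.uniform(0.1, 1.0, size=(12, 12))
        H = gaussian_psf(1.0, radius=2)
        H_adj = adjoint_psf(H)
        params = DeconvParams(lam=0.0, beta=625.0, window_radius=2, iterations=1)
        np.testing.assert_array_equal(
            mapd_step(f, g, H, H_adj, params), lr_step(f, g, H, H_adj)
        )

    def test_constant_iterate_reduces_to_lr(self, rng):
        f = np.full((12, 12), 0.5)
        g = rng.uniform(0.1, 1.0, size=(12, 12))
        H = gaussian_psf(1.0, radius=2)
        H_adj = adjoint_psf(H)
        params = DeconvParams(lam=0.2, window_radius=2)
        np.testing.assert_allclose(
            mapd_step(f, g, H, H_adj, params),
            lr_step(f, g, H, H_adj),
            atol=1e-12,
        )

    def test_matches_independent_oracle_pipeline(self, rng):
        """Full update against naive convolution + brute-force expectation."""
        f = rng.uniform(0.1, 1.0, size=(16, 16))
        g = rng.uniform(0.1, 1.0, size=(16, 16))
        H = normalize_psf(rng.uniform(0, 1, size=(3, 3)))
        H_adj = adjoint_psf(H)
        params = DeconvParams(
            lam=0.2, beta=0.01, window_radius=1, boundary="wrap",
            intensity_scale=1.0,
        )
        got = mapd_step(f, g, H, H_adj, params)

        e_hat = brute_force_expectation(f, 0.01, 1)
        m = np.maximum(naive_convolve_periodic(f, H.values), params.eps)
        num = naive_convolve_periodic(g / m, H_adj.values)
        den = np.maximum(1.0 + 0.2 * (f - e_hat), params.eps)
        np.testing.assert_allclose(got, f * num / den, atol=1e-12)

    def test_fixed_point_of_exact_solution(self):
        """If g = H*f* exactly and E_hat(f*) = f*, f* is invariant."""
        f_star = np.full((16, 16), 0.7)
        H = gaussian_psf(1.5, radius=4)
        g = apply_psf(f_star, H, boundary="wrap")
        params = DeconvParams(lam=0.2, window_radius=2, boundary="wrap")
        out = mapd_step(f_star, g, H, adjoint_psf(H), params)
        np.testing.assert_allclose(out, f_star, atol=1e-12)


class TestObjective:
    def test_poisson_minimum_at_exact_fit(self, blur_problem):
        truth, H, g = blur_problem
        val = objective(truth, g, H, 0.0, None, boundary="wrap")
        expected = float(np.sum(g - g * np.log(g)))
        assert val == pytest.approx(expected, rel=1e-9)

    def test_regularizer_vanishes_at_prior_mean(self, rng):
        f = rng.uniform(0.1, 1.0, size=(8, 8))
        H = delta_kernel()
        with_reg = objective(f, f, H, 5.0, f)
        without = objective(f, f, H, 0.0, None)
        assert with_reg == without

    def test_small_instance_hand_computation(self):
        f = np.array([[0.2, 0.4], [0.6, 0.8]])
        f = np.pad(f, 1, constant_values=0.5)  # 4x4
        g = np.full((4, 4), 0.5)
        e = np.full((4, 4), 0.45)
        H = delta_kernel()
        # delta PSF: objective = sum(f - g ln f) + lam/2 sum (f-e)^2
        expected = float(np.sum(f - g * np.log(f)) + 0.1 * np.sum((f - e) ** 2))
        assert objective(f, g, H, 0.2, e) == pytest.approx(expected, rel=1e-12)


class TestDeconvolvePipeline:
    def test_delta_psf_lr_is_stationary_at_measurement(self, rng):
        g = rng.uniform(0.3, 0.9, size=(24, 24))
        stack = ImageStack(planes=[g])
        params = DeconvParams(lam=0.0, iterations=3)
        out, traces = deconvolve(stack, delta_kernel(), params, method="lr")
        np.testing.assert_allclose(out.planes[0], g, atol=1e-10)
        assert len(traces) == 1
        assert len(traces[0].objective) == 3

    def test_mapd_lam_zero_equals_lr_whole_pipeline(self, rng):
        stack = ImageStack(planes=[rng.uniform(0.1, 1.0, size=(32, 32))])
        H = gaussian_psf(1.5, radius=4)
        params = DeconvParams(lam=0.0, iterations=5, window_radius=2)
        out_lr, _ = deconvolve(stack, H, params, method="lr")
        out_d, _ = deconvolve(stack, H, params, method="map_d")
        np.testing.assert_array_equal(out_lr.planes[0], out_d.planes[0])

    def test_channel_independence(self, rng):
        planes = [rng.uniform(0.1, 1.0, size=(32, 32)) for _ in range(3)]
        stack = ImageStack(planes=planes)
        H = gaussian_psf(1.5, radius=4)
        params = DeconvParams(iterations=4, window_radius=2)
        full, _ = deconvolve(stack, H, params, method="map_d")
        single, _ = deconvolve(
            ImageStack(planes=[planes[1]]), H, params, method="map_d"
        )
        np.testing.assert_array_equal(full.planes[1], single.planes[0])

    def test_psf_count_mismatch_rejected(self, rng):
        stack = ImageStack(planes=[rng.uniform(0, 1, size=(32, 32))] * 2)
        H = gaussian_psf(1.0, radius=2)
        with pytest.raises(ValueError, match="PSF"):
            deconvolve(stack, [H] * 3, DeconvParams(iterations=1), method="lr")

    def test_nonnegativity_of_output(self, tiny_scene):
        H = gaussian_psf(2.0)
        params = DeconvParams(iterations=5)
        out, _ = deconvolve(tiny_scene.measured, H, params, method="map_d")
        for p in out.planes:
            assert np.all(p >= 0)

    def test_unknown_method_rejected(self, rng):
        stack = ImageStack(planes=[rng.uniform(0, 1, size=(32, 32))])
        with pytest.raises(ValueError):
            deconvolve(stack, delta_kernel(), DeconvParams(), method="wiener")


def test_beta_rescaling_to_working_scale():
    params = DeconvParams(beta=625.0, intensity_scale=255.0)
    cfg = params.kernel_config
    assert cfg.beta == pytest.approx(625.0 / 255.0**2)
    assert isinstance(cfg, KernelConfig)
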