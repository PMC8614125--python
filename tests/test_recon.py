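"""Solver and baseline-reconstruction tests."""

import numpy as np
import pytest

from mocha_asl import (
    PSFModel,
    RigidTransform,
    build_prior,
    estimate_coil_maps,
    coil_combine,
    forward_pair,
    adjoint_pair,
    ifft3c,
    lucy_richardson,
    mocha_reconstruct,
    prior_value,
    reconstruct_m0,
    standard_reconstruct,
)
from mocha_asl.prior import prior_gradient

from conftest import complex_noise, small_model, trivial_model


def assemble_dense_system(model, prior, pairs):
    """Dense Hessian and right-hand side of the normal equations (oracle)."""
    n = int(np.prod(model.shape_high))
    n_pairs = model.num_pairs
    weight = float(np.prod(model.shape_low)) / n_pairs
    hmat = np.zeros((n, n), dtype=complex)
    beta = 0.0 if prior is None else prior.beta
    for j in range(n):
        e = np.zeros(n, dtype=complex)
        e[j] = 1.0
        p = e.reshape(model.shape_high)
        col = weight * sum(
            adjoint_pair(forward_pair(p, model, i), model, i) for i in range(n_pairs)
        )
        if beta > 0:
            col = col + beta * prior_gradient(p, prior)
        hmat[:, j] = col.ravel()
    b = weight * sum(adjoint_pair(pairs[i], model, i) for i in range(n_pairs))
    return hmat, b.ravel()


class TestMochaSolver:
    def test_exact_recovery_on_invertible_system(self, rng):
        model = trivial_model((16, 16, 8), n_pairs=2)
        x_true = complex_noise(rng, (16, 16, 8))
        pairs = [forward_pair(x_true, model, i) for i in range(2)]
        x, report = mocha_reconstruct(pairs, model, None, iters=100)
        assert np.linalg.norm(x - x_true) / np.linalg.norm(x_true) < 1e-6
        assert report.iterations_run <= 100

    def test_matches_dense_normal_equations(self, rng):
        model = small_model(
            shape=(6, 6, 4),
            fwhm=(0.0, 0.0, 1.2),
            transforms=[
                RigidTransform((0.5, 0, 0), (0.8, 0, 0)),
                RigidTransform((0, -1.0, 0), (0, 1.5, 0)),
            ],
            factors=(1, 1, 1),
            n_coils=2,
            accel=1,
        )
        prior = build_prior(rng.random((6, 6, 4)), (2.0, 2.0, 2.0), beta=0.5, normalize=False)
        x_true = complex_noise(rng, (6, 6, 4))
        pairs = [
            forward_pair(x_true, model, i) + 0.05 * complex_noise(rng, (2, 6, 6, 4))
            for i in range(2)
        ]
        hmat, b = assemble_dense_system(model, prior, pairs)
        x_dense = np.linalg.solve(hmat, b).reshape(model.shape_high)
        x, report = mocha_reconstruct(pairs, model, prior, iters=3000, tol=1e-14)
        assert np.linalg.norm(x - x_dense) / np.linalg.norm(x_dense) < 1e-6
        obj = np.asarray(report.objective)
        assert np.all(np.diff(obj) <= 1e-12 * max(abs(obj[0]), 1.0))

    def test_large_beta_flattens_solution_for_constant_anatomy(self, rng):
        model = trivial_model((8, 8, 8), n_pairs=1)
        x_true = np.abs(complex_noise(rng, (8, 8, 8))) + 1.0
        pairs = [forward_pair(x_true.astype(complex), model, 0)]
        prior = build_prior(np.full((8, 8, 8), 0.5), beta=1e6, normalize=False)
        x, _ = mocha_reconstruct(pairs, model, prior, iters=300)
        flat = np.abs(x)
        assert flat.std() / flat.mean() < 0.05

    def test_pair_order_permutation_invariance(self, rng):
        model = small_model(
            shape=(8, 8, 4),
            transforms=[RigidTransform(), RigidTransform((1.0, 0, 0), (1.0, 0, 0))],
            factors=(2, 2, 1),
            n_coils=2,
            accel=1,
        )
        prior = build_prior(rng.random((8, 8, 4)), beta=1.0, normalize=False)
        pairs = [complex_noise(rng, (2, 4, 4, 4)) for _ in range(2)]
        x_fwd, _ = mocha_reconstruct(pairs, model, prior, iters=60)
        model_rev = small_model(
            shape=(8, 8, 4),
            transforms=list(reversed(model.transforms)),
            factors=(2, 2, 1),
            n_coils=2,
            accel=1,
        )
        x_rev, _ = mocha_reconstruct(list(reversed(pairs)), model_rev, prior, iters=60)
        assert np.linalg.norm(x_fwd - x_rev) / np.linalg.norm(x_fwd) < 1e-6

    def test_increasing_beta_decreases_prior_value_of_solution(self, rng):
        model = trivial_model((8, 8, 8), n_pairs=1)
        prior0 = build_prior(rng.random((8, 8, 8)), beta=0.0, normalize=False)
        pairs = [complex_noise(rng, (1, 8, 8, 8))]
        values = []
        for beta in (0.0, 1.0, 10.0, 100.0):
            import dataclasses

            prior = dataclasses.replace(prior0, beta=beta)
            x, _ = mocha_reconstruct(pairs, model, prior, iters=200)
            values.append(prior_value(x, prior))
        assert np.all(np.diff(values) <= 1e-9 * values[0])

    def test_nan_data_rejected(self):
        model = trivial_model((4, 4, 4))
        bad = np.full((1, 4, 4, 4), np.nan, dtype=complex)
        with pytest.raises(ValueError):
            mocha_reconstruct([bad], model, None, iters=1)

    def test_m0_special_case_exact_recovery(self, rng):
        model = trivial_model((8, 8, 8), n_pairs=1)
        x_true = complex_noise(rng, (8, 8, 8))
        s = forward_pair(x_true, model, 0)
        x, _ = reconstruct_m0(s, model, None, iters=50)
        assert np.linalg.norm(x - x_true) / np.linalg.norm(x_true) < 1e-6


class TestCoilMaps:
    def test_single_coil_unit_modulus(self, rng):
        img = np.abs(complex_noise(rng, (1, 6, 6, 6))) + 0.1
        maps = estimate_coil_maps(img)
        np.testing.assert_allclose(np.abs(maps), 1.0, atol=1e-12)

    def test_two_identical_coils(self, rng):
        img = np.abs(complex_noise(rng, (6, 6, 6))) + 0.1
        maps = estimate_coil_maps(np.stack([img, img]))
        np.testing.assert_allclose(np.abs(maps), 1 / np.sqrt(2), atol=1e-12)

    def test_rss_of_maps_is_one(self, rng):
        imgs = complex_noise(rng, (4, 6, 6, 6))
        maps = estimate_coil_maps(imgs)
        rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
        np.testing.assert_allclose(rss, 1.0, atol=1e-10)

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning):
            maps = estimate_coil_maps(np.zeros((2, 4, 4, 4)))
        assert not np.any(maps)


class TestStandardReconstruction:
    def test_identical_controls_and_labels_give_zero(self, rng):
        k = [complex_noise(rng, (1, 6, 6, 6)) for _ in range(3)]
        maps = np.ones((1, 6, 6, 6), complex)
        out = standard_reconstruct(k, k, [RigidTransform()] * 3, maps)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_single_pair_reduces_to_ifft_difference(self, rng):
        kc = complex_noise(rng, (1, 8, 8, 8))
        kl = complex_noise(rng, (1, 8, 8, 8))
        maps = np.ones((1, 8, 8, 8), complex)
        out = standard_reconstruct([kc], [kl], [RigidTransform()], maps)
        np.testing.assert_allclose(out, ifft3c(kc[0]) - ifft3c(kl[0]), atol=1e-12)

    def test_integer_shift_pairs_match_manual_composition(self, rng):
        from mocha_asl import apply_rigid, fft3c

        maps = np.ones((1, 8, 8, 8), complex)
        spacing = (2.0, 2.0, 2.0)
        base_c = rng.standard_normal((8, 8, 8))
        base_l = rng.standard_normal((8, 8, 8))
        transforms = [
            RigidTransform((0, 0, 0), (0.0, 0.0, 0.0)),
            RigidTransform((0, 0, 0), (2.0, 0.0, 0.0)),
            RigidTransform((0, 0, 0), (0.0, -4.0, 0.0)),
        ]
        kcs, kls = [], []
        for t in transforms:
            kcs.append(fft3c(apply_rigid(base_c, t, spacing))[None])
            kls.append(fft3c(apply_rigid(base_l, t, spacing))[None])
        out = standard_reconstruct(kcs, kls, transforms, maps, spacing)
        # manual: shift each moved image back and average; interior voxels only
        manual = np.zeros((8, 8, 8))
        for t in transforms:
            c_i = apply_rigid(base_c, t, spacing)
            l_i = apply_rigid(base_l, t, spacing)
            manual += apply_rigid(c_i - l_i, t, spacing, inverse=True)
        manual /= 3
        interior = (slice(2, -2),) * 3
        np.testing.assert_allclose(out.real[interior], manual[interior], atol=1e-10)

    def test_length_mismatch_rejected(self, rng):
        maps = np.ones((1, 4, 4, 4), complex)
        with pytest.raises(ValueError):
            standard_reconstruct(
                [complex_noise(rng, (1, 4, 4, 4))], [], [RigidTransform()], maps
            )


class TestLucyRichardson:
    def test_delta_kernel_fixed_point(self, rng):
        img = np.abs(complex_noise(rng, (6, 6, 6))) + 0.5
        out = lucy_richardson(img.real, PSFModel((0, 0, 0)), iters=5)
        np.testing.assert_allclose(out, img.real, atol=1e-10)

    def test_peak_recovery_on_blurred_point_source(self):
        from mocha_asl import apply_blur

        psf = PSFModel((0.0, 0.0, 1.5))
        x = np.zeros((9, 9, 17))
        x[4, 4, 8] = 1.0
        blurred = apply_blur(x, psf).real
        out = lucy_richardson(blurred, psf, iters=100)
        assert out[4, 4, 8] > blurred[4, 4, 8]

    def test_flux_conserved_with_periodic_boundaries(self, rng):
        img = np.abs(complex_noise(rng, (8, 8, 8))) + 0.2
        psf = PSFModel((0.0, 1.2, 1.5))
        out = lucy_richardson(img.real, psf, iters=50, boundary="wrap")
        assert out.sum() == pytest.approx(img.real.sum(), rel=1e-6)

    def test_matches_skimage_reference(self, rng):
        from skimage.restoration import richardson_lucy as sk_rl

        psf = PSFModel((0.0, 0.0, 1.5), truncation_radius=3)
        kernels = psf.kernels()
        kernel3 = (
            kernels[0][:, None, None]
            * kernels[1][None, :, None]
            * kernels[2][None, None, :]
        )
        img = np.abs(complex_noise(rng, (7, 7, 9))) + 0.3
        want = sk_rl(img.real, kernel3, num_iter=10, clip=False)
        got = lucy_richardson(
            img.real, psf, iters=10, boundary="constant", u0=np.full(img.shape, 0.5)
        )
        np.testing.assert_allclose(got, want, rtol=1e-7, atol=1e-9)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            lucy_richardson(-np.ones((4, 4, 4)), PSFModel((0, 0, 1.0)))


class TestCoilCombine:
    def test_uniform_single_coil_is_identity(self, rng):
        img = complex_noise(rng, (1, 5, 5, 5))
        maps = np.ones((1, 5, 5, 5), complex)
        np.testing.assert_allclose(coil_combine(img, maps), img[0], atol=1e-13)
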