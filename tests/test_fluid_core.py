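import numpy as np
import pytest

from fluidvbm import (
    PhantomSpec,
    SolverSpec,
    ViscosityParams,
    apply_operator,
    compute_force,
    make_phantom,
    solve_gaussian,
    solve_sor,
    solve_sora,
    solve_viscous_kernel,
)
from fluidvbm.fluid_core import operator_matrix
from fluidvbm.volumes import (
    DisplacementField,
    ScalarVolume,
    VectorField,
    sample_warped,
)

from conftest import smooth_random_force

VISC = ViscosityParams(1.0, 0.0)
INTERIOR = (slice(None),) + (slice(2, -2),) * 3


class TestParams:
    def test_mu_must_be_positive(self):
        with pytest.raises(ValueError):
            ViscosityParams(mu=0.0)

    def test_mu_plus_lam_must_be_positive(self):
        with pytest.raises(ValueError):
            ViscosityParams(mu=1.0, lam=-1.5)

    @pytest.mark.parametrize("bad", [0.0, 2.0, -0.5])
    def test_relaxation_open_interval(self, bad):
        with pytest.raises(ValueError):
            SolverSpec(relaxation=bad)


class TestComputeForce:
    def test_zero_when_registered(self, sphere_pair):
        _, target = sphere_pair
        u = DisplacementField.zeros(target.shape)
        F = compute_force(target, target, u)
        np.testing.assert_array_equal(F.field, 0.0)

    def test_zero_for_constant_subject(self, sphere_pair):
        _, target = sphere_pair
        flat = target.with_data(np.full(target.shape, 0.5))
        F = compute_force(flat, target, DisplacementField.zeros(target.shape))
        np.testing.assert_array_equal(F.field, 0.0)

    def test_sign_matches_ssd_descent_at_single_voxel(self, sphere_pair):
        # oracle: perturb u at one voxel and difference the SSD cost; the
        # force component must point opposite the numerical cost gradient
        subject, target = sphere_pair
        u = DisplacementField.zeros(subject.shape)
        F = compute_force(subject, target, u)
        vox = np.unravel_index(np.argmax(np.abs(F.field[0])), subject.shape)

        def ssd(upert):
            return np.sum((sample_warped(subject, upert).data - target.data) ** 2)

        eps = 1e-4
        up = DisplacementField.zeros(subject.shape)
        up.field[(0, *vox)] = eps
        um = DisplacementField.zeros(subject.shape)
        um.field[(0, *vox)] = -eps
        dE = (ssd(up) - ssd(um)) / (2 * eps)
        assert F.field[(0, *vox)] * dE < 0  # F is the descent direction


class TestApplyOperator:
    def test_zero_field(self):
        v = VectorField.zeros((8, 8, 8))
        np.testing.assert_array_equal(apply_operator(v, VISC).field, 0.0)

    def test_constant_field_vanishes_in_interior(self):
        v = VectorField(np.ones((3, 8, 8, 8)))
        out = apply_operator(v, ViscosityParams(1.0, 0.5)).field
        np.testing.assert_allclose(out[INTERIOR], 0.0, atol=1e-12)

    def test_laplacian_stencil_weights_sum_to_zero(self):
        # unit impulse in component 1 on a 5^3 grid: the mu-Laplacian part
        # weights over the neighborhood sum to 0 at interior voxels
        v = np.zeros((3, 5, 5, 5))
        v[0, 2, 2, 2] = 1.0
        out = apply_operator(VectorField(v), VISC)
        # both the 7-point Laplacian and the central grad-div stencils have
        # zero weight sum, so each output component sums to 0
        for comp in range(3):
            assert out.field[comp].sum() == pytest.approx(0.0, abs=1e-12)

    def test_matches_sparse_matrix(self, rng):
        shape = (6, 7, 8)
        v = VectorField(rng.normal(size=(3, *shape)))
        visc = ViscosityParams(1.3, 0.4)
        A = operator_matrix(shape, visc)
        via_matrix = -(A @ v.field.reshape(-1))
        via_arrays = apply_operator(v, visc).field.reshape(-1)
        np.testing.assert_allclose(via_arrays, via_matrix, atol=1e-12)


class TestSolveSor:
    def test_zero_force_returns_zero_immediately(self):
        F = VectorField.zeros((8, 8, 8))
        v = solve_sor(F, VISC, SolverSpec(kind="sor"))
        np.testing.assert_array_equal(v.field, 0.0)

    def test_forward_residual_oracle(self):
        F = smooth_random_force(seed=3)
        spec = SolverSpec(kind="sor", tolerance=1e-6, max_sweeps=2000)
        v = solve_sor(F, VISC, spec)
        res = apply_operator(v, VISC).field + F.field
        rel = np.linalg.norm(res) / np.linalg.norm(F.field)
        assert rel <= 1e-5

    def test_gauss_seidel_limit_converges(self):
        # relaxation = 1 degenerates to plain Gauss-Seidel
        F = smooth_random_force(seed=4)
        spec = SolverSpec(kind="sor", tolerance=1e-6, max_sweeps=4000,
                          relaxation=1.0)
        v = solve_sor(F, VISC, spec)
        res = apply_operator(v, VISC).field + F.field
        assert np.linalg.norm(res) / np.linalg.norm(F.field) <= 1e-5

    def test_linearity(self):
        F1 = smooth_random_force(seed=5)
        F2 = smooth_random_force(seed=6)
        spec = SolverSpec(kind="sor", tolerance=1e-8, max_sweeps=4000)
        v1 = solve_sor(F1, VISC, spec)
        v2 = solve_sor(F2, VISC, spec)
        vc = solve_sor(VectorField(2.0 * F1.field - 0.5 * F2.field), VISC, spec)
        np.testing.assert_allclose(vc.field, 2.0 * v1.field - 0.5 * v2.field,
                                   atol=1e-6)

    def test_warns_when_sweeps_exhausted(self):
        F = smooth_random_force(seed=7)
        with pytest.warns(RuntimeWarning):
            solve_sor(F, VISC, SolverSpec(kind="sor", tolerance=1e-14,
                                          max_sweeps=2))


class TestSolveSora:
    def test_zero_force(self):
        v = solve_sora(VectorField.zeros((8, 8, 8)), VISC,
                       SolverSpec(kind="sora"))
        np.testing.assert_array_equal(v.field, 0.0)

    def test_compact_force_agrees_with_sor(self, interior_force):
        F, _, visc = interior_force
        spec_sor = SolverSpec(kind="sor", tolerance=1e-8, max_sweeps=4000)
        spec_sora = SolverSpec(kind="sora", tolerance=1e-8, max_sweeps=4000)
        v_sor = solve_sor(F, visc, spec_sor)
        v_sora = solve_sora(F, visc, spec_sora, active_threshold=1e-4)
        rel = (np.linalg.norm(v_sora.field - v_sor.field)
               / np.linalg.norm(v_sor.field))
        assert rel <= 1e-4

    def test_zero_threshold_identical_to_sor(self):
        F = smooth_random_force(seed=8)
        spec = SolverSpec(kind="sora", tolerance=1e-6, max_sweeps=2000)
        v_sora = solve_sora(F, VISC, spec, active_threshold=0.0)
        v_sor = solve_sor(F, VISC, SolverSpec(kind="sor", tolerance=1e-6,
                                              max_sweeps=2000))
        np.testing.assert_allclose(v_sora.field, v_sor.field, atol=1e-12)


class TestSolveGaussian:
    def test_zero_force(self):
        v = solve_gaussian(VectorField.zeros((8, 8, 8)),
                           SolverSpec(kind="gaussian"))
        np.testing.assert_array_equal(v.field, 0.0)

    def test_impulse_reproduces_kernel(self):
        F = np.zeros((3, 9, 9, 9))
        F[1, 4, 4, 4] = 1.0
        spec = SolverSpec(kind="gaussian", gaussian_sigma=1.5)
        v = solve_gaussian(VectorField(F), spec)
        from scipy.ndimage import gaussian_filter
        expected = gaussian_filter(F[1], 1.5, mode="constant", cval=0.0)
        np.testing.assert_allclose(v.field[1], expected, atol=1e-12)
        assert v.field[1].argmax() == expected.argmax()

    def test_constant_force_scaled_by_partial_kernel_sum(self):
        # separable kernel: response to a constant field equals the constant
        # times the product of 1D partial sums inside the grid
        n = 11
        F = VectorField(np.ones((3, n, n, n)))
        spec = SolverSpec(kind="gaussian", gaussian_sigma=1.0)
        v = solve_gaussian(F, spec)
        from scipy.ndimage import gaussian_filter1d
        line = gaussian_filter1d(np.ones(n), 1.0, mode="constant", cval=0.0)
        center = n // 2
        expected = line[center] ** 3
        assert v.field[0][center, center, center] == pytest.approx(expected)


class TestViscousKernel:
    def test_zero_force(self):
        v = solve_viscous_kernel(VectorField.zeros((8, 8, 8)), VISC)
        np.testing.assert_array_equal(v.field, 0.0)

    def test_inverts_periodic_operator_exactly(self):
        # on a pure Fourier mode the kernel must invert L to round-off
        shape = (16, 16, 16)
        idx = np.indices(shape, dtype=float)
        phase = 2 * np.pi * (2 * idx[0] + 3 * idx[1] + idx[2]) / 16
        v_true = np.stack([np.cos(phase), 0.3 * np.sin(phase),
                           np.zeros(shape)])
        visc = ViscosityParams(1.0, 0.2)
        # periodic forward operator via its Fourier symbol
        w = [2 * np.pi * np.fft.fftfreq(n) for n in shape]
        W = np.meshgrid(*w, indexing="ij")
        s = [np.sin(x) for x in W]
        lam = sum(2 * (1 - np.cos(x)) for x in W)
        vhat = np.stack([np.fft.fftn(c) for c in v_true])
        sv = sum(s[j] * vhat[j] for j in range(3))
        Lv = np.stack([np.real(np.fft.ifftn(
            -(visc.mu * lam * vhat[i] + (visc.mu + visc.lam) * s[i] * sv)))
            for i in range(3)])
        out = solve_viscous_kernel(VectorField(-Lv), visc)
        np.testing.assert_allclose(out.field, v_true, atol=1e-12)

    def test_interior_residual_on_compact_force(self, interior_force):
        F, _, visc = interior_force
        v = solve_viscous_kernel(F, visc)
        res = apply_operator(v, visc).field + F.field
        rel = (np.linalg.norm(res[INTERIOR]) / np.linalg.norm(F.field))
        assert rel <= 1e-3

    def test_agrees_with_sor_in_interior(self, interior_force):
        F, _, visc = interior_force
        v_vk = solve_viscous_kernel(F, visc)
        v_sor = solve_sor(F, visc, SolverSpec(kind="sor", tolerance=1e-8,
                                              max_sweeps=4000))
        rel = (np.linalg.norm((v_vk.field - v_sor.field)[INTERIOR])
               / np.linalg.norm(v_sor.field[INTERIOR]))
        assert rel <= 1e-2

    def test_linearity_exact(self, interior_force):
        F, _, visc = interior_force
        F2 = VectorField(np.roll(F.field, 3, axis=2))
        va = solve_viscous_kernel(
            VectorField(2.0 * F.field + 0.5 * F2.field), visc)
        vb = solve_viscous_kernel(F, visc)
        vc = solve_viscous_kernel(F2, visc)
        np.testing.assert_allclose(va.field,
                                   2.0 * vb.field + 0.5 * vc.field, atol=1e-12)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            solve_viscous_kernel(VectorField.zeros((3, 3, 3)), VISC)
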