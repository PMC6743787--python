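"""System operator, MLEM, hybrid blend, FBP and SART-TV."""

import numpy as np
import pytest

from tomomar import (
    ProjectionStack,
    ReconVolume,
    SystemOperator,
    TomoGeometry,
    back_project,
    fbp_reconstruct,
    forward_model,
    hybrid_mar,
    mlem_reconstruct,
    sart_tv_reconstruct,
)
from tomomar.recon import shepp_logan_response, total_variation


@pytest.fixture(scope="module")
def geo32():
    return TomoGeometry(
        detector_shape=(32, 32),
        pixel_pitch_mm=8.0,
        n_views=37,
        n_slices=32,
        slice_interval_mm=4.0,
    )


@pytest.fixture(scope="module")
def op32(geo32):
    return SystemOperator(geo32)


class TestSystemOperator:
    def test_adjoint_identity(self, geo32, op32):
        rng = np.random.default_rng(42)
        for _ in range(20):
            v = rng.random(op32.vol_shape)
            p = rng.random(op32.proj_shape)
            lhs = float(np.sum(op32.forward(v) * p))
            rhs = float(np.sum(v * op32.back(p)))
            assert abs(lhs - rhs) <= 1e-6 * abs(lhs)

    def test_forward_linearity_and_zero(self, geo32, op32, rng):
        v = rng.random(op32.vol_shape)
        np.testing.assert_allclose(op32.forward(3.5 * v), 3.5 * op32.forward(v), rtol=1e-12)
        assert op32.forward(np.zeros(op32.vol_shape)).max() == 0

    def test_unit_voxel_hits_expected_pixels(self, geo32, op32):
        # central voxel projects near the detector center in every view,
        # shifted along v according to the source position
        v = np.zeros(op32.vol_shape)
        k = geo32.n_slices // 2
        v[k, 16, 16] = 1.0
        proj = op32.forward(v)
        for i in range(geo32.n_views):
            nz = np.argwhere(proj[i] > 0)
            assert len(nz) >= 1
            # footprint is a (<=2)x(<=2) bilinear splat
            assert np.ptp(nz[:, 0]) <= 1 and np.ptp(nz[:, 1]) <= 1
        # total deposited weight is identical across views (full footprint)
        sums = proj.sum(axis=(1, 2))
        np.testing.assert_allclose(sums, sums[0], rtol=1e-9)

    def test_back_project_zero_stack(self, geo32):
        stack = ProjectionStack(data=np.zeros((37, 32, 32)), geometry=geo32)
        assert back_project(stack, geo32).data.max() == 0

    def test_single_bright_pixel_smears_one_ray(self, geo32, op32):
        stack = np.zeros(op32.proj_shape)
        stack[18, 16, 16] = 1.0  # central view, on-axis pixel
        vol = op32.back(stack)
        assert vol.max() > 0
        # the 0-degree on-axis ray runs straight down the volume center:
        # all deposited weight stays within 2 voxels of it on every slice
        for k in range(geo32.n_slices):
            nz = np.argwhere(vol[k] > 0)
            if len(nz):
                assert np.all(np.abs(nz - 16) <= 2)

    def test_point_object_sharpest_in_focus(self, geo32, op32):
        v = np.zeros(op32.vol_shape)
        k0 = geo32.n_slices // 2
        v[k0, 16, 16] = 1.0
        recon = op32.back(op32.forward(v))
        peaks = recon.max(axis=(1, 2))
        assert int(np.argmax(peaks)) == k0

    def test_shape_mismatch_errors(self, geo32, op32):
        with pytest.raises(ValueError, match="shape"):
            op32.forward(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="shape"):
            op32.back(np.zeros((2, 2, 2)))


class TestMLEM:
    def test_fixed_point_on_forward_of_ones(self, geo32, op32):
        data = op32.forward(np.ones(op32.vol_shape))
        stack = ProjectionStack(data=data, geometry=geo32)
        vol, _ = mlem_reconstruct(stack, geo32, iterations=5, op=op32)
        np.testing.assert_array_equal(vol.data, 1.0)

    def test_nonnegativity_and_likelihood_monotone(self, geo32, op32, rng):
        v_true = rng.random(op32.vol_shape)
        stack = ProjectionStack(data=op32.forward(v_true), geometry=geo32)
        vol, ll = mlem_reconstruct(stack, geo32, iterations=30, op=op32)
        assert vol.data.min() >= 0
        ll = np.asarray(ll)
        assert np.all(np.diff(ll) >= -1e-9 * np.abs(ll[0]))

    def test_forward_residual_shrinks(self, geo32, op32, rng):
        v_true = rng.random(op32.vol_shape)
        p = op32.forward(v_true)
        stack = ProjectionStack(data=p, geometry=geo32)
        res = []
        for it in (1, 5, 20):
            vol, _ = mlem_reconstruct(stack, geo32, iterations=it, op=op32)
            res.append(float(np.linalg.norm(op32.forward(vol.data) - p)))
        assert res[2] < res[1] < res[0]

    def test_negative_data_rejected(self, geo32, op32):
        stack = ProjectionStack(data=-np.ones(op32.proj_shape), geometry=geo32)
        with pytest.raises(ValueError, match="non-negative"):
            mlem_reconstruct(stack, geo32, iterations=1, op=op32)


class TestHybrid:
    def test_endpoints_bitwise(self, geo32, rng):
        a = ReconVolume(data=rng.random((32, 32, 32)), geometry=geo32)
        b = ReconVolume(data=rng.random((32, 32, 32)), geometry=geo32)
        np.testing.assert_array_equal(hybrid_mar(a, b, w=0.0).data, a.data)
        np.testing.assert_array_equal(hybrid_mar(a, b, w=1.0).data, b.data)

    def test_convex_combination(self, geo32, rng):
        a = ReconVolume(data=rng.random((32, 32, 32)), geometry=geo32)
        b = ReconVolume(data=rng.random((32, 32, 32)), geometry=geo32)
        h = hybrid_mar(a, b, w=0.7)
        np.testing.assert_allclose(h.data, 0.3 * a.data + 0.7 * b.data, rtol=1e-12)
        assert h.meta["w"] == 0.7

    def test_weight_out_of_range(self, geo32, rng):
        a = ReconVolume(data=rng.random((4, 4, 4)), geometry=geo32)
        with pytest.raises(ValueError, match="w"):
            hybrid_mar(a, a, w=1.5)


class TestFBP:
    def test_kernel_none_is_plain_backprojection(self, geo32, op32, rng):
        stack = ProjectionStack(data=rng.random(op32.proj_shape), geometry=geo32)
        vol = fbp_reconstruct(stack, geo32, kernel="none", op=op32)
        ref = back_project(stack, geo32, op=op32, normalize=True)
        np.testing.assert_allclose(vol.data, ref.data, rtol=1e-12)

    def test_shepp_logan_closed_form(self):
        n, pitch = 64, 2.0
        H = shepp_logan_response(n, pitch)
        f = np.fft.rfftfreq(n, d=pitch)
        f_nyq = 1.0 / (2 * pitch)
        np.testing.assert_allclose(H, np.abs(f) * np.sinc(f / (2 * f_nyq)), rtol=1e-12)
        assert H[0] == 0.0

    def test_delta_row_matches_direct_convolution(self, geo32, op32):
        # filtering a delta along v equals the kernel's impulse response,
        # and filtering any row equals circular convolution with it
        nv = 32
        H = shepp_logan_response(nv, geo32.pixel_pitch_mm)
        impulse = np.fft.irfft(H, n=nv)
        rng = np.random.default_rng(3)
        row = rng.random(nv)
        expected = np.array(
            [np.sum(row * np.roll(impulse[::-1], i + 1)) for i in range(nv)]
        )
        via_fft = np.fft.irfft(np.fft.rfft(row) * H, n=nv)
        np.testing.assert_allclose(via_fft, expected, atol=1e-12)

    def test_unknown_kernel(self, geo32, op32, rng):
        stack = ProjectionStack(data=rng.random(op32.proj_shape), geometry=geo32)
        with pytest.raises(ValueError, match="kernel"):
            fbp_reconstruct(stack, geo32, kernel="hann", op=op32)


class TestSARTTV:
    def test_zero_tv_iterations_is_plain_sart(self, geo32, op32, rng):
        v_true = rng.random(op32.vol_shape)
        stack = ProjectionStack(data=op32.forward(v_true), geometry=geo32)
        vol = sart_tv_reconstruct(stack, geo32, sart_iterations=3, tv_iterations=0, op=op32)
        # manual SART
        p = stack.data
        row_sum = np.maximum(op32.forward(np.ones(op32.vol_shape)), 1e-12)
        col_sum = np.maximum(op32.back(np.ones(op32.proj_shape)), 1e-12)
        v = np.zeros(op32.vol_shape)
        for _ in range(3):
            v = v + op32.back((p - op32.forward(v)) / row_sum) / col_sum
        np.testing.assert_allclose(vol.data, v, rtol=1e-10)

    def test_tv_phase_never_increases_tv(self, geo32, op32, rng):
        v_true = (rng.random(op32.vol_shape) > 0.7).astype(float)
        stack = ProjectionStack(data=op32.forward(v_true), geometry=geo32)

        from tomomar import recon as recon_mod

        tv_values = []
        orig = recon_mod.total_variation

        vol_plain = sart_tv_reconstruct(stack, geo32, sart_iterations=2, tv_iterations=0, op=op32)
        vol_tv = sart_tv_reconstruct(stack, geo32, sart_iterations=2, tv_iterations=30, op=op32)
        # same data-fidelity start; TV phases may only lower total variation
        assert total_variation(vol_tv.data) <= total_variation(vol_plain.data) + 1e-9

    def test_default_iteration_counts(self, geo32):
        import inspect

        sig = inspect.signature(sart_tv_reconstruct)
        assert sig.parameters["sart_iterations"].default == 10
        assert sig.parameters["tv_iterations"].default == 100
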