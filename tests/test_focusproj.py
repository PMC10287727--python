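"""Focus projection, entropy oracle equivalence, and registration checks."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from skimage.transform import AffineTransform, rotate, warp

from chronoplex import focusproj as fp
from chronoplex import synthdata as sd
from chronoplex.datatypes import FocusIndexMap


def brute_force_entropy(plane, width):
    """Independent nested-loop histogram-entropy oracle."""
    q = fp.quantize_plane(plane)
    before = width // 2 - (1 if width % 2 == 0 else 0)
    after = width // 2
    pad = np.pad(q, ((before, after), (before, after)), mode="symmetric")
    out = np.zeros(plane.shape)
    n = width * width
    for i in range(plane.shape[0]):
        for j in range(plane.shape[1]):
            win = pad[i:i + width, j:j + width].ravel()
            counts = np.bincount(win, minlength=256).astype(float)
            p = counts[counts > 0] / n
            out[i, j] = -(p * np.log2(p)).sum()
    return out


class TestStackOps:
    def test_average_identical(self):
        v = np.random.default_rng(0).random((3, 8, 8))
        assert np.allclose(fp.average_repeats([v, v, v]), v)

    def test_average_linearity(self):
        v = np.random.default_rng(1).random((2, 4, 4))
        assert np.allclose(fp.average_repeats([v, 2 * v, 3 * v]), 2 * v)

    def test_average_reduces_variance(self):
        rng = np.random.default_rng(2)
        vols = [rng.standard_normal((4, 32, 32)) for _ in range(3)]
        avg = fp.average_repeats(vols)
        assert np.var(avg) == pytest.approx(np.var(vols[0]) / 3, rel=0.2)

    def test_average_shape_mismatch(self):
        with pytest.raises(ValueError):
            fp.average_repeats([np.zeros((2, 2)), np.zeros((3, 3))])

    def test_bin_constant(self):
        out = fp.bin_xy(np.full((2, 3, 8, 8), 5.0))
        assert out.shape == (2, 3, 4, 4)
        assert np.allclose(out, 5.0)

    def test_bin_checkerboard(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        assert np.allclose(fp.bin_xy(board.astype(float)), 0.5)

    def test_bin_matches_loop_oracle(self):
        v = np.random.default_rng(3).random((10, 10))
        out = fp.bin_xy(v)
        for i in range(5):
            for j in range(5):
                assert out[i, j] == pytest.approx(v[2*i:2*i+2, 2*j:2*j+2].mean(), rel=1e-12)

    def test_bin_crops_remainder(self):
        assert fp.bin_xy(np.zeros((7, 9))).shape == (3, 4)


class TestLocalEntropy:
    def test_constant_plane_zero(self):
        assert np.allclose(fp.local_entropy(np.full((16, 16), 3.0)), 0.0)

    def test_checkerboard_one_bit(self):
        board = (np.indices((32, 32)).sum(axis=0) % 2).astype(float)
        ent = fp.local_entropy(board, width=10)
        assert np.allclose(ent[5:-5, 5:-5], 1.0)

    @pytest.mark.parametrize("width", [7, 10])
    def test_matches_brute_force_oracle(self, width):
        plane = np.random.default_rng(4).random((64, 64))
        ent = fp.local_entropy(plane, width=width)
        assert np.abs(ent - brute_force_entropy(plane, width)).max() < 1e-12

    def test_width_larger_than_plane_errors(self):
        with pytest.raises(ValueError):
            fp.local_entropy(np.zeros((8, 8)), width=10)


class TestFocusIndexMap:
    def test_single_plane_all_zero(self):
        ent = np.random.default_rng(5).random((1, 16, 16))
        assert np.all(fp.entropy_argmax(ent).raw_index == 0)

    def test_argmax_tie_takes_lowest_z(self):
        ent = np.ones((3, 4, 4))
        assert np.all(fp.entropy_argmax(ent).raw_index == 0)

    def test_flat_focal_plane_recovered(self):
        p = sd.FocalSurfaceSimParams(shape=(1, 8, 96, 96), drift_px_per_frame=0.0,
                                     warp_amplitude_px=0.0, surface_coeffs={"c0": 3.0}, seed=1)
        movie, _ = sd.gen_focal_timelapse(p)
        ent = fp.entropy_volume(movie.data[0])
        raw = fp.entropy_argmax(ent).raw_index
        interior = raw[10:-10, 10:-10]
        assert np.abs(interior - 3).mean() <= 1.0

    def test_smooth_surface_recovered(self, small_timelapse):
        movie, gt = small_timelapse
        binned = fp.bin_xy(movie.data)
        ent = fp.entropy_volume(binned[0])
        raw = fp.entropy_argmax(ent).raw_index
        zs = fp.bin_xy(gt.z_surface[0])
        assert np.abs(raw - zs)[6:-6, 6:-6].mean() <= 1.0

    def test_smoothing_preserves_constant_and_ramp(self):
        const = FocusIndexMap(index=np.full((64, 64), 4.0), raw_index=np.full((64, 64), 4))
        assert np.allclose(fp.smooth_index_map(const, 20.0).index, 4.0)
        ramp = np.tile(np.linspace(0, 10, 128), (128, 1))
        sm = fp.smooth_index_map(FocusIndexMap(index=ramp, raw_index=ramp), 20.0).index
        assert np.allclose(sm[:, 45:-45], ramp[:, 45:-45], atol=1e-4)

    def test_impulse_attenuated_by_center_weight(self):
        impulse = np.zeros((65, 65))
        impulse[32, 32] = 1.0
        sm = fp.smooth_index_map(FocusIndexMap(index=impulse, raw_index=impulse), 20.0).index
        kernel_center = gaussian_filter(impulse, sigma=10.0)[32, 32]
        assert sm[32, 32] == pytest.approx(kernel_center, rel=1e-6)

    def test_apply_integer_map_selects_plane(self):
        stack = np.stack([np.full((4, 4), z, float) for z in range(5)])
        fmap = FocusIndexMap(index=np.full((4, 4), 2.0), raw_index=np.full((4, 4), 2))
        assert np.allclose(fp.apply_index_map(stack, fmap), 2.0)

    def test_apply_fractional_map_interpolates(self):
        stack = np.stack([np.full((2, 2), 10.0), np.full((2, 2), 20.0)])
        fmap = FocusIndexMap(index=np.full((2, 2), 0.5), raw_index=np.zeros((2, 2)))
        assert np.allclose(fp.apply_index_map(stack, fmap), 15.0)

    def test_focused_projection_beats_single_planes(self, small_timelapse):
        movie, gt = small_timelapse
        binned = fp.bin_xy(movie.data)
        frame, _ = fp.focus_project_stack(binned[0])
        sharp = fp.bin_xy(gt.sharp_frames[0])
        corr = np.corrcoef(frame.ravel(), sharp.ravel())[0, 1]
        assert corr >= 0.9
        for z in range(binned.shape[1]):
            assert corr > np.corrcoef(binned[0, z].ravel(), sharp.ravel())[0, 1]


class TestHighPass:
    def test_constant_frame_zero(self):
        assert np.allclose(fp.high_pass(np.full((64, 64), 7.0)), 0.0)

    def test_offset_invariance(self):
        f = np.random.default_rng(6).random((64, 64))
        assert np.allclose(fp.high_pass(f), fp.high_pass(f + 5.0), atol=1e-10)

    def test_grating_above_cutoff_preserved(self):
        x = np.arange(128)
        grating = np.sin(2 * np.pi * x / 8.0)[None, :] * np.ones((128, 1))
        out = fp.high_pass(grating, background_sigma=50.0)
        # numerically evaluated transfer at the grating frequency
        amp = np.abs(out[64, 32:96]).max()
        assert amp == pytest.approx(1.0, rel=0.1)


class TestRegistration:
    def test_identity_on_identical_frames(self, textured_frame):
        trs, _ = fp.register_rigid(textured_frame[None], textured_frame)
        assert abs(trs[0].dy) < 0.1 and abs(trs[0].dx) < 0.1 and abs(trs[0].theta_deg) < 0.05
        mats, _ = fp.register_affine(textured_frame[None], textured_frame)
        assert np.allclose(mats[0], np.eye(3), atol=1e-3)
        fields, _ = fp.register_demons(textured_frame[None], textured_frame)
        assert np.abs(fields[0]).max() < 1e-3

    def test_translation_recovered(self, textured_frame):
        moved = warp(textured_frame, AffineTransform(translation=(-3.0, 2.0)),
                     order=3, mode="symmetric")
        trs, _ = fp.register_rigid(moved[None], textured_frame)
        assert abs(trs[0].dy - 2.0) <= 0.5
        assert abs(trs[0].dx - (-3.0)) <= 0.5

    def test_rotation_recovered(self, textured_frame):
        moved = rotate(textured_frame, -2.0, order=3, mode="symmetric")
        trs, _ = fp.register_rigid(moved[None], textured_frame)
        assert abs(trs[0].theta_deg - 2.0) <= 0.25

    def test_affine_scale_recovered(self, textured_frame):
        c = (np.array(textured_frame.shape) - 1) / 2.0
        t_to = np.array([[1, 0, c[1]], [0, 1, c[0]], [0, 0, 1.0]])
        t_from = np.array([[1, 0, -c[1]], [0, 1, -c[0]], [0, 0, 1.0]])
        m = t_to @ np.diag([1.01, 1.01, 1.0]) @ t_from
        moved = warp(textured_frame, AffineTransform(matrix=m), order=3, mode="symmetric")
        mats, _ = fp.register_affine(moved[None], textured_frame)
        recovered_scale = np.sqrt(np.linalg.det(mats[0][:2, :2]))
        assert recovered_scale == pytest.approx(1.0 / 1.01, abs=0.002)

    def test_demons_reduces_known_warp(self, textured_frame):
        rng = np.random.default_rng(8)
        u = gaussian_filter(rng.standard_normal((2, 128, 128)), (0, 16, 16), mode="reflect")
        u *= 3.0 / np.sqrt(u[0] ** 2 + u[1] ** 2).max()
        moving = fp._warp_with_field(textured_frame, u)
        fields, _ = fp.register_demons(moving[None], textured_frame)
        v = fields[0]
        resid = np.stack([v[0] + fp._warp_with_field(u[0], v),
                          v[1] + fp._warp_with_field(u[1], v)])
        epe0 = np.sqrt(u[0] ** 2 + u[1] ** 2)[8:-8, 8:-8].mean()
        epe1 = np.sqrt(resid[0] ** 2 + resid[1] ** 2)[8:-8, 8:-8].mean()
        assert epe1 <= 0.2 * epe0

    def test_demons_field_smooth(self, textured_frame):
        rng = np.random.default_rng(9)
        u = gaussian_filter(rng.standard_normal((2, 128, 128)), (0, 20, 20), mode="reflect")
        u *= 2.0 / np.sqrt(u[0] ** 2 + u[1] ** 2).max()
        moving = fp._warp_with_field(textured_frame, u)
        fields, _ = fp.register_demons(moving[None], textured_frame, sigma_reg=2.0)
        gy = np.gradient(fields[0][0])
        gx = np.gradient(fields[0][1])
        gmax = max(np.abs(gy[0]).max(), np.abs(gy[1]).max(), np.abs(gx[0]).max(), np.abs(gx[1]).max())
        assert gmax < 1.0  # bounded spatial gradient under sigma_reg=2


class TestNormalization:
    def test_crop_identity_and_arithmetic(self):
        f = np.random.default_rng(10).random((3, 100, 100))
        assert fp.crop_center(f, 1.0).shape == (3, 100, 100)
        cropped = fp.crop_center(f, 0.5)
        assert cropped.shape == (3, 50, 50)
        assert np.array_equal(cropped, f[:, 25:75, 25:75])

    def test_rescale_two_valued_endpoints(self):
        v = np.zeros(10000)
        v[:100] = 100.0
        out = fp.rescale_percentiles(v.reshape(100, 100), 1, 99)
        assert set(np.unique(out)) <= {0.0, 1.0}

    def test_rescale_affine_invariance(self):
        v = np.random.default_rng(11).random((4, 32, 32))
        a = fp.rescale_percentiles(v)
        b = fp.rescale_percentiles(3.0 * v + 2.0)
        assert np.allclose(a, b, atol=1e-12)

    def test_rescale_clips_two_percent(self):
        v = np.random.default_rng(12).random((100, 100, 10))
        out = fp.rescale_percentiles(v, 1, 99)
        clipped = np.mean((out == 0.0) | (out == 1.0))
        assert clipped == pytest.approx(0.02, abs=0.005)

    def test_rescale_degenerate_errors(self):
        with pytest.raises(ValueError):
            fp.rescale_percentiles(np.full((4, 4), 3.0))

    def test_mean_trace_constant(self):
        tr = fp.mean_intensity_trace(np.full((5, 8, 8), 0.4), 30.0)
        assert np.allclose(tr.mean_norm_intensity, 0.4)
        assert np.allclose(tr.time_h, np.arange(5) * 0.5)


class TestFullPipeline:
    def test_deterministic_and_scale_invariant(self, small_timelapse):
        movie, _ = small_timelapse
        data = movie.data[:3, :, ::2, ::2]  # trim for speed
        tr1, _, _, _ = fp.run_focus_pipeline(data, do_demons=False)
        tr2, _, _, _ = fp.run_focus_pipeline(data, do_demons=False)
        tr3, _, _, _ = fp.run_focus_pipeline(2.0 * data, do_demons=False)
        assert np.array_equal(tr1.mean_norm_intensity, tr2.mean_norm_intensity)
        assert np.allclose(tr1.mean_norm_intensity, tr3.mean_norm_intensity, atol=1e-9)
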