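"""Forward imaging model: patterned excitation, frame simulation, datasets."""

import json

import numpy as np
import pytest

import deeptfm as d
from conftest import delta_spsf


def brute_force_conv3d_at_plane(vol, kernel, plane):
    """Direct spatial-domain 3-D convolution, evaluated at one z-plane."""
    nz, ky, kx = kernel.shape
    cz, cy, cx = (nz - 1) // 2, (ky - 1) // 2, (kx - 1) // 2
    out = np.zeros(vol.shape[1:])
    for zz in range(vol.shape[0]):
        j = cz + plane - zz
        if not 0 <= j < nz:
            continue
        ks = kernel[j]
        for oy in range(out.shape[0]):
            for ox in range(out.shape[1]):
                acc = 0.0
                for yy in range(ky):
                    for xx in range(kx):
                        iy, ix = oy - (yy - cy), ox - (xx - cx)
                        if 0 <= iy < vol.shape[1] and 0 <= ix < vol.shape[2]:
                            acc += vol[zz, iy, ix] * ks[yy, xx]
                out[oy, ox] += acc
    return out


class TestPatternedExcitation:
    def test_all_zeros_pattern_gives_zero_field(self, ex_psf):
        field = d.patterned_excitation(ex_psf, np.zeros((16, 16)))
        assert np.all(field == 0)

    def test_all_ones_pattern_gives_z_marginal(self, ex_psf):
        # away from the boundary each plane is the z-marginal of the PSF
        field = d.patterned_excitation(ex_psf, np.ones((32, 32)))
        marginal = ex_psf.amplitude.sum(axis=(1, 2))
        np.testing.assert_allclose(field[:, 16, 16], marginal, rtol=1e-6, atol=1e-12)

    def test_single_pixel_pattern_replicates_psf(self, ex_psf):
        pattern = np.zeros((31, 31))
        pattern[15, 15] = 1.0
        field = d.patterned_excitation(ex_psf, pattern)
        np.testing.assert_allclose(
            field[:, 15 - 7:15 + 8, 15 - 7:15 + 8], ex_psf.amplitude, atol=1e-10
        )

    def test_shape_mismatch_rejected(self, ex_psf, bead_volume):
        with pytest.raises(ValueError):
            d.simulate_deep_frame(
                bead_volume, np.ones((8, 8)), ex_psf, ex_psf, None
            )


class TestFrameSimulation:
    def test_pstpm_reduction_matches_brute_force(self):
        # the simulated point-scanning ground truth is exactly the 3-D
        # convolution of the excitation PSF with the object at the focus
        rng = np.random.default_rng(0)
        vol = d.ObjectVolume(rng.random((8, 8, 8)).astype(np.float32))
        ex = d.make_gaussian_psf(1.0, 1.036, 1.33, (9, 7, 7), (1, 1, 1), "excitation")
        got = d.pstpm_image(vol, ex, focal_plane=3)
        want = brute_force_conv3d_at_plane(vol.intensity.astype(float), ex.amplitude, 3)
        assert np.abs(got - want).max() <= 1e-6 * want.max()

    def test_delta_reduction_uniform_pattern(self, ex_psf):
        # delta sPSF + delta emPSF + uniform pattern: the frame is the
        # object's focal plane times the local excitation field
        rng = np.random.default_rng(1)
        vol = d.ObjectVolume(rng.random((9, 24, 24)).astype(np.float32))
        em_delta = d.PSFVolume(np.ones((1, 1, 1)))
        frame = d.simulate_deep_frame(vol, np.ones((24, 24)), ex_psf, em_delta,
                                      delta_spsf(9))
        excitation = d.patterned_excitation(ex_psf, np.ones((24, 24)))
        np.testing.assert_allclose(frame, excitation[4] * vol.intensity[4], rtol=1e-5)

    def test_linearity_in_the_object(self, ex_psf, em_psf, bead_volume):
        pattern = d.make_random_patterns(1, (48, 48), 0.5, 3).patterns[0].astype(float)
        f1 = d.simulate_deep_frame(bead_volume, pattern, ex_psf, em_psf, delta_spsf(9))
        scaled = d.ObjectVolume(bead_volume.intensity * 2.5)
        f2 = d.simulate_deep_frame(scaled, pattern, ex_psf, em_psf, delta_spsf(9))
        np.testing.assert_allclose(f2, 2.5 * f1, rtol=1e-5,
                                   atol=1e-9 * float(f1.max()))

    def test_zero_object_gives_zero_frame(self, ex_psf, em_psf):
        vol = d.ObjectVolume(np.zeros((9, 16, 16), np.float32))
        frame = d.simulate_deep_frame(vol, np.ones((16, 16)), ex_psf, em_psf, None)
        assert np.all(frame == 0)

    def test_unit_sum_spsf_conserves_flux(self, ex_psf, em_psf, bead_volume):
        # blur with a broad unit-sum kernel conserves total intensity up to
        # boundary truncation (< 1% for a padded object)
        pattern = np.ones((48, 48))
        f_delta = d.simulate_deep_frame(bead_volume, pattern, ex_psf, em_psf,
                                        delta_spsf(9))
        g = np.exp(-0.5 * ((np.arange(15) - 7) ** 2)[:, None]
                   - 0.5 * ((np.arange(15) - 7) ** 2)[None, :] / 4)
        g /= g.sum()
        blurred_stack = delta_spsf(9)
        blurred_stack.images = np.stack([g] * 9)
        f_blur = d.simulate_deep_frame(bead_volume, pattern, ex_psf, em_psf,
                                       blurred_stack)
        assert f_blur.sum() == pytest.approx(f_delta.sum(), rel=0.01)


class TestMeasurementStack:
    def test_default_pattern_count_is_32(self, ex_psf, em_psf):
        vol = d.ObjectVolume(np.ones((9, 16, 16), np.float32))
        pats = d.make_random_patterns(shape=(16, 16), seed=0)
        stack = d.simulate_measurement_stack(vol, pats, ex_psf, em_psf, None)
        assert stack.t_count == 32
        assert stack.measurements.shape == (32, 16, 16)

    def test_mean_over_random_patterns_is_half_uniform_frame(self, ex_psf, em_psf,
                                                             bead_volume):
        # E[H_t] = fill = 0.5 pointwise, so the mean noise-free frame
        # approaches half the uniform-illumination frame
        pats = d.make_random_patterns(64, (48, 48), 0.5, seed=7)
        stack = d.simulate_measurement_stack(bead_volume, pats, ex_psf, em_psf,
                                             delta_spsf(9))
        uniform = d.simulate_deep_frame(bead_volume, np.ones((48, 48)), ex_psf,
                                        em_psf, delta_spsf(9))
        mean_frame = stack.measurements.mean(axis=0)
        mask = uniform > uniform.max() * 0.1
        ratio = mean_frame[mask] / uniform[mask]
        assert abs(np.median(ratio) - 0.5) < 0.05

    def test_same_seed_reproduces_stack(self, ex_psf, em_psf, small_camera, small_lut):
        vol = d.ObjectVolume(np.ones((9, 16, 16), np.float32))
        pats = d.make_random_patterns(4, (16, 16), 0.5, seed=1)
        kwargs = dict(camera=small_camera, lut=small_lut, photons_per_unit=100.0, seed=5)
        a = d.simulate_measurement_stack(vol, pats, ex_psf, em_psf, None, **kwargs)
        b = d.simulate_measurement_stack(vol, pats, ex_psf, em_psf, None, **kwargs)
        np.testing.assert_array_equal(a.measurements, b.measurements)

    def test_ground_truth_is_nonnegative_and_matches_pstpm(self, ex_psf, em_psf,
                                                           bead_volume):
        pats = d.make_random_patterns(2, (48, 48), 0.5, seed=2)
        stack = d.simulate_measurement_stack(bead_volume, pats, ex_psf, em_psf, None)
        np.testing.assert_allclose(stack.ground_truth,
                                   d.pstpm_image(bead_volume, ex_psf))


class TestDatasetBuilder:
    @pytest.fixture(scope="class")
    def dataset(self, tmp_path_factory, ex_psf, em_psf, small_camera, small_lut):
        objs = [
            d.generate_beads_volume(
                d.BeadSpec(seed=i, n_small=2, n_large=1), (9, 32, 32)
            )
            for i in range(10)
        ]
        pats = d.make_random_patterns(4, (32, 32), 0.5, seed=0)
        out = tmp_path_factory.mktemp("ds")
        manifest = d.build_dataset(objs, out, pats, ex_psf, em_psf, delta_spsf(9),
                                   small_camera, small_lut, photons_per_unit=50.0,
                                   seed=3, split=(4, 1), depth_sls=4.0)
        return manifest

    def test_split_ratio_4_to_1(self, dataset):
        manifest = json.loads(dataset.read_text())
        assert manifest["n_train"] == 8 and manifest["n_val"] == 2

    def test_depth_tag_recorded(self, dataset):
        manifest = json.loads(dataset.read_text())
        assert manifest["depth_sls"] == 4.0
        from deeptfm import io
        data, attrs = io.read_h5_stack(dataset.parent / manifest["shards"][0]["file"])
        assert attrs["depth_sls"] == 4.0

    def test_loaded_arrays_have_expected_shapes(self, dataset):
        Xtr, Ytr = d.load_dataset(dataset, "train")
        Xva, Yva = d.load_dataset(dataset, "val")
        assert Xtr.shape == (8, 4, 32, 32) and Ytr.shape == (8, 1, 32, 32)
        assert Xva.shape == (2, 4, 32, 32)
        assert np.all(Ytr >= 0)

    def test_rebuild_reproduces_identical_shards(self, dataset, tmp_path, ex_psf,
                                                 em_psf, small_camera, small_lut):
        from deeptfm import io
        manifest = json.loads(dataset.read_text())
        objs = [
            d.generate_beads_volume(
                d.BeadSpec(seed=i, n_small=2, n_large=1), (9, 32, 32)
            )
            for i in range(10)
        ]
        pats = d.make_random_patterns(4, (32, 32), 0.5, seed=0)
        again = d.build_dataset(objs, tmp_path / "again", pats, ex_psf, em_psf,
                                delta_spsf(9), small_camera, small_lut,
                                photons_per_unit=50.0, seed=3, split=(4, 1),
                                depth_sls=4.0)
        a, _ = io.read_h5_stack(dataset.parent / manifest["shards"][0]["file"])
        b, _ = io.read_h5_stack(again.parent / manifest["shards"][0]["file"])
        np.testing.assert_array_equal(a["measurements"], b["measurements"])
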