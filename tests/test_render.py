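"""Fringe rendering, ground-truth encoding, co-registration."""

import numpy as np
import pytest
from scipy import ndimage

from sfdigan.optics import DomainError, diffuse_reflectance, factors_to_properties
from sfdigan.render import (CameraParams, encode_channel, illumination_gain,
                            render_cylinder_sfdi, render_flat_sfdi,
                            render_ground_truth, render_pair)
from sfdigan.scenes import Spheroid, add_spheroids, make_cylinder_scene, \
    make_flat_scene, scatter_polyps
from conftest import mat


class TestEncodeChannel:
    @pytest.mark.parametrize("value, expected", [(0.05, 13), (0.95, 242), (0.5, 128)])
    def test_known_levels(self, value, expected):
        assert encode_channel(value) == expected

    def test_out_of_range_rejected(self):
        for bad in (0.04, 0.96, -1.0):
            with pytest.raises(DomainError):
                encode_channel(bad)

    def test_half_up_rounding_vectorised(self):
        vals = np.linspace(0.05, 0.95, 91)
        out = encode_channel(vals)
        np.testing.assert_array_equal(out, np.floor(vals * 255 + 0.5).astype(np.uint8))


class TestFlatRender:
    def test_homogeneous_scene_is_pure_sinusoid(self, flat_scene, calib):
        img = render_flat_sfdi(flat_scene, calib, resolution=128)
        inten = img.intensity
        # constant along the fringe direction
        assert np.ptp(inten, axis=0).max() < 1e-12
        # matches the forward model exactly
        p = factors_to_properties(flat_scene.regions[0].factors, calib)
        g = illumination_gain(calib)
        x_mm = (np.arange(128) + 0.5) * flat_scene.fov_mm / 128
        expected = g * (0.5 * diffuse_reflectance(p.mu_a, p.mu_s_prime, 0.0)
                        + 0.5 * diffuse_reflectance(p.mu_a, p.mu_s_prime, calib.fx)
                        * np.cos(2 * np.pi * calib.fx * x_mm))
        np.testing.assert_allclose(inten[0], expected, atol=1e-12)

    def test_near_zero_frequency_is_constant_at_dc_level(self, flat_scene, calib):
        import copy
        scene = copy.deepcopy(flat_scene)
        scene.illumination["fx"] = 1e-7
        img = render_flat_sfdi(scene, calib, resolution=64)
        p = factors_to_properties(scene.regions[0].factors, calib)
        level = illumination_gain(calib) * diffuse_reflectance(p.mu_a, p.mu_s_prime, 0.0)
        assert np.ptp(img.intensity) < 1e-6
        assert img.intensity[0, 0] == pytest.approx(level, rel=1e-5)

    def test_two_material_amplitude_ratio_matches_forward_model(self, calib):
        scene = make_flat_scene(2, "curved", [mat(0.35), mat(0.8)],
                                boundary_params=[{"chord_pos": 0.5, "sagitta": 0.0}])
        img = render_flat_sfdi(scene, calib, resolution=256)
        amp = {}
        for name, sl in (("A", np.s_[:, 10:118]), ("B", np.s_[:, 138:246])):
            region = img.intensity[sl]
            amp[name] = (region.max() - region.min()) / 2.0
        pa = factors_to_properties(mat(0.35), calib)
        pb = factors_to_properties(mat(0.8), calib)
        expected = (diffuse_reflectance(pa.mu_a, pa.mu_s_prime, calib.fx)
                    / diffuse_reflectance(pb.mu_a, pb.mu_s_prime, calib.fx))
        assert amp["A"] / amp["B"] == pytest.approx(expected, rel=0.02)

    def test_intensity_non_increasing_in_mu_a(self, calib):
        # same final factor, increasing absorption strength
        imgs = []
        for absorption in (0.8, 0.4, 0.0):  # mu_a grows as transparency falls
            scene = make_flat_scene(1, "none", [mat(0.5, absorption, 1.0)])
            imgs.append(render_flat_sfdi(scene, calib, resolution=32).intensity)
        assert np.all(imgs[0] >= imgs[1]) and np.all(imgs[1] >= imgs[2])

    def test_wrong_geometry_dispatch(self, cylinder_scene, calib):
        with pytest.raises(DomainError):
            render_flat_sfdi(cylinder_scene, calib, resolution=32)

    def test_noise_stage_is_seeded(self, flat_scene, calib):
        rng_a = np.random.default_rng(4)
        rng_b = np.random.default_rng(4)
        a = render_flat_sfdi(flat_scene, calib, 64, noise={"photons": 1e4}, rng=rng_a)
        b = render_flat_sfdi(flat_scene, calib, 64, noise={"photons": 1e4}, rng=rng_b)
        clean = render_flat_sfdi(flat_scene, calib, 64)
        np.testing.assert_array_equal(a.intensity, b.intensity)
        assert np.abs(a.intensity - clean.intensity).max() > 0


class TestCylinderRender:
    def test_intensity_falls_towards_lumen_centre(self, calib):
        scene = make_cylinder_scene(10.0, 80.0, mat(0.6))
        img, aux = render_cylinder_sfdi(scene, calib, 128, return_aux=True)
        yy, xx = np.mgrid[0:128, 0:128]
        r_img = np.hypot(yy - 63.5, xx - 63.5)
        # mean intensity per annulus decreases towards the centre (deeper wall)
        means = []
        for lo in range(16, 60, 8):
            ring = (r_img >= lo) & (r_img < lo + 8) & aux["hit"]
            means.append(img.intensity[ring].mean())
        assert np.all(np.diff(means) > 0)  # outer rings brighter
        # the very centre is background (ray exits beyond the far end)
        assert img.intensity[60:68, 60:68].max() == 0.0

    def test_local_spatial_frequency_varies_over_wall(self, calib):
        scene = make_cylinder_scene(10.0, 80.0, mat(0.6))
        _, aux = render_cylinder_sfdi(scene, calib, 128, return_aux=True)
        interior = ndimage.binary_erosion(aux["hit"], iterations=3)
        fx_local = aux["fx_local"][interior]
        assert np.nanmax(fx_local) / max(np.nanmin(fx_local), 1e-9) > 1.5

    def test_polyp_appears_as_connected_component_at_its_angle(self, calib):
        theta0 = 2.0
        polyp = Spheroid([10.0 * theta0, 40.0, 0.0], [4.0, 4.0, 2.0], mat(0.1))
        scene = make_cylinder_scene(10.0, 80.0, mat(0.8), [polyp])
        truth = render_ground_truth(scene, calib, 128)
        wall_r = truth.pixels[..., 0]
        # the wall value is the majority non-background level; polyp pixels differ
        vals, counts = np.unique(wall_r[wall_r > 0], return_counts=True)
        wall_val = vals[np.argmax(counts)]
        labels, n = ndimage.label((wall_r > 0) & (wall_r != wall_val))
        # exactly one non-wall component; centroid angle matches theta0
        sizes = ndimage.sum(np.ones_like(labels), labels, range(1, n + 1))
        main = 1 + int(np.argmax(sizes))
        cy, cx = ndimage.center_of_mass(labels == main)
        ang = np.arctan2(cy - 63.5, cx - 63.5) % (2 * np.pi)
        assert ang == pytest.approx(theta0, abs=0.25)

    def test_render_deterministic_given_seed(self, cylinder_scene, calib):
        a = render_cylinder_sfdi(cylinder_scene, calib, 64)
        b = render_cylinder_sfdi(cylinder_scene, calib, 64)
        np.testing.assert_array_equal(a.intensity, b.intensity)


class TestGroundTruth:
    def test_homogeneous_truth_is_constant(self, flat_scene, calib):
        truth = render_ground_truth(flat_scene, calib, 64)
        assert np.ptp(truth.pixels[..., 0]) == 0
        assert np.ptp(truth.pixels[..., 1]) == 0

    def test_blue_channel_identically_zero(self, cylinder_scene, calib):
        for scene in (cylinder_scene,):
            truth = render_ground_truth(scene, calib, 64)
            assert np.all(truth.pixels[..., 2] == 0)

    def test_channel_values_in_encoded_range(self, two_material_scene, calib):
        truth = render_ground_truth(two_material_scene, calib, 64)
        for ch in (0, 1):
            vals = truth.pixels[..., ch]
            assert vals.min() >= 13 and vals.max() <= 242

    def test_tumour_mask_identical_between_input_and_truth(self, flat_scene, calib):
        fov = flat_scene.fov_mm
        scene = add_spheroids(flat_scene, [Spheroid([0.4 * fov, 0.6 * fov, 0],
                                                    [6, 4, 3], mat(0.15))])
        img, truth = render_pair(scene, calib, 128)
        base_img, base_truth = render_pair(flat_scene, calib, 128)
        mask_input = np.any(img.intensity != base_img.intensity, axis=-1) \
            if img.intensity.ndim == 3 else img.intensity != base_img.intensity
        mask_truth = np.any(truth.pixels != base_truth.pixels, axis=-1)
        np.testing.assert_array_equal(mask_input, mask_truth)

    def test_quantised_pair_is_8bit(self, two_material_scene, calib):
        img, truth = render_pair(two_material_scene, calib, 64)
        assert img.quantise().dtype == np.uint8
        assert truth.pixels.dtype == np.uint8
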