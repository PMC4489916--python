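"""Linearization, grey-card standardization and cheek-patch geometry."""

import numpy as np
import pytest

from cyclechrome import synthetic_data
from cyclechrome.image_pipeline import (
    CalibrationError,
    GeometryError,
    PatchSpec,
    StandardizationError,
    cheek_patches,
    fit_linearization,
    linearize_image,
    mean_patch_rgb,
    read_tiff,
    standardize_to_grey,
    write_tiff,
)

REFLECTANCES = np.array([0.99, 0.80, 0.60, 0.40, 0.20, 0.10, 0.05, 0.02])


class TestFitLinearization:
    def test_linear_responses_fit_exactly(self):
        resp = np.column_stack([REFLECTANCES * k for k in (1000, 2000, 500)])
        model = fit_linearization(resp, REFLECTANCES)
        assert np.all(model.r2 > 1.0 - 1e-12)
        lin = model.invert(resp[:, 0], 0)
        assert np.allclose(lin, REFLECTANCES, atol=1e-8)

    def test_gamma_responses_recovered(self):
        resp = np.column_stack([REFLECTANCES ** (1 / 2.2) * 65535] * 3)
        model = fit_linearization(resp, REFLECTANCES)
        assert np.all(model.r2 > 0.999)
        lin = model.invert(resp[:, 1], 1)
        assert np.allclose(lin, REFLECTANCES, atol=1e-6)

    def test_constant_responses_rejected(self):
        resp = np.full((8, 3), 500.0)
        with pytest.raises(CalibrationError):
            fit_linearization(resp, REFLECTANCES)

    def test_non_monotone_responses_rejected(self):
        resp = np.column_stack([REFLECTANCES * 1000] * 3)
        resp[2, 0], resp[3, 0] = resp[3, 0], resp[2, 0]
        with pytest.raises(CalibrationError):
            fit_linearization(resp, REFLECTANCES)

    def test_duplicate_reflectances_rejected(self):
        refl = REFLECTANCES.copy()
        refl[1] = refl[0]
        resp = np.column_stack([np.linspace(10, 1000, 8)] * 3)
        with pytest.raises(CalibrationError):
            fit_linearization(resp, refl)

    def test_too_few_standards_rejected(self):
        with pytest.raises(CalibrationError):
            fit_linearization(np.ones((3, 3)) * [[1], [2], [3]],
                              np.array([0.1, 0.5, 0.9]))


class TestLinearizeImage:
    def test_identity_model_leaves_image_unchanged(self):
        resp = np.column_stack([REFLECTANCES] * 3)  # response == reflectance
        model = fit_linearization(resp, REFLECTANCES)
        img = np.random.default_rng(0).uniform(0.02, 0.99, (8, 8, 3))
        out = linearize_image(img, model)
        assert np.allclose(out, img, atol=1e-7)

    def test_gamma_gradient_becomes_linear(self):
        resp = np.column_stack([REFLECTANCES ** (1 / 2.2) * 65535] * 3)
        model = fit_linearization(resp, REFLECTANCES)
        grad = np.linspace(0.05, 0.95, 32)
        img = np.broadcast_to(
            (grad ** (1 / 2.2) * 65535)[None, :, None], (4, 32, 3)
        )
        out = linearize_image(img, model)
        assert np.allclose(out[0, :, 0], grad, atol=1e-6)

    def test_fifty_percent_standard_maps_to_half(self):
        resp = np.column_stack([REFLECTANCES ** (1 / 2.2) * 65535] * 3)
        model = fit_linearization(resp, REFLECTANCES)
        img = np.full((5, 5, 3), 0.5 ** (1 / 2.2) * 65535)
        out = linearize_image(img, model)
        assert np.allclose(out, 0.5, atol=1e-6)


class TestStandardizeToGrey:
    def test_scale_from_grey_mean(self):
        img = np.full((10, 10, 3), 0.36)
        out = standardize_to_grey(img, PatchSpec(0, 0, 4, 4))
        assert np.allclose(out, 0.18)

    def test_already_standard_is_unchanged(self):
        img = np.full((10, 10, 3), 0.18)
        out = standardize_to_grey(img, PatchSpec(2, 2, 4, 4))
        assert np.allclose(out, img)

    def test_per_channel_scales(self):
        img = np.ones((6, 6, 3)) * np.array([0.36, 0.18, 0.09])
        out = standardize_to_grey(img, PatchSpec(0, 0, 6, 6))
        assert np.allclose(out, 0.18)
        # scales applied to the whole image, per channel
        assert np.allclose(out / img, [0.5, 1.0, 2.0])

    def test_grey_region_exact_after_call(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0.05, 0.9, (20, 20, 3))
        region = PatchSpec(3, 4, 6, 5)
        out = standardize_to_grey(img, region)
        means = out[region.slices].reshape(-1, 3).mean(axis=0)
        assert np.allclose(means, 0.18, atol=1e-14)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0.05, 0.9, (20, 20, 3))
        region = PatchSpec(0, 0, 5, 5)
        once = standardize_to_grey(img, region)
        twice = standardize_to_grey(once, region)
        assert np.allclose(once, twice, atol=1e-14)

    def test_zero_grey_region_rejected(self):
        img = np.zeros((10, 10, 3))
        with pytest.raises(StandardizationError):
            standardize_to_grey(img, PatchSpec(0, 0, 4, 4))


class TestCheekPatches:
    def test_worked_geometry(self):
        img = np.zeros((300, 300, 3))
        left, right = cheek_patches((100, 200), (200, 200), img)
        assert (left.x0, left.x0 + left.width) == (70, 100)
        assert (right.x0, right.x0 + right.width) == (200, 230)
        for p in (left, right):
            assert (p.y0, p.y0 + p.height) == (230, 256)
            assert (p.width, p.height) == (30, 26)

    def test_coincident_pupils_rejected(self):
        img = np.zeros((100, 100, 3))
        with pytest.raises(GeometryError):
            cheek_patches((50, 50), (50, 50), img)

    def test_patch_leaving_image_names_side(self):
        img = np.zeros((260, 140, 3))
        with pytest.raises(GeometryError, match="left"):
            cheek_patches((20, 100), (120, 100), img)

    def test_mirror_symmetry(self):
        img = np.zeros((300, 301, 3))
        w = img.shape[1]
        pl, pr = (104, 140), (186, 140)
        left, right = cheek_patches(pl, pr, img)
        # reflect pupils about the vertical centre line and swap them
        rl = (w - 1 - pr[0], pr[1])
        rr = (w - 1 - pl[0], pl[1])
        left2, right2 = cheek_patches(rl, rr, img)
        # dimensions are preserved and both inner edges stay on their pupils
        assert (left2.width, left2.height) == (left.width, left.height)
        assert left.x0 + left.width == pl[0]  # inner edge on left pupil line
        assert right.x0 == pr[0]  # inner edge on right pupil line
        assert left2.x0 + left2.width == rl[0]
        assert right2.x0 == rr[0]
        # vertical placement is unchanged by the reflection
        assert left2.y0 == left.y0 and right2.y0 == right.y0

    def test_uniform_skin_gives_skin_mean(self):
        img = np.full((300, 300, 3), 0.42)
        left, right = cheek_patches((100, 100), (200, 100), img)
        assert np.allclose(mean_patch_rgb(img, left, right), 0.42)


class TestMeanPatchRgb:
    def test_equal_patches_average(self):
        img = np.zeros((10, 20, 3))
        img[:, :10] = 0.2
        img[:, 10:] = 0.4
        rgb = mean_patch_rgb(img, PatchSpec(0, 0, 10, 10),
                             PatchSpec(10, 0, 10, 10))
        assert np.allclose(rgb, 0.3)

    def test_mean_of_patch_means_not_pixel_pooled(self):
        img = np.zeros((10, 30, 3))
        img[:, :10] = 0.2  # 100 px patch
        img[:, 10:] = 0.4
        rgb = mean_patch_rgb(img, PatchSpec(0, 0, 10, 10),
                             PatchSpec(10, 0, 5, 10))  # 50 px patch
        assert np.allclose(rgb, 0.3)  # not (100*0.2 + 50*0.4)/150


class TestEndToEndExtraction:
    def test_noise_free_synthetic_face_recovers_skin_rgb(self, tmp_path):
        camera = synthetic_data.gen_camera(seed=3)
        skin = np.array([0.45, 0.30, 0.25])
        img, sidecar = synthetic_data.gen_face_image(
            skin, ((100, 90), (160, 90)), PatchSpec(5, 5, 30, 30),
            size=(256, 220), noise_sd=0.0, seed=3, camera=camera,
        )
        path = tmp_path / "face.tif"
        write_tiff(path, img)
        raw = read_tiff(path)
        assert raw.dtype == np.uint16

        resp, refl = synthetic_data.simulate_grey_standards(camera)
        model = fit_linearization(resp, refl)
        lin = linearize_image(raw, model)
        grey = PatchSpec(sidecar["grey_x0"], sidecar["grey_y0"],
                         sidecar["grey_w"], sidecar["grey_h"])
        std = standardize_to_grey(lin, grey)
        left, right = cheek_patches(
            (sidecar["pupil_lx"], sidecar["pupil_ly"]),
            (sidecar["pupil_rx"], sidecar["pupil_ry"]), std,
        )
        rgb = mean_patch_rgb(std, left, right)
        assert np.allclose(rgb, skin, atol=2e-3)

    def test_patch_mean_noise_shrinks_with_area(self):
        # Monte-Carlo: SD of patch means scales as 1/sqrt(patch area)
        camera = synthetic_data.gen_camera(seed=4)
        skin = np.array([0.4, 0.35, 0.3])
        errs = {10: [], 40: []}
        for rep in range(30):
            img, _ = synthetic_data.gen_face_image(
                skin, ((60, 50), (140, 50)), PatchSpec(2, 2, 20, 20),
                size=(200, 160), noise_sd=0.02, seed=100 + rep, camera=camera,
            )
            lin = (img.astype(float) / camera.full_scale) ** (1 / camera.exponent)
            for side in errs:
                patch = lin[100:100 + side, 60:60 + side, 0]
                errs[side].append(patch.mean() - skin[0])
        sd_small = np.std(errs[10])
        sd_big = np.std(errs[40])
        # areas differ 16x -> SDs should differ ~4x
        assert sd_small / sd_big == pytest.approx(4.0, rel=0.5)
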