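"""Renderer and ground-truth geometry tests."""

import numpy as np
import pytest

from fundusqc import (
    ValidationError,
    RangeError,
    build_projection,
    ground_truth_cells,
    render_scene,
    stripe_levels_from_samples,
)
from fundusqc.synthetic_eye import DIRECTIONS

from conftest import make_scene


def projections_for(f, k3, t, max_angle=85.0):
    return {d: build_projection(f, k3, [(0.0, t)], max_angle, direction=d)
            for d in DIRECTIONS}


class TestBuildProjection:
    def test_linear_mapping_is_identity_like(self):
        p = build_projection(10.0, 0.0, [(0.0, 10.0)], 80.0)
        assert p.radial(1.0) == pytest.approx(10.0)
        assert p.radial(80.0) == pytest.approx(800.0)

    def test_cubic_closed_form(self):
        p = build_projection(10.0, 0.001, [(0.0, 10.0)], 90.0)
        assert p.radial(80.0) == pytest.approx(800.0 + 0.001 * 512000.0)

    def test_non_monotone_mapping_rejected_with_theta(self):
        with pytest.raises(ValidationError, match=r"5\.7"):
            build_projection(1.0, -0.01, [(0.0, 5.0)], 80.0)

    def test_empty_transverse_samples_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            build_projection(10.0, 0.0, [], 80.0)

    @pytest.mark.parametrize("f,max_angle", [(0.0, 80.0), (5.0, 0.0),
                                             (5.0, 111.0)])
    def test_invalid_parameters_rejected(self, f, max_angle):
        with pytest.raises(ValidationError):
            build_projection(f, 0.0, [(0.0, 5.0)], max_angle)

    def test_radial_inverse_roundtrip(self):
        p = build_projection(7.0, 2e-4, [(0.0, 7.0)], 100.0)
        theta = np.linspace(0.0, 100.0, 23)
        assert p.radial_inverse(p.radial(theta)) == pytest.approx(
            theta, abs=1e-3)


class TestGroundTruthCells:
    def test_uniform_scale_gives_square_cells(self):
        truth = ground_truth_cells(projections_for(10.0, 0.0, 10.0), [40.0])
        for d in DIRECTIONS:
            cell = truth.cells[(d, 40.0)]
            assert cell["h"] == pytest.approx(50.0)
            assert cell["w"] == pytest.approx(50.0)

    def test_cubic_radial_extent_at_80(self):
        # r(82.5) - r(77.5) for r = 10*t + 0.001*t^3, frozen from the
        # closed-form evaluation
        truth = ground_truth_cells(projections_for(10.0, 0.001, 10.0, 90.0),
                                   [80.0])
        assert truth.cells[("superior", 80.0)]["h"] == pytest.approx(146.03125)
        assert truth.cells[("left", 80.0)]["w"] == pytest.approx(146.03125)

    def test_symmetric_center_cell(self):
        truth = ground_truth_cells(projections_for(10.0, 0.0, 10.0), [0.0])
        h0, w0 = truth.center
        assert h0 == pytest.approx(50.0)
        assert w0 == pytest.approx(50.0)

    def test_out_of_range_eccentricity_rejected(self):
        projs = projections_for(10.0, 0.0, 10.0, max_angle=45.0)
        with pytest.raises(RangeError):
            ground_truth_cells(projs, [45.0])

    @pytest.mark.parametrize("c", [0.5, 3.0])
    def test_scaling_all_coefficients_scales_extents(self, c):
        base = ground_truth_cells(projections_for(6.0, 1e-4, 7.0), [0.0, 40.0])
        scaled = ground_truth_cells(
            projections_for(6.0 * c, 1e-4 * c, 7.0 * c), [0.0, 40.0])
        for key, cell in base.cells.items():
            assert scaled.cells[key]["h"] == pytest.approx(c * cell["h"])
            assert scaled.cells[key]["w"] == pytest.approx(c * cell["w"])


class TestRenderScene:
    def test_noiseless_tape_pixels_match_configured_levels(self,
                                                           isotropic_scene,
                                                           isotropic_render):
        img, truth = isotropic_render
        r, c = isotropic_scene.center
        r, c = int(r), int(c)
        # probe interior pixels of known cells along the inferior meridian:
        # cell j is centered at 30*j px at 6 px/deg; odd cells are black
        assert img[r + 30, c] == 40    # cell 1, black
        assert img[r + 60, c] == 220   # cell 2, white
        assert img[r, c] == 220        # center cell, white
        assert img[5, 5] == 10         # background

    def test_render_is_deterministic(self):
        spec = make_scene(noise_sd=4.0, blur_sigma=0.5, jpeg_quality=90,
                          seed=7, max_angle=30.0)
        img1, _ = render_scene(spec)
        img2, _ = render_scene(spec)
        assert img1.tobytes() == img2.tobytes()

    def test_seed_changes_noise(self):
        a, _ = render_scene(make_scene(noise_sd=4.0, seed=1, max_angle=30.0))
        b, _ = render_scene(make_scene(noise_sd=4.0, seed=2, max_angle=30.0))
        assert a.tobytes() != b.tobytes()

    def test_noisy_cell_mean_near_configured_level(self):
        spec = make_scene(noise_sd=5.0, seed=3, max_angle=30.0)
        img, _ = render_scene(spec)
        r, c = (int(v) for v in spec.center)
        # interior of the white cell at z=10 (even index), inferior meridian
        patch = img[r + 50:r + 70, c - 10:c + 11].astype(float)
        n = patch.size
        assert abs(patch.mean() - 220.0) < 3.0 * 5.0 / np.sqrt(n) + 0.5

    def test_pixel_counting_matches_ground_truth(self, isotropic_scene,
                                                 isotropic_render):
        # direct transition counting along the meridian, independent of the
        # measurement module
        img, truth = isotropic_render
        r, c = (int(v) for v in isotropic_scene.center)
        column = img[r:, c].astype(float)
        mid = 130.0  # halfway between the 40/220 cell fills
        a = column - mid
        strict = np.where(a[:-1] * a[1:] < 0)[0]
        exact = np.where(a == 0)[0]
        crossings = np.sort(np.concatenate([
            strict + a[strict] / (a[strict] - a[strict + 1]),
            exact.astype(float),
        ]))
        widths = np.diff(crossings)
        expected = truth.cells[("inferior", 40.0)]["h"]
        assert np.abs(widths[1:-1] - expected).max() < 1.0

    def test_truth_records_stripe_levels_and_fov(self, isotropic_render):
        _, truth = isotropic_render
        assert truth.stripes[("inferior", 40.0)] == (40.0, 220.0)
        assert truth.fov["superior"] == 85.0

    def test_jpeg_quality_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            render_scene(make_scene(jpeg_quality=0, max_angle=30.0))

    def test_tape_exceeding_frame_rejected(self):
        spec = make_scene(max_angle=30.0)
        bad = spec.replace(image_shape=(101, 101), center=(50.0, 50.0))
        with pytest.raises(ValidationError, match="does not fit"):
            render_scene(bad)

    def test_truth_json_roundtrip(self, isotropic_render, tmp_path):
        from fundusqc import save_scene
        from fundusqc.synthetic_eye import load_truth
        img, truth = isotropic_render
        save_scene(img, truth, tmp_path / "scene.png")
        back = load_truth(tmp_path / "scene.truth.json")
        assert back.fov == truth.fov
        key = ("inferior", 40.0)
        assert back.cells[key]["h"] == pytest.approx(truth.cells[key]["h"])


class TestStripeLevels:
    def test_interpolation_at_cell_centers(self):
        levels = stripe_levels_from_samples(
            {0.0: (40.0, 220.0), 80.0: (80.0, 180.0)}, max_angle=80.0)
        assert levels[0] == pytest.approx([40.0, 220.0])
        assert levels[16] == pytest.approx([80.0, 180.0])
        assert levels[8] == pytest.approx([60.0, 200.0])  # midpoint at 40 deg

    def test_covers_partial_outer_cell(self):
        levels = stripe_levels_from_samples({0.0: (40.0, 220.0)},
                                            max_angle=88.2)
        assert levels.shape[0] >= 19  # cell index floor((88.2+2.5)/5) = 18
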