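"""Measurement pipeline tests: axis location, edges, cells, stripes, FOV."""

import numpy as np
import pytest

from fundusqc import (
    DetectionError,
    MeasurementError,
    RangeError,
    locate_axes,
    max_field_of_view,
    measure_cell,
    measure_image,
    render_scene,
    sample_stripes,
    trace_cell_edges,
)
from fundusqc.measurement import AxisFrame
from fundusqc.synthetic_eye import DIRECTIONS, stripe_levels_from_samples

from conftest import make_scene


class TestLocateAxes:
    def test_recovers_known_center(self, device_renders):
        for name, (spec, img, _) in device_renders.items():
            frame = locate_axes(img)
            assert abs(frame.center[0] - spec.center[0]) < 2.0
            assert abs(frame.center[1] - spec.center[1]) < 2.0

    def test_uniform_image_raises(self):
        with pytest.raises(DetectionError):
            locate_axes(np.full((200, 200), 128, dtype=np.uint8))

    def test_hint_consistent_with_free_search(self, device_renders):
        spec, img, _ = device_renders["200Tx"]
        free = locate_axes(img)
        hinted = locate_axes(img, center_hint=spec.center)
        assert abs(free.center[0] - hinted.center[0]) < 0.5
        assert abs(free.center[1] - hinted.center[1]) < 0.5

    def test_center_off_image_rejected(self, device_renders):
        from fundusqc import ValidationError
        _, img, _ = device_renders["200Tx"]
        with pytest.raises(ValidationError):
            locate_axes(img, center_hint=(-500.0, -500.0))


class TestTraceCellEdges:
    def test_linear_cell_edges_50px_apart(self):
        # 10 px/deg: a 5-degree cell spans 50 px
        spec = make_scene(f=10.0, k3=0.0, transverse=10.0, max_angle=45.0)
        img, _ = render_scene(spec)
        frame = AxisFrame(center=spec.center)
        (e_in, e_out), (t_lo, t_hi) = trace_cell_edges(img, frame,
                                                       "inferior", 40.0)
        assert e_out - e_in == pytest.approx(50.0, abs=0.5)
        assert t_hi - t_lo == pytest.approx(50.0, abs=0.5)
        assert e_in == pytest.approx(375.0, abs=0.5)

    def test_cell_beyond_rendered_range_raises(self, isotropic_scene,
                                               isotropic_render):
        img, _ = isotropic_render
        frame = AxisFrame(center=isotropic_scene.center)
        with pytest.raises(MeasurementError):
            trace_cell_edges(img, frame, "inferior", 100.0)

    def test_blur_shifts_edges_less_than_half_pixel(self):
        clean_spec = make_scene(max_angle=50.0)
        blurred_spec = make_scene(max_angle=50.0, blur_sigma=1.0)
        frame = AxisFrame(center=clean_spec.center)
        clean, _ = render_scene(clean_spec)
        blurred, _ = render_scene(blurred_spec)
        (a0, a1), _ = trace_cell_edges(clean, frame, "superior", 40.0)
        (b0, b1), _ = trace_cell_edges(blurred, frame, "superior", 40.0)
        assert abs(a0 - b0) < 0.5
        assert abs(a1 - b1) < 0.5


class TestMeasureCell:
    def test_isotropic_cells_are_square(self, isotropic_scene,
                                        isotropic_render):
        img, _ = isotropic_render
        frame = AxisFrame(center=isotropic_scene.center)
        for d in DIRECTIONS:
            cell = measure_cell(img, frame, d, 40.0)
            assert cell.h == pytest.approx(cell.w, abs=1.0)

    def test_anisotropic_transverse_scale_recovered(self):
        # radial 6 px/deg, transverse 4.8 px/deg on the vertical tape
        per_dir = {d: (6.0, 0.0, 4.8) for d in ("superior", "inferior")}
        spec = make_scene(per_direction=per_dir, max_angle=50.0)
        img, truth = render_scene(spec)
        frame = AxisFrame(center=spec.center)
        cell = measure_cell(img, frame, "superior", 40.0)
        assert cell.h == pytest.approx(30.0, abs=1.0)  # radial 6 px/deg
        assert cell.w == pytest.approx(24.0, abs=1.0)  # transverse 4.8
        t = truth.cells[("superior", 40.0)]
        assert cell.h == pytest.approx(t["h"], abs=1.0)
        assert cell.w == pytest.approx(t["w"], abs=1.0)

    def test_center_cell_symmetric(self, isotropic_scene, isotropic_render):
        img, _ = isotropic_render
        frame = AxisFrame(center=isotropic_scene.center)
        cell = measure_cell(img, frame, "center", 0.0)
        assert cell.direction == "center"
        assert cell.h == pytest.approx(30.0, abs=1.0)
        assert cell.w == pytest.approx(30.0, abs=1.0)

    def test_vertical_flip_swaps_superior_inferior(self, device_renders):
        spec, img, _ = device_renders["California"]
        flipped = np.flipud(img)
        frame = AxisFrame(center=spec.center)
        fframe = AxisFrame(center=(img.shape[0] - 1 - spec.center[0],
                                   spec.center[1]))
        for z in (40.0, 80.0):
            sup = measure_cell(img, frame, "superior", z)
            inf_f = measure_cell(flipped, fframe, "inferior", z)
            assert sup.h == pytest.approx(inf_f.h, abs=1e-6)
            assert sup.w == pytest.approx(inf_f.w, abs=1e-6)


class TestSampleStripes:
    def test_noiseless_levels_recovered_exactly(self, isotropic_scene,
                                                isotropic_render):
        img, _ = isotropic_render
        frame = AxisFrame(center=isotropic_scene.center)
        pair = sample_stripes(img, frame, "inferior", 40.0)
        assert pair.B == 40.0
        assert pair.W == 220.0

    def test_center_pair_reported_as_center(self, isotropic_scene,
                                            isotropic_render):
        img, _ = isotropic_render
        frame = AxisFrame(center=isotropic_scene.center)
        pair = sample_stripes(img, frame, "superior", 0.0)
        assert pair.direction == "center"
        assert pair.W == 220.0

    def test_noise_bound_on_stripe_mean(self):
        spec = make_scene(noise_sd=4.0, seed=11, max_angle=50.0)
        img, _ = render_scene(spec)
        frame = AxisFrame(center=spec.center)
        pair = sample_stripes(img, frame, "inferior", 40.0)
        # mean of 4 pixels with sd 4: |error| < 3 * 4/2 with high probability
        assert abs(pair.B - 40.0) < 6.0
        assert abs(pair.W - 220.0) < 6.0

    def test_unrendered_stripe_raises_range_error(self, isotropic_scene,
                                                  isotropic_render):
        img, _ = isotropic_render
        frame = AxisFrame(center=isotropic_scene.center)
        with pytest.raises((RangeError, MeasurementError)):
            sample_stripes(img, frame, "inferior", 105.0)


class TestFieldOfView:
    def test_full_contrast_tape_read_to_max_angle(self, isotropic_scene,
                                                  isotropic_render):
        img, _ = isotropic_render
        frame = AxisFrame(center=isotropic_scene.center)
        fov = max_field_of_view(img, frame)
        assert fov.degrees == {d: 85.0 for d in DIRECTIONS}

    def test_levels_converging_beyond_90_limits_fov(self):
        # stripes lose contrast beyond 90 degrees although the tape runs on
        levels = stripe_levels_from_samples(
            {0.0: (60.0, 200.0), 85.0: (60.0, 200.0), 90.0: (130.0, 130.0)},
            max_angle=105.0)
        spec = make_scene(f=6.5, max_angle=105.0)
        spec = spec.replace(stripe_levels={d: levels for d in DIRECTIONS})
        img, truth = render_scene(spec)
        frame = AxisFrame(center=spec.center)
        fov = max_field_of_view(img, frame)
        assert fov.degrees["inferior"] == 90.0
        assert truth.fov["inferior"] == 90.0

    def test_fov_non_increasing_in_threshold(self, device_renders):
        spec, img, _ = device_renders["200Tx"]
        frame = AxisFrame(center=spec.center)
        prev = None
        for thr in (0.005, 0.02, 0.05, 0.2, 0.6):
            fov = max_field_of_view(img, frame, readability_threshold=thr)
            if prev is not None:
                for d in DIRECTIONS:
                    assert fov.degrees[d] <= prev[d]
            prev = fov.degrees


class TestMeasureImage:
    def test_full_protocol_runs_without_errors(self, device_renders):
        for name, (spec, img, truth) in device_renders.items():
            m = measure_image(img)
            assert not m.errors
            assert {c.z for c in m.cells} == {0.0, 40.0, 80.0}
            assert m.fov.degrees == truth.fov

    def test_recovery_within_one_pixel_noiseless(self, device_renders):
        for name, (spec, img, truth) in device_renders.items():
            m = measure_image(img)
            for c in m.cells:
                t = truth.cells[(c.direction, c.z)]
                assert abs(c.h - t["h"]) < 1.0, (name, c)
                assert abs(c.w - t["w"]) < 1.0, (name, c)

    def test_failures_recorded_not_fatal(self, isotropic_render):
        img, _ = isotropic_render
        m = measure_image(img, geometry_positions=(0.0, 40.0, 100.0))
        assert m.errors  # z=100 is beyond the rendered range
        assert any(c.z == 40.0 for c in m.cells)
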