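"""Metric definitions, invariances and table assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fundusqc import (
    ValidationError,
    amplitude,
    amplitude_summary,
    aspect_ratio,
    build_metric_table,
    contrast,
    square_ratio,
    summarize_replicates,
    summarize_table,
)
from fundusqc.measurement import CellMeasure, StripePair
from fundusqc.synthetic_eye import DIRECTIONS

positive = st.floats(min_value=1e-3, max_value=1e3,
                     allow_nan=False, allow_infinity=False)


class TestElementaryMetrics:
    @pytest.mark.parametrize("h,w,expected", [
        (100.0, 100.0, 1.0), (89.0, 100.0, 0.89), (50.0, 40.0, 1.25),
    ])
    def test_aspect_ratio(self, h, w, expected):
        assert aspect_ratio(h, w) == pytest.approx(expected)

    @pytest.mark.parametrize("args,expected", [
        ((10, 10, 10, 10), 1.0), ((20, 20, 10, 10), 4.0),
        ((12, 15, 10, 10), 1.8),
    ])
    def test_square_ratio(self, args, expected):
        assert square_ratio(*args) == pytest.approx(expected)

    @pytest.mark.parametrize("B,W,expected", [
        (128.0, 128.0, 0.0), (150.0, 100.0, 0.2), (100.0, 150.0, 0.2),
    ])
    def test_contrast_absolute_value_convention(self, B, W, expected):
        assert contrast(B, W) == pytest.approx(expected)

    @pytest.mark.parametrize("bad_call", [
        lambda: aspect_ratio(0.0, 1.0),
        lambda: aspect_ratio(1.0, -2.0),
        lambda: square_ratio(1.0, 1.0, 0.0, 1.0),
        lambda: contrast(0.0, 0.0),
        lambda: contrast(300.0, 100.0),
    ])
    def test_domain_errors(self, bad_call):
        with pytest.raises(ValidationError):
            bad_call()

    @given(h=positive, w=positive, c=positive)
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, h, w, c):
        assert aspect_ratio(c * h, c * w) == pytest.approx(
            aspect_ratio(h, w), rel=1e-9)
        assert square_ratio(c * h, c * w, c * h, c * w) == 1.0

    @given(h=positive, w=positive)
    @settings(max_examples=50, deadline=None)
    def test_square_ratio_center_is_exactly_one(self, h, w):
        assert square_ratio(h, w, h, w) == 1.0


class TestAmplitude:
    def test_forty_degree_examples(self):
        assert amplitude({"superior": 0.79, "left": 1.01,
                          "inferior": 0.82, "right": 0.97}
                         ) == pytest.approx(0.22)
        assert amplitude({"superior": 0.93, "left": 1.04,
                          "inferior": 0.93, "right": 1.04}
                         ) == pytest.approx(0.11)

    def test_constant_input_gives_zero(self):
        assert amplitude({d: 1.0 for d in DIRECTIONS}) == 0.0

    def test_missing_direction_rejected(self):
        with pytest.raises(ValidationError):
            amplitude({"superior": 1.0, "left": 1.0, "inferior": 1.0})

    @given(st.permutations(["superior", "inferior", "left", "right"]),
           st.lists(positive, min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance(self, order, vals):
        base = dict(zip(DIRECTIONS, vals))
        permuted = dict(zip(order, vals))
        # same multiset of values in different direction slots: the spread
        # of values is unchanged
        assert amplitude(permuted) == pytest.approx(
            max(vals) - min(vals))
        assert amplitude(base) == pytest.approx(max(vals) - min(vals))


class TestSummaries:
    def test_constant_replicates(self):
        assert summarize_replicates([0.9] * 10) == (0.9, 0.0)

    def test_closed_form_sd(self):
        mean, sd = summarize_replicates([0.8, 1.0, 1.2])
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.2)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize_replicates([])


def _fake_measurement(scale=1.0, aniso=1.0, B=100.0, W=150.0):
    """Synthetic per-replicate measurement with analytic geometry."""
    cells = [CellMeasure("center", 0.0, 30.0 * scale, 30.0 * scale)]
    stripes = [StripePair("center", 0.0, B, W)]
    for z in (40.0, 80.0):
        grow = 1.0 + z / 200.0
        for d in DIRECTIONS:
            h = 30.0 * scale * grow * (aniso if d in ("superior", "inferior")
                                       else 1.0)
            w = 30.0 * scale * grow * (1.0 if d in ("superior", "inferior")
                                       else aniso)
            cells.append(CellMeasure(d, z, h, w))
            if z == 80.0:
                stripes.append(StripePair(d, z, B, W))
    return cells, stripes


class TestBuildMetricTable:
    def test_isotropic_measurements_give_unit_aspect(self):
        table = build_metric_table([_fake_measurement()])
        geom = table.data.dropna(subset=["aspect_ratio"])
        assert np.allclose(geom["aspect_ratio"], 1.0)
        center = table.data[table.data["direction"] == "center"]
        assert np.allclose(center["square_ratio"].dropna(), 1.0)

    def test_missing_center_rejected(self):
        cells, stripes = _fake_measurement()
        cells = [c for c in cells if c.direction != "center"]
        with pytest.raises(ValidationError, match="center"):
            build_metric_table([(cells, stripes)])

    def test_identical_replicates_have_zero_sd(self):
        table = build_metric_table([_fake_measurement()] * 10)
        assert table.n == 10
        summary = summarize_table(table)
        assert np.allclose(summary["aspect_ratio_sd"].dropna(), 0.0)

    def test_contrast_only_rows_present_at_80(self):
        table = build_metric_table([_fake_measurement()])
        at80 = table.data[table.data["z_deg"] == 80.0]
        assert at80["contrast"].notna().all()
        assert at80["contrast"].iloc[0] == pytest.approx(50.0 / 250.0)


class TestAmplitudeSummary:
    def test_anisotropy_produces_positive_amplitude(self):
        table = build_metric_table([_fake_measurement(aniso=0.8)
                                    for _ in range(5)])
        summaries = {(s.metric, s.z): s for s in amplitude_summary(table)}
        amp = summaries[("aspect_ratio", 40.0)]
        # vertical cells have aspect 0.8, horizontal 1/0.8 = 1.25
        assert amp.mean == pytest.approx(1.25 - 0.8, abs=1e-9)
        assert amp.sd == pytest.approx(0.0, abs=1e-12)
        assert amp.of_means == pytest.approx(amp.mean)

    def test_isotropic_amplitude_is_zero(self):
        table = build_metric_table([_fake_measurement()])
        for s in amplitude_summary(table):
            assert s.mean == 0.0
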