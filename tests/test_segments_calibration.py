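import math

import pytest

from hullbsp.mass_properties import BSPVector, PARAMETER_NAMES, mass_properties
from hullbsp.mesh_io import make_box
from hullbsp.segments_calibration import (
    APPENDICULAR_SEGMENTS,
    AXIAL_SEGMENTS,
    SEGMENT_NAMES,
    CalibrationModel,
    CalibrationTable,
    ExtrapolationWarning,
    SegmentLabel,
    load_bundled_table,
    mirror_bsp,
    mirror_model,
    predict_parameter,
    predict_segment,
)


@pytest.fixture(scope="module")
def table() -> CalibrationTable:
    return load_bundled_table()


def identity_table() -> CalibrationTable:
    t = CalibrationTable()
    for segment in SEGMENT_NAMES:
        side = "left" if segment in APPENDICULAR_SEGMENTS else "none"
        for parameter in PARAMETER_NAMES:
            transform = "log10" if parameter in ("mass", "ixx", "iyy", "izz") else "linear"
            t.add(CalibrationModel(segment, side, parameter, 0.0, 1.0, transform))
    return t


def sample_bsp(**overrides) -> BSPVector:
    base = dict(
        mass=2.0, cm_x=0.05, cm_y=0.01, cm_z=-0.02,
        ixx=0.004, iyy=0.005, izz=0.006,
        ixy=0.0002, ixz=-0.0001, iyz=0.00015, density=1000.0,
    )
    base.update(overrides)
    return BSPVector(**base)


class TestSegmentLabel:
    def test_thirteen_fit_keys(self):
        assert len(SEGMENT_NAMES) == 13
        assert len(APPENDICULAR_SEGMENTS) == 6
        assert len(AXIAL_SEGMENTS) == 7

    def test_axial_has_no_side(self):
        label = SegmentLabel("torso")
        assert label.is_axial
        assert label.segment_class == "axial"
        with pytest.raises(ValueError):
            SegmentLabel("torso", "left")

    def test_appendicular_needs_side(self):
        label = SegmentLabel("thigh", "left")
        assert label.segment_class == "appendicular"
        with pytest.raises(ValueError):
            SegmentLabel("thigh")

    def test_parse(self):
        assert SegmentLabel.parse("left_thigh") == SegmentLabel("thigh", "left")
        assert SegmentLabel.parse("right_arm") == SegmentLabel("arm", "right")
        assert SegmentLabel.parse("tail2") == SegmentLabel("tail2")
        with pytest.raises(ValueError):
            SegmentLabel.parse("left_torso")


class TestBundledTable:
    def test_130_models(self, table):
        assert len(table) == 130

    def test_all_cells_present(self, table):
        for segment in SEGMENT_NAMES:
            for parameter in PARAMETER_NAMES:
                table.get(segment, parameter)  # must not raise

    def test_transform_rule(self, table):
        for (segment, parameter), model in table.models.items():
            expected = "log10" if parameter in ("mass", "ixx", "iyy", "izz") else "linear"
            assert model.transform == expected, (segment, parameter)

    def test_left_thigh_mass_coefficients(self, table):
        model = table.get("thigh", "mass")
        assert model.intercept == pytest.approx(0.549)
        assert model.slope == pytest.approx(0.94)
        assert model.transform == "log10"

    def test_head_mass_coefficients(self, table):
        model = table.get("head", "mass")
        assert model.intercept == pytest.approx(0.106)
        assert model.slope == pytest.approx(0.93)

    def test_left_arm_mass_slope(self, table):
        assert table.get("arm", "mass").slope == pytest.approx(0.88)

    def test_cis_bracket_estimates(self, table):
        for (segment, parameter), model in table.models.items():
            ilo, ihi = model.intercept_ci
            slo, shi = model.slope_ci
            assert ilo <= ihi and slo <= shi
            # printed CIs should bracket the printed point estimates up to
            # their own rounding (3 s.f. / 2 d.p.)
            assert ilo - 5e-3 <= model.intercept <= ihi + 5e-3, (segment, parameter)
            assert slo - 5e-3 <= model.slope <= shi + 5e-3, (segment, parameter)

    def test_csv_roundtrip(self, table, tmp_path):
        path = tmp_path / "table.csv"
        table.to_csv(path)
        back = CalibrationTable.from_csv(path)
        assert len(back) == 130
        m0 = table.get("thigh", "mass")
        m1 = back.get("thigh", "mass")
        assert m1.intercept == m0.intercept
        assert m1.slope_ci == m0.slope_ci


class TestPredictParameter:
    def test_thigh_mass_at_1kg(self, table):
        model = table.get("thigh", "mass")
        assert predict_parameter(1.0, model) == pytest.approx(10**0.549, rel=1e-12)

    def test_linear_identity(self):
        model = CalibrationModel("torso", "none", "cm_x", 0.0, 1.0, "linear")
        for value in (-0.3, 0.0, 1.7):
            assert predict_parameter(value, model) == value

    def test_arm_mass_at_2kg(self, table):
        model = table.get("arm", "mass")
        expected = 10 ** (0.305 + 0.88 * math.log10(2.0))
        assert predict_parameter(2.0, model) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(3.716, abs=5e-3)

    def test_log_model_rejects_nonpositive(self, table):
        with pytest.raises(ValueError):
            predict_parameter(0.0, table.get("thigh", "mass"))

    def test_log_monotonicity(self, table):
        model = table.get("thigh", "mass")
        values = [predict_parameter(v, model) for v in (0.5, 1.0, 2.0, 4.0)]
        assert values == sorted(values)


class TestMirrorModel:
    def test_caption_example(self):
        model = CalibrationModel("arm", "left", "cm_y", 1.55e-3, 0.97, "linear")
        mirrored = mirror_model(model)
        assert mirrored.intercept == pytest.approx(-1.55e-3)
        assert mirrored.slope == 0.97
        assert mirrored.side == "right"

    def test_involution(self):
        from dataclasses import replace

        model = CalibrationModel(
            "arm", "left", "iyz", -1.23e-3, 1.84, "linear", intercept_ci=(-2e-3, -1e-3)
        )
        # mirror, relabel as left, mirror again: coefficients must return
        twice = mirror_model(replace(mirror_model(model), side="left"))
        assert twice.intercept == model.intercept
        assert twice.intercept_ci == model.intercept_ci
        assert twice.slope == model.slope

    def test_non_mirrored_parameter_unchanged(self, table):
        model = table.get("arm", "mass")
        mirrored = mirror_model(model)
        assert mirrored.intercept == model.intercept
        assert mirrored.slope == model.slope
        assert mirrored.side == "right"

    def test_rejects_non_left(self):
        model = CalibrationModel("torso", "none", "cm_y", 1e-3, 1.0, "linear")
        with pytest.raises(ValueError):
            mirror_model(model)


class TestMirrorBsp:
    def test_symmetric_fixed_point(self):
        bsp = sample_bsp(cm_y=0.0, ixy=0.0, iyz=0.0)
        assert mirror_bsp(bsp) == bsp

    def test_involution(self):
        bsp = sample_bsp()
        assert mirror_bsp(mirror_bsp(bsp)) == bsp

    def test_shifted_cube(self):
        mesh = make_box((1, 1, 1), (0.0, 2.0, 0.0))
        bsp = mass_properties(mesh)
        mirrored = mirror_bsp(bsp)
        assert mirrored.cm_y == pytest.approx(-bsp.cm_y)
        assert mirrored.cm_x == bsp.cm_x
        assert mirrored.mass == bsp.mass


class TestPredictSegment:
    def test_identity_table_is_identity(self):
        bsp = sample_bsp()
        predicted = predict_segment(bsp, SegmentLabel("thigh", "left"), identity_table())
        for name in PARAMETER_NAMES:
            assert predicted.get(name) == pytest.approx(bsp.get(name), rel=1e-12)

    def test_axial_zeroing(self, table):
        bsp = sample_bsp()
        predicted = predict_segment(bsp, SegmentLabel("torso"), table, zero_axial=True)
        assert predicted.cm_y == 0.0
        assert predicted.ixy == 0.0
        assert predicted.iyz == 0.0
        assert predicted.mass > 0

    def test_axial_without_flag_keeps_values(self, table):
        bsp = sample_bsp()
        predicted = predict_segment(bsp, SegmentLabel("torso"), table, zero_axial=False)
        assert predicted.cm_y != 0.0

    def test_mirror_consistency(self, table):
        bsp = sample_bsp()
        right = predict_segment(bsp, SegmentLabel("thigh", "right"), table)
        left_of_mirror = predict_segment(mirror_bsp(bsp), SegmentLabel("thigh", "left"), table)
        expected = mirror_bsp(left_of_mirror)
        for name in PARAMETER_NAMES:
            assert right.get(name) == pytest.approx(expected.get(name), rel=1e-12), name

    def test_extrapolation_warning(self, table):
        heavy = sample_bsp(mass=5e4, ixx=1e4, iyy=1e4, izz=1e4)
        with pytest.warns(ExtrapolationWarning):
            predict_segment(heavy, SegmentLabel("torso"), table)

    def test_zero_axial_not_applied_to_limbs(self, table):
        bsp = sample_bsp()
        predicted = predict_segment(bsp, SegmentLabel("thigh", "left"), table, zero_axial=True)
        assert predicted.cm_y != 0.0
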